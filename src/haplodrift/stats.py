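"""Population diversity statistics on masked alignments.

Implements the standard summary statistics for a set of aligned haploid
sequences:

* ``S`` — number of segregating columns (a column with any number of
  alternative states counts once),
* Watterson's estimator ``theta_w = S / (a1 * L)`` with
  ``a1 = sum_{i=1}^{n-1} 1/i`` (per site),
* nucleotide diversity ``pi`` — mean pairwise difference per site — with
  its standard deviation from the Nei (1987) total-variance estimator
  (sampling plus stochastic variance),
* Tajima's D with the constants of the original 1989 definition, and a
  deterministic two-sided significance call from the beta-distribution
  approximation of its null.

All statistics are computed after complete deletion: columns containing a
gap or ambiguous base in any sequence are removed first, and the analyzed
length ``L`` refers to the retained columns only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .alignment import MaskedAlignment

__all__ = [
    "TajimaConstants",
    "DiversityStats",
    "segregating_sites",
    "nucleotide_diversity",
    "watterson_theta",
    "tajimas_d",
    "tajimas_d_from_summary",
    "tajima_significance",
    "diversity_stats",
]


@dataclass(frozen=True)
class TajimaConstants:
    """The n-dependent constants of Tajima's D (Tajima 1989)."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def from_n(cls, n: int) -> "TajimaConstants":
        if n < 2:
            raise ValueError("Tajima constants require n >= 2")
        a1 = sum(1.0 / i for i in range(1, n))
        a2 = sum(1.0 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def _clean(masked: MaskedAlignment) -> MaskedAlignment:
    clean = masked.complete_deletion()
    if clean.L == 0:
        raise ValueError("no fully resolved columns left after complete deletion")
    return clean


def _column_base_counts(matrix: np.ndarray) -> np.ndarray:
    """(4, L) counts of A/C/G/T per column; matrix must be gap-free."""
    return np.stack([(matrix == base).sum(axis=0) for base in (b"A", b"C", b"G", b"T")])


def segregating_sites(masked: MaskedAlignment) -> int:
    """Number of columns with more than one nucleotide state."""
    if masked.n < 2:
        raise ValueError("segregating sites require n >= 2 sequences")
    counts = _column_base_counts(_clean(masked).matrix)
    return int(((counts > 0).sum(axis=0) > 1).sum())


def _total_pairwise_differences(matrix: np.ndarray) -> int:
    """Sum over all sequence pairs of per-pair differences (gap-free input).

    Uses the identity: differences in a column = C(n,2) - sum_b C(count_b,2).
    """
    n = matrix.shape[0]
    counts = _column_base_counts(matrix)
    same = (counts * (counts - 1) // 2).sum()
    total_pairs_per_col = n * (n - 1) // 2
    return int(total_pairs_per_col * matrix.shape[1] - same)


def nucleotide_diversity(masked: MaskedAlignment) -> tuple[float, float]:
    """Nucleotide diversity per site and its standard deviation.

    Returns ``(pi, sd_pi)`` where ``pi`` is the mean pairwise difference
    divided by the analyzed length and ``sd_pi`` is the square root of the
    Nei (1987, eq. 10.7) total variance
    ``V = b1 * pi / L + b2 * pi**2`` with ``b1 = (n+1)/(3(n-1))`` and
    ``b2 = 2(n^2+n+3)/(9n(n-1))``.
    """
    if masked.n < 2:
        raise ValueError("nucleotide diversity requires n >= 2 sequences")
    clean = _clean(masked)
    n, L = clean.n, clean.L
    diffs = _total_pairwise_differences(clean.matrix)
    pairs = n * (n - 1) // 2
    pi = diffs / (pairs * L)
    const = TajimaConstants.from_n(n)
    variance = const.b1 * pi / L + const.b2 * pi**2
    return pi, math.sqrt(variance)


def watterson_theta(masked: MaskedAlignment) -> float:
    """Watterson's theta per site: S / (a1 * L)."""
    if masked.n < 2:
        raise ValueError("Watterson's theta requires n >= 2 sequences")
    clean = _clean(masked)
    S = segregating_sites(clean)
    if S == 0:
        return 0.0
    const = TajimaConstants.from_n(clean.n)
    return S / (const.a1 * clean.L)


def tajimas_d_from_summary(n: int, S: int, mean_pairwise_k: float) -> float:
    """Tajima's D from the summary triple (n, S, mean pairwise differences).

    ``mean_pairwise_k`` is the mean *count* of pairwise differences
    (``pi * L``), not the per-site value; D is scale-free in L.
    Returns NaN when undefined (n < 4 or S = 0), matching the convention of
    reporting "NA" rather than 0 for uninformative groups.
    """
    if n < 4 or S == 0:
        return float("nan")
    const = TajimaConstants.from_n(n)
    num = mean_pairwise_k - S / const.a1
    den = math.sqrt(const.e1 * S + const.e2 * S * (S - 1))
    return num / den


def tajimas_d(masked: MaskedAlignment) -> float:
    """Tajima's D of an alignment; NaN when undefined (n < 4 or S = 0)."""
    if masked.n < 2:
        raise ValueError("Tajima's D requires n >= 2 sequences")
    clean = _clean(masked)
    S = segregating_sites(clean)
    pairs = clean.n * (clean.n - 1) // 2
    k = _total_pairwise_differences(clean.matrix) / pairs
    return tajimas_d_from_summary(clean.n, S, k)


def _beta_null(n: int) -> tuple[float, float, float, float]:
    """Support and shape parameters of the beta approximation of D's null.

    D is assumed to range over (Dmin, Dmax) with
    ``Dmin = (2/n - 1/a1)/sqrt(e2)`` and ``Dmax = ((n+1)/(2n) - 1/a1)/sqrt(e2)``,
    and to follow a scaled beta with mean 0 and variance 1 there
    (Tajima 1989), giving shape parameters
    ``alpha = -(1 + Dmin*Dmax)*Dmax/(Dmax - Dmin)`` and
    ``beta  =  (1 + Dmin*Dmax)*Dmin/(Dmax - Dmin)``.
    """
    const = TajimaConstants.from_n(n)
    root_e2 = math.sqrt(const.e2)
    d_min = (2.0 / n - 1.0 / const.a1) / root_e2
    d_max = ((n + 1) / (2.0 * n) - 1.0 / const.a1) / root_e2
    span = d_max - d_min
    alpha = -(1.0 + d_min * d_max) * d_max / span
    beta = (1.0 + d_min * d_max) * d_min / span
    return d_min, d_max, beta, alpha


def tajima_d_null_interval(n: int, alpha_level: float = 0.05) -> tuple[float, float]:
    """Two-sided (1 - alpha_level) interval of D under the beta null."""
    d_min, d_max, shape_low, shape_high = _beta_null(n)
    dist = sps.beta(shape_low, shape_high, loc=d_min, scale=d_max - d_min)
    return dist.ppf(alpha_level / 2.0), dist.ppf(1.0 - alpha_level / 2.0)


def tajima_significance(
    tajima_d: float, n: int, alpha_level: float = 0.05
) -> bool | None:
    """Whether D falls outside the two-sided null interval.

    Returns ``None`` when D is undefined (NaN).  Deterministic: uses the
    beta-distribution approximation of the null, not a simulated null.
    """
    if tajima_d is None or (isinstance(tajima_d, float) and math.isnan(tajima_d)):
        return None
    low, high = tajima_d_null_interval(n, alpha_level)
    return bool(tajima_d < low or tajima_d > high)


@dataclass(frozen=True)
class DiversityStats:
    """One row of a per-group diversity summary table."""

    group: str
    n: int
    L: int
    S: int
    theta_w: float
    pi: float
    sd_pi: float
    tajima_d: float
    significant: bool | None


def diversity_stats(masked: MaskedAlignment, group: str = "all") -> DiversityStats:
    """All statistics for one sequence group, sharing one complete-deletion pass."""
    if masked.n < 2:
        raise ValueError("diversity statistics require n >= 2 sequences")
    clean = _clean(masked)
    S = segregating_sites(clean)
    pi, sd_pi = nucleotide_diversity(clean)
    theta = watterson_theta(clean)
    d = tajimas_d(clean)
    sig = tajima_significance(d, clean.n)
    if clean.n == 3 and not math.isnan(d):  # defensive; n<4 already yields NaN
        warnings.warn("Tajima's D undefined for n=3")
    return DiversityStats(
        group=group, n=clean.n, L=clean.L, S=S,
        theta_w=theta, pi=pi, sd_pi=sd_pi, tajima_d=d, significant=sig,
    )
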