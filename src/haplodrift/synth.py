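"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all bit-reproducible given a seed:

* a neutral constant-size coalescent producing haploid sequence alignments
  with a known population-scaled mutation parameter theta (infinite-sites
  mutations placed on distinct columns), for testing the diversity
  statistics against their theoretical expectations
  (E[S] = theta * a1, E[pi * L] = theta);
* haplogroup sample tables with configurable east/west focal-haplogroup
  frequencies, for the contingency analysis;
* noisy (generation, Ne) anchor points from a known sigmoid truth curve,
  resembling per-phase archaeological population estimates, for testing
  trajectory fitting.

The default anchor generations are the six Jomon phase boundaries
(Incipient through Final, 16500/11300/7100/5400/4400/3200/2400 years ago)
converted at 25 years per generation with generation 0 at 25000 ya.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb, log, sqrt

import numpy as np
import pandas as pd

from .alignment import MaskedAlignment
from .contingency import HaplogroupTable
from .demography import SigmoidCurve

__all__ = [
    "CoalescentSpec",
    "AnchorSpec",
    "JOMON_PHASE_GENERATIONS",
    "simulate_coalescent_alignment",
    "make_haplogroup_table",
    "make_sigmoid_anchors",
]

#: Jomon phase boundaries (years ago) -> generations at 25 y/gen, origin 25000 ya.
JOMON_PHASE_BOUNDARIES_YA = (16500, 11300, 7100, 5400, 4400, 3200, 2400)
JOMON_PHASE_GENERATIONS = tuple(
    round((25000 - ya) / 25) for ya in JOMON_PHASE_BOUNDARIES_YA
)  # (340, 548, 716, 784, 824, 872, 904)

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


@dataclass(frozen=True)
class CoalescentSpec:
    """Constant-size neutral coalescent fixture parameters."""

    n: int
    theta: float
    L: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 samples")
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        if self.L < 1:
            raise ValueError("L must be >= 1")


def _simulate_tree(n: int, rng: np.random.Generator):
    """Kingman coalescent: returns (children, branch_lengths, leaf sets).

    Nodes 0..n-1 are tips; each coalescence appends a node.  Branch length
    of node v is the time from v to its parent, in coalescent units of
    2N generations (so the mutation rate per branch is theta/2 per unit).
    """
    times = [0.0] * n
    node_leaves: list[set[int]] = [{i} for i in range(n)]
    active = list(range(n))
    t = 0.0
    branch_end: dict[int, float] = {}
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(1.0 / comb(k, 2))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        branch_end[a] = t
        branch_end[b] = t
        times.append(t)
        node_leaves.append(node_leaves[a] | node_leaves[b])
        active = [v for v in active if v not in (a, b)]
        active.append(len(times) - 1)
    lengths = {v: branch_end[v] - times[v] for v in branch_end}
    return lengths, node_leaves


def simulate_coalescent_alignment(
    spec: CoalescentSpec,
) -> tuple[MaskedAlignment, dict]:
    """Neutral alignment with infinite-sites mutations on distinct columns.

    Coalescence times are exponential with rate C(k,2) on the scaled
    clock; each branch receives Poisson(theta/2 * length) mutations, and
    every mutation occupies its own uniformly chosen unused column (a
    derived base differing from the ancestral 'A').  Exceeding ``L``
    distinct columns is an error instructing a larger ``L``, never a
    silent recurrent mutation.

    Returns the alignment and a summary with the realized segregating-site
    count and total tree length.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n, spec.L
    matrix = np.full((n, L), b"A", dtype="S1")
    total_len = 0.0
    mutated_cols: list[int] = []
    if spec.theta > 0:
        lengths, node_leaves = _simulate_tree(n, rng)
        total_len = sum(lengths.values())
        n_mut_per_branch = {
            v: rng.poisson(spec.theta / 2.0 * ell) for v, ell in lengths.items()
        }
        n_mut = int(sum(n_mut_per_branch.values()))
        if n_mut > L:
            raise ValueError(
                f"{n_mut} mutations exceed L={L} columns under infinite "
                "sites; rerun with a larger L"
            )
        columns = rng.choice(L, size=n_mut, replace=False)
        mutated_cols = [int(c) for c in columns]
        idx = 0
        for v, m in n_mut_per_branch.items():
            carriers = sorted(node_leaves[v])
            for _ in range(m):
                col = columns[idx]
                idx += 1
                derived = _BASES[1 + rng.integers(3)]  # C/G/T, never ancestral A
                matrix[carriers, col] = derived
    alignment = MaskedAlignment(
        sample_ids=[f"sample{i + 1}" for i in range(n)],
        matrix=matrix,
        positions=np.arange(1, L + 1),
    )
    distinct_states = len({tuple(matrix[:, c]) for c in mutated_cols})
    info = {
        "realized_mutations": len(mutated_cols),
        "realized_S": sum(
            1 for c in mutated_cols if len(set(matrix[:, c])) > 1
        ),
        "total_tree_length": total_len,
        "distinct_patterns": distinct_states,
    }
    return alignment, info


def make_haplogroup_table(
    n_east: int,
    n_west: int,
    f_east_n9b: float,
    f_west_n9b: float,
    seed: int | None = None,
    boundary: str = "chubu_kinki",
) -> HaplogroupTable:
    """Random sample table: per-region binomial N9b/M7a labels."""
    if n_east < 0 or n_west < 0:
        raise ValueError("sample counts must be non-negative")
    for f in (f_east_n9b, f_west_n9b):
        if not 0.0 <= f <= 1.0:
            raise ValueError("frequencies must be in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for region, n, f in (("east", n_east, f_east_n9b), ("west", n_west, f_west_n9b)):
        labels = np.where(rng.random(n) < f, "N9b", "M7a")
        for i, hg in enumerate(labels):
            rows.append(
                {
                    "individual_id": f"{region}_{i + 1:03d}",
                    "site_id": f"{region}_synthetic_site",
                    "region": region,
                    "haplogroup": str(hg),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["individual_id", "site_id", "region", "haplogroup"]
    )
    return HaplogroupTable(data=frame, boundary=boundary)


@dataclass(frozen=True)
class AnchorSpec:
    """Noisy per-phase (generation, Ne) anchor generator parameters."""

    truth: SigmoidCurve
    phase_generations: tuple[int, ...] = field(default=JOMON_PHASE_GENERATIONS)
    noise_cv: float = 0.0
    seed: int | None = None
    one_tenth_scaling: bool = False

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")


def make_sigmoid_anchors(spec: AnchorSpec) -> list[tuple[int, float]]:
    """Truth curve at the phase generations times mean-1 lognormal noise.

    With ``one_tenth_scaling`` the anchors are divided by 10, emulating
    the census-to-effective conversion applied to archaeological
    population estimates.
    """
    rng = np.random.default_rng(spec.seed)
    gens = spec.phase_generations
    values = np.array([spec.truth(g) for g in gens], dtype=float)
    if spec.noise_cv > 0:
        sigma = sqrt(log(1.0 + spec.noise_cv**2))
        values = values * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=len(gens))
    if spec.one_tenth_scaling:
        values = values / 10.0
    return [(int(g), float(v)) for g, v in zip(gens, values)]
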