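"""Demographic scenario description: sigmoid Ne trajectories and the
two-deme split model.

The simulated scenario is a single panmictic common ancestral population
(CAP) of constant haploid effective size that, at a fixed generation,
splits into an eastern and a western deme.  Post-split effective sizes
follow per-deme sigmoid (four-parameter logistic) curves

    N(t) = A + (K - A) / (1 + exp(-r (t - t0)))

fitted by least squares to archaeologically informed anchor points
(per-phase population estimates, optionally scaled by the conventional
one-tenth census-to-effective rule).  Time is measured in generations
(default 25 years each) counted forward from the start of the scenario.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

__all__ = [
    "SigmoidCurve",
    "SigmoidFit",
    "fit_sigmoid",
    "DemographyModel",
    "MigrationScheme",
    "ne_at",
]


@dataclass(frozen=True)
class SigmoidCurve:
    """Four-parameter logistic size trajectory.

    Parameters
    ----------
    A : floor (individuals), ``0 < A <= K``
    K : ceiling (individuals)
    r : rate per generation; positive for growth, 0 gives the constant
        curve ``(A + K) / 2``
    t0 : midpoint generation
    """

    A: float
    K: float
    r: float
    t0: float

    def __post_init__(self) -> None:
        if not (self.K >= self.A > 0):
            raise ValueError(f"require K >= A > 0; got A={self.A}, K={self.K}")

    def __call__(self, t):
        from scipy.special import expit  # overflow-safe logistic

        t = np.asarray(t, dtype=float)
        value = self.A + (self.K - self.A) * expit(self.r * (t - self.t0))
        return float(value) if value.ndim == 0 else value

    @classmethod
    def constant(cls, ne: float) -> "SigmoidCurve":
        """A flat trajectory at ``ne`` (r = 0 makes the logistic constant)."""
        return cls(A=float(ne), K=float(ne), r=0.0, t0=0.0)


@dataclass(frozen=True)
class SigmoidFit:
    """A fitted curve plus its root-mean-square residual in individuals."""

    curve: SigmoidCurve
    rms_residual: float
    n_anchors: int

    def __call__(self, t):
        return self.curve(t)


class SigmoidFitError(RuntimeError):
    """Least-squares fit failed to converge; carries the residual trace."""

    def __init__(self, message: str, residuals: np.ndarray | None = None):
        super().__init__(message)
        self.residuals = residuals


def _logistic(t, A, K, r, t0):
    from scipy.special import expit

    return A + (K - A) * expit(r * (t - t0))


def fit_sigmoid(anchors: Sequence[tuple[float, float]]) -> SigmoidFit:
    """Least-squares fit of a four-parameter logistic to (generation, Ne) anchors.

    Requires at least 4 anchors with strictly increasing generations (four
    free parameters).  Initialization is deterministic: the floor and
    ceiling start at the extreme anchor values, the midpoint at the
    generation where the anchors cross their half range, and the rate from
    the steepest observed inter-anchor slope.  A set of anchors with
    (near-)zero spread is fitted as a constant curve directly, which the
    optimizer cannot distinguish from any r = 0 solution.
    """
    pts = sorted((float(g), float(ne)) for g, ne in anchors)
    if len(pts) < 4:
        raise SigmoidFitError(f"need >= 4 anchors, got {len(pts)}")
    gens = np.array([p[0] for p in pts])
    nes = np.array([p[1] for p in pts])
    if np.any(np.diff(gens) <= 0):
        raise SigmoidFitError("anchor generations must be strictly increasing")
    if np.any(nes <= 0):
        raise SigmoidFitError("anchor Ne values must be positive")

    spread = nes.max() - nes.min()
    if spread <= 1e-9 * max(1.0, nes.mean()):
        mean = float(nes.mean())
        return SigmoidFit(SigmoidCurve.constant(mean), rms_residual=float(
            np.sqrt(np.mean((nes - mean) ** 2))), n_anchors=len(pts))

    a0, k0 = float(nes.min()), float(nes.max())
    half = (a0 + k0) / 2.0
    t0_0 = float(np.interp(half, nes, gens)) if nes[0] < nes[-1] else float(
        np.interp(half, nes[::-1], gens[::-1]))
    slopes = np.diff(nes) / np.diff(gens)
    steepest = float(slopes[np.argmax(np.abs(slopes))])
    r0 = 4.0 * steepest / spread  # logistic max slope = r (K - A) / 4
    if r0 == 0.0:
        r0 = 1.0 / (gens[-1] - gens[0])

    try:
        params, _ = curve_fit(
            _logistic, gens, nes,
            p0=[a0, k0, r0, t0_0],
            bounds=([1e-9, 1e-9, -np.inf, -np.inf], [np.inf] * 4),
            maxfev=20000,
        )
    except RuntimeError as err:
        residuals = nes - _logistic(gens, a0, k0, r0, t0_0)
        raise SigmoidFitError(f"sigmoid fit did not converge: {err}", residuals)

    A, K, r, t0 = (float(v) for v in params)
    if K < A:  # optimizer may swap roles when r flips sign
        A, K, r = K, A, -r
        t0 = t0  # midpoint unchanged under the (A,K,r) reflection
    curve = SigmoidCurve(A=A, K=K, r=r, t0=t0)
    rms = float(np.sqrt(np.mean((nes - curve(gens)) ** 2)))
    logger.info("sigmoid fit: A=%.4g K=%.4g r=%.4g t0=%.4g rms=%.4g", A, K, r, t0, rms)
    return SigmoidFit(curve=curve, rms_residual=rms, n_anchors=len(pts))


@dataclass(frozen=True)
class MigrationScheme:
    """Symmetric scheduled migration between the two demes.

    ``rate`` is the fraction of a deme's current Ne that emigrates at each
    migration event; ``interval`` is the number of generations between
    events.  Events fire at generations ``t > split`` with
    ``(t - split) % interval == 0``.  A per-event migrant count is
    ``round(rate * Ne)`` and may be zero for small ``rate * Ne``; the
    effective per-generation migration pressure is ``rate / interval``.
    """

    rate: float = 0.0
    interval: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 0.5:
            raise ValueError("migration rate must be in [0, 0.5)")
        if self.interval < 1:
            raise ValueError("migration interval must be >= 1 generation")

    def fires_at(self, generation: int, split_generation: int) -> bool:
        return (
            self.rate > 0.0
            and generation > split_generation
            and (generation - split_generation) % self.interval == 0
        )


@dataclass(frozen=True)
class DemographyModel:
    """Complete two-deme scenario: CAP phase, split, per-deme Ne curves.

    Defaults mirror a 1000-generation scenario at 25 years per generation
    (generation 0 = 25000 years before present): a 100-generation CAP, a
    split at generation 100, and haplogroup frequencies starting at 0.5.
    """

    cap_ne: int = 5000
    cap_generations: int = 100
    total_generations: int = 1000
    generation_time: float = 25.0
    split_ratio: float = 0.5
    east_curve: SigmoidCurve | None = None
    west_curve: SigmoidCurve | None = None
    p0: float = 0.5
    split_tolerance: float = field(default=0.25, repr=False)

    def __post_init__(self) -> None:
        if self.cap_ne < 2:
            raise ValueError("cap_ne must be >= 2")
        if not 0.0 < self.split_ratio < 1.0:
            raise ValueError("split_ratio must be strictly between 0 and 1")
        if not 0.0 <= self.p0 <= 1.0:
            raise ValueError("p0 must be in [0, 1]")
        if not 0 < self.cap_generations < self.total_generations:
            raise ValueError("require 0 < cap_generations < total_generations")
        if self.east_curve is None:
            object.__setattr__(
                self, "east_curve",
                SigmoidCurve.constant(max(2, round(self.split_ratio * self.cap_ne))),
            )
        if self.west_curve is None:
            object.__setattr__(
                self, "west_curve",
                SigmoidCurve.constant(
                    max(2, round((1 - self.split_ratio) * self.cap_ne))
                ),
            )
        # Curves fitted to anchors need not hit the split sizes exactly;
        # log the mismatch rather than forcing continuity.
        for deme, curve, target in (
            ("east", self.east_curve, self.split_ratio * self.cap_ne),
            ("west", self.west_curve, (1 - self.split_ratio) * self.cap_ne),
        ):
            value = curve(self.split_generation)
            rel = abs(value - target) / max(target, 1.0)
            if rel > self.split_tolerance:
                logger.warning(
                    "%s curve at split generation %d gives Ne=%.1f vs "
                    "cap_ne*ratio=%.1f (relative mismatch %.2f)",
                    deme, self.split_generation, value, target, rel,
                )

    @property
    def split_generation(self) -> int:
        """The split coincides with the end of the CAP phase."""
        return self.cap_generations

    def years_before_present(self, generation: int, origin_ybp: float = 25000.0) -> float:
        return origin_ybp - generation * self.generation_time


def ne_at(model: DemographyModel, generation: int, deme: str) -> int:
    """Haploid effective size of a deme at a generation.

    Before the split every deme sees the CAP size; from the split onward
    the deme's sigmoid curve is evaluated, rounded to the nearest integer,
    and floored at 2 (a deme never drops below one reproducing pair of
    lineages).
    """
    if not 0 <= generation < model.total_generations:
        raise ValueError(
            f"generation {generation} outside [0, {model.total_generations})"
        )
    if deme not in ("east", "west"):
        raise ValueError(f"unknown deme {deme!r}; expected 'east' or 'west'")
    if generation < model.split_generation:
        return model.cap_ne
    curve = model.east_curve if deme == "east" else model.west_curve
    return max(2, int(round(curve(generation))))
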