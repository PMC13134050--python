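"""Forward-time Wright-Fisher simulation of two haplogroup frequencies.

A haploid population carries two mitochondrial haplogroups (tracked as the
count of the focal one, "N9b").  Each generation the next count is a
binomial draw from the current frequency, with the trial number set by the
next generation's effective size — pure genetic drift, no mutation or
selection.  The scenario (CAP phase, split, per-deme Ne trajectories) comes
from :class:`~haplodrift.demography.DemographyModel`; scheduled symmetric
migration exchanges a fixed fraction of each deme.

Timeline convention: the generation-0 state is the initial frequency;
drift updates happen at generations 1 .. split-1 within the CAP; at the
split generation each deme's count is drawn binomially from the final CAP
frequency (the split event itself contributes drift); from the next
generation on, each deme drifts independently, with migration applied
after the drift update of any generation ``t > split`` where
``(t - split) % interval == 0``.

The engine is vectorized over trials: ``count`` arguments may be numpy
arrays of per-trial counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .demography import DemographyModel, MigrationScheme, ne_at

__all__ = [
    "wf_step",
    "apply_migration",
    "run_trial",
    "estimate_probability",
    "run_grid",
    "GridConfig",
    "SimulationResult",
    "wilson_interval",
]

DEFAULT_CHECKPOINTS = (400, 500, 600, 700, 800, 900)


def wf_step(count, ne_now: int, ne_next: int, rng: np.random.Generator):
    """One Wright-Fisher generation: Binomial(ne_next, count / ne_now).

    ``count`` may be a scalar or an array of per-trial counts; frequencies
    0 and 1 are absorbing (degenerate binomial draws).
    """
    if ne_now <= 0:
        raise ValueError("ne_now must be positive")
    count_arr = np.asarray(count)
    if np.any(count_arr < 0) or np.any(count_arr > ne_now):
        raise ValueError("count must lie in [0, ne_now]")
    draw = rng.binomial(ne_next, count_arr / ne_now)
    return int(draw) if np.isscalar(count) else draw


def apply_migration(
    east: tuple, west: tuple, scheme: MigrationScheme, rng: np.random.Generator
) -> tuple[tuple, tuple]:
    """Symmetric simultaneous exchange between the demes.

    Each deme emits ``round(rate * Ne)`` individuals; the haplogroup
    composition of a migrant group is drawn Binomial(n_migrants, f_source)
    from the pre-migration source frequency, truncated to the compositions
    actually available in the source deme (only relevant at very small
    Ne).  Receiving-deme count and Ne are updated; total individuals are
    conserved.

    Parameters are ``(count, ne)`` pairs; ``count`` may be an array.
    """
    (count_e, ne_e), (count_w, ne_w) = east, west
    n_e = int(round(scheme.rate * ne_e))
    n_w = int(round(scheme.rate * ne_w))
    if n_e > ne_e or n_w > ne_w:
        raise ValueError("migrant count exceeds deme size")
    if n_e == 0 and n_w == 0:
        return (count_e, ne_e), (count_w, ne_w)

    count_e = np.asarray(count_e)
    count_w = np.asarray(count_w)
    sent_e = rng.binomial(n_e, count_e / ne_e)
    sent_w = rng.binomial(n_w, count_w / ne_w)
    # Feasibility truncation: a migrant group cannot carry more copies of
    # the focal haplogroup than the deme holds, nor leave behind more
    # copies than residents remain.
    sent_e = np.clip(sent_e, np.maximum(0, count_e - (ne_e - n_e)), np.minimum(n_e, count_e))
    sent_w = np.clip(sent_w, np.maximum(0, count_w - (ne_w - n_w)), np.minimum(n_w, count_w))

    new_count_e = count_e - sent_e + sent_w
    new_count_w = count_w - sent_w + sent_e
    new_ne_e = ne_e - n_e + n_w
    new_ne_w = ne_w - n_w + n_e
    return (new_count_e, new_ne_e), (new_count_w, new_ne_w)


def _simulate_batch(
    model: DemographyModel,
    scheme: MigrationScheme,
    n_trials: int,
    rng: np.random.Generator,
    checkpoints: Sequence[int] = (),
    record: bool = False,
):
    """Core loop shared by single-trajectory and Monte-Carlo entry points.

    Returns ``(checkpoint_diffs, trajectory_rows, final_state)`` where
    ``checkpoint_diffs`` maps generation -> array of (f_east - f_west),
    ``trajectory_rows`` is populated only when ``record`` is set, and
    ``final_state`` is ``(count_east, ne_east, count_west, ne_west)`` at
    the last simulated generation (counts are per-trial arrays).
    """
    split = model.split_generation
    for cp in checkpoints:
        if not split < cp < model.total_generations:
            raise ValueError(
                f"checkpoint {cp} outside ({split}, {model.total_generations})"
            )
    rows: list[tuple] = []
    cap_ne = model.cap_ne
    count = np.full(n_trials, int(round(model.p0 * cap_ne)), dtype=np.int64)
    if record:
        rows.append((0, "cap", cap_ne, count.copy()))
    for t in range(1, split):
        count = rng.binomial(cap_ne, count / cap_ne)
        if record:
            rows.append((t, "cap", cap_ne, count.copy()))

    f_cap = count / cap_ne
    ne_e = ne_at(model, split, "east")
    ne_w = ne_at(model, split, "west")
    count_e = rng.binomial(ne_e, f_cap)
    count_w = rng.binomial(ne_w, f_cap)

    wanted = set(checkpoints)
    diffs: dict[int, np.ndarray] = {}

    def snapshot(t: int) -> None:
        if record:
            rows.append((t, "east", ne_e, count_e.copy()))
            rows.append((t, "west", ne_w, count_w.copy()))
        if t in wanted:
            diffs[t] = count_e / ne_e - count_w / ne_w

    snapshot(split)
    for t in range(split + 1, model.total_generations):
        ne_e_next = ne_at(model, t, "east")
        ne_w_next = ne_at(model, t, "west")
        count_e = rng.binomial(ne_e_next, count_e / ne_e)
        count_w = rng.binomial(ne_w_next, count_w / ne_w)
        ne_e, ne_w = ne_e_next, ne_w_next
        if scheme.fires_at(t, split):
            (count_e, ne_e), (count_w, ne_w) = apply_migration(
                (count_e, ne_e), (count_w, ne_w), scheme, rng
            )
        snapshot(t)
    return diffs, rows, (count_e, ne_e, count_w, ne_w)


def run_trial(
    model: DemographyModel,
    scheme: MigrationScheme | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """One full trajectory as a tidy frame.

    Columns: ``generation, deme, ne, count_n9b, freq_n9b``; the CAP phase
    appears as deme ``"cap"``, post-split generations as ``"east"`` and
    ``"west"``.
    """
    scheme = scheme or MigrationScheme()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    _, rows, _ = _simulate_batch(model, scheme, 1, rng, record=True)
    frame = pd.DataFrame(
        [(t, deme, ne, int(c[0])) for t, deme, ne, c in rows],
        columns=["generation", "deme", "ne", "count_n9b"],
    )
    frame["freq_n9b"] = frame["count_n9b"] / frame["ne"]
    return frame


def wilson_interval(successes: int, trials: int, z: float = 1.959963984540054):
    """Wilson 95% score interval for a binomial proportion."""
    if trials <= 0:
        raise ValueError("trials must be positive")
    p = successes / trials
    denom = 1 + z**2 / trials
    center = (p + z**2 / (2 * trials)) / denom
    half = z * math.sqrt(p * (1 - p) / trials + z**2 / (4 * trials**2)) / denom
    return max(0.0, center - half), min(1.0, center + half)


@dataclass(frozen=True)
class SimulationResult:
    """Monte-Carlo estimate of P(f_east - f_west >= threshold) per checkpoint."""

    probabilities: Mapping[int, float]
    intervals: Mapping[int, tuple[float, float]]
    n_trials: int
    threshold: float
    checkpoints: tuple[int, ...]
    seed: int | None
    config: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "checkpoint": list(self.probabilities),
                "P": list(self.probabilities.values()),
                "ci_low": [self.intervals[c][0] for c in self.probabilities],
                "ci_high": [self.intervals[c][1] for c in self.probabilities],
            }
        )


def estimate_probability(
    model: DemographyModel,
    scheme: MigrationScheme | None = None,
    n_trials: int = 1000,
    threshold: float = 0.5,
    checkpoints: Sequence[int] = DEFAULT_CHECKPOINTS,
    seed: int | np.random.SeedSequence | None = None,
) -> SimulationResult:
    """Probability that the east-minus-west frequency difference of the
    focal haplogroup reaches ``threshold`` (inclusive) at each checkpoint.

    The difference is directional (east minus west), not absolute.
    Reproducible given ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    scheme = scheme or MigrationScheme()
    rng = np.random.default_rng(seed)
    diffs, _, _ = _simulate_batch(model, scheme, n_trials, rng, checkpoints=checkpoints)
    probs = {cp: float((diffs[cp] >= threshold).mean()) for cp in checkpoints}
    ivs = {
        cp: wilson_interval(int((diffs[cp] >= threshold).sum()), n_trials)
        for cp in checkpoints
    }
    seed_repr = seed if isinstance(seed, (int, type(None))) else None
    return SimulationResult(
        probabilities=probs,
        intervals=ivs,
        n_trials=n_trials,
        threshold=threshold,
        checkpoints=tuple(checkpoints),
        seed=seed_repr,
        config={
            "cap_ne": model.cap_ne,
            "split_ratio": model.split_ratio,
            "migration_rate": scheme.rate,
            "migration_interval": scheme.interval,
            "total_generations": model.total_generations,
            "p0": model.p0,
        },
    )


@dataclass(frozen=True)
class GridConfig:
    """Full-factorial sweep over scenario parameters.

    Defaults follow the headline analysis: three CAP sizes, the nine split
    ratios 1:9 .. 9:1, migration rates {0, 0.1%, 1%} crossed with
    intervals {1, 10, 100}.  The alternative rate set
    ``(0, 0.0001, 0.001)`` is available as the ``"figure3"`` preset via
    :meth:`with_rate_preset`.  Post-split deme sizes are constant at the
    split of ``cap_ne`` unless per-deme curves are supplied to the model
    factory.
    """

    cap_ne: tuple[int, ...] = (1000, 5000, 10000)
    split_ratios: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    rates: tuple[float, ...] = (0.0, 0.001, 0.01)
    intervals: tuple[int, ...] = (1, 10, 100)
    n_trials: int = 1000
    threshold: float = 0.5
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS
    total_generations: int = 1000
    cap_generations: int = 100
    p0: float = 0.5
    seed: int = 0

    RATE_PRESETS = {
        "methods": (0.0, 0.001, 0.01),
        "figure3": (0.0, 0.0001, 0.001),
    }

    def with_rate_preset(self, name: str) -> "GridConfig":
        from dataclasses import replace

        return replace(self, rates=self.RATE_PRESETS[name])

    def migration_settings(self) -> list[MigrationScheme]:
        """Distinct (rate, interval) cells; interval is dead at rate 0."""
        seen: dict[tuple[float, int], MigrationScheme] = {}
        for rate in self.rates:
            for interval in self.intervals:
                key = (rate, interval if rate > 0 else 1)
                seen.setdefault(key, MigrationScheme(rate=key[0], interval=key[1]))
        return list(seen.values())


def _cell_seed(master_seed: int, cap_ne: int, ratio: float, scheme: MigrationScheme):
    """Deterministic, order-independent substream for one grid cell.

    The key is built from the *effective* parameters (interval is
    normalized to 1 at rate 0), so dead parameters cannot change results.
    """
    return np.random.SeedSequence(
        [
            int(master_seed) % (2**31),
            int(cap_ne),
            int(round(ratio * 1000)),
            int(round(scheme.rate * 10**6)),
            int(scheme.interval if scheme.rate > 0 else 1),
        ]
    )


def run_grid(config: GridConfig) -> pd.DataFrame:
    """Factorial sweep; long-format frame, one row per (cell, checkpoint).

    Columns: ``cap_ne, split_ratio, rate, interval, checkpoint, P,
    ci_low, ci_high, n_trials``.  Deterministic given ``config.seed``;
    per-cell substreams make the result independent of iteration order.
    """
    settings = config.migration_settings()
    if not (config.cap_ne and config.split_ratios and settings):
        raise ValueError("grid has an empty axis")
    records = []
    for cap in config.cap_ne:
        for ratio in config.split_ratios:
            model = DemographyModel(
                cap_ne=cap,
                cap_generations=config.cap_generations,
                total_generations=config.total_generations,
                split_ratio=ratio,
                p0=config.p0,
            )
            for scheme in settings:
                result = estimate_probability(
                    model,
                    scheme,
                    n_trials=config.n_trials,
                    threshold=config.threshold,
                    checkpoints=config.checkpoints,
                    seed=_cell_seed(config.seed, cap, ratio, scheme),
                )
                for cp in config.checkpoints:
                    lo, hi = result.intervals[cp]
                    records.append(
                        (cap, ratio, scheme.rate, scheme.interval, cp,
                         result.probabilities[cp], lo, hi, config.n_trials)
                    )
    return pd.DataFrame(
        records,
        columns=["cap_ne", "split_ratio", "rate", "interval",
                 "checkpoint", "P", "ci_low", "ci_high", "n_trials"],
    )
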