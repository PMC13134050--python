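"""Headline pipelines: the per-group diversity table and the drift
probability grid, with manifests for reproducibility.

Outputs are plain TSV (long format for the grid) so downstream plotting is
format-agnostic; every written artifact is accompanied by a manifest
recording the configuration, package version, master seed and SHA-256
digests of inputs and outputs.  Digests cover content only (timestamps are
recorded but excluded from hashed content), so a rerun with the same
config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .alignment import MaskedAlignment, apply_mask, read_fasta_alignment
from .contingency import HaplogroupTable, haplogroup_contingency, read_sample_table
from .regions import RegionSpec, get_preset
from .simulate import GridConfig, run_grid
from .stats import diversity_stats

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_table2", "run_figure3", "format_stats_table"]

FLOAT_FORMAT = "%.5f"  # match the 5-decimal precision of published tables


@dataclass
class RunManifest:
    """Traceability record for one pipeline invocation."""

    stage: str
    config: dict
    seed: int | None = None
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    input_digests: dict = field(default_factory=dict)
    output_digests: dict = field(default_factory=dict)

    def add_input(self, name: str, path: str | Path) -> None:
        self.input_digests[name] = _sha256_file(path)

    def add_output(self, name: str, content: bytes) -> None:
        self.output_digests[name] = hashlib.sha256(content).hexdigest()

    def write(self, path: str | Path) -> None:
        payload = {
            "stage": self.stage,
            "config": self.config,
            "seed": self.seed,
            "version": self.version,
            "timestamp": self.timestamp,
            "input_digests": self.input_digests,
            "output_digests": self.output_digests,
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")

    def verify_output(self, name: str, path: str | Path) -> bool:
        return _sha256_file(path) == self.output_digests.get(name)


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _resolve_region(region: str | RegionSpec) -> RegionSpec:
    if isinstance(region, RegionSpec):
        return region
    if str(region).endswith(".json"):
        return RegionSpec.from_json(region)
    return get_preset(str(region))


def _groups(samples: pd.DataFrame, group_by: str) -> dict[str, list[str]]:
    if group_by == "all":
        return {"all": samples["individual_id"].tolist()}
    key = {"site": "site_id", "region": "region"}.get(group_by)
    if key is None:
        raise ValueError("group_by must be one of 'site', 'region', 'all'")
    return {
        str(name): grp["individual_id"].tolist()
        for name, grp in samples.groupby(key, sort=True)
    }


def format_stats_table(frame: pd.DataFrame) -> str:
    """Render the stats table as TSV with floats at 5 decimal places and
    undefined statistics as NA."""
    out = frame.copy()
    for col in ("theta_w", "pi", "sd_pi", "tajima_d"):
        out[col] = out[col].map(
            lambda v: "NA" if pd.isna(v) else FLOAT_FORMAT % v
        )
    out["significant"] = out["significant"].map(
        lambda v: "NA" if v is None or (isinstance(v, float) and pd.isna(v)) else str(bool(v))
    )
    return out.to_csv(sep="\t", index=False)


def run_table2(
    fasta: str | Path | MaskedAlignment,
    samples: str | Path | HaplogroupTable,
    region: str | RegionSpec = "noncoding",
    group_by: str = "site",
    out: str | Path | None = None,
    reference_id: str | None = None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Per-group diversity statistics table (one row per group).

    Groups with fewer than two sequences are skipped with a warning;
    Tajima's D is reported as NA for groups with n < 4, where the
    statistic is undefined for the purposes of this table.
    """
    manifest = RunManifest(
        stage="table2",
        config={
            "region": region if isinstance(region, str) else region.name,
            "group_by": group_by,
        },
    )
    if isinstance(fasta, (str, Path)):
        manifest.add_input("fasta", fasta)
        alignment = read_fasta_alignment(fasta, reference_id=reference_id)
    else:
        alignment = fasta
    if isinstance(samples, (str, Path)):
        manifest.add_input("samples", samples)
        table = read_sample_table(samples)
    else:
        table = samples

    masked = apply_mask(alignment, _resolve_region(region))
    rows = []
    for name, ids in _groups(table.data, group_by).items():
        ids = [sid for sid in ids if sid in alignment.sample_ids]
        if len(ids) < 2:
            logger.warning("group %r has n=%d < 2; skipped", name, len(ids))
            continue
        stats = diversity_stats(masked.subset(ids), group=name)
        rows.append(
            (stats.group, stats.n, stats.L, stats.S, stats.theta_w,
             stats.pi, stats.sd_pi, stats.tajima_d, stats.significant)
        )
    frame = pd.DataFrame(
        rows,
        columns=["group", "n", "L", "S", "theta_w", "pi", "sd_pi",
                 "tajima_d", "significant"],
    )
    rendered = format_stats_table(frame)
    manifest.add_output("stats_tsv", rendered.encode())
    if out is not None:
        Path(out).write_text(rendered)
        manifest.write(Path(out).with_suffix(Path(out).suffix + ".manifest.json"))
    return frame, manifest


def run_fisher(
    samples: str | Path | HaplogroupTable,
    boundary: str = "chubu_kinki",
    out: str | Path | None = None,
) -> tuple[dict, RunManifest]:
    """East/west x N9b/M7a contingency counts and Fisher's exact P."""
    manifest = RunManifest(stage="fisher", config={"boundary": boundary})
    if isinstance(samples, (str, Path)):
        manifest.add_input("samples", samples)
        table = read_sample_table(samples, boundary=boundary)
    else:
        table = samples
    counts, p_value = haplogroup_contingency(table)
    payload = {
        "boundary": table.boundary,
        "counts": {r: counts.loc[r].to_dict() for r in counts.index},
        "n_tested": int(counts.to_numpy().sum()),
        "p_value": p_value,
    }
    content = json.dumps(payload, indent=2) + "\n"
    manifest.add_output("fisher_json", content.encode())
    if out is not None:
        Path(out).write_text(content)
        manifest.write(Path(out).with_suffix(".manifest.json"))
    return payload, manifest


def run_figure3(
    config: GridConfig,
    out: str | Path | None = None,
    plot: str | Path | None = None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Probability grid sweep; optionally renders the panel figure.

    The plot lays out one panel per (rate, interval) combination with the
    eastern split ratio on the x axis and P on the y axis (capped at 0.30
    for display), colored by CAP size, one marker per checkpoint.
    """
    manifest = RunManifest(
        stage="figure3",
        config={k: getattr(config, k) for k in (
            "cap_ne", "split_ratios", "rates", "intervals", "n_trials",
            "threshold", "checkpoints", "total_generations", "p0",
        )},
        seed=config.seed,
    )
    frame = run_grid(config)
    rendered = frame.to_csv(sep="\t", index=False, float_format="%.5f")
    manifest.add_output("grid_tsv", rendered.encode())
    if out is not None:
        Path(out).write_text(rendered)
        manifest.write(Path(out).with_suffix(Path(out).suffix + ".manifest.json"))
    if plot is not None:
        plot_grid(frame, plot)
        manifest.add_output("plot", Path(plot).read_bytes())
    return frame, manifest


def plot_grid(frame: pd.DataFrame, path: str | Path, y_max: float = 0.30) -> None:
    """Panel figure of the grid sweep (one box per rate x interval)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = sorted(frame.groupby(["rate", "interval"]).groups)
    ncols = len({i for _, i in cells})
    nrows = len({r for r, _ in cells})
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
        sharex=True, sharey=True, squeeze=False,
    )
    rate_order = sorted({r for r, _ in cells})
    interval_order = sorted({i for _, i in cells})
    markers = ["o", "s", "^", "v", "D", "P", "X"]
    checkpoints = sorted(frame["checkpoint"].unique())
    for (rate, interval), sub in frame.groupby(["rate", "interval"]):
        ax = axes[rate_order.index(rate)][interval_order.index(interval)]
        for cap, cap_sub in sub.groupby("cap_ne"):
            for k, cp in enumerate(checkpoints):
                cp_sub = cap_sub[cap_sub["checkpoint"] == cp].sort_values("split_ratio")
                ax.plot(
                    cp_sub["split_ratio"], cp_sub["P"],
                    marker=markers[k % len(markers)], markersize=3,
                    linewidth=0.8, label=f"Ne={cap}" if k == 0 else None,
                )
        ax.set_title(f"rate={rate:g}, interval={interval}", fontsize=8)
        ax.set_ylim(0, y_max)
    for ax in axes[-1]:
        ax.set_xlabel("eastern split ratio")
    for row in axes:
        row[0].set_ylabel("P")
    handles, labels = axes[0][0].get_legend_handles_labels()
    if handles:
        fig.legend(handles, labels, loc="upper right", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
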