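"""East-west haplogroup contingency analysis.

A sample table assigns each individual to a region (east or west of a named
geographic boundary) and a mitochondrial haplogroup.  Restricting to the
two haplogroups of interest (by default N9b and M7a) yields a 2x2 table
whose association is tested with a two-sided Fisher's exact test, computed
here by full hypergeometric enumeration: with margins fixed, the two-sided
P is the sum of the probabilities of all tables no more probable than the
observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "HaplogroupTable",
    "read_sample_table",
    "fisher_exact_2x2",
    "haplogroup_contingency",
]

REGIONS = ("east", "west")
BOUNDARIES = ("chubu_kinki", "itoigawa_shizuoka")


@dataclass
class HaplogroupTable:
    """Individual -> region -> haplogroup assignments.

    ``boundary`` names the east/west dividing line the region labels were
    assigned under (``chubu_kinki`` or ``itoigawa_shizuoka``); the package
    performs no geography — region membership is input data.
    """

    data: pd.DataFrame
    boundary: str = "chubu_kinki"

    def __post_init__(self) -> None:
        required = {"individual_id", "site_id", "region", "haplogroup"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"sample table missing columns: {sorted(missing)}")
        if self.data["individual_id"].duplicated().any():
            dupes = self.data.loc[
                self.data["individual_id"].duplicated(), "individual_id"
            ].tolist()
            raise ValueError(f"duplicate individual ids: {dupes}")
        bad = set(self.data["region"]) - set(REGIONS)
        if bad:
            raise ValueError(f"region labels must be in {REGIONS}; got {sorted(bad)}")
        if self.boundary not in BOUNDARIES:
            raise ValueError(f"boundary must be one of {BOUNDARIES}")

    def __len__(self) -> int:
        return len(self.data)


def read_sample_table(path: str | Path, boundary: str = "chubu_kinki") -> HaplogroupTable:
    """Read the TSV sample table (individual_id, site_id, region, haplogroup[, phase])."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return HaplogroupTable(data=frame, boundary=boundary)


def fisher_exact_2x2(table: np.ndarray | list) -> float:
    """Two-sided Fisher's exact P for a 2x2 count table, by enumeration.

    Enumerates every table compatible with the observed margins, computes
    each hypergeometric probability exactly from binomial coefficients, and
    sums those not exceeding the observed table's probability (with a
    1 + 1e-7 relative guard against floating-point ties, the conventional
    choice).  A table with any zero margin is degenerate: P = 1 with a
    warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a 2x2 table of non-negative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if 0 in (row1, row2, col1, b + d):
        warnings.warn("degenerate 2x2 table (zero margin); P = 1", stacklevel=2)
        return 1.0

    denom = comb(n, col1)

    def prob(x: int) -> float:
        return comb(row1, x) * comb(row2, col1 - x) / denom

    p_obs = prob(a)
    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    total = sum(
        p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-7)
    )
    return min(total, 1.0)


def haplogroup_contingency(
    table: HaplogroupTable,
    haplogroups: tuple[str, str] = ("N9b", "M7a"),
) -> tuple[pd.DataFrame, float]:
    """Region x haplogroup 2x2 counts and two-sided Fisher's exact P.

    Individuals whose haplogroup is not one of ``haplogroups`` are excluded
    before counting (the classic analysis restricts to the two haplogroups
    that dominate the population).
    """
    df = table.data[table.data["haplogroup"].isin(haplogroups)]
    counts = pd.DataFrame(
        0, index=list(REGIONS), columns=list(haplogroups), dtype=int
    )
    observed = (
        df.groupby(["region", "haplogroup"], observed=True).size().unstack(fill_value=0)
    )
    for region in observed.index:
        for hg in observed.columns:
            counts.loc[region, hg] = int(observed.loc[region, hg])
    p_value = fisher_exact_2x2(counts.to_numpy())
    return counts, p_value
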