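"""rCRS coordinate region masks for mitogenome alignments.

All coordinates are 1-based inclusive positions on the revised Cambridge
Reference Sequence (rCRS, 16569 bp), the convention used throughout the
mitochondrial literature.  A :class:`RegionSpec` is a set of included
intervals minus a set of excluded positions; two presets ship with the
package:

``noncoding``
    The mitochondrial control region, positions 1-576 and 16024-16569
    (containing hypervariable regions I and II), minus positions known to
    be unalignable due to homopolymer/indel hypervariability
    (303-315, 522-523, 16180-16193 and 16519).  1092 retained positions.

``coding``
    The union of the 13 protein-coding gene intervals of the standard rCRS
    annotation.  The genes span 11395 bp of sequence but overlap by 54 bp
    (ATP8/ATP6 46 bp, ATP6/COX3 1 bp, ND4L/ND4 7 bp); the union of
    positions is 11341.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

RCRS_LENGTH = 16569

__all__ = ["RegionSpec", "RCRS_LENGTH", "get_preset", "list_presets"]


@dataclass(frozen=True)
class RegionSpec:
    """A coordinate mask on the rCRS: included intervals minus excluded sites.

    Parameters
    ----------
    included_intervals
        ``(start, end)`` pairs, 1-based inclusive, non-overlapping, each
        within ``[1, 16569]``.
    excluded_positions
        Individual rCRS positions removed from the included set.  A
        position outside every included interval is dropped with a
        warning (it cannot affect the mask).
    name
        Optional label used in logs and output manifests.
    """

    included_intervals: tuple[tuple[int, int], ...]
    excluded_positions: frozenset[int] = field(default_factory=frozenset)
    name: str = "custom"

    def __init__(
        self,
        included_intervals: Iterable[Sequence[int]],
        excluded_positions: Iterable[int] = (),
        name: str = "custom",
    ) -> None:
        intervals = tuple(sorted((int(s), int(e)) for s, e in included_intervals))
        if not intervals:
            raise ValueError("RegionSpec requires at least one interval")
        for start, end in intervals:
            if start > end:
                raise ValueError(f"interval start {start} > end {end}")
            if start < 1 or end > RCRS_LENGTH:
                raise ValueError(
                    f"interval ({start}, {end}) outside rCRS range [1, {RCRS_LENGTH}]"
                )
        for (_, e_prev), (s_next, _) in zip(intervals, intervals[1:]):
            if s_next <= e_prev:
                raise ValueError("included intervals overlap")

        kept: set[int] = set()
        for pos in excluded_positions:
            pos = int(pos)
            if any(s <= pos <= e for s, e in intervals):
                kept.add(pos)
            else:
                warnings.warn(
                    f"excluded position {pos} lies outside every included "
                    "interval; ignored",
                    stacklevel=2,
                )
        object.__setattr__(self, "included_intervals", intervals)
        object.__setattr__(self, "excluded_positions", frozenset(kept))
        object.__setattr__(self, "name", name)

    def positions(self) -> list[int]:
        """All retained rCRS positions, ascending."""
        out: list[int] = []
        for start, end in self.included_intervals:
            out.extend(
                p for p in range(start, end + 1) if p not in self.excluded_positions
            )
        return out

    def __contains__(self, position: int) -> bool:
        if position in self.excluded_positions:
            return False
        return any(s <= position <= e for s, e in self.included_intervals)

    def __len__(self) -> int:
        total = sum(e - s + 1 for s, e in self.included_intervals)
        return total - len(self.excluded_positions)

    @classmethod
    def from_dict(cls, payload: dict) -> "RegionSpec":
        return cls(
            included_intervals=[tuple(iv) for iv in payload["included_intervals"]],
            excluded_positions=payload.get("excluded_positions", []),
            name=payload.get("name", "custom"),
        )

    @classmethod
    def from_json(cls, path) -> "RegionSpec":
        with open(path) as handle:
            return cls.from_dict(json.load(handle))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "included_intervals": [list(iv) for iv in self.included_intervals],
            "excluded_positions": sorted(self.excluded_positions),
        }


def _load_presets() -> dict[str, RegionSpec]:
    text = resources.files("haplodrift.data").joinpath("region_presets.json").read_text()
    raw = json.loads(text)
    return {key: RegionSpec.from_dict(value) for key, value in raw.items()}


_PRESETS: dict[str, RegionSpec] | None = None


def list_presets() -> list[str]:
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_presets()
    return sorted(_PRESETS)


def get_preset(name: str) -> RegionSpec:
    """Return a shipped region preset (``noncoding``, ``coding``, ``full``)."""
    global _PRESETS
    if _PRESETS is None:
        _PRESETS = _load_presets()
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown region preset {name!r}; available: {sorted(_PRESETS)}"
        ) from None
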