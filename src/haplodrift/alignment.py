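"""Aligned mitogenome sequences and rCRS coordinate masking.

The central container is :class:`MaskedAlignment`: a rectangular character
matrix with one row per sample plus, for every column, the rCRS position it
represents (columns that are insertions relative to the rCRS carry no
position and are dropped when a mask is applied).

Missing data policy (complete deletion): any column containing a gap or an
ambiguous base in *any* sequence is removed before diversity statistics are
computed, so the analyzed length L reported for a group reflects only fully
resolved columns.  This mirrors the default of the classic desktop tools
used for mitochondrial diversity tables and is what makes per-group L
differ from the nominal mask size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .regions import RegionSpec

logger = logging.getLogger(__name__)

#: bases that count as fully resolved; everything else (gaps, N, IUPAC
#: ambiguity codes, '?') is treated as missing.
VALID_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")

__all__ = ["MaskedAlignment", "read_fasta_alignment", "apply_mask"]


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, empty input, ...)."""


@dataclass
class MaskedAlignment:
    """Aligned sequences plus the rCRS coordinate of every column.

    Attributes
    ----------
    sample_ids
        Sequence identifiers, in input order.
    matrix
        ``(n, L)`` array of single-byte characters (dtype ``S1``), upper case.
    positions
        ``(L,)`` int array; rCRS position of each column, ``-1`` for
        insertion columns with no rCRS coordinate.
    source_region
        The mask that produced this view, if any.
    """

    sample_ids: list[str]
    matrix: np.ndarray
    positions: np.ndarray
    source_region: RegionSpec | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="S1")
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-dimensional")
        self.positions = np.asarray(self.positions, dtype=int)
        if self.positions.shape != (self.matrix.shape[1],):
            raise AlignmentError("positions must have one entry per column")
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise AlignmentError("one sample id per row required")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        """Analyzed length: number of columns currently retained."""
        return self.matrix.shape[1]

    def subset(self, sample_ids: Iterable[str]) -> "MaskedAlignment":
        """Row subset by identifier, preserving the requested order."""
        wanted = list(sample_ids)
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        missing = [sid for sid in wanted if sid not in index]
        if missing:
            raise KeyError(f"sample ids not in alignment: {missing}")
        rows = [index[sid] for sid in wanted]
        return MaskedAlignment(
            sample_ids=wanted,
            matrix=self.matrix[rows],
            positions=self.positions.copy(),
            source_region=self.source_region,
        )

    def complete_deletion(self) -> "MaskedAlignment":
        """Drop every column with a gap or ambiguous base in any row."""
        valid = np.isin(self.matrix, VALID_BASES)
        keep = valid.all(axis=0)
        dropped = int((~keep).sum())
        if dropped:
            logger.info(
                "complete deletion removed %d of %d columns (%d retained)",
                dropped, self.L, self.L - dropped,
            )
        return MaskedAlignment(
            sample_ids=list(self.sample_ids),
            matrix=self.matrix[:, keep],
            positions=self.positions[keep],
            source_region=self.source_region,
        )


def read_fasta_alignment(
    path: str | Path,
    reference_id: str | None = None,
    drop_reference: bool = True,
) -> MaskedAlignment:
    """Read an aligned FASTA into a :class:`MaskedAlignment`.

    Column-to-rCRS coordinates are assigned from ``reference_id`` if given:
    the reference row's k-th non-gap character defines rCRS position k and
    columns where the reference is gapped are insertions (position ``-1``).
    Without a reference row, columns are numbered 1..L (the alignment is
    assumed to be in rCRS coordinates already, e.g. a gap-free alignment of
    full mitogenomes to the 16569-bp reference frame).

    Raises
    ------
    AlignmentError
        If the file is empty or records have unequal lengths.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    lengths = {len(rec.seq) for rec in records}
    if len(lengths) != 1:
        raise AlignmentError(
            f"aligned records must all have equal length; found {sorted(lengths)}"
        )
    ids = [rec.id for rec in records]
    matrix = np.array(
        [list(str(rec.seq).upper()) for rec in records], dtype="S1"
    )

    ncols = matrix.shape[1]
    if reference_id is not None:
        if reference_id not in ids:
            raise AlignmentError(f"reference id {reference_id!r} not in file")
        ref_row = matrix[ids.index(reference_id)]
        is_base = ref_row != b"-"
        positions = np.where(is_base, np.cumsum(is_base), -1)
        if drop_reference:
            keep_rows = [i for i, sid in enumerate(ids) if sid != reference_id]
            matrix = matrix[keep_rows]
            ids = [ids[i] for i in keep_rows]
    else:
        positions = np.arange(1, ncols + 1)

    return MaskedAlignment(sample_ids=ids, matrix=matrix, positions=positions)


def apply_mask(alignment: MaskedAlignment, region: RegionSpec) -> MaskedAlignment:
    """Restrict an alignment to the columns a region mask retains.

    Keeps exactly the columns whose rCRS position lies inside an included
    interval and is not excluded; insertion columns (position ``-1``) are
    always dropped.

    Raises
    ------
    AlignmentError
        If the mask retains zero columns.
    """
    wanted = np.zeros(alignment.L, dtype=bool)
    pos = alignment.positions
    for start, end in region.included_intervals:
        wanted |= (pos >= start) & (pos <= end)
    if region.excluded_positions:
        wanted &= ~np.isin(pos, list(region.excluded_positions))
    wanted &= pos > 0
    if not wanted.any():
        raise AlignmentError(
            f"region {region.name!r} selects no columns of this alignment"
        )
    masked = MaskedAlignment(
        sample_ids=list(alignment.sample_ids),
        matrix=alignment.matrix[:, wanted],
        positions=pos[wanted],
        source_region=region,
    )
    logger.info(
        "mask %s retained %d of %d columns", region.name, masked.L, alignment.L
    )
    return masked


def alignment_from_strings(
    sequences: Sequence[str], sample_ids: Sequence[str] | None = None
) -> MaskedAlignment:
    """Build an alignment from equal-length strings (testing/synthesis aid)."""
    if not sequences:
        raise AlignmentError("no sequences given")
    if len({len(s) for s in sequences}) != 1:
        raise AlignmentError("sequences must have equal length")
    ids = list(sample_ids) if sample_ids is not None else [
        f"seq{i + 1}" for i in range(len(sequences))
    ]
    matrix = np.array([list(s.upper()) for s in sequences], dtype="S1")
    return MaskedAlignment(
        sample_ids=ids, matrix=matrix, positions=np.arange(1, matrix.shape[1] + 1)
    )
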