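"""Indel detection and character coding on a species-level alignment.

Gap handling follows the simple-indel-coding family of schemes: every
distinct maximal gap span (identical start and end columns) becomes one
binary character; a taxon whose own gap strictly contains another taxon's
span cannot be scored for the shorter span and is coded ``?``
(inapplicable). Leading and trailing gap runs are treated as missing data
rather than indel characters, so length computation can assume intact
flanking regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import AlignmentDegenerateError, FrameError
from .io_formats import GappedAlignment

STATE_ABSENT = "0"
STATE_GAP = "1"
STATE_INAPPLICABLE = "?"


@dataclass
class GapBlock:
    """A distinct gap span shared by one or more taxa.

    Columns are 1-based inclusive. ``presence`` maps each taxon to '1'
    (has exactly this gap span), '0' (residues across the span) or '?'
    (span unobservable inside a larger gap of that taxon).
    """

    start_col: int
    end_col: int
    region_label: str = ""
    presence: dict[str, str] = field(default_factory=dict)

    @property
    def length_nt(self) -> int:
        return self.end_col - self.start_col + 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start_col, self.end_col)

    @property
    def label(self) -> str:
        return f"{self.region_label}-{self.length_nt}"


@dataclass
class IndelCharacterMatrix:
    """Binary indel characters (one per distinct gap span) over taxa."""

    taxa: list[str]
    blocks: list[GapBlock]

    @property
    def n_characters(self) -> int:
        return len(self.blocks)

    def states(self, block_index: int) -> dict[str, str]:
        return self.blocks[block_index].presence

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {b.label: [b.presence[t] for t in self.taxa] for b in self.blocks},
            index=self.taxa,
        )

    def to_nexus(self) -> str:
        """Standard-datatype NEXUS matrix (symbols 01, missing ?)."""
        width = max((len(t) for t in self.taxa), default=1) + 2
        lines = [
            "#NEXUS",
            "BEGIN DATA;",
            f"  DIMENSIONS NTAX={len(self.taxa)} NCHAR={self.n_characters};",
            '  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;',
            "  MATRIX",
        ]
        for t in self.taxa:
            row = "".join(b.presence[t] for b in self.blocks)
            lines.append(f"    {t:<{width}}{row}")
        lines += ["  ;", "END;"]
        return "\n".join(lines) + "\n"


def _maximal_gap_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal runs of '-' as 1-based inclusive (start, end) pairs."""
    runs = []
    start = None
    for i, ch in enumerate(seq):
        if ch == "-":
            if start is None:
                start = i
        elif start is not None:
            runs.append((start + 1, i))
            start = None
    if start is not None:
        runs.append((start + 1, len(seq)))
    return runs


def find_gap_blocks(aln: GappedAlignment) -> list[GapBlock]:
    """Collect distinct gap spans across taxa as coded characters.

    Terminal (leading/trailing) runs are excluded. A column gapped in every
    taxon raises :class:`AlignmentDegenerateError` — such columns carry no
    signal and should have been stripped upstream.
    """
    n = aln.n_columns
    for col in range(n):
        if all(r.seq[col] == "-" for r in aln.records):
            raise AlignmentDegenerateError(
                f"column {col + 1} is gapped in every taxon"
            )
    runs_by_taxon: dict[str, list[tuple[int, int]]] = {}
    spans: dict[tuple[int, int], list[str]] = {}
    for rec in aln.records:
        runs = _maximal_gap_runs(rec.seq)
        # terminal runs = missing data, not indels
        internal = [r for r in runs if r[0] > 1 and r[1] < n]
        runs_by_taxon[rec.id] = internal
        for span in internal:
            spans.setdefault(span, []).append(rec.id)
    blocks = []
    for idx, span in enumerate(sorted(spans), start=1):
        start, end = span
        block = GapBlock(start, end, region_label=f"R{idx}")
        for rec in aln.records:
            taxon = rec.id
            if span in runs_by_taxon[taxon]:
                block.presence[taxon] = STATE_GAP
            elif any(
                s <= start and end <= e and (s, e) != span
                for s, e in runs_by_taxon[taxon]
            ):
                block.presence[taxon] = STATE_INAPPLICABLE
            else:
                block.presence[taxon] = STATE_ABSENT
        blocks.append(block)
    return blocks


def code_indels(blocks: list[GapBlock], aln: GappedAlignment) -> IndelCharacterMatrix:
    """One binary character per distinct gap span, '?' for nested spans."""
    return IndelCharacterMatrix(taxa=aln.ids, blocks=list(blocks))


@dataclass
class FrameReport:
    """Per-block length mod 3; overall pass iff every block is in-frame."""

    block_labels: list[str]
    lengths_nt: list[int]

    @property
    def remainders(self) -> list[int]:
        return [ln % 3 for ln in self.lengths_nt]

    @property
    def passed(self) -> bool:
        return all(r == 0 for r in self.remainders)

    @property
    def violations(self) -> list[str]:
        return [
            lab
            for lab, rem in zip(self.block_labels, self.remainders)
            if rem != 0
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": self.block_labels,
                "length_nt": self.lengths_nt,
                "length_mod_3": self.remainders,
                "in_frame": [r == 0 for r in self.remainders],
            }
        )


def check_frame(blocks: list[GapBlock]) -> FrameReport:
    """Report whether every gap span preserves the reading frame (3n nt)."""
    return FrameReport(
        block_labels=[b.label or f"({b.start_col},{b.end_col})" for b in blocks],
        lengths_nt=[b.length_nt for b in blocks],
    )


@dataclass
class LengthTable:
    """Ungapped nucleotide and amino-acid lengths per species."""

    data: pd.DataFrame  # columns: species, nt_length, aa_length

    def nt(self, species: str) -> int:
        return int(self.data.set_index("species").loc[species, "nt_length"])

    def aa(self, species: str) -> int:
        return int(self.data.set_index("species").loc[species, "aa_length"])


def ungapped_lengths(aln: GappedAlignment) -> LengthTable:
    """Count non-gap nucleotides per species; aa length = nt/3.

    Raises :class:`FrameError` if any ungapped length is not a multiple of
    three (run :func:`check_frame` first).
    """
    rows = []
    for rec in aln.records:
        nt = len(rec.ungapped)
        if nt % 3 != 0:
            raise FrameError(
                f"{rec.id}: ungapped length {nt} is not a multiple of 3"
            )
        rows.append({"species": rec.id, "nt_length": nt, "aa_length": nt // 3})
    return LengthTable(pd.DataFrame(rows))
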