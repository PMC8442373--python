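"""Multiple sequence alignments of locus alleles.

An :class:`Msa` holds gapped rows over the alphabet ``{A, C, G, T, -, N}``.
Rows are the known alleles of a single locus (gene or intergenic region);
``-`` marks an alignment gap and any non-AGCT symbol is dropped when a row
is converted back to a DNA sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

_DNA = frozenset("ACGT")
ALPHABET = frozenset("ACGT-N")


def degap(row: str) -> str:
    """Return the DNA sequence of an aligned row: all non-AGCT symbols removed."""
    return "".join(c for c in row if c in _DNA)


@dataclass
class Msa:
    """An alignment of locus alleles: equal-length rows plus locus-unique ids."""

    rows: list[str]
    row_ids: list[str] = field(default_factory=list)
    locus_id: str = ""

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("MSA must contain at least one row")
        n = len(self.rows[0])
        if n < 1:
            raise ValueError("MSA rows must have length >= 1")
        if any(len(r) != n for r in self.rows):
            raise ValueError("all MSA rows must have equal length")
        bad = set(itertools.chain.from_iterable(self.rows)) - ALPHABET
        if bad:
            raise ValueError(f"unexpected alignment symbols: {sorted(bad)}")
        if not self.row_ids:
            self.row_ids = [f"row{i}" for i in range(len(self.rows))]
        if len(self.row_ids) != len(self.rows):
            raise ValueError("row_ids must match number of rows")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def slice_cols(self, start: int, end: int) -> "Msa":
        return Msa([r[start:end] for r in self.rows], list(self.row_ids), self.locus_id)

    def subset_rows(self, idx: Sequence[int]) -> "Msa":
        return Msa([self.rows[i] for i in idx], [self.row_ids[i] for i in idx], self.locus_id)

    def degapped(self) -> list[str]:
        return [degap(r) for r in self.rows]


def ref_of_alignment(msa: Msa | Iterable[str]) -> str:
    """Concatenate the modal nucleotide of each column.

    Gaps and N never vote.  Columns with no A/C/G/T at all contribute
    nothing; ties go to the lexicographically smallest base so the result
    is deterministic.
    """
    rows = msa.rows if isinstance(msa, Msa) else list(msa)
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c in _DNA:
                counts[c] = counts.get(c, 0) + 1
        if counts:
            # max count, then smallest base
            out.append(min(counts, key=lambda b: (-counts[b], b)))
    return "".join(out)


def read_msa_fasta(path: str | Path, locus_id: str | None = None) -> Msa:
    """Read one aligned FASTA file (gaps as ``-``); the stem is the locus id."""
    path = Path(path)
    ids: list[str] = []
    rows: list[str] = []
    seq: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ids:
                    rows.append("".join(seq))
                ids.append(line[1:].split()[0])
                seq = []
            else:
                seq.append(line.upper())
        if ids:
            rows.append("".join(seq))
    if not rows:
        raise ValueError(f"no sequences in {path}")
    return Msa(rows, ids, locus_id or path.stem)


def write_msa_fasta(msa: Msa, path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(msa.row_ids, msa.rows):
            fh.write(f">{rid}\n{row}\n")
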