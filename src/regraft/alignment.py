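"""Protein alignment container plus the coordinate bookkeeping the pipeline needs.

The alignment is the substrate of every downstream stage: likelihood
computation, column masking (a reproducible surrogate for manual removal of
ambiguously aligned sites), and mapping of alignment columns onto the
residue numbering of a designated reference sequence (the convention used
when reporting indel positions).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
AMBIGUOUS = "X"
ALPHABET = frozenset(AMINO_ACIDS + GAP + AMBIGUOUS)

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class AlignmentError(ValueError):
    """Raised for malformed alignments or alignment-format problems."""


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", GAP).replace("?", AMBIGUOUS)


@dataclass(frozen=True)
class Alignment:
    """Rectangular amino-acid alignment over the 20 residues plus '-' and 'X'."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("taxa and rows differ in length")
        if not self.taxa:
            raise AlignmentError("empty alignment")
        seen = set()
        dups = sorted({t for t in self.taxa if t in seen or seen.add(t)})
        if dups:
            raise AlignmentError(f"duplicate taxon labels: {', '.join(dups)}")
        for t in self.taxa:
            if not t or t != t.strip():
                raise AlignmentError(f"bad taxon label {t!r}")
        n = len(self.rows[0])
        if n < 1:
            raise AlignmentError("alignment has zero columns")
        for t, r in zip(self.taxa, self.rows):
            if len(r) != n:
                raise AlignmentError(
                    f"ragged alignment: taxon {t!r} has {len(r)} columns, expected {n}"
                )
            for j, ch in enumerate(r):
                if ch not in ALPHABET:
                    raise AlignmentError(
                        f"illegal character {ch!r} for taxon {t!r} at column {j}"
                    )

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "Alignment":
        taxa, rows = [], []
        for t, r in pairs:
            taxa.append(t.strip())
            rows.append(_normalise(r))
        return cls(tuple(taxa), tuple(rows))

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise AlignmentError(f"unknown taxon {taxon!r}") from None

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    def take_taxa(self, taxa: Sequence[str]) -> "Alignment":
        return Alignment(tuple(taxa), tuple(self.row(t) for t in taxa))

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment(self.taxa, tuple("".join(r[j] for j in cols) for r in self.rows))


@dataclass(frozen=True)
class ColumnMask:
    """Original 0-based indices of the columns retained by masking."""

    kept: tuple[int, ...]

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.kept, self.kept[1:])):
            raise AlignmentError("mask indices must be strictly increasing")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kept_index\toriginal_index\n")
            for k, orig in enumerate(self.kept):
                fh.write(f"{k}\t{orig}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ColumnMask":
        kept = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                kept.append(int(line.split("\t")[1]))
        return cls(tuple(kept))


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed PHYLIP protein alignment.

    Lowercase residues are uppercased; ``.`` is normalised to the gap
    character and ``?`` to the ambiguity character ``X``.
    """
    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"no such file: {path}")
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"no FASTA records in {path}")
        return Alignment.from_pairs((r.id, str(r.seq)) for r in records)
    if format == "phylip":
        text = path.read_text()
        last_err: Exception | None = None
        for dialect in ("phylip-relaxed", "phylip-sequential", "phylip"):
            try:
                msa = AlignIO.read(io.StringIO(text), dialect)
                return Alignment.from_pairs((r.id, str(r.seq)) for r in msa)
            except Exception as e:  # try the next dialect
                last_err = e
        raise AlignmentError(f"could not parse {path} as PHYLIP: {last_err}")
    raise AlignmentError(f"unknown alignment format {format!r}")


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write FASTA, or sequential relaxed PHYLIP (whitespace-delimited names)."""
    with open(path, "w") as fh:
        if format == "fasta":
            for t, r in zip(aln.taxa, aln.rows):
                fh.write(f">{t}\n{r}\n")
        elif format == "phylip":
            fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
            width = max(len(t) for t in aln.taxa) + 2
            for t, r in zip(aln.taxa, aln.rows):
                fh.write(t.ljust(width) + r + "\n")
        else:
            raise AlignmentError(f"unknown alignment format {format!r}")


def mask_columns(
    aln: Alignment, max_gap_fraction: float = 0.5, drop_ambiguous: bool = True
) -> tuple[Alignment, ColumnMask]:
    """Drop gap-rich (and optionally ambiguity-containing) columns.

    A column is removed when its gap fraction exceeds ``max_gap_fraction``
    or, with ``drop_ambiguous``, when it contains any 'X'. Taxon order is
    preserved; the returned mask records the surviving original indices.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise AlignmentError("max_gap_fraction must be in [0, 1]")
    kept = []
    n = aln.n_taxa
    for j in range(aln.n_sites):
        col = aln.column(j)
        if col.count(GAP) / n > max_gap_fraction:
            continue
        if drop_ambiguous and AMBIGUOUS in col:
            continue
        kept.append(j)
    if not kept:
        raise AlignmentError(
            "masking removed every column; raise max_gap_fraction or "
            "disable drop_ambiguous"
        )
    return aln.take_columns(kept), ColumnMask(tuple(kept))


def map_to_reference(aln: Alignment, ref_taxon: str) -> list[int | None]:
    """Map each column to the 1-based residue number of a reference taxon.

    Columns where the reference carries a gap map to ``None``; over the
    remaining columns the mapping counts the reference's non-gap residues
    cumulatively, so it is strictly increasing from 1.
    """
    row = aln.row(ref_taxon)
    out: list[int | None] = []
    pos = 0
    for ch in row:
        if ch == GAP:
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out
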