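"""Alignment containers, FASTA/relaxed-PHYLIP I/O, column arithmetic,
RY recoding, and G+C compositional screening.

Coordinates are 1-based and inclusive at every public interface, matching the
convention used to report alignment positions in the gene-conversion analyses
(e.g. a tract spanning columns 111-190 has 80 columns).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment
from scipy.stats import norm

from .errors import (
    AlignmentShapeError,
    AlphabetError,
    CoordinateError,
    DegenerateSequenceError,
    IdentifierError,
)

#: Canonical residue orders. AA follows the conventional PAML order used by
#: the embedded LG/WAG tables.
ALPHABETS = {
    "AA": "ARNDCQEGHILKMFPSTWYV",
    "NT": "ACGT",
    "RY": "RY",
}

#: The symbol an unreadable/ambiguous character is normalized to, per alphabet.
UNKNOWN = {"AA": "X", "NT": "N", "RY": "?"}

GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """A rectangular character matrix over a named alphabet.

    Rows are equal-length uppercase strings; any character that is neither a
    state of the alphabet nor the gap ``-`` is stored as the alphabet's
    unknown symbol and treated as missing data downstream.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    alphabet: str

    def __post_init__(self):
        if self.alphabet not in ALPHABETS:
            raise AlphabetError(f"unknown alphabet {self.alphabet!r}")
        if len(self.ids) != len(self.rows):
            raise AlignmentShapeError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise IdentifierError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentShapeError(f"ragged rows: lengths {sorted(lengths)}")
        allowed = set(ALPHABETS[self.alphabet]) | {GAP, UNKNOWN[self.alphabet]}
        clean = []
        for r in self.rows:
            r = r.upper()
            if set(r) <= allowed:
                clean.append(r)
            else:
                clean.append(
                    "".join(c if c in allowed else UNKNOWN[self.alphabet] for c in r)
                )
        object.__setattr__(self, "rows", tuple(clean))

    @property
    def n_seqs(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise IdentifierError(f"no sequence {seq_id!r}") from None

    def column(self, pos: int) -> str:
        """Characters of 1-based column ``pos``, in row order."""
        if not 1 <= pos <= self.length:
            raise CoordinateError(f"column {pos} outside [1, {self.length}]")
        return "".join(r[pos - 1] for r in self.rows)


def _records_to_alignment(records, alphabet: str) -> Alignment:
    ids = tuple(r.id for r in records)
    rows = tuple(str(r.seq) for r in records)
    if not ids:
        raise AlignmentShapeError("empty alignment file")
    return Alignment(ids=ids, rows=rows, alphabet=alphabet)


def read_alignment(path, format: str = "fasta", alphabet: str = "AA") -> Alignment:
    """Read an alignment from FASTA or relaxed sequential PHYLIP.

    Relaxed PHYLIP allows whitespace-delimited names of any practical length,
    avoiding the classic 10-character truncation of long bacterial names.
    """
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
        lengths = {len(r.seq) for r in records}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"FASTA rows have unequal lengths {sorted(lengths)}"
            )
    elif format == "phylip":
        try:
            records = list(AlignIO.read(str(path), "phylip-relaxed"))
        except ValueError as exc:
            raise AlignmentShapeError(f"cannot parse PHYLIP: {exc}") from exc
    else:
        raise ValueError(f"unknown alignment format {format!r}")
    return _records_to_alignment(records, alphabet)


def write_alignment(aln: Alignment, path, format: str = "fasta") -> None:
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.ids, aln.rows)
    ]
    if format == "fasta":
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.seq}\n")
    elif format == "phylip":
        msa = MultipleSeqAlignment(records)
        with open(path, "w") as fh:
            AlignIO.write(msa, fh, "phylip-relaxed")
    else:
        raise ValueError(f"unknown alignment format {format!r}")


def alignment_from_string(text: str, format: str = "fasta", alphabet: str = "AA") -> Alignment:
    """Parse an alignment held in a string (convenience for small inputs)."""
    handle = _io.StringIO(text)
    fmt = "fasta" if format == "fasta" else "phylip-relaxed"
    records = list(SeqIO.parse(handle, fmt)) if format == "fasta" else list(
        AlignIO.read(handle, fmt)
    )
    if format == "fasta":
        lengths = {len(r.seq) for r in records}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"FASTA rows have unequal lengths {sorted(lengths)}"
            )
    return _records_to_alignment(records, alphabet)


def slice_columns(aln: Alignment, start: int, end: int) -> Alignment:
    """Columns ``start``..``end`` (1-based, inclusive)."""
    if not (1 <= start <= end <= aln.length):
        raise CoordinateError(
            f"slice [{start}, {end}] outside alignment of length {aln.length}"
        )
    return Alignment(
        ids=aln.ids,
        rows=tuple(r[start - 1 : end] for r in aln.rows),
        alphabet=aln.alphabet,
    )


def concat(aln_a: Alignment, aln_b: Alignment) -> Alignment:
    """Column-wise concatenation; rows are matched by id, not by order."""
    if set(aln_a.ids) != set(aln_b.ids):
        raise IdentifierError("alignments have different id sets")
    if aln_a.alphabet != aln_b.alphabet:
        raise AlphabetError("alignments have different alphabets")
    rows = tuple(row + aln_b.row(sid) for sid, row in zip(aln_a.ids, aln_a.rows))
    return Alignment(ids=aln_a.ids, rows=rows, alphabet=aln_a.alphabet)


def select_rows(aln: Alignment, ids) -> Alignment:
    """Sub-alignment restricted to ``ids``, in the order given."""
    missing = [i for i in ids if i not in aln.ids]
    if missing:
        raise IdentifierError(f"ids not in alignment: {missing}")
    return Alignment(
        ids=tuple(ids),
        rows=tuple(aln.row(i) for i in ids),
        alphabet=aln.alphabet,
    )


_RY_MAP = {"A": "R", "G": "R", "C": "Y", "T": "Y", GAP: GAP}


def ry_recode(aln_nt: Alignment) -> Alignment:
    """Recode nucleotides to purine (R: A/G) / pyrimidine (Y: C/T).

    RY coding removes differences within each base class, which cancels or
    reduces artifacts caused by G+C-content variation across lineages.
    Gaps are preserved; ambiguity codes become the unknown symbol.
    """
    if aln_nt.alphabet != "NT":
        raise AlphabetError("ry_recode requires a nucleotide alignment")
    unknown = UNKNOWN["RY"]
    rows = tuple(
        "".join(_RY_MAP.get(c, unknown) for c in row) for row in aln_nt.rows
    )
    return Alignment(ids=aln_nt.ids, rows=rows, alphabet="RY")


@dataclass(frozen=True)
class GcReport:
    """Per-sequence G+C fraction with a Wald confidence interval.

    ``flagged`` is true when the across-sequence grand mean falls outside this
    sequence's interval, i.e. the sequence's composition departs significantly
    from the average.
    """

    id: str
    gc_fraction: float
    ci_low: float
    ci_high: float
    flagged: bool


def gc_screen(aln_nt: Alignment, conf: float = 0.95) -> list[GcReport]:
    """Flag sequences whose G+C content departs from the across-sequence mean.

    For each sequence the G+C fraction p is computed over its n non-gap,
    unambiguous columns and given a Wald interval p +/- z*sqrt(p(1-p)/n).
    A sequence is flagged when the grand mean of the fractions lies outside
    its interval (two-sided test at level 1-conf per sequence).
    """
    if aln_nt.alphabet != "NT":
        raise AlphabetError("gc_screen requires a nucleotide alignment")
    z = float(norm.ppf(0.5 + conf / 2.0))
    fracs, ns = [], []
    for sid, row in zip(aln_nt.ids, aln_nt.rows):
        counts = {c: row.count(c) for c in "ACGT"}
        n = sum(counts.values())
        if n == 0:
            raise DegenerateSequenceError(f"sequence {sid!r} has no A/C/G/T characters")
        fracs.append((counts["G"] + counts["C"]) / n)
        ns.append(n)
    grand_mean = float(np.mean(fracs))
    reports = []
    for sid, p, n in zip(aln_nt.ids, fracs, ns):
        half = z * np.sqrt(p * (1.0 - p) / n)
        lo, hi = p - half, p + half
        reports.append(
            GcReport(
                id=sid,
                gc_fraction=p,
                ci_low=lo,
                ci_high=hi,
                flagged=not (lo <= grand_mean <= hi),
            )
        )
    return reports


def write_gc_report(reports: list[GcReport], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tgc\tci_low\tci_high\tflagged\n")
        for r in reports:
            fh.write(
                f"{r.id}\t{r.gc_fraction:.6f}\t{r.ci_low:.6f}\t{r.ci_high:.6f}\t"
                f"{str(r.flagged).lower()}\n"
            )
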