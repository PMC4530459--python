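"""Classification of the anchored indel motif carried by each sequence.

The converted release-factor paralogs are marked by an insertion between
two fixed alignment columns (the anchors, columns 150 and 151 by default:
the residues immediately flanking the motif).  A sequence's motif class is
decided purely by the number of non-gap residues strictly between the
anchors — e.g. {4: "4aa", 7: "7aa", 12: "12aa"} — with the raw segment kept
for manual inspection.  Zero residues means the motif is absent; a length
matching no class is reported as unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CoordinateError
from .io import GAP, Alignment

ABSENT = "absent"
UNCLASSIFIED = "unclassified"

#: motif lengths observed among bacterial class-I release factors
DEFAULT_CLASSES = {4: "4aa", 7: "7aa", 12: "12aa"}

DEFAULT_LEFT_ANCHOR = 150
DEFAULT_RIGHT_ANCHOR = 151


@dataclass(frozen=True)
class MotifCall:
    id: str
    motif_class: str
    segment: str
    segment_length: int


def classify_motifs(
    aln: Alignment,
    left_anchor: int = DEFAULT_LEFT_ANCHOR,
    right_anchor: int = DEFAULT_RIGHT_ANCHOR,
    classes: dict[int, str] | None = None,
) -> list[MotifCall]:
    """Classify each sequence's inter-anchor segment by residue count."""
    if classes is None:
        classes = dict(DEFAULT_CLASSES)
    if not (1 <= left_anchor < right_anchor <= aln.length):
        raise CoordinateError(
            f"anchors ({left_anchor}, {right_anchor}) invalid for length {aln.length}"
        )
    calls = []
    for sid, row in zip(aln.ids, aln.rows):
        segment = row[left_anchor:right_anchor - 1].replace(GAP, "")
        n = len(segment)
        if n == 0:
            label = ABSENT
        else:
            label = classes.get(n, UNCLASSIFIED)
        calls.append(
            MotifCall(id=sid, motif_class=label, segment=segment, segment_length=n)
        )
    return calls


def motif_partition(calls: list[MotifCall]) -> dict[str, set[str]]:
    """Disjoint id sets keyed by motif class; the union is every id."""
    out: dict[str, set[str]] = {}
    for call in calls:
        out.setdefault(call.motif_class, set()).add(call.id)
    return out


def write_motif_tsv(calls: list[MotifCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tmotif_class\tsegment_length\tsegment\n")
        for c in calls:
            fh.write(f"{c.id}\t{c.motif_class}\t{c.segment_length}\t{c.segment}\n")
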