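"""Classify the anchored indel motif carried by each sequence.

Converted release-factor paralogs are marked by an insertion at a fixed
loop position; the class (4aa / 7aa / 12aa) is decided by the number of
non-gap residues between the two anchor columns flanking the insertion.
"""

import paraconv as pc
from paraconv.io import Alignment
from paraconv.motif import motif_partition

rows = {
    "Bacteroidia_RF1":  "QKAIEGHIKLMNPQRSTE",   # 12 residues between anchors
    "Bacteroidia_RF2":  "QKAWEGHIKLMNPQRSTE",
    "Flavobact_RF1":    "QKA--------IEGHRTE",   # 4-residue motif
    "Chloroflexi_RF2":  "QKA-----IEGHIKLSTE",   # 7-residue motif
    "Outgroup_RF1":     "QKA------------STE",   # motif absent
}
aln = Alignment(ids=tuple(rows), rows=tuple(rows.values()), alphabet="AA")

calls = pc.classify_motifs(aln, left_anchor=3, right_anchor=16)
for call in calls:
    print(f"{call.id:<18} {call.motif_class:<12} "
          f"segment={call.segment or '-'} ({call.segment_length} aa)")

print()
for label, ids in sorted(motif_partition(calls).items()):
    print(f"{label}: {sorted(ids)}")

# Shared motif classes across RF1 and RF2 of the same lineage are the
# marker that nominates candidate converted pairs for the window scan.
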