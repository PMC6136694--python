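"""Marker-gene windows and the merge rules on a small hand-built genome.

Two Spo0F marker genes (fbaA at ORF 10, transaldolase at ORF 14) are three
intervening ORFs apart, so their +/-4 windows merge into one neighborhood; a
third marker far away (CTP synthase at ORF 40) stays separate.
"""

from spo0scan.model import DomainHit, Gene, GenomeAnnotation, Replicon, SPO0F_MARKERS
from spo0scan.neighborhoods import discover_neighborhoods, neighborhoods_to_table

genes, proteins, hits = [], {}, []
for i in range(60):
    gid = f"toy_{i:03d}"
    genes.append(Gene(gid, "toy", "chr", i, i * 1000 + 1, i * 1000 + 300, "+", 100))
    proteins[gid] = "A" * 100
for i, dom in [(10, "F_bp_aldolase"), (14, "Transaldolase"), (40, "CTP_Synth_N")]:
    hits.append(DomainHit(f"toy_{i:03d}", dom, "PFAM", 2, 90, 1e-30))
ann = GenomeAnnotation("toy", [Replicon("chr", 61000)], genes, proteins, hits)

merged = discover_neighborhoods(ann, SPO0F_MARKERS)
print(f"{len(merged)} merged neighborhoods:")
print(neighborhoods_to_table(ann, merged).to_string(index=False))
# The first row spans ORFs 6..18 (the union of the two overlapping windows);
# the second covers ORFs 36..44 around the isolated marker.  A Spo0F
# candidate would be searched for among the member genes of these sets.
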