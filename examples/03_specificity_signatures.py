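"""Extract specificity-residue signatures from the construct panel and
compare them.

Signatures are read off a local alignment anchored on the conserved
phospho-accepting His (kinases, Spo0B) or Asp (receivers); six residues on
the donor side, seven on the receiver side.
"""

from spo0scan import group_distance_summary, hamming, position_frequency_matrix
from spo0scan.references import default_hiska_profile, default_rec_profile, construct_panel
from spo0scan.specificity import extract_signature

cons = construct_panel()
hp, rp = default_hiska_profile(), default_rec_profile()

kinases = {name: extract_signature(cons[name], hp, name) for name in ("BsKinA", "Dt1918", "Ca0903", "Ca3319")}
for name, sig in kinases.items():
    print(f"{name:8s} {sig.residues}  (anchor His at {sig.anchor_position}, score {sig.alignment_score:.0f})")
print(f"BsKinA vs Dt1918 Hamming distance: {hamming(kinases['BsKinA'], kinases['Dt1918'])}")
# Distance 1 is why the D. acetoxidans kinase was the natural candidate for
# cross-species phosphotransfer against the B. subtilis relay.

relay = [kinases["BsKinA"], kinases["Dt1918"]]
direct = [kinases["Ca0903"], kinases["Ca3319"]]
dist = group_distance_summary({"relay": relay, "direct": direct})
print("\nmean pairwise Hamming distances (within on the diagonal):")
print(dist.round(2).to_string())
# Phosphorelay kinase signatures cluster apart from direct-phosphorylation
# kinase signatures — the signal behind the kinase-driven remodeling model.

receivers = [extract_signature(cons[n], rp, n) for n in ("Bs0F", "Dt0F", "Bs0A", "Dt0A", "Ca0A")]
print("\nreceiver position frequency matrix (counts per signature position):")
m = position_frequency_matrix(receivers)
print(m.loc[:, (m != 0).any()].to_string())
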