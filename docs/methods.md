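# Methods

## Overview

`spo0scan` predicts, per bacterial genome, the components and architecture of
the sporulation-initiation (Spo0) signaling pathway from three inputs: gene
coordinates (GFF3), protein sequences (FASTA), and precomputed protein-domain
calls (a TSV subset of hmmscan domtblout; Pfam- and Agfam-style names). It
never runs an HMM search itself. The unit of analysis is one annotated
genome; cohort runs add a species tree (Newick) for ordering and for a
parsimony summary of architecture changes.

## Gene neighborhoods

Spo0F and Spo0B cannot be identified by sequence alone, so they are located
by conserved gene context. A *marker gene* is any gene with a hit to a
marker domain (Spo0F: `F_bp_aldolase`, `Transaldolase`, `CTP_Synth_N`;
Spo0B: `GTP1_OBG`, `Ribosomal_L21p`, `Ribosomal_L27`). Each marker gene
defines a window of the `radius = 4` adjacent ORFs up- and downstream
(ORF rank is coordinate order per replicon; windows wrap across the origin
of circular replicons and never span replicons). Windows are merged
transitively when they share a member gene or when two marker genes are
separated by at most `merge_gap = 4` intervening ORFs, regardless of
intergenic distance in base pairs. "No more than four ORFs" is read as ≤ 4
*intervening* ORFs (markers at ranks 10 and 15 merge; 10 and 16 do not);
`merge_gap` is configurable to absorb the alternative reading. Merging is
idempotent and input-order invariant (property-tested), and every marker
gene ends up in exactly one merged neighborhood.

When several merged neighborhoods exist, the marker neighborhood is chosen
by priority: (1) a set containing a candidate gene (stand-alone REC protein
for Spo0F; alignable Pfam-free protein for Spo0B), (2) the set with the most
distinct marker genes, (3) the set with the lowest member ORF rank — a
deterministic stand-in for an otherwise arbitrary choice.

`select_marker_domains` reconstructs the marker-choice procedure for method
development: candidate domains are ranked by the add-one-smoothed log-odds
of occurring inside guide neighborhoods versus in outside genes,

    score(d) = log[(n_in+1)/(N_in+2)] − log[(n_out+1)/(N_out+2)],

with ties broken by smaller mean ORF distance to the anchoring marker genes
(domains encoded close to the anchor are favored), then by name. With small
guide sets the smoothing can leave a domain that is merely *rare* outside
with a positive score; the sign is only informative when outside occurrence
is appreciable.

## Component classifiers

**Spo0A** — any gene with a `Spo0A_C` hit, genome-wide; a missing REC hit is
flagged `no_REC`, never silently dropped.

**Spo0F** — within the chosen Spo0F neighborhood, a protein whose domain
annotation consists of exactly one REC hit (`Response_reg`; aliases
configurable) covering at least `min_rec_coverage = 0.90` of the protein
(inclusive). Raising the threshold can only remove candidates. If more than
one member qualifies, the highest-coverage one is emitted flagged
`multiple_candidates`; proteins shorter than 100 aa are flagged `truncated`.
CheY-like proteins elsewhere in the genome are not candidates: the context
restriction *is* the classifier.

**Spo0B** — within the chosen Spo0B neighborhood, a protein with zero
Pfam-db hits whose local alignment to the first 50 residues of the reference
Spo0B reaches ≥ 25 % identity over ≥ 40 aligned columns (BLOSUM62, affine
gaps −11/−1). These thresholds operationalize "alignable"; they are the
package's own choice, exposed in `ScanParams`. Whether the candidate lies
between the L27 and ObgE genes is recorded as evidence
(`between_L27_ObgE`) but not required, since gene order is an observation
about known Spo0B loci rather than part of the selection criterion.

**Kinases** — proteins with both a HisKA-family hit (`HisKA`, `HisKA_2`,
`HisKA_3`, `HWE_HK`) and catalytic evidence (`HATPase_c`, or an Agfam
`HK_CA*` row, whose family label is passed through, never computed). A
co-occurring REC hit marks a hybrid kinase. A kinase is an *orphan* iff no
other gene within ± `orphan_window = 4` ORFs carries a two-component domain
(REC, HisKA family, HPt); the window mirrors the neighborhood radius because
"co-located" is not otherwise quantified. The relation is symmetric by
construction. Primary sporulation-kinase candidates are non-hybrid orphans
with a PAS/PAC hit starting before the HisKA hit; PAS-less non-hybrid
orphans form a secondary tier; hybrids are excluded from both tiers because
their fused REC domain insulates them from non-cognate receivers.

## Specificity residues

Partner choice in His–Asp phosphotransfer is governed by six interface
residues on the phosphodonor (HisKA helix hairpin; Spo0B is treated with the
same profile because its four-helix bundle presents an equivalent interface)
and seven on the receiver. Extraction aligns the target locally against a
panel of three reference domains per role, takes the best-scoring alignment
(ties by reference order; minimum raw score 40), maps the reference anchor
(the conserved His or Asp) onto the target, and reads residues at fixed
anchor-relative offsets through the alignment. Offsets are data (profile
sidecar TSV), not code. Positions falling in gaps or off the protein yield
`'-'` with a `gapped_position` flag; failure to anchor yields an all-gap
signature flagged `no_anchor`.

**Synthetic reference data.** The natural reference sequences (the *E. coli*
HisKA/REC panels and the *B. subtilis* Spo0B N-terminus) are not shipped;
`scripts/build_reference_data.py` deterministically builds synthetic
scaffold references in their place, together with a synthetic stand-in for
the 11 tagged expression-construct proteins in which the published
specificity strings are planted at the profile offsets (files are labelled
`*_synthetic*`). The shipped offsets (donor: +3,+4,+7,+8,+11,+12 from the
anchor His; receiver: +5,+6,+9,+10,+13,+56,+57 from the anchor Asp) are
helix-face-plausible, non-contiguous positions calibrated against this
panel: the calibration test demonstrates that anchored extraction recovers
every planted string exactly. Consequently the calibration validates the
extraction *machinery* with known truth; applying the package to real
genomes requires re-deriving offsets against natural reference sequences
with experimentally known specificity residues, which the profile-file
format supports without code changes.

Signature comparison uses Hamming distance (`'-'` mismatches every residue;
two gaps match), a metric on gap-free strings (property-tested). Cohort
summaries are position frequency matrices (counts per signature position,
gaps excluded; directly consumable by logo tools) and a within/between-group
mean pairwise distance table — the package's declared statistic for
comparing signature similarity across taxonomic or architectural groupings.

## Architecture and phylogeny

The architecture call is a pure function of the per-genome inventory:
Spo0A ∧ Spo0F ∧ Spo0B ⇒ `PHOSPHORELAY`; Spo0A alone ⇒ `DIRECT`; Spo0A with
exactly one intermediate ⇒ `PARTIAL_RELAY` (both partial cases map to the
same label rather than being forced into either class); no Spo0A ⇒
`NO_SPO0`.

Patchiness of the architecture distribution is quantified with Fitch small
parsimony: the minimum number of label changes on a rooted tree explaining
the leaf labels. Leaves labeled outside the considered state set (e.g.
`NO_SPO0`) are pruned first; polytomies are resolved deterministically by
left-folding children in sorted order (different resolutions of a polytomy
can change the count, so determinism matters more than any particular
resolution). By default the three Spo0 states are distinct unordered
states; treating `PARTIAL_RELAY` as `PHOSPHORELAY` is a caller-side
relabeling. The implementation is verified against brute-force enumeration
over all internal labelings on random trees with ≤ 8 leaves.

## Synthetic genomes

The generator emulates what the pipeline consumes, not sequence evolution:
2000–4000 ORFs on one circular replicon, ~20 paired two-component operons
and 5 CheY-like stand-alone REC decoys per genome, filler genes with pool
domains at rate 0.3. Architecture-dependent content: Spo0F (124 aa, single
REC hit covering 92.7 %) immediately upstream of fbaA with transaldolase
and CTP synthase 0–2 ORFs apart; a 190 aa Pfam-free Spo0B between L27 and
ObgE whose N-terminus is the reference mutated at rate 0.15; Spo0A with
REC + Spo0A_C; 2–5 orphan kinases (PAS with probability 0.8, plus an
occasional hybrid orphan decoy). Fillers within the Spo0B neighborhood
always carry a domain, mimicking the gene-dense ribosomal-protein cluster;
this makes the zero-noise Spo0B call exact rather than probabilistic.
Protein sequences are random except where alignment matters; planted
signatures are the published *B. subtilis* / *C. acetobutylicum* strings
mutated at 10 % per position. Noise knobs: marker deletion probability,
per-hit domain dropout, and the mutation rates above. All randomness flows
from `default_rng([seed, genome_index])`, so outputs are byte-identical for
a given seed and configuration.

What passing tests therefore show: the decision rules, merge algebra,
anchored extraction, and architecture logic are implemented exactly and are
robust to the modeled noise (Spo0F recall degrades monotonically with
domain dropout). What they do not show: performance on real annotation
error modes (split/fused ORFs, missed domains correlated by family,
horizontally transferred neighborhoods), which the synthetic data does not
model.

## Problem sizes and numerical choices

The property suites run at 50 genomes (classifier precision/recall), 200
random trees (parsimony oracle), 500 marker layouts (merge algebra), and a
16-leaf clade (end-to-end recovery) — sizes chosen to exercise every code
path many times while keeping the default suite fast. Alignment uses
BLOSUM62 with gap open −11 / extend −1 throughout; identity is computed
over aligned (non-gap) columns only. Ties anywhere (reference choice,
candidate choice, neighborhood choice, polytomy resolution) are broken
deterministically and documented at the site. Degenerate inputs (empty
domain tables, empty signature lists, single-leaf trees, genomes missing
from the tree) return well-defined empty or flagged results rather than
raising, except where the input is unusable (duplicate gene IDs, unlabeled
leaves, empty guide sets), which is a hard error.

## Known limitations

* Real-genome headline counts (e.g. cohort fractions of Spo0A/Spo0F/Spo0B
  across 84 Firmicutes) depend on specific Pfam/Agfam annotation versions
  and genome sets and are out of scope here.
* Shipped specificity offsets are calibrated to synthetic references, not to
  the natural HisKA/REC panels (see above).
* Orphan status is a window heuristic; kinases adjacent to non-cognate
  two-component genes of unrelated pathways are conservatively non-orphan.
* Ancestral-state claims beyond the parsimony count (which architecture was
  ancestral) are interpretation, not computation, and are not emitted.
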