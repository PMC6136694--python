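"""Classifiers for the three Spo0 pathway proteins.

* Spo0A is the one Spo0 protein with a diagnostic domain: its Spo0A_C
  DNA-binding domain uniquely distinguishes it from other response
  regulators, so it is called genome-wide from domain content alone.
* Spo0F is a stand-alone REC-domain protein, indistinguishable from CheY by
  sequence; it is called only inside a merged Spo0F marker neighborhood as
  the protein whose domain annotation consists of exactly one REC hit
  covering at least ``min_rec_coverage`` of the protein.
* Spo0B lacks recognizable Pfam domains; it is called inside a merged Spo0B
  marker neighborhood as a Pfam-domain-free protein alignable to the
  N-terminal 50 residues of B. subtilis Spo0B.  The identity/length
  thresholds that operationalize "alignable" are this package's own
  (configurable) choice.  Placement between the L27 and ObgE genes is
  recorded as supporting evidence but not required.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .align import AlignParams, align_local
from .model import (
    Gene,
    GenomeAnnotation,
    Neighborhood,
    Role,
    Spo0Candidate,
)

SPO0A_C = "Spo0A_C"
REC_DOMAINS = ("Response_reg",)  # PF00072; aliases may be added via config
PAS_DOMAINS = ("PAS", "PAC")
TRUNCATED_SPO0F_AA = 100  # below this a Spo0F candidate is flagged truncated


def classify_spo0a(ann: GenomeAnnotation, rec_domains: Sequence[str] = REC_DOMAINS) -> list[Spo0Candidate]:
    """Genome-wide Spo0A call: any gene with a Spo0A_C hit.

    Candidates lacking a REC hit are kept but flagged ``no_REC`` (the
    canonical Spo0A architecture is REC + Spo0A_C).
    """
    out: list[Spo0Candidate] = []
    rec = set(rec_domains)
    for g in ann.genes:
        doms = ann.domain_names(g.gene_id)
        if SPO0A_C not in doms:
            continue
        flags: set[str] = set()
        if not (doms & rec):
            flags.add("no_REC")
        out.append(
            Spo0Candidate(
                role=Role.SPO0A.value,
                gene_id=g.gene_id,
                genome_id=ann.genome_id,
                evidence={"domains": sorted(doms)},
                confidence_flags=flags,
            )
        )
    return out


def rec_only_coverage(ann: GenomeAnnotation, gene: Gene, rec_domains: Sequence[str] = REC_DOMAINS) -> Optional[float]:
    """REC coverage fraction if the protein's hits are exactly one REC hit, else None."""
    hits = ann.hits(gene.gene_id)
    if len(hits) != 1 or hits[0].domain_name not in set(rec_domains):
        return None
    h = hits[0]
    return (h.ali_to - h.ali_from + 1) / gene.product_length


def is_spo0f_like(
    ann: GenomeAnnotation,
    gene: Gene,
    min_rec_coverage: float = 0.90,
    rec_domains: Sequence[str] = REC_DOMAINS,
) -> bool:
    """Stand-alone REC protein test (also the S4-Fig candidate predicate)."""
    cov = rec_only_coverage(ann, gene, rec_domains)
    return cov is not None and cov >= min_rec_coverage


def classify_spo0f(
    nbhd: Neighborhood,
    ann: GenomeAnnotation,
    min_rec_coverage: float = 0.90,
    rec_domains: Sequence[str] = REC_DOMAINS,
) -> Optional[Spo0Candidate]:
    """The stand-alone REC protein inside a merged Spo0F marker neighborhood.

    A qualifying protein encodes only a single REC domain taking up
    ``min_rec_coverage`` (default 90%, inclusive) or more of the protein.
    If several members qualify, the highest-coverage one is emitted with a
    ``multiple_candidates`` flag.
    """
    if nbhd.target is not None and nbhd.target != "SPO0F":
        raise ValueError(f"neighborhood targets {nbhd.target}, not SPO0F")
    qualifying: list[tuple[float, Gene]] = []
    for g in nbhd.member_genes(ann):
        cov = rec_only_coverage(ann, g, rec_domains)
        if cov is not None and cov >= min_rec_coverage:
            qualifying.append((cov, g))
    if not qualifying:
        return None
    qualifying.sort(key=lambda t: (-t[0], t[1].gene_id))
    cov, gene = qualifying[0]
    flags: set[str] = set()
    if len(qualifying) > 1:
        flags.add("multiple_candidates")
    if gene.product_length < TRUNCATED_SPO0F_AA:
        flags.add("truncated")
    return Spo0Candidate(
        role=Role.SPO0F.value,
        gene_id=gene.gene_id,
        genome_id=ann.genome_id,
        evidence={
            "rec_coverage": cov,
            "neighborhood": f"{nbhd.replicon_id}:{nbhd.min_index}",
            "product_length": gene.product_length,
        },
        confidence_flags=flags,
    )


def classify_spo0b(
    nbhd: Neighborhood,
    ann: GenomeAnnotation,
    ref_nterm: str,
    align_params: AlignParams = AlignParams(),
    min_identity: float = 0.25,
    min_aligned: int = 40,
) -> Optional[Spo0Candidate]:
    """A Pfam-domain-free protein alignable to the Spo0B N-terminal reference.

    ``ref_nterm`` is the first ~50 residues of a reference Spo0B.  Whether
    the candidate lies between the L27 and ObgE genes is recorded as a
    ``between_L27_ObgE`` evidence flag (informative, not required).
    """
    if not ref_nterm:
        raise ValueError("missing Spo0B N-terminal reference sequence")
    if nbhd.target is not None and nbhd.target != "SPO0B":
        raise ValueError(f"neighborhood targets {nbhd.target}, not SPO0B")
    passing: list[tuple[float, float, int, Gene]] = []
    for g in nbhd.member_genes(ann):
        if any(h.db == "PFAM" for h in ann.hits(g.gene_id)):
            continue
        seq = ann.proteins.get(g.gene_id)
        if not seq:
            continue
        aln = align_local(ref_nterm, seq, align_params)
        if aln is None:
            continue
        if aln.identity >= min_identity and aln.aligned_columns >= min_aligned:
            passing.append((aln.score, aln.identity, aln.aligned_columns, g))
    if not passing:
        return None
    passing.sort(key=lambda t: (-t[0], t[3].gene_id))
    score, identity, ncols, gene = passing[0]
    flags: set[str] = set()
    if len(passing) > 1:
        flags.add("multiple_candidates")
    evidence = {
        "identity": identity,
        "aligned_columns": ncols,
        "alignment_score": score,
        "neighborhood": f"{nbhd.replicon_id}:{nbhd.min_index}",
        "between_L27_ObgE": _between_l27_obge(nbhd, ann, gene),
    }
    return Spo0Candidate(
        role=Role.SPO0B.value,
        gene_id=gene.gene_id,
        genome_id=ann.genome_id,
        evidence=evidence,
        confidence_flags=flags,
    )


def _between_l27_obge(nbhd: Neighborhood, ann: GenomeAnnotation, gene: Gene) -> bool:
    l27 = [g.orf_index for g in nbhd.member_genes(ann) if "Ribosomal_L27" in ann.domain_names(g.gene_id)]
    obg = [g.orf_index for g in nbhd.member_genes(ann) if "GTP1_OBG" in ann.domain_names(g.gene_id)]
    i = gene.orf_index
    return any(min(a, b) < i < max(a, b) for a in l27 for b in obg)
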