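"""Histidine-kinase inventory: orphan status, N-terminal PAS, candidate Spo0 kinases.

Experimentally verified sporulation kinases share no diagnostic sequence
feature, but they are orphans — not co-located with other two-component
signaling genes — and N-terminal PAS sensor domains occur more often in
sporulation kinases than in the kinase complement at large.  Orphan status
combined with an N-terminal PAS domain is therefore the primary prediction
signature; PAS-less orphans form a secondary tier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .model import GenomeAnnotation, KinaseRecord

HISKA_DOMAINS = ("HisKA", "HisKA_2", "HisKA_3", "HWE_HK")
CATALYTIC_DOMAINS = ("HATPase_c",)
AGFAM_CATALYTIC_PREFIX = "HK_CA"
REC_DOMAINS = ("Response_reg",)
HPT_DOMAINS = ("Hpt", "HPT")
PAS_DOMAINS = ("PAS", "PAC")

#: domains marking a gene as a two-component signaling protein for the
#: purposes of orphan-status assignment
TCS_DOMAINS = HISKA_DOMAINS + REC_DOMAINS + HPT_DOMAINS


def find_histidine_kinases(ann: GenomeAnnotation) -> list[KinaseRecord]:
    """Proteins with both a HisKA-family hit and a kinase catalytic hit.

    The catalytic evidence is a Pfam HATPase_c hit or an Agfam HK_CA row in
    the domain table; the Agfam family name (e.g. ``HK_CA:3``) is passed
    through as an annotation, never computed.  A REC hit on the same protein
    marks a hybrid kinase.
    """
    records: list[KinaseRecord] = []
    for g in ann.genes:
        hits = ann.hits(g.gene_id)
        names = {h.domain_name for h in hits}
        has_hiska = bool(names & set(HISKA_DOMAINS))
        agfam = sorted(
            h.domain_name
            for h in hits
            if h.db == "AGFAM" and h.domain_name.startswith(AGFAM_CATALYTIC_PREFIX)
        )
        has_cat = bool(names & set(CATALYTIC_DOMAINS)) or bool(agfam)
        if not (has_hiska and has_cat):
            continue
        records.append(
            KinaseRecord(
                gene_id=g.gene_id,
                genome_id=ann.genome_id,
                has_hiska=True,
                has_catalytic=True,
                catalytic_family=agfam[0] if agfam else "",
                is_hybrid=bool(names & set(REC_DOMAINS)),
            )
        )
    return records


def assign_orphan_status(
    ann: GenomeAnnotation,
    kinases: list[KinaseRecord],
    window: int = 4,
    tcs_domains: Sequence[str] = TCS_DOMAINS,
) -> list[KinaseRecord]:
    """Mark each kinase orphan iff no other gene within +/- ``window`` ORFs
    encodes a two-component signaling protein; record the nearest distance.

    The relation is symmetric: two adjacent kinases make each other
    non-orphan.
    """
    tcs = set(tcs_domains)
    tcs_index: dict[str, list[int]] = {}  # replicon -> orf indices of TCS genes
    for g in ann.genes:
        if ann.domain_names(g.gene_id) & tcs:
            tcs_index.setdefault(g.replicon_id, []).append(g.orf_index)
    for rec in kinases:
        gene = ann.gene(rec.gene_id)
        n = len(ann.genes_on(gene.replicon_id))
        circ = ann.replicon(gene.replicon_id).circular
        best = float("inf")
        for j in tcs_index.get(gene.replicon_id, []):
            if j == gene.orf_index:
                continue
            d = abs(gene.orf_index - j)
            if circ:
                d = min(d, n - d)
            best = min(best, d)
        rec.nearest_tcs_distance = best
        rec.is_orphan = best > window
    return kinases


def flag_nterm_pas(record: KinaseRecord, ann: GenomeAnnotation) -> KinaseRecord:
    """Set has_nterm_pas iff a PAS/PAC hit starts before the HisKA hit."""
    hits = ann.hits(record.gene_id)
    hiska_starts = [h.ali_from for h in hits if h.domain_name in HISKA_DOMAINS]
    if not hiska_starts:
        record.has_nterm_pas = False
        return record
    first_hiska = min(hiska_starts)
    record.has_nterm_pas = any(
        h.ali_from < first_hiska for h in hits if h.domain_name in PAS_DOMAINS
    )
    return record


@dataclass
class SporulationKinasePrediction:
    """Candidate sporulation kinases, tiered by confidence."""

    primary: list[str] = field(default_factory=list)  # orphan + N-terminal PAS, non-hybrid
    secondary: list[str] = field(default_factory=list)  # PAS-less non-hybrid orphans


def predict_sporulation_kinases(records: Sequence[KinaseRecord]) -> SporulationKinasePrediction:
    """Nominate Spo0 kinase candidates from orphan and PAS flags.

    Hybrid kinases are excluded from both tiers: their fused REC domain
    insulates them from non-cognate receivers.
    """
    pred = SporulationKinasePrediction()
    for rec in records:
        if not rec.is_orphan or rec.is_hybrid:
            continue
        (pred.primary if rec.has_nterm_pas else pred.secondary).append(rec.gene_id)
    return pred


def kinase_inventory_table(records: Sequence[KinaseRecord]):
    """One row per kinase with all flags and distances."""
    import pandas as pd

    rows = [
        dict(
            genome_id=r.genome_id,
            gene_id=r.gene_id,
            catalytic_family=r.catalytic_family,
            is_hybrid=r.is_hybrid,
            is_orphan=r.is_orphan,
            has_nterm_pas=r.has_nterm_pas,
            nearest_tcs_distance=r.nearest_tcs_distance,
        )
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "gene_id",
            "catalytic_family",
            "is_hybrid",
            "is_orphan",
            "has_nterm_pas",
            "nearest_tcs_distance",
        ],
    )
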