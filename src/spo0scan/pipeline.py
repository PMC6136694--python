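"""End-to-end orchestration: load -> neighborhoods -> classifiers -> kinases
-> signatures -> architecture -> report.

The library entry point is :func:`scan_annotation` (one genome, in memory)
and :func:`scan_annotations` (a cohort, optionally with a species tree);
:func:`run_scan` wraps them with file I/O, per-genome fault tolerance, and a
machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .align import AlignParams
from .annotation_io import read_annotation, read_phenotype_table
from .classifiers import classify_spo0a, classify_spo0b, classify_spo0f, is_spo0f_like
from .kinases import (
    assign_orphan_status,
    find_histidine_kinases,
    flag_nterm_pas,
    kinase_inventory_table,
    predict_sporulation_kinases,
)
from .model import (
    GenomeAnnotation,
    MarkerSpec,
    Spo0Inventory,
    SPO0B_MARKERS,
    SPO0F_MARKERS,
)
from .neighborhoods import choose_marker_neighborhood, discover_neighborhoods
from .phylo import call_architecture, fitch_transition_count, itol_annotation, presence_absence_report
from .references import default_hiska_profile, default_rec_profile, spo0b_nterm_reference
from .specificity import (
    SpecificitySignature,
    extract_signature,
    position_frequency_matrix,
    signatures_table,
)

log = logging.getLogger("spo0scan")


@dataclass
class ScanParams:
    """Classifier thresholds and marker specifications for one run."""

    spo0f_markers: MarkerSpec = SPO0F_MARKERS
    spo0b_markers: MarkerSpec = SPO0B_MARKERS
    min_rec_coverage: float = 0.90
    spo0b_min_identity: float = 0.25
    spo0b_min_aligned: int = 40
    orphan_window: int = 4
    align_params: AlignParams = AlignParams()

    def validate(self) -> None:
        if not (0.0 < self.min_rec_coverage <= 1.0):
            raise ValueError("min_rec_coverage outside (0, 1]")
        if not (0.0 <= self.spo0b_min_identity <= 1.0):
            raise ValueError("spo0b_min_identity outside [0, 1]")
        if self.orphan_window < 0:
            raise ValueError("orphan_window must be >= 0")


@dataclass
class GenomeScanResult:
    inventory: Spo0Inventory
    architecture: str
    signatures: list[SpecificitySignature] = field(default_factory=list)
    sporulation_kinase_candidates: list[str] = field(default_factory=list)
    secondary_kinase_candidates: list[str] = field(default_factory=list)


def scan_annotation(ann: GenomeAnnotation, params: Optional[ScanParams] = None) -> GenomeScanResult:
    """Run every prediction stage on one loaded genome."""
    params = params or ScanParams()
    params.validate()
    b_ref = spo0b_nterm_reference()

    spo0a = classify_spo0a(ann)

    spo0f = None
    f_nbhds = discover_neighborhoods(ann, params.spo0f_markers)
    if f_nbhds:
        chosen = choose_marker_neighborhood(
            f_nbhds, ann, lambda a, g: is_spo0f_like(a, g, params.min_rec_coverage)
        )
        spo0f = classify_spo0f(chosen, ann, params.min_rec_coverage)

    spo0b = None
    b_nbhds = discover_neighborhoods(ann, params.spo0b_markers)
    if b_nbhds:

        def spo0b_like(a: GenomeAnnotation, g) -> bool:
            if any(h.db == "PFAM" for h in a.hits(g.gene_id)):
                return False
            from .align import align_local

            seq = a.proteins.get(g.gene_id)
            if not seq:
                return False
            aln = align_local(b_ref, seq, params.align_params)
            return (
                aln is not None
                and aln.identity >= params.spo0b_min_identity
                and aln.aligned_columns >= params.spo0b_min_aligned
            )

        chosen = choose_marker_neighborhood(b_nbhds, ann, spo0b_like)
        spo0b = classify_spo0b(
            chosen,
            ann,
            b_ref,
            params.align_params,
            params.spo0b_min_identity,
            params.spo0b_min_aligned,
        )

    kinases = find_histidine_kinases(ann)
    kinases = assign_orphan_status(ann, kinases, params.orphan_window)
    for rec in kinases:
        flag_nterm_pas(rec, ann)
    prediction = predict_sporulation_kinases(kinases)

    hiska_prof = default_hiska_profile()
    rec_prof = default_rec_profile()
    sigs: list[SpecificitySignature] = []
    for cand in spo0a:
        sigs.append(extract_signature(ann.proteins[cand.gene_id], rec_prof, cand.gene_id, params.align_params))
    if spo0f is not None:
        sigs.append(extract_signature(ann.proteins[spo0f.gene_id], rec_prof, spo0f.gene_id, params.align_params))
    if spo0b is not None:
        sigs.append(extract_signature(ann.proteins[spo0b.gene_id], hiska_prof, spo0b.gene_id, params.align_params))
    for rec in kinases:
        if rec.is_orphan:
            sigs.append(extract_signature(ann.proteins[rec.gene_id], hiska_prof, rec.gene_id, params.align_params))

    inv = Spo0Inventory(
        genome_id=ann.genome_id,
        spo0a=spo0a,
        spo0f=spo0f,
        spo0b=spo0b,
        kinases=kinases,
        phenotype=ann.sporulation_phenotype,
    )
    return GenomeScanResult(
        inventory=inv,
        architecture=call_architecture(inv).label,
        signatures=sigs,
        sporulation_kinase_candidates=prediction.primary,
        secondary_kinase_candidates=prediction.secondary,
    )


@dataclass
class CohortScanResult:
    results: dict[str, GenomeScanResult]
    failed: dict[str, str] = field(default_factory=dict)
    transition_count: Optional[int] = None
    report: Optional[pd.DataFrame] = None


def scan_annotations(
    anns: Sequence[GenomeAnnotation],
    params: Optional[ScanParams] = None,
    tree_newick: Optional[str] = None,
    strict: bool = False,
) -> CohortScanResult:
    """Scan a cohort; one genome failing does not abort the run unless strict."""
    out = CohortScanResult(results={})
    for ann in anns:
        try:
            out.results[ann.genome_id] = scan_annotation(ann, params)
        except Exception as exc:  # noqa: BLE001 - per-genome fault containment
            if strict:
                raise
            log.warning("genome %s failed: %s", ann.genome_id, exc)
            out.failed[ann.genome_id] = str(exc)
    invs = [r.inventory for r in out.results.values()]
    out.report = presence_absence_report(invs, tree_newick)
    if tree_newick is not None and invs:
        labels = {gid: r.architecture for gid, r in out.results.items()}
        try:
            out.transition_count = fitch_transition_count(
                tree_newick, labels, states=["PHOSPHORELAY", "DIRECT", "PARTIAL_RELAY"]
            )
        except ValueError as exc:
            log.warning("transition count skipped: %s", exc)
    return out


@dataclass
class RunConfig:
    genome_dir: str
    out_dir: str
    tree_path: Optional[str] = None
    phenotype_path: Optional[str] = None
    params: ScanParams = field(default_factory=ScanParams)
    strict: bool = False
    seed: int = 0


def _inventory_rows(result: GenomeScanResult) -> list[dict]:
    inv = result.inventory
    rows = []
    for cand in inv.spo0a:
        rows.append(dict(genome_id=inv.genome_id, role="SPO0A", gene_id=cand.gene_id,
                         flags=",".join(sorted(cand.confidence_flags)),
                         evidence=json.dumps(cand.evidence, sort_keys=True)))
    for cand in (inv.spo0f, inv.spo0b):
        if cand is not None:
            rows.append(dict(genome_id=inv.genome_id, role=cand.role, gene_id=cand.gene_id,
                             flags=",".join(sorted(cand.confidence_flags)),
                             evidence=json.dumps(cand.evidence, sort_keys=True)))
    return rows


def run_scan(cfg: RunConfig) -> Path:
    """Scan every genome under ``genome_dir`` and write versioned outputs.

    Expects ``<genome>.gff3``, ``<genome>.faa`` and ``<genome>.domains.tsv``
    triplets.  Writes inventory, signature, kinase and architecture tables,
    per-role frequency matrices, an iTOL annotation (when a tree is given),
    and a manifest with per-stage counts.  Returns the output directory.
    """
    cfg.params.validate()
    genome_dir = Path(cfg.genome_dir)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    phenotypes = read_phenotype_table(cfg.phenotype_path) if cfg.phenotype_path else {}
    tree_newick = Path(cfg.tree_path).read_text() if cfg.tree_path else None
    if cfg.tree_path is None:
        log.info("no tree supplied; tree-dependent outputs skipped")

    anns: list[GenomeAnnotation] = []
    load_failures: dict[str, str] = {}
    for gff in sorted(genome_dir.glob("*.gff3")):
        gid = gff.stem
        try:
            anns.append(
                read_annotation(
                    gff,
                    genome_dir / f"{gid}.faa",
                    genome_dir / f"{gid}.domains.tsv",
                    phenotype=phenotypes.get(gid),
                    genome_id=gid,
                )
            )
        except Exception as exc:  # noqa: BLE001
            if cfg.strict:
                raise
            log.warning("failed to load %s: %s", gid, exc)
            load_failures[gid] = str(exc)

    cohort = scan_annotations(anns, cfg.params, tree_newick, cfg.strict)

    inv_rows = [row for r in cohort.results.values() for row in _inventory_rows(r)]
    pd.DataFrame(inv_rows, columns=["genome_id", "role", "gene_id", "flags", "evidence"]).to_csv(
        out / "inventory.tsv", sep="\t", index=False
    )
    all_sigs = [s for r in cohort.results.values() for s in r.signatures]
    sig_df = signatures_table(all_sigs)
    sig_df.insert(0, "genome_id", [
        gid for gid, r in cohort.results.items() for _ in r.signatures
    ])
    sig_df.to_csv(out / "signatures.tsv", sep="\t", index=False)

    kin_df = pd.concat(
        [kinase_inventory_table(r.inventory.kinases) for r in cohort.results.values()],
        ignore_index=True,
    ) if cohort.results else kinase_inventory_table([])
    kin_df.to_csv(out / "kinases.tsv", sep="\t", index=False)

    arch = {gid: r.architecture for gid, r in cohort.results.items()}
    pd.DataFrame(
        [dict(genome_id=g, architecture=a) for g, a in arch.items()]
    ).to_csv(out / "architecture.tsv", sep="\t", index=False)
    (out / "architecture.json").write_text(json.dumps(arch, indent=1, sort_keys=True))

    for role in ("HISKA_LIKE", "REC"):
        role_sigs = [s for s in all_sigs if s.role == role and "no_anchor" not in s.flags]
        if role_sigs:
            position_frequency_matrix(role_sigs).to_csv(
                out / f"frequency_matrix_{role.lower()}.tsv", sep="\t"
            )

    assert cohort.report is not None
    cohort.report.to_csv(out / "report.tsv", sep="\t", index=False)
    if tree_newick is not None:
        (out / "itol_spo0.txt").write_text(itol_annotation(cohort.report))

    counts = dict(
        genomes_loaded=len(anns),
        genomes_scanned=len(cohort.results),
        genomes_failed=len(cohort.failed) + len(load_failures),
        with_spo0a=sum(1 for r in cohort.results.values() if r.inventory.spo0a),
        with_spo0f=sum(1 for r in cohort.results.values() if r.inventory.spo0f),
        with_spo0b=sum(1 for r in cohort.results.values() if r.inventory.spo0b),
        with_orphan_kinase=sum(
            1 for r in cohort.results.values() if any(k.is_orphan for k in r.inventory.kinases)
        ),
        architectures={a: list(arch.values()).count(a) for a in sorted(set(arch.values()))},
        transition_count=cohort.transition_count,
    )
    cfg_blob = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = dict(
        tool="spo0scan",
        version=__version__,
        config=json.loads(cfg_blob),
        config_hash=hashlib.sha256(cfg_blob.encode()).hexdigest()[:16],
        counts=counts,
        failures={**load_failures, **cohort.failed},
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    log.info(
        "scan complete: %d genomes, Spo0A in %d, Spo0F in %d, Spo0B in %d",
        counts["genomes_scanned"], counts["with_spo0a"], counts["with_spo0f"], counts["with_spo0b"],
    )
    return out
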