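"""Reading and writing genome annotations, proteins, and domain-hit tables.

Input dialect
-------------
* GFF3 with CDS features carrying stable ``ID`` attributes; replicon lengths
  come from ``##sequence-region`` pragmas; circularity from a ``region``
  feature with ``Is_circular=true`` (the GFF3 convention) or from an explicit
  ``circular`` argument.
* Protein FASTA keyed by the same IDs.
* Domain hits as a tab-separated table with header
  ``gene_id  domain_name  db  evalue  ali_from  ali_to`` — a strict subset of
  hmmscan ``--domtblout`` content (a converter is provided); the pipeline
  consumes precomputed domain calls and never runs an HMM search itself.

Domain rows referencing unknown genes, or with alignment envelopes outside the
protein, are excluded with a warning and counted in the genome's
:class:`~spo0scan.model.LoadReport`; duplicate gene IDs are a hard error.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional

import gffutils
import pandas as pd
from Bio import SeqIO

from .model import (
    DomainHit,
    Gene,
    GenomeAnnotation,
    LoadReport,
    Phenotype,
    Replicon,
    as_strand,
)

DOMAIN_TABLE_COLUMNS = ["gene_id", "domain_name", "db", "evalue", "ali_from", "ali_to"]


def read_annotation(
    gff_path: str | Path,
    fasta_path: str | Path,
    domains_path: Optional[str | Path] = None,
    phenotype: Optional[str] = None,
    genome_id: Optional[str] = None,
    circular: Optional[dict[str, bool]] = None,
) -> GenomeAnnotation:
    """Load one genome into the pipeline's data model.

    Parameters
    ----------
    gff_path, fasta_path, domains_path
        GFF3 of CDS features, protein FASTA, and the domain-hit TSV.
        ``domains_path=None`` loads a genome with zero domain hits.
    phenotype
        Optional sporulation phenotype (``spore_former`` / ``non_spore_former``).
    genome_id
        Defaults to the GFF file stem.
    circular
        Optional per-replicon circularity overrides.
    """
    gff_path = Path(gff_path)
    gid = genome_id or gff_path.stem
    report = LoadReport()

    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )

    # replicon table from sequence-region pragmas and/or region features
    lengths: dict[str, int] = dict(_sequence_regions(gff_path))
    circ: dict[str, bool] = {}
    for feat in db.features_of_type("region"):
        lengths.setdefault(feat.seqid, feat.end)
        flag = feat.attributes.get("Is_circular", ["false"])[0].lower()
        circ[feat.seqid] = flag == "true"
    if circular:
        circ.update(circular)

    proteins = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}

    raw: list[dict] = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS"):
        fid = feat.attributes.get("ID", [None])[0] or feat.id
        if fid in seen:
            raise ValueError(f"duplicate gene ID {fid!r} in {gff_path}")
        seen.add(fid)
        if fid not in proteins:
            report.skipped_cds_without_translation += 1
            report.messages.append(f"CDS {fid} has no protein sequence; skipped")
            continue
        raw.append(
            dict(
                gene_id=fid,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=as_strand(feat.strand),
                product_length=len(proteins[fid]),
            )
        )

    genes = _assign_orf_indices(gid, raw)
    known = {g.gene_id: g for g in genes}
    proteins = {k: v for k, v in proteins.items() if k in known}

    replicon_ids = sorted({g.replicon_id for g in genes} | set(lengths))
    replicons = [
        Replicon(
            rid,
            lengths.get(rid, max((g.end for g in genes if g.replicon_id == rid), default=1)),
            circ.get(rid, False),
        )
        for rid in replicon_ids
    ]

    hits: list[DomainHit] = []
    if domains_path is not None:
        hits = _read_domain_rows(domains_path, known, report)

    pheno = Phenotype(phenotype).value if phenotype else Phenotype.UNKNOWN.value
    return GenomeAnnotation(
        genome_id=gid,
        replicons=replicons,
        genes=genes,
        proteins=proteins,
        domain_hits=hits,
        sporulation_phenotype=pheno,
        load_report=report,
    )


def _sequence_regions(gff_path: Path) -> Iterable[tuple[str, int]]:
    with open(gff_path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    yield parts[1], int(parts[3])
            elif line and not line.startswith("#"):
                break


def _assign_orf_indices(genome_id: str, raw: list[dict]) -> list[Gene]:
    genes: list[Gene] = []
    byrep: dict[str, list[dict]] = {}
    for row in raw:
        byrep.setdefault(row["replicon_id"], []).append(row)
    for rows in byrep.values():
        rows.sort(key=lambda r: (r["start"], r["end"], r["gene_id"]))
        for i, row in enumerate(rows):
            genes.append(Gene(genome_id=genome_id, orf_index=i, **row))
    return genes


def _read_domain_rows(
    path: str | Path, known: dict[str, Gene], report: LoadReport
) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "domain_name": str, "db": str})
    if df.empty:
        return []
    missing = [c for c in DOMAIN_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"domain table {path} missing columns: {missing}")
    hits: list[DomainHit] = []
    for row in df.itertuples(index=False):
        gene = known.get(row.gene_id)
        if gene is None:
            report.unknown_gene_domain_rows += 1
            report.messages.append(f"domain row for unknown gene {row.gene_id!r} excluded")
            continue
        a, b = int(row.ali_from), int(row.ali_to)
        if not (1 <= a <= b <= gene.product_length):
            report.out_of_range_domain_rows += 1
            report.messages.append(
                f"domain row {row.domain_name} on {row.gene_id} "
                f"({a}-{b}) outside protein of {gene.product_length} aa; excluded"
            )
            continue
        hits.append(
            DomainHit(
                gene_id=row.gene_id,
                domain_name=row.domain_name,
                db=str(row.db),
                ali_from=a,
                ali_to=b,
                score_or_evalue=float(row.evalue),
            )
        )
    if report.excluded_domain_rows:
        warnings.warn(
            f"{report.excluded_domain_rows} domain rows excluded while loading", stacklevel=2
        )
    return hits


def write_annotation(
    ann: GenomeAnnotation,
    gff_path: str | Path,
    fasta_path: str | Path,
    domains_path: str | Path,
) -> None:
    """Write a genome back out in the same GFF3/FASTA/TSV dialect."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in ann.replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {rep.length}\n")
        for rep in ann.replicons:
            circ = "true" if rep.circular else "false"
            fh.write(
                f"{rep.replicon_id}\tspo0scan\tregion\t1\t{rep.length}\t.\t+\t.\t"
                f"ID=region-{rep.replicon_id};Is_circular={circ}\n"
            )
        for rep in ann.replicons:
            for g in ann.genes_on(rep.replicon_id):
                fh.write(
                    f"{g.replicon_id}\tspo0scan\tCDS\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t0\tID={g.gene_id}\n"
                )
    with open(fasta_path, "w") as fh:
        for g in ann.genes:
            seq = ann.proteins.get(g.gene_id)
            if seq:
                fh.write(f">{g.gene_id}\n{seq}\n")
    rows = [
        dict(
            gene_id=h.gene_id,
            domain_name=h.domain_name,
            db=h.db,
            evalue=h.score_or_evalue,
            ali_from=h.ali_from,
            ali_to=h.ali_to,
        )
        for h in ann.domain_hits
    ]
    pd.DataFrame(rows, columns=DOMAIN_TABLE_COLUMNS).to_csv(domains_path, sep="\t", index=False)


def domains_of(ann: GenomeAnnotation, gene_id: str) -> list[DomainHit]:
    """All domain hits on one protein, sorted by alignment start."""
    return ann.hits(gene_id)


def normalized_position(
    ann: GenomeAnnotation, gene_id: str, replicon_id: Optional[str] = None
) -> float:
    """Genomic position of a gene as a fraction of replicon length, in [0, 1).

    The position of the start codon is used for genes on the forward strand
    and the stop codon for genes on the reverse strand; both correspond to the
    leftmost (lowest) coordinate of the CDS.
    """
    gene = ann.gene(gene_id)
    rid = replicon_id or gene.replicon_id
    if rid != gene.replicon_id:
        raise KeyError(f"gene {gene_id} is not on replicon {rid}")
    rep = ann.replicon(rid)
    return (gene.start % rep.length) / rep.length


def convert_domtblout(domtblout_path: str | Path, out_path: str | Path, db: str = "PFAM") -> int:
    """Convert hmmscan ``--domtblout`` output to the pipeline's domain TSV.

    Keeps target name, i-Evalue, and the alignment envelope; returns the
    number of rows written.
    """
    rows = []
    with open(domtblout_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.split()
            rows.append(
                dict(
                    gene_id=f[3],
                    domain_name=f[0],
                    db=db,
                    evalue=float(f[12]),
                    ali_from=int(f[17]),
                    ali_to=int(f[18]),
                )
            )
    pd.DataFrame(rows, columns=DOMAIN_TABLE_COLUMNS).to_csv(out_path, sep="\t", index=False)
    return len(rows)


def read_phenotype_table(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV of genome_id and sporulation status."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "genome_id" not in df.columns or "status" not in df.columns:
        raise ValueError("phenotype table needs columns: genome_id, status")
    return {r.genome_id: Phenotype(r.status).value for r in df.itertuples(index=False)}
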