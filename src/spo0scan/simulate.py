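"""Synthetic annotated genomes with planted Spo0 pathways and ground truth.

The generator emulates the statistical structure of an annotated bacterial
genome as the pipeline sees it: a few thousand ordered ORFs on a circular
chromosome, domain calls per protein, and — depending on the planted
architecture — a Spo0F gene immediately upstream of a fructose-bisphosphate
aldolase (fbaA) gene with transaldolase and CTP synthase nearby, a
Pfam-domain-free Spo0B between the L27 and ObgE genes, a Spo0A with
REC + Spo0A_C domains, and one or more orphan sensor kinases with N-terminal
PAS domains.  Negative controls are planted alongside: CheY-like stand-alone
REC proteins far from the marker neighborhoods, paired (non-orphan)
two-component operons, and domain-free filler proteins.

Protein sequences are random except where an alignment-dependent stage needs
them (Spo0B N-termini and the signature-bearing HisKA/REC regions), which
are mutated copies of the shipped reference scaffolds with the planted
specificity residues spliced in at the profile offsets.  All randomness
flows from one seeded generator; the genome index perturbs the stream
deterministically, so the same seed and configuration reproduce the same
genomes byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .model import (
    Architecture,
    DomainHit,
    Gene,
    GenomeAnnotation,
    Phenotype,
    Replicon,
)
from .references import default_hiska_profile, default_rec_profile, spo0b_nterm_reference

AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_ARR = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

FILLER_DOMAINS = (
    "ABC_tran", "AAA", "DUF3794", "Sigma70_r2", "Helicase_C",
    "Glycos_transf_1", "MFS_1", "Acetyltransf_1", "Radical_SAM", "Aminotran_1_2",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic-genome generator.

    Defaults define the baseline study conditions: zero annotation noise,
    genomes of 2000-4000 genes on one circular chromosome, marker gaps of
    0-2 intervening ORFs, ~20 paired two-component operons and 5 CheY-like
    decoys per genome, and planted specificity signatures derived from the
    published B. subtilis / C. acetobutylicum strings mutated at 10% per
    position.
    """

    seed: int = 0
    n_genomes: int = 1
    genes_per_genome: tuple[int, int] = (2000, 4000)
    circular: bool = True
    architecture: str = Architecture.PHOSPHORELAY.value
    # marker-neighborhood geometry
    marker_gap_range: tuple[int, int] = (0, 2)  # intervening ORFs between Spo0F markers
    # decoys
    n_tcs_operons: int = 20
    n_chey_decoys: int = 5
    filler_domain_prob: float = 0.3
    # kinase complement
    orphan_kinase_range: tuple[int, int] = (2, 5)
    pas_kinase_prob: float = 0.8
    hybrid_orphan_prob: float = 0.5
    # noise
    marker_deletion_prob: float = 0.0
    domain_dropout_prob: float = 0.0
    signature_mutation_rate: float = 0.1
    spo0b_nterm_mutation_rate: float = 0.15
    # base signatures planted (then mutated per genome)
    relay_kinase_signature: str = "TAGFQL"
    direct_kinase_signature: str = "NVSAQV"
    spo0f_signature: str = "QGILEVD"
    spo0b_signature: str = "QLGNSL"
    spo0a_signature: str = "NELLEYD"

    def __post_init__(self) -> None:
        for p in (
            self.marker_deletion_prob,
            self.domain_dropout_prob,
            self.signature_mutation_rate,
            self.spo0b_nterm_mutation_rate,
            self.filler_domain_prob,
            self.pas_kinase_prob,
            self.hybrid_orphan_prob,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for one synthetic genome."""

    genome_id: str
    architecture: str
    roles: dict[str, str] = field(default_factory=dict)  # SPO0A/SPO0F/SPO0B -> gene_id
    orphan_kinases: list[str] = field(default_factory=list)
    pas_orphan_kinases: list[str] = field(default_factory=list)
    hybrid_orphan_kinases: list[str] = field(default_factory=list)
    non_orphan_kinases: list[str] = field(default_factory=list)
    chey_decoys: list[str] = field(default_factory=list)
    signatures: dict[str, dict] = field(default_factory=dict)  # gene_id -> {role, residues}

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


# -- sequence helpers ----------------------------------------------------

def _random_protein(rng: np.random.Generator, n: int) -> str:
    return _AA_ARR[rng.integers(0, 20, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float, protected: frozenset[int] = frozenset()) -> str:
    out = list(seq)
    hit = rng.random(len(out)) < rate
    for i in np.flatnonzero(hit):
        if int(i) in protected:
            continue
        choices = [a for a in AA if a != out[i]]
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _mutate_signature(rng: np.random.Generator, sig: str, rate: float) -> str:
    return _mutate(rng, sig, rate)


def _plant(seq: str, anchor0: int, offsets: Sequence[int], residues: str) -> str:
    out = list(seq)
    for off, aa in zip(offsets, residues):
        out[anchor0 + off] = aa
    return "".join(out)


@dataclass
class _Slot:
    kind: str = "filler"
    aa_len: int = 0
    domains: list[tuple[str, str, int, int]] = field(default_factory=list)  # name, db, from, to
    protein: Optional[str] = None


# -- the generator -------------------------------------------------------

def generate_genome(
    cfg: SimulationConfig,
    genome_index: int = 0,
    architecture: Optional[str] = None,
    genome_id: Optional[str] = None,
) -> tuple[GenomeAnnotation, GroundTruth]:
    """Generate one annotated genome with the requested planted architecture."""
    arch = Architecture(architecture or cfg.architecture).value
    gid = genome_id or f"sim{genome_index:03d}"
    rng = np.random.default_rng([cfg.seed % (2**31), genome_index % (2**31)])

    hiska_prof = default_hiska_profile()
    rec_prof = default_rec_profile()
    hiska_base = hiska_prof.references[0].sequence
    rec_base = rec_prof.references[0].sequence
    h_anchor0 = hiska_prof.references[0].anchor_pos - 1
    r_anchor0 = rec_prof.references[0].anchor_pos - 1
    h_protect = frozenset({h_anchor0} | {h_anchor0 + o for o in hiska_prof.offsets})
    r_protect = frozenset({r_anchor0} | {r_anchor0 + o for o in rec_prof.offsets})
    b_ref = spo0b_nterm_reference()

    truth = GroundTruth(genome_id=gid, architecture=arch)

    n = int(rng.integers(cfg.genes_per_genome[0], cfg.genes_per_genome[1] + 1))
    slots = [_Slot() for _ in range(n)]

    has_a = arch != Architecture.NO_SPO0.value
    has_f = arch == Architecture.PHOSPHORELAY.value
    has_b = arch in (Architecture.PHOSPHORELAY.value, Architecture.PARTIAL_RELAY.value)
    relay_like = has_f or has_b

    n_orph = (
        int(rng.integers(cfg.orphan_kinase_range[0], cfg.orphan_kinase_range[1] + 1))
        if has_a
        else int(rng.integers(0, 3))
    )
    want_hybrid = bool(rng.random() < cfg.hybrid_orphan_prob)

    blocks: list[tuple[str, int]] = [("spo0f_nbhd", 10), ("spo0b_nbhd", 6)]
    if has_a:
        blocks.append(("spo0a", 1))
    blocks += [("kinase", 1)] * n_orph
    if want_hybrid:
        blocks.append(("hybrid_kinase", 1))
    blocks += [("tcs", 2)] * cfg.n_tcs_operons
    blocks += [("chey", 1)] * cfg.n_chey_decoys

    seg = n // len(blocks)
    if seg < 30:
        raise ValueError(
            f"genome of {n} genes too small for {len(blocks)} planted blocks"
        )
    order = rng.permutation(len(blocks))
    kin_sig_base = cfg.relay_kinase_signature if relay_like else cfg.direct_kinase_signature
    mut = cfg.signature_mutation_rate

    def filler_len() -> int:
        return int(np.clip(rng.normal(300, 80), 60, 1200))

    def pool_domain(length: int) -> tuple[str, str, int, int]:
        name = FILLER_DOMAINS[rng.integers(0, len(FILLER_DOMAINS))]
        a = int(rng.integers(1, max(2, length // 4)))
        b = min(length, a + int(rng.integers(40, 160)))
        return (name, "PFAM", a, b)

    def keep_marker() -> bool:
        return rng.random() >= cfg.marker_deletion_prob

    for bpos, bidx in enumerate(order):
        kind, _width = blocks[bidx]
        start = bpos * seg + int(rng.integers(0, max(1, seg - 24)))
        if kind == "spo0f_nbhd":
            _plant_spo0f_block(
                cfg, rng, slots, start, has_f, truth, gid,
                rec_base, r_anchor0, rec_prof.offsets, r_protect,
                keep_marker, filler_len, mut,
            )
        elif kind == "spo0b_nbhd":
            _plant_spo0b_block(
                cfg, rng, slots, start, has_b, truth, gid,
                b_ref, h_anchor0, hiska_prof.offsets, h_protect,
                keep_marker, mut,
            )
        elif kind == "spo0a":
            _plant_spo0a(cfg, rng, slots, start, truth, gid,
                         rec_base, r_anchor0, rec_prof.offsets, r_protect, mut)
        elif kind in ("kinase", "hybrid_kinase"):
            _plant_kinase(cfg, rng, slots, start, truth, gid,
                          hiska_base, h_anchor0, hiska_prof.offsets, h_protect,
                          kin_sig_base, mut, hybrid=(kind == "hybrid_kinase"))
        elif kind == "tcs":
            _plant_tcs(rng, slots, start, truth, gid)
        elif kind == "chey":
            _plant_chey(rng, slots, start, truth, gid, rec_base)

    # force annotated domains on fillers flanking the Spo0B neighborhood, so
    # the only Pfam-free protein there is a planted Spo0B (the region mimics
    # the gene-dense ribosomal protein cluster)
    guard = [i for i, s in enumerate(slots) if s.kind in ("l21", "l27", "obg", "spo0b")]
    for i in guard:
        for j in range(max(0, i - 5), min(n, i + 6)):
            if slots[j].kind == "filler":
                slots[j].kind = "blockfiller"

    # fill remaining slots
    for s in slots:
        if s.kind == "filler":
            s.aa_len = filler_len()
            if rng.random() < cfg.filler_domain_prob:
                s.domains.append(pool_domain(s.aa_len))
        elif s.kind == "blockfiller" and s.aa_len == 0:
            s.aa_len = filler_len()
            s.domains.append(pool_domain(s.aa_len))

    # bulk random sequences for everything without a crafted protein
    need = [i for i, s in enumerate(slots) if s.protein is None]
    lengths = [slots[i].aa_len for i in need]
    total = int(np.sum(lengths))
    big = _AA_ARR[rng.integers(0, 20, size=total)].tobytes().decode("ascii")
    pos = 0
    for i, L in zip(need, lengths):
        slots[i].protein = big[pos : pos + L]
        pos += L

    # coordinates along one circular replicon
    genes: list[Gene] = []
    proteins: dict[str, str] = {}
    hits: list[DomainHit] = []
    cursor = 1
    for idx, s in enumerate(slots):
        gene_id = f"{gid}_{idx:05d}"
        start = cursor + int(rng.integers(20, 200))
        end = start + s.aa_len * 3 + 2
        cursor = end
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            Gene(
                gene_id=gene_id,
                genome_id=gid,
                replicon_id="chr",
                orf_index=idx,
                start=start,
                end=end,
                strand=strand,
                product_length=s.aa_len,
            )
        )
        proteins[gene_id] = s.protein  # type: ignore[assignment]
        for name, db, a, b in s.domains:
            if cfg.domain_dropout_prob and rng.random() < cfg.domain_dropout_prob:
                continue
            hits.append(
                DomainHit(
                    gene_id=gene_id, domain_name=name, db=db,
                    ali_from=a, ali_to=b, score_or_evalue=1e-20,
                )
            )
        # rewrite planted truth ids now that the gene id is known
        _rename_truth(truth, idx, gene_id)

    replicon_len = cursor + int(rng.integers(200, 2000))
    pheno = Phenotype.SPORE_FORMER.value if has_a else Phenotype.NON_SPORE_FORMER.value
    ann = GenomeAnnotation(
        genome_id=gid,
        replicons=[Replicon("chr", replicon_len, cfg.circular)],
        genes=genes,
        proteins=proteins,
        domain_hits=hits,
        sporulation_phenotype=pheno,
    )
    return ann, truth


# -- block planters (record slot indices; renamed to gene ids at the end) --

def _remember(truth: GroundTruth, listname: str, idx: int) -> None:
    getattr(truth, listname).append(f"@{idx}")


def _rename_truth(truth: GroundTruth, idx: int, gene_id: str) -> None:
    tag = f"@{idx}"
    for listname in (
        "orphan_kinases", "pas_orphan_kinases", "hybrid_orphan_kinases",
        "non_orphan_kinases", "chey_decoys",
    ):
        lst = getattr(truth, listname)
        for k, v in enumerate(lst):
            if v == tag:
                lst[k] = gene_id
    for role, v in list(truth.roles.items()):
        if v == tag:
            truth.roles[role] = gene_id
    if tag in truth.signatures:
        truth.signatures[gene_id] = truth.signatures.pop(tag)


def _rec_only_protein(
    rng, rec_base: str, anchor0: int, offsets, protect, signature: str, scaffold_rate: float
) -> str:
    core = _mutate(rng, rec_base, scaffold_rate, protect)
    core = _plant(core, anchor0, offsets, signature)
    return _random_protein(rng, 4) + core + _random_protein(rng, 5)


def _plant_spo0f_block(
    cfg, rng, slots, start, has_f, truth, gid,
    rec_base, r_anchor0, r_offsets, r_protect, keep_marker, filler_len, mut,
) -> None:
    i = start
    if has_f:
        sig = _mutate_signature(rng, cfg.spo0f_signature, mut)
        s = slots[i]
        s.kind = "spo0f"
        s.protein = _rec_only_protein(rng, rec_base, r_anchor0, r_offsets, r_protect, sig, 0.10)
        s.aa_len = len(s.protein)
        s.domains.append(("Response_reg", "PFAM", 5, 119))
        truth.roles["SPO0F"] = f"@{i}"
        truth.signatures[f"@{i}"] = {"role": "REC", "residues": sig}
        i += 1
    markers = [("fbaA", "F_bp_aldolase", 330), ("transald", "Transaldolase", 220), ("ctps", "CTP_Synth_N", 550)]
    for k, (kind, dom, length) in enumerate(markers):
        s = slots[i]
        s.aa_len = length
        if keep_marker():
            s.kind = kind
            s.domains.append((dom, "PFAM", 2, min(length, 250)))
        else:
            s.kind = "blockfiller"
            s.domains.append(("ABC_tran", "PFAM", 10, 200))
        i += 1
        if k < 2:
            gap = int(rng.integers(cfg.marker_gap_range[0], cfg.marker_gap_range[1] + 1))
            for _ in range(gap):
                slots[i].kind = "blockfiller"
                i += 1


def _plant_spo0b_block(
    cfg, rng, slots, start, has_b, truth, gid,
    b_ref, h_anchor0, h_offsets, h_protect, keep_marker, mut,
) -> None:
    layout = [("l21", "Ribosomal_L21p", 102), ("l27", "Ribosomal_L27", 95)]
    if has_b:
        layout.append(("spo0b", None, 190))
    layout.append(("obg", "GTP1_OBG", 430))
    i = start
    for kind, dom, length in layout:
        s = slots[i]
        s.aa_len = length
        if kind == "spo0b":
            sig = _mutate_signature(rng, cfg.spo0b_signature, mut)
            nterm = _mutate(rng, b_ref, cfg.spo0b_nterm_mutation_rate, h_protect)
            nterm = _plant(nterm, h_anchor0, h_offsets, sig)
            s.kind = "spo0b"
            s.protein = nterm + _random_protein(rng, length - len(nterm))
            truth.roles["SPO0B"] = f"@{i}"
            truth.signatures[f"@{i}"] = {"role": "HISKA_LIKE", "residues": sig}
        elif keep_marker():
            s.kind = kind
            s.domains.append((dom, "PFAM", 2, min(length, 240)))
        else:
            s.kind = "blockfiller"
            s.domains.append(("AAA", "PFAM", 10, 90))
        i += 1


def _plant_spo0a(cfg, rng, slots, start, truth, gid, rec_base, r_anchor0, r_offsets, r_protect, mut) -> None:
    sig = _mutate_signature(rng, cfg.spo0a_signature, mut)
    core = _mutate(rng, rec_base, 0.10, r_protect)
    core = _plant(core, r_anchor0, r_offsets, sig)
    s = slots[start]
    s.kind = "spo0a"
    s.protein = _random_protein(rng, 4) + core + _random_protein(rng, 120)
    s.aa_len = len(s.protein)
    s.domains.append(("Response_reg", "PFAM", 5, 119))
    s.domains.append(("Spo0A_C", "PFAM", 140, 235))
    truth.roles["SPO0A"] = f"@{start}"
    truth.signatures[f"@{start}"] = {"role": "REC", "residues": sig}


def _plant_kinase(
    cfg, rng, slots, start, truth, gid,
    hiska_base, h_anchor0, h_offsets, h_protect, sig_base, mut, hybrid: bool,
) -> None:
    sig = _mutate_signature(rng, sig_base, mut)
    has_pas = bool(rng.random() < cfg.pas_kinase_prob)
    core = _mutate(rng, hiska_base, 0.10, h_protect)
    core = _plant(core, h_anchor0, h_offsets, sig)
    prefix_len = 110 if has_pas else 15
    prefix = _random_protein(rng, prefix_len)
    tail = _random_protein(rng, 30) + _random_protein(rng, 160)
    seq = prefix + core + tail
    s = slots[start]
    s.kind = kind = "hybrid_kinase" if hybrid else "kinase"
    hiska_from = prefix_len + 1
    s.domains.append(("HisKA", "PFAM", hiska_from, hiska_from + len(core) - 1))
    cat_from = prefix_len + len(core) + 31
    s.domains.append(("HATPase_c", "PFAM", cat_from, cat_from + 150))
    s.domains.append((
        "HK_CA:3" if sig_base == cfg.relay_kinase_signature else "HK_CA:2",
        "AGFAM", cat_from, cat_from + 150,
    ))
    if has_pas:
        s.domains.append(("PAS", "PFAM", 8, 105))
    if hybrid:
        rec_tail = _random_protein(rng, 115)
        seq = seq + rec_tail
        rec_from = prefix_len + len(core) + 30 + 161
        s.domains.append(("Response_reg", "PFAM", rec_from, rec_from + 110))
    s.protein = seq
    s.aa_len = len(seq)
    tag_list = "hybrid_orphan_kinases" if hybrid else "orphan_kinases"
    _remember(truth, tag_list, start)
    if hybrid:
        _remember(truth, "orphan_kinases", start)
    if has_pas:
        _remember(truth, "pas_orphan_kinases", start)
    truth.signatures[f"@{start}"] = {"role": "HISKA_LIKE", "residues": sig}


def _plant_tcs(rng, slots, start, truth, gid) -> None:
    hk = slots[start]
    hk.kind = "tcs_hk"
    hk.aa_len = 460
    hk.domains.append(("HisKA", "PFAM", 180, 248))
    hk.domains.append(("HATPase_c", "PFAM", 290, 440))
    rr = slots[start + 1]
    rr.kind = "tcs_rr"
    rr.aa_len = 230
    rr.domains.append(("Response_reg", "PFAM", 5, 115))
    rr.domains.append(("Trans_reg_C", "PFAM", 140, 220))
    _remember(truth, "non_orphan_kinases", start)


def _plant_chey(rng, slots, start, truth, gid, rec_base) -> None:
    s = slots[start]
    s.kind = "chey"
    core = _mutate(rng, rec_base, 0.30)
    s.protein = _random_protein(rng, 4) + core + _random_protein(rng, 5)
    s.aa_len = len(s.protein)
    s.domains.append(("Response_reg", "PFAM", 5, 119))
    _remember(truth, "chey_decoys", start)


# -- clades --------------------------------------------------------------

@dataclass
class CladeSimulation:
    genomes: dict[str, GenomeAnnotation]
    truths: dict[str, GroundTruth]
    planted_transition_count: int
    tree_newick: str


def generate_clade(
    tree: str,
    cfg: SimulationConfig,
    architecture_map: dict[str, str],
) -> CladeSimulation:
    """One genome per tree leaf with the mapped architecture.

    The Fitch parsimony count of the planted labels is recorded as the true
    transition count.
    """
    import dendropy

    from .phylo import fitch_transition_count

    dtree = dendropy.Tree.get(data=tree, schema="newick") if isinstance(tree, str) else tree
    leaves = [
        (leaf.taxon.label if leaf.taxon else "").replace(" ", "_")
        for leaf in dtree.leaf_node_iter()
    ]
    if len(set(leaves)) != len(leaves):
        raise ValueError("tree leaf names are not unique")
    missing = [l for l in leaves if l not in architecture_map]
    if missing:
        raise ValueError(f"leaves missing from architecture_map: {missing}")
    genomes: dict[str, GenomeAnnotation] = {}
    truths: dict[str, GroundTruth] = {}
    for k, leaf in enumerate(leaves):
        ann, truth = generate_genome(cfg, genome_index=k, architecture=architecture_map[leaf], genome_id=leaf)
        genomes[leaf] = ann
        truths[leaf] = truth
    count = (
        fitch_transition_count(dtree, architecture_map) if len(leaves) > 1 else 0
    )
    newick = dtree.as_string(schema="newick").strip()
    return CladeSimulation(genomes, truths, count, newick)


def write_simulation(
    out_dir: str | Path,
    genomes: dict[str, GenomeAnnotation],
    truths: dict[str, GroundTruth],
    tree_newick: Optional[str] = None,
) -> None:
    """Emit the same GFF3/FASTA/domain-TSV dialect that annotation_io reads,
    plus ground truth as JSON."""
    from .annotation_io import write_annotation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for gid, ann in genomes.items():
        write_annotation(ann, out / f"{gid}.gff3", out / f"{gid}.faa", out / f"{gid}.domains.tsv")
    truth_blob = {gid: json.loads(t.to_json()) for gid, t in truths.items()}
    (out / "ground_truth.json").write_text(json.dumps(truth_blob, indent=1, sort_keys=True))
    if tree_newick:
        (out / "tree.nwk").write_text(tree_newick + "\n")
    rows = ["genome_id\tstatus"]
    rows += [f"{gid}\t{ann.sporulation_phenotype}" for gid, ann in genomes.items()]
    (out / "phenotypes.tsv").write_text("\n".join(rows) + "\n")
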