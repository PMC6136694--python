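"""Core data model for annotated genomes and Spo0 pathway predictions.

The unit of analysis is a :class:`GenomeAnnotation`: an ordered set of ORFs on
one or more (possibly circular) replicons, the amino-acid sequence of each
protein product, and a table of protein-domain hits (Pfam/Agfam style).
Downstream stages attach :class:`Neighborhood`, :class:`Spo0Candidate`,
:class:`KinaseRecord` and :class:`SpecificitySignature` records to these genes.

Coordinates follow the GFF3 convention: 1-based, inclusive, ``start <= end``
regardless of strand.  ``orf_index`` is the 0-based rank of the ORF along its
replicon in coordinate order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class Strand(str, Enum):
    PLUS = "+"
    MINUS = "-"


class DomainDB(str, Enum):
    PFAM = "PFAM"
    AGFAM = "AGFAM"
    OTHER = "OTHER"


class Phenotype(str, Enum):
    SPORE_FORMER = "spore_former"
    NON_SPORE_FORMER = "non_spore_former"
    UNKNOWN = "unknown"


class Role(str, Enum):
    SPO0A = "SPO0A"
    SPO0F = "SPO0F"
    SPO0B = "SPO0B"


class Architecture(str, Enum):
    """Per-genome Spo0 pathway architecture label.

    PHOSPHORELAY: kinase -> Spo0F -> Spo0B -> Spo0A four-protein relay.
    DIRECT: sensor kinases phosphorylate Spo0A with no Spo0F/Spo0B.
    PARTIAL_RELAY: Spo0A plus exactly one of Spo0F/Spo0B.
    NO_SPO0: no Spo0A detected.
    """

    PHOSPHORELAY = "PHOSPHORELAY"
    DIRECT = "DIRECT"
    PARTIAL_RELAY = "PARTIAL_RELAY"
    NO_SPO0 = "NO_SPO0"


@dataclass(frozen=True)
class Gene:
    gene_id: str
    genome_id: str
    replicon_id: str
    orf_index: int
    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive, >= start
    strand: str  # "+" or "-"
    product_length: int  # aa

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.product_length <= 0:
            raise ValueError(f"{self.gene_id}: non-positive product_length")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class DomainHit:
    gene_id: str
    domain_name: str
    db: str = DomainDB.PFAM.value
    ali_from: int = 1  # 1-based aa
    ali_to: int = 1  # 1-based aa, >= ali_from
    score_or_evalue: float = 0.0

    def __post_init__(self) -> None:
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(
                f"{self.gene_id}/{self.domain_name}: bad envelope "
                f"{self.ali_from}-{self.ali_to}"
            )


@dataclass(frozen=True)
class Replicon:
    replicon_id: str
    length: int  # bp
    circular: bool = False


@dataclass
class LoadReport:
    """Counts of rows excluded or warned about while loading one genome."""

    unknown_gene_domain_rows: int = 0
    out_of_range_domain_rows: int = 0
    skipped_cds_without_translation: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def excluded_domain_rows(self) -> int:
        return self.unknown_gene_domain_rows + self.out_of_range_domain_rows


@dataclass
class GenomeAnnotation:
    """One genome: ordered genes, protein sequences, and domain hits."""

    genome_id: str
    replicons: list[Replicon]
    genes: list[Gene]
    proteins: dict[str, str]
    domain_hits: list[DomainHit]
    sporulation_phenotype: str = Phenotype.UNKNOWN.value
    load_report: LoadReport = field(default_factory=LoadReport)

    # lazily built indexes
    _by_id: Optional[dict[str, Gene]] = field(default=None, repr=False, compare=False)
    _hits_by_gene: Optional[dict[str, list[DomainHit]]] = field(
        default=None, repr=False, compare=False
    )
    _by_replicon: Optional[dict[str, list[Gene]]] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.validate()

    # -- indexes ---------------------------------------------------------
    def _index(self) -> None:
        self._by_id = {g.gene_id: g for g in self.genes}
        hits: dict[str, list[DomainHit]] = {}
        for h in self.domain_hits:
            hits.setdefault(h.gene_id, []).append(h)
        for lst in hits.values():
            lst.sort(key=lambda h: (h.ali_from, h.ali_to, h.domain_name))
        self._hits_by_gene = hits
        byrep: dict[str, list[Gene]] = {}
        for g in self.genes:
            byrep.setdefault(g.replicon_id, []).append(g)
        for lst in byrep.values():
            lst.sort(key=lambda g: g.orf_index)
        self._by_replicon = byrep

    def invalidate(self) -> None:
        self._by_id = self._hits_by_gene = self._by_replicon = None

    def gene(self, gene_id: str) -> Gene:
        if self._by_id is None:
            self._index()
        try:
            return self._by_id[gene_id]  # type: ignore[index]
        except KeyError:
            raise KeyError(f"unknown gene {gene_id!r} in genome {self.genome_id}")

    def hits(self, gene_id: str) -> list[DomainHit]:
        self.gene(gene_id)  # raises on unknown gene
        assert self._hits_by_gene is not None
        return list(self._hits_by_gene.get(gene_id, []))

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.replicon_id == replicon_id:
                return r
        raise KeyError(f"unknown replicon {replicon_id!r} in genome {self.genome_id}")

    def genes_on(self, replicon_id: str) -> list[Gene]:
        if self._by_replicon is None:
            self._index()
        assert self._by_replicon is not None
        return list(self._by_replicon.get(replicon_id, []))

    def gene_at(self, replicon_id: str, orf_index: int) -> Gene:
        genes = self.genes_on(replicon_id)
        n = len(genes)
        if not (0 <= orf_index < n):
            raise IndexError(f"orf_index {orf_index} out of range on {replicon_id}")
        return genes[orf_index]

    def domain_names(self, gene_id: str) -> set[str]:
        return {h.domain_name for h in self.hits(gene_id)}

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        known = {r.replicon_id for r in self.replicons}
        seen_ids: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen_ids:
                raise ValueError(f"duplicate gene id {g.gene_id!r}")
            seen_ids.add(g.gene_id)
            if g.replicon_id not in known:
                raise ValueError(f"gene {g.gene_id} on unknown replicon {g.replicon_id}")
        byrep: dict[str, list[Gene]] = {}
        for g in self.genes:
            byrep.setdefault(g.replicon_id, []).append(g)
        for rep, genes in byrep.items():
            idx = sorted(g.orf_index for g in genes)
            if idx != list(range(len(genes))):
                raise ValueError(f"orf_index not a 0..n-1 bijection on {rep}")
        for h in self.domain_hits:
            if h.gene_id not in seen_ids:
                raise ValueError(f"domain hit references unknown gene {h.gene_id!r}")
        for gid in self.proteins:
            if gid not in seen_ids:
                raise ValueError(f"protein sequence for unknown gene {gid!r}")
        self.invalidate()


@dataclass(frozen=True)
class MarkerSpec:
    """Marker domains locating a Spo0F or Spo0B gene neighborhood.

    Spo0F neighborhoods are marked by fructose-bisphosphate aldolase (fbaA),
    transaldolase and CTP synthase; Spo0B neighborhoods by the ObgE GTPase and
    ribosomal proteins L21 and L27.
    """

    target: str  # "SPO0F" or "SPO0B"
    marker_domains: tuple[str, ...]
    radius: int = 4  # ORFs up- and downstream included in a window
    merge_gap: int = 4  # max intervening ORFs between markers to merge

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("radius must be >= 1")
        if self.merge_gap < 0:
            raise ValueError("merge_gap must be >= 0")
        if not self.marker_domains:
            raise ValueError("marker_domains must be non-empty")


SPO0F_MARKERS = MarkerSpec(
    target="SPO0F",
    marker_domains=("F_bp_aldolase", "Transaldolase", "CTP_Synth_N"),
)
SPO0B_MARKERS = MarkerSpec(
    target="SPO0B",
    marker_domains=("GTP1_OBG", "Ribosomal_L21p", "Ribosomal_L27"),
)


@dataclass
class Neighborhood:
    """A set of ORF indices on one replicon grouping marker genes."""

    genome_id: str
    replicon_id: str
    member_orf_indices: tuple[int, ...]  # sorted, unique
    marker_gene_ids: frozenset[str]
    candidate_gene_ids: set[str] = field(default_factory=set)
    target: Optional[str] = None  # "SPO0F"/"SPO0B" when built from a MarkerSpec

    def __post_init__(self) -> None:
        self.member_orf_indices = tuple(sorted(set(self.member_orf_indices)))
        self.marker_gene_ids = frozenset(self.marker_gene_ids)

    @property
    def min_index(self) -> int:
        return min(self.member_orf_indices)

    def member_genes(self, ann: GenomeAnnotation) -> list[Gene]:
        return [self.gene_at(ann, i) for i in self.member_orf_indices]

    def gene_at(self, ann: GenomeAnnotation, orf_index: int) -> Gene:
        return ann.gene_at(self.replicon_id, orf_index)


@dataclass
class Spo0Candidate:
    role: str  # Role value
    gene_id: str
    genome_id: str
    evidence: dict = field(default_factory=dict)
    confidence_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        role = Role(self.role)
        if role is Role.SPO0F and "rec_coverage" not in self.evidence:
            raise ValueError("SPO0F candidate requires rec_coverage evidence")
        if role is Role.SPO0B and "identity" not in self.evidence:
            raise ValueError("SPO0B candidate requires alignment evidence")


@dataclass
class KinaseRecord:
    gene_id: str
    genome_id: str
    has_hiska: bool = True
    has_catalytic: bool = True
    catalytic_family: str = ""  # pass-through Agfam annotation, e.g. "HK_CA:3"
    is_hybrid: bool = False
    is_orphan: bool = False
    has_nterm_pas: bool = False
    nearest_tcs_distance: float = float("inf")  # ORFs


@dataclass
class SpecificitySignature:
    """Phosphotransfer specificity residues read off an anchored alignment.

    Six residues for HisKA-like phosphodonors (sensor kinases and Spo0B),
    seven for REC-domain receivers.  ``'-'`` marks positions falling in
    alignment gaps or off the end of the protein.
    """

    gene_id: str
    role: str  # "HISKA_LIKE" or "REC"
    residues: str
    anchor_position: int = -1  # 1-based aa position of the anchor in the target
    alignment_score: float = 0.0
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        expected = {"HISKA_LIKE": 6, "REC": 7}[self.role]
        if len(self.residues) != expected:
            raise ValueError(
                f"{self.role} signature must have {expected} residues, "
                f"got {self.residues!r}"
            )
        valid = set("ACDEFGHIKLMNPQRSTVWY-X")
        if not set(self.residues) <= valid:
            raise ValueError(f"invalid residue characters in {self.residues!r}")


@dataclass
class Spo0Inventory:
    """Per-genome record of detected Spo0 pathway components."""

    genome_id: str
    spo0a: list[Spo0Candidate] = field(default_factory=list)
    spo0f: Optional[Spo0Candidate] = None
    spo0b: Optional[Spo0Candidate] = None
    kinases: list[KinaseRecord] = field(default_factory=list)
    phenotype: str = Phenotype.UNKNOWN.value


@dataclass
class ArchitectureCall:
    genome_id: str
    label: str  # Architecture value
    rationale: str = ""


def as_strand(value: str) -> str:
    """Normalize strand symbols (accepts unicode minus)."""
    if value in ("+", "1"):
        return "+"
    if value in ("-", "−", "-1"):
        return "-"
    raise ValueError(f"unrecognized strand {value!r}")
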