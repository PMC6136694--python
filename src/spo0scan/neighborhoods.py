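"""Conserved gene-neighborhood discovery around marker domains.

Spo0F and Spo0B orthologs resist sequence-based identification (Spo0F is a
bare REC domain easily confused with CheY; Spo0B has no reliably diagnostic
Pfam domain), so they are located by genome context instead: find genes
carrying neighborhood marker domains, take the window of four adjacent ORFs
up- and downstream of each, and merge windows that share a gene or whose
marker genes are separated by at most ``merge_gap`` intervening ORFs
(regardless of intergenic distance in base pairs).  Windows wrap across the
origin on circular replicons and never span replicons.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

from .model import Gene, GenomeAnnotation, MarkerSpec, Neighborhood


def find_marker_genes(ann: GenomeAnnotation, spec: MarkerSpec) -> list[Gene]:
    """Every gene with at least one hit to any marker domain, reported once."""
    markers = set(spec.marker_domains)
    out: list[Gene] = []
    seen: set[str] = set()
    for hit in ann.domain_hits:
        if hit.domain_name in markers and hit.gene_id not in seen:
            seen.add(hit.gene_id)
            out.append(ann.gene(hit.gene_id))
    out.sort(key=lambda g: (g.replicon_id, g.orf_index))
    return out


def window(ann: GenomeAnnotation, gene: Gene, radius: int = 4, target: str | None = None) -> Neighborhood:
    """The +/- ``radius`` ORF window around a gene, clipped or wrapped."""
    n = len(ann.genes_on(gene.replicon_id))
    rep = ann.replicon(gene.replicon_id)
    i = gene.orf_index
    if rep.circular:
        if n <= 2 * radius + 1:
            members = range(n)
        else:
            members = [(i + d) % n for d in range(-radius, radius + 1)]
    else:
        members = range(max(0, i - radius), min(n - 1, i + radius) + 1)
    return Neighborhood(
        genome_id=ann.genome_id,
        replicon_id=gene.replicon_id,
        member_orf_indices=tuple(members),
        marker_gene_ids=frozenset({gene.gene_id}),
        target=target,
    )


def _orf_distance(i: int, j: int, n: int, circular: bool) -> int:
    d = abs(i - j)
    return min(d, n - d) if circular else d


def merge_neighborhoods(
    nbhds: Sequence[Neighborhood],
    ann: GenomeAnnotation,
    merge_gap: int = 4,
) -> list[Neighborhood]:
    """Transitive closure of the two merge rules, per genome.

    Two windows are combined when they share a member gene, or when their
    marker genes are separated by no more than ``merge_gap`` intervening ORFs.
    The merged member set is the union of the member windows.  The operation
    is idempotent and invariant to input order; the result is sorted by
    smallest member index.
    """
    nbhds = list(nbhds)
    if not nbhds:
        return []
    genomes = {nb.genome_id for nb in nbhds}
    if genomes != {ann.genome_id}:
        raise ValueError(f"neighborhoods from multiple genomes: {sorted(genomes)}")

    order = sorted(range(len(nbhds)), key=lambda k: (nbhds[k].replicon_id, nbhds[k].min_index))
    parent = list(range(len(nbhds)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    marker_idx = {
        k: [ann.gene(g).orf_index for g in nbhds[k].marker_gene_ids] for k in range(len(nbhds))
    }
    for ai in range(len(nbhds)):
        for bi in range(ai + 1, len(nbhds)):
            a, b = nbhds[ai], nbhds[bi]
            if a.replicon_id != b.replicon_id:
                continue
            n = len(ann.genes_on(a.replicon_id))
            circ = ann.replicon(a.replicon_id).circular
            if set(a.member_orf_indices) & set(b.member_orf_indices):
                union(ai, bi)
                continue
            gap = min(
                _orf_distance(i, j, n, circ) - 1
                for i in marker_idx[ai]
                for j in marker_idx[bi]
            )
            if gap <= merge_gap:
                union(ai, bi)

    groups: dict[int, list[int]] = {}
    for k in order:
        groups.setdefault(find(k), []).append(k)

    merged: list[Neighborhood] = []
    for members in groups.values():
        parts = [nbhds[k] for k in members]
        merged.append(
            Neighborhood(
                genome_id=ann.genome_id,
                replicon_id=parts[0].replicon_id,
                member_orf_indices=tuple(
                    sorted({i for p in parts for i in p.member_orf_indices})
                ),
                marker_gene_ids=frozenset().union(*(p.marker_gene_ids for p in parts)),
                candidate_gene_ids=set().union(*(p.candidate_gene_ids for p in parts)),
                target=parts[0].target,
            )
        )
    merged.sort(key=lambda nb: (nb.replicon_id, nb.min_index))
    return merged


def discover_neighborhoods(ann: GenomeAnnotation, spec: MarkerSpec) -> list[Neighborhood]:
    """find markers -> windows -> merge, in one call."""
    markers = find_marker_genes(ann, spec)
    wins = [window(ann, g, spec.radius, target=spec.target) for g in markers]
    return merge_neighborhoods(wins, ann, spec.merge_gap)


def select_marker_domains(
    guide_neighborhoods: Sequence[Neighborhood],
    all_genomes: Sequence[GenomeAnnotation],
    top_k: int = 3,
) -> list[tuple[str, float]]:
    """Rank candidate marker domains by neighborhood enrichment.

    For a domain ``d``::

        score(d) = log[(n_in+1)/(N_in+2)] - log[(n_out+1)/(N_out+2)]

    where ``n_in`` counts guide neighborhoods containing a gene hit to ``d``,
    ``N_in`` the number of guide neighborhoods, ``n_out`` the guide-genome
    genes outside any guide neighborhood hitting ``d``, and ``N_out`` the
    total number of such outside genes.  Ties are broken by smaller mean ORF
    distance to the neighborhood's marker (anchor) genes, then by name, so
    that domains encoded close to the anchored gene are favored.
    """
    if not guide_neighborhoods:
        raise ValueError("empty guide neighborhood set")
    anns = {a.genome_id: a for a in all_genomes}
    inside: dict[str, set[str]] = {}  # genome -> member gene ids
    for nb in guide_neighborhoods:
        ann = anns[nb.genome_id]
        inside.setdefault(nb.genome_id, set()).update(
            g.gene_id for g in nb.member_genes(ann)
        )

    n_in: dict[str, int] = {}
    dist_sum: dict[str, float] = {}
    dist_n: dict[str, int] = {}
    for nb in guide_neighborhoods:
        ann = anns[nb.genome_id]
        anchor_idx = [ann.gene(g).orf_index for g in nb.marker_gene_ids]
        n = len(ann.genes_on(nb.replicon_id))
        circ = ann.replicon(nb.replicon_id).circular
        doms_here: dict[str, int] = {}
        for g in nb.member_genes(ann):
            d_anchor = min(_orf_distance(g.orf_index, a, n, circ) for a in anchor_idx)
            for dom in ann.domain_names(g.gene_id):
                doms_here[dom] = min(doms_here.get(dom, d_anchor), d_anchor)
        for dom, d_anchor in doms_here.items():
            n_in[dom] = n_in.get(dom, 0) + 1
            dist_sum[dom] = dist_sum.get(dom, 0.0) + d_anchor
            dist_n[dom] = dist_n.get(dom, 0) + 1

    n_out: dict[str, int] = {}
    N_out = 0
    for gid, members in inside.items():
        ann = anns[gid]
        for g in ann.genes:
            if g.gene_id in members:
                continue
            N_out += 1
            for dom in ann.domain_names(g.gene_id):
                n_out[dom] = n_out.get(dom, 0) + 1
    N_in = len(guide_neighborhoods)

    domains = sorted(set(n_in) | set(n_out))
    scored = []
    for dom in domains:
        score = math.log((n_in.get(dom, 0) + 1) / (N_in + 2)) - math.log(
            (n_out.get(dom, 0) + 1) / (N_out + 2)
        )
        mean_dist = dist_sum[dom] / dist_n[dom] if dist_n.get(dom) else float("inf")
        scored.append((dom, score, mean_dist))
    scored.sort(key=lambda t: (-t[1], t[2], t[0]))
    return [(dom, score) for dom, score, _ in scored[:top_k]]


def choose_marker_neighborhood(
    merged: Sequence[Neighborhood],
    ann: GenomeAnnotation,
    candidate_predicate: Callable[[GenomeAnnotation, Gene], bool],
) -> Neighborhood:
    """Pick the marker neighborhood among merged sets.

    Priority: (1) a set containing a gene passing ``candidate_predicate``;
    (2) the set with the most distinct marker genes; (3) the set with the
    lowest member ORF index (a deterministic stand-in for an arbitrary
    choice).
    """
    merged = list(merged)
    if not merged:
        raise ValueError("no neighborhoods to choose from")

    def has_candidate(nb: Neighborhood) -> bool:
        return any(candidate_predicate(ann, g) for g in nb.member_genes(ann))

    merged.sort(
        key=lambda nb: (
            not has_candidate(nb),
            -len(nb.marker_gene_ids),
            nb.min_index,
            nb.replicon_id,
        )
    )
    return merged[0]


def neighborhoods_to_table(ann: GenomeAnnotation, nbhds: Iterable[Neighborhood]):
    """BED-like per-neighborhood summary (one row per neighborhood)."""
    import pandas as pd

    rows = []
    for nb in nbhds:
        genes = nb.member_genes(ann)
        rows.append(
            dict(
                genome_id=nb.genome_id,
                replicon_id=nb.replicon_id,
                target=nb.target or "",
                start=min(g.start for g in genes),
                end=max(g.end for g in genes),
                n_members=len(genes),
                member_gene_ids=",".join(g.gene_id for g in genes),
                marker_gene_ids=",".join(sorted(nb.marker_gene_ids)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id",
            "replicon_id",
            "target",
            "start",
            "end",
            "n_members",
            "member_gene_ids",
            "marker_gene_ids",
        ],
    )
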