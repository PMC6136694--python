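"""Shared fixtures: a programmatic toy-genome builder.

All test inputs are built in memory or in tmp_path at test time; nothing is
read from data files except the package's own shipped reference data.
"""

from __future__ import annotations

import pytest

from spo0scan.model import DomainHit, Gene, GenomeAnnotation, Replicon


def build_genome(
    n: int = 30,
    genome_id: str = "g",
    circular: bool = False,
    domains: dict[int, list[tuple]] | None = None,
    proteins: dict[int, str] | None = None,
    product_length: int = 100,
    replicon_id: str = "chr",
) -> GenomeAnnotation:
    """A linear or circular toy genome of ``n`` evenly spaced ORFs.

    ``domains`` maps orf_index -> list of (name, db, ali_from, ali_to);
    ``proteins`` maps orf_index -> amino-acid sequence (others get poly-A of
    ``product_length``).
    """
    domains = domains or {}
    proteins = proteins or {}
    genes, prot, hits = [], {}, []
    for i in range(n):
        gid = f"{genome_id}_{i:04d}"
        seq = proteins.get(i, "A" * product_length)
        genes.append(
            Gene(
                gene_id=gid,
                genome_id=genome_id,
                replicon_id=replicon_id,
                orf_index=i,
                start=i * 1000 + 1,
                end=i * 1000 + 3 * len(seq),
                strand="+" if i % 2 == 0 else "-",
                product_length=len(seq),
            )
        )
        prot[gid] = seq
        for name, db, a, b in domains.get(i, []):
            hits.append(DomainHit(gene_id=gid, domain_name=name, db=db, ali_from=a, ali_to=b))
    return GenomeAnnotation(
        genome_id=genome_id,
        replicons=[Replicon(replicon_id, n * 1000 + 1000, circular)],
        genes=genes,
        proteins=prot,
        domain_hits=hits,
    )


@pytest.fixture
def toy_genome_factory():
    return build_genome
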