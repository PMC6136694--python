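"""Loading, validation, and round-tripping of genome annotations."""

from __future__ import annotations

import textwrap

import pytest

from spo0scan import (
    SimulationConfig,
    convert_domtblout,
    domains_of,
    generate_genome,
    normalized_position,
    read_annotation,
    write_annotation,
)
from spo0scan.model import DomainHit, Gene, GenomeAnnotation, Replicon


GFF3 = textwrap.dedent(
    """\
    ##gff-version 3
    ##sequence-region chr 1 10000
    chr\tsrc\tregion\t1\t10000\t.\t+\t.\tID=region-chr;Is_circular=true
    chr\tsrc\tCDS\t100\t399\t.\t+\t0\tID=gA
    chr\tsrc\tCDS\t500\t799\t.\t-\t0\tID=gB
    chr\tsrc\tCDS\t900\t1199\t.\t+\t0\tID=gC
    """
)
FAA = ">gA\nMKKLLVA\n>gB\nMNNPQRSTVW\n>gC\nMAAAA\n"
DOMAINS = (
    "gene_id\tdomain_name\tdb\tevalue\tali_from\tali_to\n"
    "gA\tResponse_reg\tPFAM\t1e-20\t2\t7\n"
    "gB\tHisKA\tPFAM\t1e-10\t1\t9\n"
)


def _write_inputs(tmp_path, gff=GFF3, faa=FAA, domains=DOMAINS):
    (tmp_path / "g.gff3").write_text(gff)
    (tmp_path / "g.faa").write_text(faa)
    (tmp_path / "g.domains.tsv").write_text(domains)
    return tmp_path / "g.gff3", tmp_path / "g.faa", tmp_path / "g.domains.tsv"


class TestReadAnnotation:
    def test_toy_genome_loads_with_coordinate_order_orf_indices(self, tmp_path):
        ann = read_annotation(*_write_inputs(tmp_path))
        assert [g.gene_id for g in ann.genes_on("chr")] == ["gA", "gB", "gC"]
        assert [g.orf_index for g in ann.genes_on("chr")] == [0, 1, 2]
        assert len(ann.domain_hits) == 2
        assert ann.replicon("chr").circular
        assert ann.replicon("chr").length == 10000

    def test_empty_domain_table_gives_zero_hits(self, tmp_path):
        paths = _write_inputs(tmp_path, domains="gene_id\tdomain_name\tdb\tevalue\tali_from\tali_to\n")
        ann = read_annotation(*paths)
        assert ann.domain_hits == []
        assert ann.load_report.excluded_domain_rows == 0

    def test_out_of_range_domain_row_excluded_and_counted(self, tmp_path):
        bad = DOMAINS + "gC\tPAS\tPFAM\t1e-5\t2\t50\n"  # gC is 5 aa long
        paths = _write_inputs(tmp_path, domains=bad)
        with pytest.warns(UserWarning):
            ann = read_annotation(*paths)
        assert len(ann.domain_hits) == 2
        assert ann.load_report.out_of_range_domain_rows == 1

    def test_unknown_gene_domain_row_excluded_with_warning(self, tmp_path):
        bad = DOMAINS + "ghost\tPAS\tPFAM\t1e-5\t1\t10\n"
        paths = _write_inputs(tmp_path, domains=bad)
        with pytest.warns(UserWarning):
            ann = read_annotation(*paths)
        assert ann.load_report.unknown_gene_domain_rows == 1

    def test_duplicate_gene_ids_hard_error(self, tmp_path):
        dup = GFF3 + "chr\tsrc\tCDS\t2000\t2299\t.\t+\t0\tID=gA\n"
        paths = _write_inputs(tmp_path, gff=dup)
        with pytest.raises(ValueError, match="duplicate"):
            read_annotation(*paths)

    def test_cds_without_translation_skipped_with_count(self, tmp_path):
        extra = GFF3 + "chr\tsrc\tCDS\t3000\t3299\t.\t+\t0\tID=gD\n"
        paths = _write_inputs(tmp_path, gff=extra)
        ann = read_annotation(*paths)
        assert ann.load_report.skipped_cds_without_translation == 1
        assert len(ann.genes) == 3


class TestRoundTrip:
    def test_simulated_genome_round_trips_exactly(self, tmp_path):
        cfg = SimulationConfig(seed=3, genes_per_genome=(1200, 1200), n_tcs_operons=8)
        ann, _ = generate_genome(cfg, 0)
        write_annotation(ann, tmp_path / "s.gff3", tmp_path / "s.faa", tmp_path / "s.domains.tsv")
        back = read_annotation(
            tmp_path / "s.gff3", tmp_path / "s.faa", tmp_path / "s.domains.tsv", genome_id=ann.genome_id
        )
        assert [g.gene_id for g in back.genes] == [g.gene_id for g in ann.genes]
        assert [(g.start, g.end, g.strand, g.orf_index) for g in back.genes] == [
            (g.start, g.end, g.strand, g.orf_index) for g in ann.genes
        ]
        assert sorted(back.domain_hits, key=lambda h: (h.gene_id, h.ali_from, h.domain_name)) == sorted(
            ann.domain_hits, key=lambda h: (h.gene_id, h.ali_from, h.domain_name)
        )
        assert back.proteins == ann.proteins
        assert back.replicon("chr").circular

    def test_orf_index_bijection_enforced(self):
        genes = [
            Gene("a", "g", "chr", 0, 1, 30, "+", 10),
            Gene("b", "g", "chr", 2, 40, 70, "+", 10),  # skips index 1
        ]
        with pytest.raises(ValueError, match="bijection"):
            GenomeAnnotation("g", [Replicon("chr", 100)], genes, {}, [])


class TestDomainsOf:
    def test_hits_sorted_by_alignment_start(self, toy_genome_factory):
        ann = toy_genome_factory(
            n=3,
            domains={1: [("HisKA", "PFAM", 60, 99), ("PAS", "PFAM", 10, 50)]},
        )
        hits = domains_of(ann, ann.genes[1].gene_id)
        assert [h.domain_name for h in hits] == ["PAS", "HisKA"]

    def test_no_hits_gives_empty_list(self, toy_genome_factory):
        ann = toy_genome_factory(n=2)
        assert domains_of(ann, ann.genes[0].gene_id) == []

    def test_unknown_gene_raises(self, toy_genome_factory):
        ann = toy_genome_factory(n=2)
        with pytest.raises(KeyError):
            domains_of(ann, "nope")


class TestNormalizedPosition:
    def test_forward_strand_uses_start_codon(self):
        genes = [Gene("a", "g", "chr", 0, 500_000, 500_900, "+", 300)]
        ann = GenomeAnnotation("g", [Replicon("chr", 5_000_000)], genes, {"a": "M" * 300}, [])
        assert normalized_position(ann, "a") == pytest.approx(0.1)

    def test_reverse_strand_uses_stop_codon_end(self):
        genes = [Gene("a", "g", "chr", 0, 100, 400, "-", 100)]
        ann = GenomeAnnotation("g", [Replicon("chr", 1000)], genes, {"a": "M" * 100}, [])
        assert normalized_position(ann, "a") == pytest.approx(0.1)

    def test_result_in_unit_interval(self):
        genes = [Gene("a", "g", "chr", 0, 999, 1000, "+", 1)]
        ann = GenomeAnnotation("g", [Replicon("chr", 1000)], genes, {"a": "M"}, [])
        assert 0.0 <= normalized_position(ann, "a") < 1.0

    def test_unknown_replicon_raises(self):
        genes = [Gene("a", "g", "chr", 0, 1, 30, "+", 10)]
        ann = GenomeAnnotation("g", [Replicon("chr", 1000)], genes, {"a": "M" * 10}, [])
        with pytest.raises(KeyError):
            normalized_position(ann, "a", replicon_id="plasmid")


def test_domtblout_converter(tmp_path):
    dom = tmp_path / "hits.domtblout"
    dom.write_text(
        "# comment line\n"
        "Response_reg PF00072.1 112 gA - 120 1e-30 100.0 0.1 1 1 1e-28 1e-28 99.0 0.1 1 110 5 115 4 116 0.98 -\n"
    )
    out = tmp_path / "hits.tsv"
    assert convert_domtblout(dom, out) == 1
    text = out.read_text().splitlines()
    assert text[0].split("\t") == ["gene_id", "domain_name", "db", "evalue", "ali_from", "ali_to"]
    assert text[1].split("\t")[:2] == ["gA", "Response_reg"]
    assert text[1].split("\t")[4:6] == ["5", "115"]
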