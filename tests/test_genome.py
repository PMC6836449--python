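"""Genome loading, GFF3 parsing and the four-way region classification."""

import numpy as np
import pytest

from polyguide import (
    FixtureSpec,
    GeneModel,
    build_region_map,
    classify_position,
    load_annotation,
    load_genome,
    make_toy_genome,
)
from polyguide.errors import (
    CdsOutsideExonError,
    DuplicateContigError,
    EmptyFileError,
    FeatureBoundsError,
    MissingFileError,
    OrphanFeatureError,
    OutOfBoundsError,
)
from polyguide.genome import GenomeSequence, Isoform, REGION_LABELS

from helpers import paint_regions_by_hand


def _gene(gene_id, contig, strand, exons, cds, span=None):
    iso = Isoform(f"{gene_id}.1", tuple(exons), tuple(cds))
    span = span or (min(e[0] for e in exons), max(e[1] for e in exons))
    return GeneModel(gene_id, contig, strand, span, (iso,))


class TestLoadGenome:
    def test_uppercases_and_preserves_order(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nacgt\n>c2\nTTAA\n")
        g = load_genome(p)
        assert g.contig_ids == ["c1", "c2"]
        assert g.contigs["c1"] == "ACGT"

    def test_ambiguity_codes_become_n(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">c1\nACGRYT\n")
        assert load_genome(p).contigs["c1"] == "ACGNNT"

    @pytest.mark.parametrize(
        "content,err",
        [
            (None, MissingFileError),
            ("", EmptyFileError),
            (">c1\nACGT\n>c1\nAAAA\n", DuplicateContigError),
        ],
    )
    def test_input_errors_are_distinct(self, tmp_path, content, err):
        p = tmp_path / "g.fa"
        if content is not None:
            p.write_text(content)
        with pytest.raises(err):
            load_genome(p)


GFF_TWO_ISOFORMS = """##gff-version 3
c1\tt\tgene\t101\t700\t.\t+\t.\tID=g1
c1\tt\tmRNA\t101\t700\t.\t+\t.\tID=g1.1;Parent=g1
c1\tt\texon\t101\t300\t.\t+\t.\tParent=g1.1
c1\tt\texon\t401\t700\t.\t+\t.\tParent=g1.1
c1\tt\tCDS\t151\t300\t.\t+\t0\tParent=g1.1
c1\tt\tCDS\t401\t650\t.\t+\t0\tParent=g1.1
c1\tt\tmRNA\t101\t300\t.\t+\t.\tID=g1.2;Parent=g1
c1\tt\texon\t101\t300\t.\t+\t.\tParent=g1.2
c1\tt\tCDS\t151\t300\t.\t+\t0\tParent=g1.2
"""


class TestLoadAnnotation:
    @pytest.fixture
    def genome(self):
        return GenomeSequence({"c1": "A" * 1000})

    def test_two_isoforms_grouped_under_one_gene(self, tmp_path, genome):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_TWO_ISOFORMS)
        genes = load_annotation(p, genome)
        assert len(genes) == 1
        g = genes[0]
        assert len(g.isoforms) == 2
        # 1-based closed -> 0-based half-open
        assert g.isoforms[0].exons == ((100, 300), (400, 700))
        assert g.isoforms[0].cds == ((150, 300), (400, 650))
        assert g.span == (100, 700)

    @pytest.mark.parametrize(
        "mutation,err",
        [
            (("701\t1200", "exon"), FeatureBoundsError),
            (("CDS\t151\t300", "CDS\t90\t300"), CdsOutsideExonError),
            (("Parent=g1\n", "Parent=gX\n"), OrphanFeatureError),
        ],
    )
    def test_validation_errors_are_distinct(self, tmp_path, genome, mutation, err):
        old, new = mutation
        if err is FeatureBoundsError:
            text = GFF_TWO_ISOFORMS.replace(
                "c1\tt\texon\t401\t700", "c1\tt\texon\t401\t1200"
            ).replace("CDS\t401\t650", "CDS\t401\t650")
        else:
            text = GFF_TWO_ISOFORMS.replace(old, new, 1)
        p = tmp_path / "a.gff3"
        p.write_text(text)
        with pytest.raises(err):
            load_annotation(p, genome)

    def test_unknown_contig_rejected(self, tmp_path, genome):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_TWO_ISOFORMS.replace("c1", "cX"))
        with pytest.raises(Exception) as exc:
            load_annotation(p, genome)
        assert "unknown contig" in str(exc.value)


class TestRegionMap:
    def test_plus_strand_promoter_upstream_of_cds(self):
        genome = GenomeSequence({"c1": "A" * 10_000})
        gene = _gene("g1", "c1", "+", [(5000, 6000)], [(5000, 6000)])
        rm = build_region_map([gene], genome, promoter_length=2000)
        assert rm.intervals("promoter")["c1"] == [(3000, 5000)]
        assert rm.intervals("coding")["c1"] == [(5000, 6000)]
        assert classify_position(rm, "c1", 2999) == "intergenic"
        assert classify_position(rm, "c1", 6000) == "intergenic"

    def test_minus_strand_promoter_is_downstream_in_coordinates(self):
        genome = GenomeSequence({"c1": "A" * 10_000})
        gene = _gene("g1", "c1", "-", [(5000, 6000)], [(5000, 6000)])
        rm = build_region_map([gene], genome, promoter_length=2000)
        assert rm.intervals("promoter")["c1"] == [(6000, 8000)]

    def test_promoter_clipped_at_contig_start(self):
        genome = GenomeSequence({"c1": "A" * 10_000})
        gene = _gene("g1", "c1", "+", [(500, 900)], [(500, 900)])
        rm = build_region_map([gene], genome, promoter_length=2000)
        assert rm.intervals("promoter")["c1"] == [(0, 500)]

    def test_coding_wins_over_overlapping_promoter(self):
        genome = GenomeSequence({"c1": "A" * 10_000})
        a = _gene("a", "c1", "+", [(5000, 6000)], [(5000, 6000)])
        b = _gene("b", "c1", "+", [(7000, 7500)], [(7000, 7500)])
        rm = build_region_map([a, b], genome, promoter_length=2000)
        # b's promoter [5000,7000) overlaps a's CDS
        assert classify_position(rm, "c1", 5500) == "coding"
        assert classify_position(rm, "c1", 6500) == "promoter"

    def test_intron_is_other_genic_and_far_upstream_is_intergenic(self):
        genome = GenomeSequence({"c1": "A" * 10_000})
        g = _gene(
            "g1", "c1", "+",
            [(5000, 5200), (5600, 5800)],
            [(5000, 5200), (5600, 5800)],
        )
        rm = build_region_map([g], genome, promoter_length=2000)
        assert classify_position(rm, "c1", 5400) == "other_genic"
        assert classify_position(rm, "c1", 500) == "intergenic"

    def test_gene_without_cds_gets_no_promoter(self, caplog):
        genome = GenomeSequence({"c1": "A" * 10_000})
        g = _gene("g1", "c1", "+", [(5000, 6000)], [])
        with caplog.at_level("WARNING"):
            rm = build_region_map([g], genome)
        assert rm.intervals("promoter")["c1"] == []
        assert rm.intervals("other_genic")["c1"] == [(5000, 6000)]
        assert "no CDS" in caplog.text

    def test_out_of_bounds_position_raises(self):
        genome = GenomeSequence({"c1": "A" * 100})
        rm = build_region_map([], genome)
        with pytest.raises(OutOfBoundsError):
            classify_position(rm, "c1", 100)
        with pytest.raises(OutOfBoundsError):
            classify_position(rm, "cX", 0)

    @pytest.mark.parametrize("seed", [3, 7])
    def test_partition_matches_hand_painted_labels(self, seed):
        fx = make_toy_genome(
            FixtureSpec(n_genes=5, contig_length=30_000, seed=seed)
        )
        hand = paint_regions_by_hand(fx.genes, fx.genome, 2000)
        for cid, arr in fx.region_map.labels.items():
            got = [REGION_LABELS[c] for c in arr]
            assert got == hand[cid]
        # four label sets partition the contig exactly
        for cid in fx.genome.contigs:
            total = sum(
                e - s
                for lab in REGION_LABELS
                for s, e in fx.region_map.intervals(lab)[cid]
            )
            assert total == fx.genome.length(cid)

    def test_strand_symmetry_under_reverse_complement(self):
        fx = make_toy_genome(FixtureSpec(n_genes=4, contig_length=25_000, seed=5))
        L = fx.genome.length("contig1")

        def mirror_iv(iv):
            return (L - iv[1], L - iv[0])

        mirrored_genes = []
        for g in fx.genes:
            isoforms = tuple(
                Isoform(
                    iso.isoform_id,
                    tuple(sorted(mirror_iv(iv) for iv in iso.exons)),
                    tuple(sorted(mirror_iv(iv) for iv in iso.cds)),
                )
                for iso in g.isoforms
            )
            mirrored_genes.append(
                GeneModel(
                    g.gene_id, g.contig_id,
                    "-" if g.strand == "+" else "+",
                    mirror_iv(g.span), isoforms,
                )
            )
        from polyguide._seq import revcomp

        mg = GenomeSequence({"contig1": revcomp(fx.genome.contigs["contig1"])})
        rm2 = build_region_map(mirrored_genes, mg, 2000)
        assert np.array_equal(
            rm2.labels["contig1"], fx.region_map.labels["contig1"][::-1]
        )
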