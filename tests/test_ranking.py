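"""Region-CFD aggregation, overall scores, isoform coverage, ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from polyguide import (
    GuideReport,
    RegionCfdSummary,
    aggregate_region_cfd,
    isoform_coverage,
    load_homoeolog_groups,
    overall_score_default,
    overall_score_homoeolog,
    rank_guides,
)
from polyguide.errors import ContractError
from polyguide.genome import GeneModel, GenomeSequence, Isoform, build_region_map
from polyguide.offtarget import OffTargetHit
from polyguide.pam import OnTargetGuide, PamSite

unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


def _hit(region, cfd, pos=100, contig="c1", self_hit=False):
    site = PamSite(contig, "+", pos, pos, "A" * 20, "TGG", "NGG", region)
    return OffTargetHit("g", site, k=1, self_hit=self_hit, cfd=cfd)


class TestAggregate:
    def test_no_hits_beyond_self_gives_zero_summary(self):
        s, hm = aggregate_region_cfd([_hit("coding", 1.0, self_hit=True)])
        assert s == RegionCfdSummary(0.0, 0.0, 0.0, 0.0)
        assert hm is None

    def test_max_semantics_per_region(self):
        hits = [_hit("coding", 0.2), _hit("coding", 0.5), _hit("intergenic", 0.1)]
        s, _ = aggregate_region_cfd(hits)
        assert s == RegionCfdSummary(0.5, 0.0, 0.0, 0.1)

    def test_homoeologue_hits_diverted_from_maxima(self):
        # triplet of identical single-exon genes; hit lands in B's CDS
        genome = GenomeSequence({"c1": "A" * 30_000})
        genes = [
            GeneModel(
                gid, "c1", "+", (s, s + 1000),
                (Isoform(f"{gid}.1", ((s, s + 1000),), ((s, s + 1000),)),),
            )
            for gid, s in [("A", 5000), ("B", 10_000), ("C", 15_000)]
        ]
        rm = build_region_map(genes, genome, promoter_length=2000)
        hits = [_hit("coding", 0.9, pos=10_500)]
        s, hm = aggregate_region_cfd(
            hits, homoeolog_partners=["B", "C"], region_map=rm
        )
        assert s.cfd_coding == 0.0
        assert hm == [0.9, 0.0]  # best per partner, zero-filled, sorted by id


class TestOverallScores:
    def test_default_corner_cases(self):
        assert overall_score_default(1.0, RegionCfdSummary()) == pytest.approx(1.5)
        assert overall_score_default(
            0.0, RegionCfdSummary(1.0, 1.0, 1.0, 1.0)
        ) == pytest.approx(0.5)

    def test_default_worked_example(self):
        s = RegionCfdSummary(cfd_coding=0.5)
        assert overall_score_default(0.6, s) == pytest.approx(1.125)

    def test_homoeolog_corner_cases(self):
        assert overall_score_homoeolog(
            1.0, RegionCfdSummary(), [1.0, 1.0]
        ) == pytest.approx(1.67)
        assert overall_score_homoeolog(
            0.0, RegionCfdSummary(1.0, 1.0, 1.0, 1.0), [0.0, 0.0]
        ) == pytest.approx(0.67)

    def test_homoeolog_reward_is_linear_in_mean(self):
        s = RegionCfdSummary()
        lo = overall_score_homoeolog(0.5, s, [0.4, 0.4])
        hi = overall_score_homoeolog(0.5, s, [0.5, 0.5])
        assert hi - lo == pytest.approx(0.034)

    def test_finite_differences_recover_printed_coefficients(self):
        base = overall_score_default(0.0, RegionCfdSummary())
        assert overall_score_default(1.0, RegionCfdSummary()) - base == pytest.approx(0.5)
        assert base - overall_score_default(
            0.0, RegionCfdSummary(cfd_coding=1.0)
        ) == pytest.approx(0.35)  # 0.5 * 0.7
        assert base - overall_score_default(
            0.0, RegionCfdSummary(cfd_promoter=1.0)
        ) == pytest.approx(0.35)
        assert base - overall_score_default(
            0.0, RegionCfdSummary(cfd_other_genic=1.0)
        ) == pytest.approx(0.1)
        assert base - overall_score_default(
            0.0, RegionCfdSummary(cfd_intergenic=1.0)
        ) == pytest.approx(0.05)
        h0 = overall_score_homoeolog(0.0, RegionCfdSummary(), [0.0])
        h1 = overall_score_homoeolog(0.0, RegionCfdSummary(), [1.0])
        assert h1 - h0 == pytest.approx(0.34)

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ContractError):
            overall_score_default(1.2, RegionCfdSummary())
        with pytest.raises(ContractError):
            overall_score_default(0.5, RegionCfdSummary(cfd_coding=-0.1))
        with pytest.raises(ContractError):
            overall_score_homoeolog(0.5, RegionCfdSummary(), [])

    @settings(max_examples=200, derandomize=True)
    @given(rs2=unit, c=unit, p=unit, o=unit, i=unit, h=st.lists(unit, min_size=1, max_size=5))
    def test_bounds_and_monotonicity(self, rs2, c, p, o, i, h):
        s = RegionCfdSummary(c, p, o, i)
        d = overall_score_default(rs2, s)
        assert 0.5 - 1e-12 <= d <= 1.5 + 1e-12
        hm = overall_score_homoeolog(rs2, s, h)
        assert 0.67 - 1e-12 <= hm <= 1.67 + 1e-12
        # non-increasing in each cfd component, non-decreasing in rs2
        worse = RegionCfdSummary(min(1.0, c + 0.1), p, o, i)
        assert overall_score_default(rs2, worse) <= d + 1e-12
        assert overall_score_default(min(1.0, rs2 + 0.1), s) >= d - 1e-12


class TestIsoformCoverage:
    @pytest.fixture
    def two_isoform_gene(self):
        exons_full = ((100, 400), (600, 900), (1100, 1400))
        exons_skip = ((100, 400), (1100, 1400))
        return GeneModel(
            "g1", "c1", "+", (100, 1400),
            (
                Isoform("g1.1", exons_full, ((160, 400), (600, 900), (1100, 1340))),
                Isoform("g1.2", exons_skip, ((160, 400), (1100, 1340))),
            ),
        )

    def _guide(self, pos, region="coding"):
        site = PamSite("c1", "+", pos, pos, "A" * 20, "TGG", "NGG", region)
        return OnTargetGuide(site, "g1", rs2=0.5)

    def test_guide_in_shared_exon_covers_all(self, two_isoform_gene):
        assert isoform_coverage(self._guide(200), two_isoform_gene) == (True, 1.0)

    def test_guide_in_skipped_exon_covers_half(self, two_isoform_gene):
        assert isoform_coverage(self._guide(700), two_isoform_gene) == (False, 0.5)

    def test_promoter_guide_covers_nothing(self, two_isoform_gene):
        got = isoform_coverage(self._guide(50, region="promoter"), two_isoform_gene)
        assert got == (False, 0.0)

    def test_footprint_straddling_exon_edge_not_covered(self, two_isoform_gene):
        # footprint [390, 413) crosses into the intron
        assert isoform_coverage(self._guide(390), two_isoform_gene)[1] == 0.0


def _report(overall, rs2, pos, contig="c1"):
    site = PamSite(contig, "+", pos, pos, "A" * 20, "TGG", "NGG", "coding")
    return GuideReport(
        guide=OnTargetGuide(site, "g1", rs2=rs2),
        summary=RegionCfdSummary(),
        cfd_hmlgs=None,
        overall=overall,
    )


class TestRanking:
    def test_ranks_are_a_permutation_and_top_ten_flagged(self):
        rng = np.random.default_rng(1)
        reports = [
            _report(float(v), 0.5, i * 40)
            for i, v in enumerate(rng.uniform(0.5, 1.5, 15))
        ]
        ranked = rank_guides(list(reports))
        assert [r.rank for r in ranked] == list(range(1, 16))
        assert sum(r.top for r in ranked) == 10
        assert all(
            ranked[i].overall >= ranked[i + 1].overall for i in range(14)
        )

    def test_tie_broken_by_rs2_then_position(self):
        a = _report(1.0, 0.8, 500)
        b = _report(1.0, 0.6, 100)
        c = _report(1.0, 0.8, 100)
        ranked = rank_guides([a, b, c])
        assert [r.guide.site.protospacer_start for r in ranked] == [100, 500, 100]
        assert [r.guide.rs2 for r in ranked] == [0.8, 0.8, 0.6]

    def test_order_insensitive_to_input_permutation(self):
        rng = np.random.default_rng(2)
        reports = [
            _report(float(rng.uniform(0.5, 1.5)), float(rng.uniform(0, 1)), i * 31)
            for i in range(20)
        ]
        ids = lambda rs: [r.guide.site.protospacer_start for r in rs]
        ref = ids(rank_guides(list(reports)))
        for _ in range(5):
            rng.shuffle(reports)
            assert ids(rank_guides(list(reports))) == ref

    def test_empty_input_gives_empty_ranking(self):
        assert rank_guides([]) == []


class TestHomoeologGroups:
    def test_round_trip_and_partners(self):
        text = "# comment\ngene_id\tgroup_id\ngA\tG1\ngB\tG1\ngC\tG1\ngX\tG2\n"
        groups = load_homoeolog_groups(text)
        assert groups.partners("gA") == ["gB", "gC"]
        assert groups.partners("gX") == []
        assert groups.partners("unknown") == []

    def test_gene_in_two_groups_rejected(self):
        with pytest.raises(ContractError):
            load_homoeolog_groups("gA\tG1\ngA\tG2\n")
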