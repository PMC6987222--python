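"""Two-region fragment classification, counting, and FPKM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neatquant.isoform_quant import (
    AlignedFragment,
    GenomicRegion,
    RegionModel,
    classify_fragment,
    count_fragments,
    fpkm,
    quantify_sam,
    quantify_sample,
    select_neat1_1_samples,
)
from neatquant.synthetic import ReadSimParams, simulate_locus_fragments, write_fragments_sam


class TestRegionModel:
    def test_default_lengths_match_printed_coordinates(self, model):
        assert model.L_common == 3735
        assert round(model.L_common / 1000, 1) == 3.7  # the short-isoform size
        assert model.L_specific == 19008
        assert model.locus_length == 22743

    def test_regions_must_be_adjacent(self):
        with pytest.raises(ValueError, match="adjacent"):
            RegionModel(
                common=GenomicRegion("chr11", 100, 200),
                specific=GenomicRegion("chr11", 300, 400),
            )

    def test_bed_round_trip(self, model, tmp_path):
        path = tmp_path / "regions.bed"
        model.to_bed(path)
        lines = path.read_text().strip().splitlines()
        # 0-based half-open on disk
        assert lines[0].split("\t")[:4] == ["chr11", "65422797", "65426532", "common"]
        assert RegionModel.from_bed(path) == model


class TestClassifyFragment:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (65_423_000, 65_423_300, "common"),  # strictly inside common
            (65_426_500, 65_426_700, "spanning"),  # covers the junction
            (65_422_798, 65_422_798, "common"),  # 1 bp at the printed start
            (65_426_533, 65_426_533, "specific"),  # 1 bp at specific start
            (65_426_532, 65_426_533, "spanning"),  # minimal junction fragment
            (65_430_000, 65_430_300, "specific"),
            (70_000_000, 70_000_300, "outside"),
            (65_422_000, 65_422_900, "common"),  # extends upstream off-locus
        ],
    )
    def test_labels(self, model, start, end, expected):
        frag = AlignedFragment("chr11", start, end)
        assert classify_fragment(frag, model) == expected

    def test_wrong_contig_is_outside(self, model):
        assert classify_fragment(AlignedFragment("chr1", 65_423_000, 65_423_300), model) == "outside"

    def test_unmapped_rejected(self, model):
        frag = AlignedFragment("*", 0, 0, is_mapped=False)
        with pytest.raises(ValueError, match="unmapped"):
            classify_fragment(frag, model)

    @given(
        start=st.integers(65_400_000, 65_460_000),
        length=st.integers(1, 1000),
    )
    @settings(max_examples=300, deadline=None)
    def test_partition_exactly_one_label(self, start, length):
        """Every fragment gets exactly one of the four labels."""
        model = RegionModel.default()
        label = classify_fragment(AlignedFragment("chr11", start, start + length - 1), model)
        assert label in {"common", "specific", "spanning", "outside"}


class TestCountFragments:
    def test_empty_input(self, model):
        counts = count_fragments([], model)
        assert (counts.rm_common, counts.rm_specific, counts.rm_total) == (0, 0, 0)

    def test_conservation_by_construction(self, model):
        frags = (
            [AlignedFragment("chr11", 65_423_000 + i, 65_423_200 + i) for i in range(10)]
            + [AlignedFragment("chr11", 65_430_000 + i, 65_430_200 + i) for i in range(5)]
            + [AlignedFragment("chr11", 65_426_400, 65_426_700)] * 2
            + [AlignedFragment("background", 100, 300)] * 3
        )
        counts = count_fragments(frags, model)
        assert counts.rm_common == 10
        assert counts.rm_specific == 5
        assert counts.n_spanning_excluded == 2
        assert counts.rm_total == 20
        assert counts.n_outside == 3

    def test_unmapped_skipped_and_tallied(self, model):
        frags = [
            AlignedFragment("chr11", 65_423_000, 65_423_200),
            AlignedFragment("*", 0, 0, is_mapped=False),
        ]
        counts = count_fragments(frags, model)
        assert counts.rm_total == 1
        assert counts.n_unmapped_skipped == 1

    def test_require_proper_pairs_filters(self, model):
        frags = [
            AlignedFragment("chr11", 65_423_000, 65_423_200, is_proper_pair=False),
            AlignedFragment("chr11", 65_423_000, 65_423_200, is_proper_pair=True),
        ]
        assert count_fragments(frags, model).rm_common == 2
        assert count_fragments(frags, model, require_proper_pairs=True).rm_common == 1

    def test_counts_match_brute_force_oracle(self, model):
        """Counting agrees with a naive per-fragment interval-overlap tally."""
        params = ReadSimParams(2000, 3000, 1500, seed=42)
        frags, _ = simulate_locus_fragments(params, model)
        counts = count_fragments(frags, model)

        # independent brute-force double loop over fragments x regions
        naive = {"common": 0, "specific": 0, "spanning": 0, "outside": 0}
        for f in frags:
            hit_c = (
                f.chrom == model.common.chrom
                and f.span_start <= model.common.end
                and f.span_end >= model.common.start
            )
            hit_s = (
                f.chrom == model.specific.chrom
                and f.span_start <= model.specific.end
                and f.span_end >= model.specific.start
            )
            if hit_c and hit_s:
                naive["spanning"] += 1
            elif hit_c:
                naive["common"] += 1
            elif hit_s:
                naive["specific"] += 1
            else:
                naive["outside"] += 1
        assert counts.rm_common == naive["common"]
        assert counts.rm_specific == naive["specific"]
        assert counts.n_spanning_excluded == naive["spanning"]
        assert counts.n_outside == naive["outside"]
        assert counts.rm_total == len(frags)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_partition_identity(self, seed):
        """rm_common + rm_specific + spanning + outside = total mapped."""
        model = RegionModel.default()
        rng = np.random.default_rng(seed)
        frags = []
        for _ in range(200):
            start = int(rng.integers(65_420_000, 65_450_000))
            frags.append(AlignedFragment("chr11", start, start + int(rng.integers(1, 2000))))
        c = count_fragments(frags, model)
        assert c.rm_common + c.rm_specific + c.n_spanning_excluded + c.n_outside == c.rm_total


class TestFpkm:
    def test_zero_count_gives_zero(self):
        assert fpkm(0, 10**6, 3735) == 0.0

    def test_unit_cancellation(self):
        assert fpkm(1000, 10**6, 1000) == 1000.0

    def test_hand_evaluated_value(self):
        assert fpkm(100, 2 * 10**6, 3735) == pytest.approx(13.387, abs=1e-3)

    def test_undefined_inputs_raise(self):
        with pytest.raises(ValueError):
            fpkm(10, 0, 1000)
        with pytest.raises(ValueError):
            fpkm(10, 1000, 0)

    @given(
        rm_g=st.integers(0, 10**6),
        rm_t=st.integers(1, 10**8),
        length=st.integers(1, 10**6),
        k=st.integers(1, 50),
    )
    @settings(max_examples=200, deadline=None)
    def test_homogeneity(self, rm_g, rm_t, length, k):
        """FPKM is degree-1 in RMg and degree -1 in RMt."""
        base = fpkm(rm_g, rm_t, length)
        assert fpkm(k * rm_g, rm_t, length) == pytest.approx(k * base, rel=1e-12)
        assert fpkm(rm_g, k * rm_t, length) == pytest.approx(base / k, rel=1e-12)


class TestQuantifySample:
    def test_no_locus_fragments_is_eligible(self, model):
        frags = [AlignedFragment("background", 1, 300)] * 100
        q = quantify_sample("s", frags, model)
        assert q.fpkm_common == 0.0 and q.fpkm_specific == 0.0
        assert q.neat1_1_eligible

    def test_eligibility_boundary_is_strict(self, model):
        """FPKM exactly 1.0 in the specific region is filtered out."""
        # rm_specific * 1e9 / (rm_total * 19008) == 1.0
        rm_specific = 19008
        rm_total = 10**9
        frags = [AlignedFragment("chr11", 65_430_000, 65_430_300)] * rm_specific
        q_counts = count_fragments(frags, model)
        assert q_counts.rm_specific == rm_specific
        assert fpkm(rm_specific, rm_total, model.L_specific) == 1.0
        from neatquant.isoform_quant import RegionCounts, SampleQuant

        q = SampleQuant(
            "s", RegionCounts(rm_specific=rm_specific, rm_total=rm_total),
            fpkm_common=0.0,
            fpkm_specific=fpkm(rm_specific, rm_total, model.L_specific),
        )
        assert not q.neat1_1_eligible
        with pytest.raises(ValueError, match="mixture"):
            q.neat1_1_fpkm

    def test_pure_short_isoform_library(self, model):
        """A pure short-isoform library leaves the specific region empty."""
        params = ReadSimParams(1000, 0, 500, seed=11)
        frags, _ = simulate_locus_fragments(params, model)
        q = quantify_sample("s", frags, model)
        assert q.counts.rm_specific == 0
        assert q.fpkm_specific == 0.0
        assert q.neat1_1_eligible

    def test_mixture_fpkm_ratio_normalizes_length(self, model):
        """Uniform coverage of the full locus gives matching region FPKMs."""
        params = ReadSimParams(0, 20_000, 0, seed=5)
        frags, _ = simulate_locus_fragments(params, model)
        q = quantify_sample("s", frags, model)
        assert q.fpkm_specific / q.fpkm_common == pytest.approx(1.0, rel=0.10)

    def test_filter_monotone_in_specific_counts(self, model):
        """Adding specific-region fragments never restores eligibility."""
        from neatquant.isoform_quant import RegionCounts, SampleQuant

        def make(rm_specific):
            rm_total = 10**6
            return SampleQuant(
                "s", RegionCounts(rm_specific=rm_specific, rm_total=rm_total),
                fpkm_common=0.0,
                fpkm_specific=fpkm(rm_specific, rm_total, model.L_specific),
            )

        flipped = False
        prev_eligible = True
        for rm_s in range(0, 200, 10):
            eligible = make(rm_s).neat1_1_eligible
            if not prev_eligible:
                assert not eligible
            prev_eligible = eligible
            flipped = flipped or not eligible
        assert flipped  # the sweep actually crosses the threshold


class TestSelectSamples:
    def _mixed_cohort(self, model):
        quants = []
        for i, n_long in enumerate([0, 10, 200, 2000, 0, 50]):
            params = ReadSimParams(500, n_long, 100_000, seed=100 + i)
            frags, _ = simulate_locus_fragments(params, model)
            quants.append(quantify_sample(f"s{i}", frags, model))
        return quants

    def test_all_or_none(self, model):
        quants = self._mixed_cohort(model)
        eligible = [q for q in quants if q.neat1_1_eligible]
        assert select_neat1_1_samples(eligible) == eligible
        ineligible = [q for q in quants if not q.neat1_1_eligible]
        assert select_neat1_1_samples(ineligible) == []

    def test_retained_set_matches_threshold(self, model):
        quants = self._mixed_cohort(model)
        retained = select_neat1_1_samples(quants)
        assert {q.sample_id for q in retained} == {
            q.sample_id for q in quants if q.fpkm_specific < 1.0
        }
        assert 0 < len(retained) < len(quants)  # the mixture straddles 1.0


class TestSamRoundTrip:
    def test_sam_preserves_counts(self, model, tmp_path):
        params = ReadSimParams(800, 1200, 500, seed=9)
        frags, _ = simulate_locus_fragments(params, model)
        direct = quantify_sample("s", frags, model)
        path = tmp_path / "sim.sam"
        write_fragments_sam(frags, path, model)
        via_sam = quantify_sam(path, "s", model)
        assert via_sam.counts == direct.counts
        assert via_sam.fpkm_common == pytest.approx(direct.fpkm_common)

    def test_sam_is_coordinate_sorted(self, model, tmp_path):
        params = ReadSimParams(100, 100, 50, seed=2)
        frags, _ = simulate_locus_fragments(params, model)
        path = tmp_path / "sim.sam"
        write_fragments_sam(frags, path, model)
        import pysam

        with pysam.AlignmentFile(str(path)) as sam:
            assert sam.header["HD"]["SO"] == "coordinate"
            last = {}
            for read in sam:
                tid = read.reference_id
                assert read.reference_start >= last.get(tid, -1) or tid not in last
                last[tid] = read.reference_start
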