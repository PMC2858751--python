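import numpy as np
import pytest

from conftest import iv, tr

from utrx import (
    ComputationError,
    ConservationTrack,
    GenomicInterval,
    ValidationError,
    confirm_by_tags,
    conservation_comparison,
    extension_region,
    extract_sequence,
    mean_conservation,
    pair_distance,
    sample_matched_region_sets,
)


class TestPairDistance:
    def test_plus_strand_gap(self):
        assert pair_distance(iv("chr1", 1000, 1025), iv("chr1", 1200, 1225)) == 175

    def test_minus_strand_mirror(self):
        assert pair_distance(
            iv("chr1", 1200, 1225, "-"), iv("chr1", 1000, 1025, "-")
        ) == 175

    def test_abutting_gives_zero(self):
        assert pair_distance(iv("chr1", 1000, 1025), iv("chr1", 1025, 1050)) == 0

    def test_overlap_or_mismatched_locus_raise(self):
        with pytest.raises(ValidationError):
            pair_distance(iv("chr1", 1000, 1025), iv("chr1", 1010, 1040))
        with pytest.raises(ValidationError):
            pair_distance(iv("chr1", 1000, 1025), iv("chr2", 1200, 1225))
        with pytest.raises(ValidationError):
            pair_distance(iv("chr1", 1000, 1025), iv("chr1", 1200, 1225, "-"))


class TestExtensionRegion:
    def test_plus_strand_far_edge(self):
        t = tr("T1", "g", "chr1", 0, 1000, "+")
        er = extension_region(t, iv("chr1", 1200, 1225))
        assert (er.region.start, er.region.end, er.length) == (1000, 1225, 225)

    def test_minus_strand_far_edge(self):
        t = tr("T1", "g", "chr1", 1000, 2000, "-")
        er = extension_region(t, iv("chr1", 800, 825, "-"))
        assert (er.region.start, er.region.end, er.length) == (800, 1000, 200)

    def test_near_edge_mode_stops_at_proximal_edge(self):
        t = tr("T1", "g", "chr1", 0, 1000, "+")
        er = extension_region(t, iv("chr1", 1200, 1225), span_mode="near")
        assert (er.region.start, er.region.end) == (1000, 1200)

    def test_target_overlapping_span_raises(self):
        t = tr("T1", "g", "chr1", 0, 1000, "+")
        with pytest.raises(ValidationError):
            extension_region(t, iv("chr1", 900, 1100))


class TestMeanConservation:
    def test_constant_track(self):
        track = ConservationTrack({"chr1": [(0, 100, 0.5)]})
        assert mean_conservation(track, iv("chr1", 10, 60)) == pytest.approx(0.5)

    def test_half_and_half(self):
        track = ConservationTrack({"chr1": [(0, 50, 1.0), (50, 100, 0.0)]})
        assert mean_conservation(track, iv("chr1", 0, 100)) == pytest.approx(0.5)

    def test_absent_bases_score_zero(self):
        track = ConservationTrack({"chr1": [(0, 4, 0.8)]})
        assert mean_conservation(track, iv("chr1", 0, 10)) == pytest.approx(0.32)

    def test_partial_run_overlap_weighted_by_covered_bases(self):
        track = ConservationTrack({"chr1": [(0, 10, 1.0)]})
        assert mean_conservation(track, iv("chr1", 5, 25)) == pytest.approx(0.25)

    def test_split_recombine_invariance(self):
        rng = np.random.default_rng(6)
        runs = [(i, i + 1, float(v)) for i, v in
                enumerate(rng.uniform(0, 1, 200))]
        track = ConservationTrack({"chr1": runs})
        region = iv("chr1", 13, 177)
        whole = mean_conservation(track, region)
        for cut in (50, 100, 150):
            a = iv("chr1", 13, cut)
            b = iv("chr1", cut, 177)
            recombined = (
                mean_conservation(track, a) * a.length
                + mean_conservation(track, b) * b.length
            ) / region.length
            assert recombined == pytest.approx(whole, abs=1e-12)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValidationError):
            ConservationTrack({"chr1": [(0, 10, 1.5)]})


class TestMatchedRegionSets:
    def test_exact_length_pool_interval_is_always_chosen(self):
        pool = [iv("chr1", 100, 150)]
        sets = sample_matched_region_sets(pool, [50], 5, seed=0)
        assert all(s == [iv("chr1", 100, 150)] for s in sets)

    def test_each_set_total_matches_target_total(self):
        rng = np.random.default_rng(4)
        pool = [iv("chr1", i * 10_000, i * 10_000 + int(rng.integers(800, 5000)))
                for i in range(40)]
        target_lengths = [657] + [2000] * 107  # sums to 214657
        assert sum(target_lengths) == 214_657
        sets = sample_matched_region_sets(pool, target_lengths, 3, seed=1)
        for s in sets:
            assert sum(r.length for r in s) == 214_657
            for r in s:
                parent = [p for p in pool if p.chrom == r.chrom
                          and p.start <= r.start and r.end <= p.end]
                assert parent, "sampled region must lie inside a pool interval"

    def test_deterministic_given_seed(self):
        pool = [iv("chr1", 0, 5000), iv("chr2", 0, 3000)]
        a = sample_matched_region_sets(pool, [100, 200], 4, seed=9)
        b = sample_matched_region_sets(pool, [100, 200], 4, seed=9)
        assert a == b

    def test_oversized_target_names_the_length(self):
        with pytest.raises(ValidationError, match="999"):
            sample_matched_region_sets([iv("chr1", 0, 500)], [999], 1, seed=0)


class TestConservationComparison:
    def _track_and_pools(self, utr_mu=0.233, ig_mu=0.124):
        rng = np.random.default_rng(8)
        utr_pool = [iv("chr1", i * 5000, i * 5000 + 1200) for i in range(30)]
        ig_pool = [iv("chr2", i * 5000, i * 5000 + 1200) for i in range(30)]
        runs = {"chr1": [], "chr2": []}
        for p in utr_pool:
            vals = np.clip(rng.normal(utr_mu, 0.1, p.length), 0, 1)
            runs["chr1"] += [(p.start + k, p.start + k + 1, float(v))
                             for k, v in enumerate(vals)]
        for p in ig_pool:
            vals = np.clip(rng.normal(ig_mu, 0.1, p.length), 0, 1)
            runs["chr2"] += [(p.start + k, p.start + k + 1, float(v))
                             for k, v in enumerate(vals)]
        return ConservationTrack(runs), utr_pool, ig_pool

    def test_conserved_regions_give_large_z_and_tiny_p(self):
        track, utr_pool, ig_pool = self._track_and_pools()
        ext = [iv("chr1", p.start, p.start + 400) for p in utr_pool[:20]]
        cmp_ = conservation_comparison(ext, utr_pool, ig_pool, track,
                                       n_sets=100, seed=3)
        assert cmp_.z > 3.72
        assert 0 < cmp_.p < 1e-4

    def test_self_draws_from_intergenic_pool_center_near_zero(self):
        track, utr_pool, ig_pool = self._track_and_pools()
        zs = []
        for seed in range(8):
            self_regions = sample_matched_region_sets(
                ig_pool, [400] * 20, 1, seed=1000 + seed)[0]
            cmp_ = conservation_comparison(self_regions, utr_pool, ig_pool,
                                           track, n_sets=60, seed=seed)
            zs.append(cmp_.z)
        assert abs(np.mean(zs)) < 2
        assert max(abs(z) for z in zs) < 5

    def test_constant_track_is_degenerate(self):
        track = ConservationTrack({"chr1": [(0, 100_000, 0.5)]})
        pool = [iv("chr1", i * 2000, i * 2000 + 1000) for i in range(20)]
        with pytest.raises(ComputationError):
            conservation_comparison(pool[:3], pool, pool, track, n_sets=10, seed=0)


class TestConfirmByTags:
    target = iv("chr1", 5000, 5025, "+")

    def test_tag_ending_inside_target_confirms(self):
        assert confirm_by_tags(self.target, [iv("chr1", 4980, 5010, "+")])

    def test_tag_entirely_upstream_does_not_confirm(self):
        assert not confirm_by_tags(self.target, [iv("chr1", 4000, 4500, "+")])

    def test_tag_far_downstream_confirms(self):
        assert confirm_by_tags(self.target, [iv("chr1", 9980, 10_000, "+")])

    def test_wrong_strand_or_chrom_ignored(self):
        assert not confirm_by_tags(self.target, [iv("chr1", 5000, 5025, "-")])
        assert not confirm_by_tags(self.target, [iv("chr2", 5000, 5025, "+")])

    def test_minus_strand_downstream_is_lower_coordinates(self):
        target = iv("chr1", 5000, 5025, "-")
        assert confirm_by_tags(target, [iv("chr1", 4000, 4020, "-")])
        assert not confirm_by_tags(target, [iv("chr1", 6000, 6020, "-")])

    def test_downstream_window_bounds_confirmation(self):
        far = [iv("chr1", 24_980, 25_000, "+")]  # ~20 kb past the target
        assert confirm_by_tags(self.target, far)
        assert not confirm_by_tags(self.target, far, max_downstream=10_000)
        near = [iv("chr1", 9_980, 10_000, "+")]
        assert confirm_by_tags(self.target, near, max_downstream=10_000)


def test_extract_sequence_is_strand_aware():
    seqs = {"chr1": "AACCGGTTACGT"}
    assert extract_sequence(seqs, iv("chr1", 2, 6, "+")) == "CCGG"
    assert extract_sequence(seqs, iv("chr1", 2, 6, "-")) == "CCGG"  # palindrome
    assert extract_sequence(seqs, iv("chr1", 6, 10, "+")) == "TTAC"
    assert extract_sequence(seqs, iv("chr1", 6, 10, "-")) == "GTAA"
    with pytest.raises(ValidationError):
        extract_sequence(seqs, iv("chr1", 5, 100))
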