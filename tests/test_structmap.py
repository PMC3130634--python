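"""Truncation mapping, accessibility smoothing/thresholding, clustering test."""

import numpy as np
import pytest
from scipy import stats

from hydsel.seqcore import (
    CodingSequence,
    PointMutation,
    ValidationError,
    VariantRecord,
    apply_mutations,
)
from hydsel.structmap import (
    AccessibilityProfile,
    DomainAnnotation,
    SurfaceRegions,
    read_accessibility,
    read_domains,
    smooth_profile,
    surface_cluster_test,
    surface_regions,
    threshold_regions,
    truncation_report,
    write_accessibility,
    write_domains,
)
from hydsel.synthdata import generate_accessibility_profile


class TestSmoothProfile:
    def test_constant_profile_unchanged(self):
        out = smooth_profile(np.full(20, 3.5), window=5)
        assert np.allclose(out, 3.5)

    def test_single_spike_hand_computed(self):
        x = np.array([0, 0, 0, 0, 0, 10, 0, 0, 0, 0], dtype=float)
        out = smooth_profile(x, window=5)
        # positions 4-8 (1-based) see the spike in their full window
        expected = np.array([0, 0, 0, 2, 2, 2, 2, 2, 0, 0], dtype=float)
        assert np.allclose(out, expected)

    def test_window_one_is_identity(self):
        x = np.arange(12, dtype=float)
        assert np.allclose(smooth_profile(x, window=1), x)

    def test_even_window_rejected(self):
        with pytest.raises(ValidationError, match="odd"):
            smooth_profile(np.zeros(10), window=4)

    def test_output_bounded_by_input_range(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-3, 7, size=101)
        out = smooth_profile(x, window=7)
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12


class TestThresholdRegions:
    def test_all_below_threshold_empty(self):
        regions = threshold_regions(np.zeros(10), threshold=1.0)
        assert regions.intervals == []

    def test_step_profile_single_interval(self):
        x = np.array([0, 0, 0, 1, 1, 1, 1, 0, 0, 0], dtype=float)
        regions = threshold_regions(x, threshold=0.5)
        assert regions.intervals == [(4, 7)]

    def test_minus_infinity_covers_everything(self):
        regions = threshold_regions(np.zeros(15), threshold=-np.inf)
        assert regions.intervals == [(1, 15)]

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        x = smooth_profile(rng.uniform(0, 1, size=200), window=5)
        for t1, t2 in [(0.3, 0.5), (0.4, 0.7)]:
            m1 = threshold_regions(x, t1).mask(200)
            m2 = threshold_regions(x, t2).mask(200)
            assert not (m2 & ~m1).any()  # regions shrink as tau rises

    def test_generated_bumps_recovered(self):
        profile = generate_accessibility_profile(
            200, bumps=[(40, 80, 1.0), (120, 160, 1.0)], baseline=0.2,
            noise=0.05, seed=3,
        )
        regions = surface_regions(profile, window=5)
        mask = regions.mask(200)
        # interiors recovered; edges may shift by the window half-width
        assert mask[44:76].all() and mask[124:156].all()
        assert not mask[:35].any() and not mask[165:].any()


class TestTruncationReport:
    @pytest.fixture()
    def parent_and_domains(self, summary):
        return summary.parent, summary.domains

    def test_variant_without_stop_keeps_full_length(self, summary):
        full = [
            v for v in summary.variants if v.activity_class.value == "FULL"
        ][0]
        rep = truncation_report(full, summary.parent, summary.domains)
        assert rep.first_stop_codon_index is None
        assert rep.residues_retained == 574 and rep.residues_lost == 0

    def test_stop_at_codon_104_retains_103(self, summary):
        bb12 = next(v for v in summary.variants if v.variant_id == "BB12")
        rep = truncation_report(bb12, summary.parent, summary.domains)
        assert rep.first_stop_codon_index == 104
        assert rep.residues_retained == 103
        assert rep.residues_lost == 574 - 103
        assert "catalytic" in rep.domains_lost

    def test_late_stop_loses_33_residues(self, summary):
        bb22 = next(v for v in summary.variants if v.variant_id == "BB22")
        rep = truncation_report(bb22, summary.parent, summary.domains)
        assert rep.residues_lost == 33
        assert "catalytic" in rep.domains_disrupted

    def test_agrees_with_direct_translation(self, summary):
        for v in summary.variants:
            rep = truncation_report(v, summary.parent)
            peptide = apply_mutations(summary.parent, v.mutations).translate()
            first = peptide.find("*")
            assert rep.residues_retained == (
                first if 0 <= first < 574 else 574
            )

    def test_retained_plus_lost_is_full_length(self, summary):
        for v in summary.variants:
            rep = truncation_report(v, summary.parent)
            assert rep.residues_retained + rep.residues_lost == 574


class TestSurfaceClusterTest:
    def test_regions_covering_everything_gives_p_one(self):
        regions = SurfaceRegions([(1, 100)], threshold=0.0, window=5)
        res = surface_cluster_test([3, 50, 99], regions, n_residues=100,
                                   n_perm=500, seed=0)
        assert res.observed == 3 and res.p_value == 1.0

    def test_empty_regions_gives_p_one(self):
        regions = SurfaceRegions([], threshold=9.9, window=5)
        res = surface_cluster_test([3, 50], regions, n_residues=100,
                                   n_perm=500, seed=0)
        assert res.observed == 0 and res.p_value == 1.0

    def test_empty_eligible_set_rejected(self):
        regions = SurfaceRegions([(1, 10)], threshold=0.0, window=5)
        with pytest.raises(ValidationError):
            surface_cluster_test([1], regions, n_residues=100, eligible=[],
                                 n_perm=10, seed=0)

    def test_planted_clustering_detected(self):
        # 10 of 12 hits inside regions covering 30% of residues: binomial
        # tail P(X >= 10 | n=12, p=0.3) ~ 2e-4, so p < 0.01 at 10^4 perms
        regions = SurfaceRegions([(1, 300)], threshold=0.0, window=5)
        rng = np.random.default_rng(2)
        inside = rng.choice(np.arange(1, 301), size=10, replace=False)
        outside = rng.choice(np.arange(301, 1001), size=2, replace=False)
        res = surface_cluster_test(
            np.concatenate([inside, outside]), regions, n_residues=1000,
            n_perm=10_000, seed=5,
        )
        assert res.observed == 10
        assert res.p_value < 0.01
        # agreement with the closed-form binomial tail, allowing for the
        # add-one correction and Monte Carlo error of a 2e-4 tail estimate
        binom_tail = stats.binom.sf(9, 12, 0.3)
        mc_sd = np.sqrt(binom_tail / 10_000)
        assert abs(res.p_value - (binom_tail + 1 / 10_001)) <= 4 * mc_sd

    def test_super_uniform_under_uniform_placement(self):
        regions = SurfaceRegions([(1, 250)], threshold=0.0, window=5)
        rng = np.random.default_rng(11)
        alpha = 0.05
        hits = 0
        trials = 400
        for i in range(trials):
            pos = rng.integers(1, 1001, size=12)
            res = surface_cluster_test(pos, regions, n_residues=1000,
                                       n_perm=500, seed=1000 + i)
            hits += res.p_value <= alpha
        assert hits / trials <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / trials)


class TestIO:
    def test_domain_table_round_trip(self, tmp_path, summary):
        p = tmp_path / "domains.tsv"
        write_domains(summary.domains, p)
        back = read_domains(p)
        assert tuple(back) == summary.domains

    def test_accessibility_round_trip_and_validation(self, tmp_path):
        profile = generate_accessibility_profile(50, bumps=[(10, 20, 1.0)], seed=1)
        p = tmp_path / "acc.tsv"
        write_accessibility(profile, p)
        back = read_accessibility(p)
        assert np.allclose(back.scores, profile.scores)
        bad = tmp_path / "bad.tsv"
        bad.write_text("residue\tscore\n1\t0.5\n3\t0.6\n")
        with pytest.raises(ValidationError, match="contiguously"):
            read_accessibility(bad)
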