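import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cfcnv import (
    BiasRegion,
    BinGrid,
    CnvEvent,
    SimConfig,
    TruthProfile,
    expected_log2ratio,
    make_truth_profile,
    normalize_nocontrol,
    simulate_counts,
    simulate_fragment_lengths,
    simulate_healthy_cohort,
)
from cfcnv.simdata import bias_vector, expected_bin_means

from conftest import midpoint_scan


# ---------------------------------------------------------------------------
# Truth profiles
# ---------------------------------------------------------------------------

class TestTruthProfile:
    def test_no_events_is_diploid_everywhere(self, small_grid):
        truth = make_truth_profile(small_grid, [])
        assert (truth.bin_copy() == 2).all()

    def test_whole_chromosome_event(self, small_grid):
        truth = make_truth_profile(small_grid, [("chr2", 0, 3_000_000, 3)])
        copy = truth.bin_copy()
        sl = small_grid.chrom_slice("chr2")
        assert (copy[sl] == 3).all()
        outside = np.ones(small_grid.n_bins, bool)
        outside[sl] = False
        assert (copy[outside] == 2).all()

    def test_midpoint_rule_matches_brute_force_scan(self, small_grid):
        # boundaries deliberately not bin-aligned
        start, end = 130_000, 1_240_000
        truth = make_truth_profile(small_grid, [("chr1", start, end, 4)])
        copy = truth.bin_copy()
        expected = midpoint_scan(small_grid, "chr1", start, end)
        assert sorted(np.flatnonzero(copy == 4)) == expected

    def test_overlapping_events_rejected_with_pair(self, small_grid):
        with pytest.raises(ValueError, match="overlap"):
            make_truth_profile(
                small_grid,
                [("chr1", 0, 1_000_000, 3), ("chr1", 500_000, 2_000_000, 1)],
            )

    def test_event_outside_grid_rejected(self, small_grid):
        with pytest.raises(ValueError, match="exceeds"):
            make_truth_profile(small_grid, [("chr2", 0, 9_000_000, 3)])
        with pytest.raises(ValueError, match="not in grid"):
            make_truth_profile(small_grid, [("chr7", 0, 100_000, 3)])

    def test_negative_copy_rejected(self):
        with pytest.raises(ValueError):
            CnvEvent("chr1", 0, 100_000, -1)


# ---------------------------------------------------------------------------
# Expected log2ratio
# ---------------------------------------------------------------------------

class TestExpectedLog2Ratio:
    @pytest.mark.parametrize("f", [0.0, 0.3, 1.0])
    def test_neutral_copy_is_zero(self, f):
        assert expected_log2ratio(2, f) == 0.0

    def test_known_values(self):
        assert expected_log2ratio(4, 1.0) == pytest.approx(1.0)
        assert expected_log2ratio(4, 0.1) == pytest.approx(np.log2(1.1))
        assert expected_log2ratio(0, 1.0, floor=-4) == -4.0

    @given(
        c=st.integers(min_value=0, max_value=8),
        f=st.floats(min_value=0.01, max_value=1.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_copy_and_fraction(self, c, f):
        assert expected_log2ratio(c + 1, f) > expected_log2ratio(c, f)
        if f <= 0.99:
            hi = expected_log2ratio(c, min(f + 0.01, 1.0))
            lo = expected_log2ratio(c, f)
            if c > 2:
                assert hi > lo
            elif c < 2:
                assert hi < lo


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

class TestSimulateCounts:
    def test_uniform_expectation_over_replicates(self, small_grid):
        # f=0, no bias, Poisson: per-bin mean = N * w_i / sum(w); over 200
        # replicates the empirical mean must sit within 3 standard errors
        cfg = SimConfig(total_reads=50_000, seed=11)
        truth = TruthProfile(small_grid)
        mu = expected_bin_means(small_grid, truth, cfg)
        rng = cfg.rng()
        reps = np.array([
            simulate_counts(small_grid, truth, cfg, rng=rng).counts
            for _ in range(200)
        ])
        se = np.sqrt(mu / 200)
        assert (np.abs(reps.mean(axis=0) - mu) <= 3 * se + 1e-9).mean() >= 0.97
        # expectation conservation: totals average to N
        total_se = np.sqrt(cfg.total_reads / 200)
        assert abs(reps.sum(axis=1).mean() - cfg.total_reads) <= 3 * total_se

    def test_genome_scale_mean_reads_per_bin(self, human_grid):
        # ~30,000 bins at 100 kb, 2 M reads -> ~66.7 reads per bin
        cfg = SimConfig(total_reads=2_000_000, seed=1)
        mu = expected_bin_means(human_grid, TruthProfile(human_grid), cfg)
        full = human_grid.bin_widths == human_grid.bin_width
        assert mu[full].mean() == pytest.approx(
            2_000_000 / human_grid.n_bins, rel=0.02)
        assert mu.sum() == pytest.approx(2_000_000)

    def test_pure_tumor_event_doubles_depth(self, medium_grid):
        truth = make_truth_profile(medium_grid, [("chr1", 0, 15_000_000, 4)])
        cfg = SimConfig(tumor_fraction=1.0, total_reads=500_000, seed=3)
        p = simulate_counts(medium_grid, truth, cfg)
        in_ev = truth.bin_copy() == 4
        ratio = p.counts[in_ev].mean() / p.counts[~in_ev & medium_grid.autosome_mask
                                                  & (medium_grid.bin_widths == 100_000)].mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_deterministic_given_config(self, small_grid):
        cfg = SimConfig(total_reads=10_000, seed=42, dispersion=0.05)
        truth = TruthProfile(small_grid)
        a = simulate_counts(small_grid, truth, cfg)
        b = simulate_counts(small_grid, truth, cfg)
        assert (a.counts == b.counts).all()

    def test_overdispersion_inflates_variance(self, small_grid):
        truth = TruthProfile(small_grid)
        pois = SimConfig(total_reads=100_000, seed=5)
        nb = SimConfig(total_reads=100_000, seed=5, dispersion=0.2)
        var_p = simulate_counts(small_grid, truth, pois).counts.var()
        var_nb = simulate_counts(small_grid, truth, nb).counts.var()
        assert var_nb > 2 * var_p

    def test_invalid_inputs_rejected(self, small_grid):
        with pytest.raises(ValueError):
            SimConfig(total_reads=0)
        with pytest.raises(ValueError):
            SimConfig(tumor_fraction=1.5)
        with pytest.raises(ValueError):
            BiasRegion("chr1", 0, 100_000, factor=0.0)


# ---------------------------------------------------------------------------
# Healthy cohorts with shared artifacts
# ---------------------------------------------------------------------------

class TestHealthyCohort:
    def test_shared_bias_appears_in_every_sample(self, medium_grid):
        region = BiasRegion("chr1", 5_000_000, 10_000_000, 1.07, shared=True)
        cfg = SimConfig(total_reads=2_000_000, seed=7, bias_regions=(region,))
        cohort = simulate_healthy_cohort(medium_grid, 5, cfg)
        hit = bias_vector(medium_grid, [region]) > 1
        for p in cohort:
            r = normalize_nocontrol(p)
            observed = np.nanmean(r.log2ratio[hit])
            assert observed == pytest.approx(np.log2(1.07), abs=0.03)

    def test_no_bias_gives_noise_only_cohort(self, medium_grid):
        cfg = SimConfig(total_reads=1_000_000, seed=9)
        cohort = simulate_healthy_cohort(medium_grid, 3, cfg)
        for p in cohort:
            r = normalize_nocontrol(p)
            assert np.nanmax(np.abs(r.log2ratio)) < 0.5  # pure sampling noise
        assert not (cohort[0].counts == cohort[1].counts).all()

    def test_non_shared_bias_hits_exactly_one_sample(self, medium_grid):
        region = BiasRegion("chr2", 0, 10_000_000, 1.30, shared=False)
        cfg = SimConfig(total_reads=2_000_000, seed=13,
                        bias_regions=(region,))
        cohort = simulate_healthy_cohort(medium_grid, 5, cfg)
        hit = bias_vector(medium_grid, [region]) > 1
        # brute-force per-sample threshold scan
        recurrence = 0
        for p in cohort:
            r = normalize_nocontrol(p)
            if np.nanmean(r.log2ratio[hit]) > 0.5 * np.log2(1.30):
                recurrence += 1
        assert recurrence == 1

    def test_shared_bias_estimates_agree_across_samples(self, medium_grid):
        region = BiasRegion("chr1", 0, 10_000_000, 1.15, shared=True)
        cfg = SimConfig(total_reads=2_000_000, seed=21,
                        bias_regions=(region,))
        cohort = simulate_healthy_cohort(medium_grid, 4, cfg)
        hit = bias_vector(medium_grid, [region]) > 1
        estimates = [
            np.nanmean(normalize_nocontrol(p).log2ratio[hit]) for p in cohort
        ]
        assert np.ptp(estimates) < 0.04  # sampling error only

    def test_cohort_size_validated(self, small_grid):
        with pytest.raises(ValueError):
            simulate_healthy_cohort(small_grid, 1, SimConfig(seed=1))


# ---------------------------------------------------------------------------
# Fragment lengths
# ---------------------------------------------------------------------------

class TestFragmentLengths:
    def test_mononucleosomal_mode(self):
        cfg = SimConfig(seed=2, shoulder_weight=0.0)
        fl = simulate_fragment_lengths(10_000, cfg)
        assert abs(fl.mode - 169) <= 10

    def test_pure_shoulder_mode(self):
        cfg = SimConfig(seed=2, shoulder_weight=1.0)
        fl = simulate_fragment_lengths(10_000, cfg)
        assert abs(fl.mode - 320) <= 10

    def test_component_proportions_recovered(self):
        # assign fragments to components at the 245-bp midpoint; the
        # shoulder share must match the mixing weight within 3 binomial SE
        w = 0.2
        n = 50_000
        cfg = SimConfig(seed=4, shoulder_weight=w)
        fl = simulate_fragment_lengths(n, cfg)
        share = (fl.lengths > 245).mean()
        se = np.sqrt(w * (1 - w) / n)
        assert abs(share - w) <= 3 * se

    def test_bimodal_histogram(self):
        cfg = SimConfig(seed=8, shoulder_weight=0.25)
        fl = simulate_fragment_lengths(50_000, cfg)
        hist = np.convolve(fl.histogram(500), np.ones(5) / 5, mode="same")
        lo_peak = hist[120:250].argmax() + 120
        hi_peak = hist[250:450].argmax() + 250
        assert abs(lo_peak - 169) <= 10
        assert abs(hi_peak - 320) <= 15

    def test_determinism_and_validation(self):
        cfg = SimConfig(seed=6)
        a = simulate_fragment_lengths(1000, cfg)
        b = simulate_fragment_lengths(1000, cfg)
        assert (a.lengths == b.lengths).all()
        with pytest.raises(ValueError):
            simulate_fragment_lengths(0, cfg)
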