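"""Rate and temporal neurometrics: RTH, z-scores, VS/Rayleigh, MTS, MI, similarity."""

import numpy as np
import pytest
from scipy.stats import poisson

from diplisten import neurometrics as nm
from diplisten import simulate as sim
from conftest import flat_profile


def poisson_trains(rate_hz, n_trials, seed=0):
    t = np.arange(-1.0, 2.0, 0.001)
    lam = np.full_like(t, rate_hz)
    rng = np.random.default_rng(seed)
    return [sim.sample_spike_train(t, lam, 0.0, rng, trial_index=i)
            for i in range(n_trials)]


class TestRTH:
    def test_flat_rate_recovered(self):
        trains = poisson_trains(20.0, 400)
        rth = nm.compute_rth(trains)
        assert rth.density.mean() == pytest.approx(20.0, rel=0.03)
        assert rth.density.std() < 3.0

    def test_single_spike_gives_rectangular_bump(self):
        rth = nm.compute_rth([np.array([0.005])])
        nz = rth.density > 1e-12
        assert nz.sum() == 5  # 50 ms kernel on the 10 ms grid
        np.testing.assert_allclose(rth.density[nz], 20.0)  # 1/(0.01*5) spikes/s

    def test_mass_conservation(self):
        trains = poisson_trains(15.0, 50, seed=3)
        rth = nm.compute_rth(trains)
        mean_count = np.mean([len(tr.spike_times_s) for tr in trains])
        assert rth.density.sum() * 0.010 == pytest.approx(mean_count, rel=0.01)

    def test_locked_unit_rth_periodic_at_10hz(self, locked_nogo_trains):
        rth = nm.compute_rth(locked_nogo_trains)
        d = rth.density - rth.density.mean()
        ac = np.correlate(d, d, mode="full")[len(d) - 1:]
        lag_bins = int(np.argmax(ac[5:16])) + 5  # search 50-150 ms
        assert lag_bins == 10  # 100 ms

    def test_empty_trains_allowed(self):
        rth = nm.compute_rth([np.empty(0), np.empty(0)])
        np.testing.assert_allclose(rth.density, 0.0)


class TestIncrementalRates:
    def test_single_spike_arithmetic(self):
        rates = nm.incremental_rates([np.array([0.02])], n_steps=3)
        np.testing.assert_allclose(rates[0], [20.0, 10.0, 20 / 3])

    def test_no_spikes_all_zero(self):
        rates = nm.incremental_rates([np.empty(0)], n_steps=5)
        np.testing.assert_allclose(rates, 0.0)

    def test_converges_to_true_rate(self):
        trains = poisson_trains(25.0, 300, seed=4)
        rates = nm.incremental_rates(trains, n_steps=40)
        assert rates[:, -1].mean() == pytest.approx(25.0, rel=0.05)


class TestRateZscore:
    def test_closed_form(self):
        go = np.array([8.0, 10.0, 12.0])  # mu 10, sd 2
        nogo = np.array([4.0, 6.0, 8.0])  # mu 6, sd 2
        assert nm.rate_zscore(go, nogo).z == pytest.approx(2.0)

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10, 2, 500)
        y = rng.normal(10, 2, 500)
        assert abs(nm.rate_zscore(x, y).z) < 0.2

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(5, 1, 50), rng.normal(7, 2, 50)
        assert nm.rate_zscore(a, b).z == pytest.approx(-nm.rate_zscore(b, a).z)

    def test_zero_variance_flagged_nan(self):
        assert np.isnan(nm.rate_zscore([1.0, 1.0, 1.0], [2.0, 2.0]).z)


class TestVectorStrength:
    def test_perfect_locking(self):
        t = 0.3 + 0.1 * np.arange(20)  # same phase every cycle
        assert nm.vector_strength(t).vs == pytest.approx(1.0)

    def test_symmetric_phases_cancel(self):
        t = np.array([0.0, 0.025, 0.05, 0.075])  # phases 0, pi/2, pi, 3pi/2
        assert nm.vector_strength(t).vs == pytest.approx(0.0, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nm.vector_strength(np.empty(0))

    def test_spectrum_grid(self):
        t = 0.1 * np.arange(50)
        stats_ = nm.vector_strength_spectrum(t)
        assert [s.f_base_hz for s in stats_] == list(range(1, 21))
        by_f = {s.f_base_hz: s.vs for s in stats_}
        assert by_f[10.0] == pytest.approx(1.0)


class TestRayleigh:
    @pytest.mark.parametrize("n", [1, 5, 17, 1000])
    def test_identity_at_vs_zero(self, n):
        assert nm.rayleigh_p(0.0, n) == 1.0

    def test_direct_evaluation(self):
        # VS=1, n=10: p = exp(sqrt(41) - 21)
        assert nm.rayleigh_p(1.0, 10) == pytest.approx(np.exp(np.sqrt(41) - 21))

    def test_monotone_decreasing_in_n(self):
        ps = [nm.rayleigh_p(0.3, n) for n in (10, 50, 100, 500)]
        assert all(b < a for a, b in zip(ps, ps[1:]))


class TestMTS:
    def test_locked_unit_peaks_at_10hz(self, locked_nogo_trains):
        f, psds = nm.mts_psd(locked_nogo_trains, seed=1)
        mean = psds.mean(axis=0)
        i10 = int(np.argmin(np.abs(f - 10.0)))
        neighbors = mean[(f >= 3) & (f <= 17) & (np.abs(f - 10) > 2)]
        assert mean[i10] > 3.0 * neighbors.mean()

    def test_homogeneous_poisson_flat_at_10hz(self):
        trains = poisson_trains(20.0, 60, seed=9)
        f, psds = nm.mts_psd(trains, seed=2)
        mean = psds.mean(axis=0)
        i10 = int(np.argmin(np.abs(f - 10.0)))
        neighbors = mean[(f >= 3) & (f <= 17) & (np.abs(f - 10) > 2)]
        assert mean[i10] < 2.0 * neighbors.mean()

    def test_deterministic_under_seed(self, locked_nogo_trains):
        _, a = nm.mts_psd(locked_nogo_trains, seed=3)
        _, b = nm.mts_psd(locked_nogo_trains, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_peak_decreases_with_locking_suppression(self):
        """Weaker locking during the target -> smaller 10 Hz peak."""
        heights = []
        for supp in (0.0, 0.3, 0.6):
            prof = sim.UnitProfile(
                0, 20.0, 0.8, {}, {}, {}, {0.0: supp})
            t, lam = sim.intensity_function(prof, "Go", 0.0, "passive")
            rng = np.random.default_rng(12)
            trains = [sim.sample_spike_train(t, lam, 0.0, rng)
                      for _ in range(80)]
            f, psds = nm.mts_psd(trains, seed=4)
            i10 = int(np.argmin(np.abs(f - 10.0)))
            heights.append(psds.mean(axis=0)[i10])
        assert heights[0] > heights[1] > heights[2]

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            nm.mts_psd(poisson_trains(10.0, 3))


class TestPsdZscore:
    def test_identical_ensembles_near_zero(self):
        trains = poisson_trains(20.0, 40, seed=13)
        f, a = nm.mts_psd(trains, seed=5)
        _, b = nm.mts_psd(trains, seed=5)
        assert nm.psd10_zscore(a, b, f).z == pytest.approx(0.0, abs=1e-12)

    def test_sign_flips_under_condition_swap(self, locked_nogo_trains):
        f, a = nm.mts_psd(locked_nogo_trains, seed=6)
        _, b = nm.mts_psd(poisson_trains(20.0, 40, seed=14), seed=7)
        assert nm.psd10_zscore(a, b, f).z == pytest.approx(
            -nm.psd10_zscore(b, a, f).z)


class TestSlidingRho:
    def test_identical_rths_give_unit_rho(self, locked_nogo_trains):
        rth = nm.compute_rth(locked_nogo_trains)
        stats_ = nm.sliding_rho(rth, rth)
        defined = stats_.rho_series[~np.isnan(stats_.rho_series)]
        np.testing.assert_allclose(defined, 1.0, atol=1e-9)

    def test_rho_invariant_to_constant_offset(self, locked_nogo_trains):
        rth = nm.compute_rth(locked_nogo_trains)
        shifted = nm.RTH(rth.bin_centers_s, rth.density + 5.0, rth.n_trials)
        stats_ = nm.sliding_rho(shifted, rth)
        defined = stats_.rho_series[~np.isnan(stats_.rho_series)]
        np.testing.assert_allclose(defined, 1.0, atol=1e-9)

    def test_target_evoked_pattern_change_drops_rho(self):
        """A unit whose locking collapses at target onset decorrelates."""
        go_prof = sim.UnitProfile(0, 20.0, 0.8, {}, {},
                                  {0.0: 1.0}, {0.0: 0.75})
        nogo_prof = flat_profile(rate_hz=20.0, depth=0.8)
        rng = np.random.default_rng(15)
        t, lam_g = sim.intensity_function(go_prof, "Go", 0.0, "passive")
        _, lam_n = sim.intensity_function(nogo_prof, "NoGo", -np.inf, "passive")
        go = [sim.sample_spike_train(t, lam_g, 0.001, rng) for _ in range(150)]
        nogo = [sim.sample_spike_train(t, lam_n, 0.001, rng) for _ in range(150)]
        stats_ = nm.sliding_rho(nm.compute_rth(go), nm.compute_rth(nogo))
        s = stats_.window_start_s
        rho_pre = np.nanmean(stats_.rho_series[(s >= -0.6) & (s < -0.3)])
        rho_onset = np.nanmean(stats_.rho_series[(s >= 0.0) & (s < 0.3)])
        assert rho_onset < rho_pre - 0.2

    def test_grid_mismatch_rejected(self, locked_nogo_trains):
        rth = nm.compute_rth(locked_nogo_trains)
        other = nm.RTH(rth.bin_centers_s + 0.005, rth.density, rth.n_trials)
        with pytest.raises(ValueError):
            nm.sliding_rho(rth, other)


class TestDecorrelationZscore:
    def _stats(self, seed, go_same_as_nogo):
        rng = np.random.default_rng(seed)
        nogo_prof = flat_profile(rate_hz=20.0, depth=0.8)
        t, lam_n = sim.intensity_function(nogo_prof, "NoGo", -np.inf, "passive")
        if go_same_as_nogo:
            lam_g = lam_n
        else:
            go_prof = sim.UnitProfile(0, 20.0, 0.8, {}, {}, {0.0: 1.0},
                                      {0.0: 0.75})
            _, lam_g = sim.intensity_function(go_prof, "Go", 0.0, "passive")
        go = [sim.sample_spike_train(t, lam_g, 0.001, rng) for _ in range(120)]
        nogo = [sim.sample_spike_train(t, lam_n, 0.001, rng) for _ in range(120)]
        return nm.sliding_rho(nm.compute_rth(go), nm.compute_rth(nogo))

    def test_null_case_centered_on_zero(self):
        """Without a target effect the z-score has no systematic sign.

        Single-realization z values are noisy (the rho series is strongly
        autocorrelated across overlapping windows), so the check is on the
        mean over seeds against its own standard error.
        """
        zs = [nm.decorrelation_zscore(self._stats(s, True), -0.3).z
              for s in range(8)]
        sem = np.std(zs, ddof=1) / np.sqrt(len(zs))
        assert abs(np.mean(zs)) < 3 * sem + 0.5

    def test_strong_decorrelation_negative_z(self):
        z = nm.decorrelation_zscore(self._stats(16, False), -0.3).z
        assert z < -1.0

    def test_window_swap_negates_z(self):
        stats_ = self._stats(17, False)
        fwd = nm.decorrelation_zscore(stats_, poke_time_s=-0.3, onset_time_s=0.0)
        # exchanging the two window sets (onset windows become the baseline
        # and vice versa) must negate the z-score
        rev = nm.decorrelation_zscore(stats_, poke_time_s=0.3, onset_time_s=-0.6)
        assert fwd.z == pytest.approx(-rev.z)


class TestMutualInformation:
    @staticmethod
    def brute_force_mi(lam_g, lam_n, support=1000):
        ks = np.arange(support + 1)
        pg, pn = poisson.pmf(ks, lam_g), poisson.pmf(ks, lam_n)
        mix = 0.5 * (pg + pn)
        out = 0.0
        for p in (pg, pn):
            nz = (p > 1e-300) & (mix > 1e-300)
            out += 0.5 * np.sum(p[nz] * np.log2(p[nz] / mix[nz]))
        return out

    def test_identical_rates_zero_information(self):
        pp = nm.poisson_mutual_information([5, 6, 4, 5], [5, 4, 6, 5])
        assert pp.mi_bits == pytest.approx(0.0, abs=1e-12)

    def test_separable_limit_approaches_one_bit(self):
        pp = nm.poisson_mutual_information([0, 0, 0], [200, 201, 199])
        assert pp.mi_bits == pytest.approx(1.0, abs=1e-6)

    def test_matches_brute_force_summation(self):
        lam_grid = [0.0, 0.5, 2.0, 8.0, 20.0, 50.0]
        for lg in lam_grid:
            for ln in lam_grid:
                assert abs(nm._two_poisson_mi_bits(lg, ln)
                           - self.brute_force_mi(lg, ln)) < 1e-9

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nm.poisson_mutual_information([-1, 2], [3, 4])

    def test_sustained_counts_window(self):
        train = sim.SpikeTrain(0, 0, np.array([-0.5, 0.05, 0.2, 0.5, 0.94, 1.5]))
        assert nm.sustained_counts([train])[0] == 3


class TestSimilarityIndex:
    def test_identical_rths_slope_one(self, locked_nogo_trains):
        rth = nm.compute_rth(locked_nogo_trains)
        assert nm.similarity_index(rth, rth).slope == pytest.approx(1.0)

    def test_scaled_rth_slope_half(self, locked_nogo_trains):
        rth = nm.compute_rth(locked_nogo_trains)
        half = nm.RTH(rth.bin_centers_s, 0.5 * rth.density, rth.n_trials)
        assert nm.similarity_index(half, rth).slope == pytest.approx(0.5)

    def test_uncorrelated_rths_slope_near_zero(self):
        a = nm.compute_rth(poisson_trains(20.0, 200, seed=20))
        b = nm.compute_rth(poisson_trains(20.0, 200, seed=21))
        assert abs(nm.similarity_index(a, b).slope) < 0.2

    def test_constant_nogo_rejected(self, locked_nogo_trains):
        rth = nm.compute_rth(locked_nogo_trains)
        const = nm.RTH(rth.bin_centers_s, np.full_like(rth.density, 3.0),
                       rth.n_trials)
        with pytest.raises(ValueError):
            nm.similarity_index(rth, const)


class TestFirstSpikeLatency:
    def test_first_post_onset_spike(self):
        out = nm.first_spike_latency([np.array([-0.1, 0.02, 0.4])])
        assert out.latencies_s[0] == pytest.approx(0.02)
        assert out.n_excluded == 0

    def test_trials_without_post_onset_spikes_excluded(self):
        out = nm.first_spike_latency([np.array([-0.5, -0.1]), np.array([0.03])])
        assert out.n_excluded == 1
        assert out.mean_s == pytest.approx(0.03)

    def test_onset_transient_dominates_latency(self):
        """A strong 20 ms-latency onset transient pulls mean latency near it."""
        prof = sim.UnitProfile(
            0, 2.0, 0.0, {0.0: sim.Transient(300.0, 0.020, 0.030)}, {},
            {0.0: 1.0}, {0.0: 0.0})
        t, lam = sim.intensity_function(prof, "Go", 0.0, "passive")
        rng = np.random.default_rng(22)
        trains = [sim.sample_spike_train(t, lam, 0.001, rng) for _ in range(300)]
        out = nm.first_spike_latency(trains)
        assert 0.015 < out.mean_s < 0.06
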