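"""Feature extractor: network rate, burst/fragment detection, ISI, MAC."""

import numpy as np
import pytest

from mea_sbi import (
    SpikeRaster,
    binarized_cc,
    compute_features,
    detect_bursts,
    detect_fragments,
    isi_distance,
    isi_series,
    mac,
    network_rate,
)
from mea_sbi.features import NetworkBurst, NetworkRate
from mea_sbi.fixtures import crafted_raster


def _empty(duration=60.0, n=12):
    return SpikeRaster([np.empty(0)] * n, duration)


class TestNetworkRate:
    def test_empty_raster(self):
        r = network_rate(_empty())
        assert r.max_rate == 0 and r.counts.sum() == 0

    def test_single_bin(self):
        raster = SpikeRaster([np.array([0.01])] * 12, 60.0)
        r = network_rate(raster)
        assert r.counts[0] == 12 and r.counts[1:].sum() == 0

    def test_counts_conserve_spikes_poisson(self):
        rng = np.random.default_rng(0)
        rate_hz = 5.0
        raster = SpikeRaster(
            [np.sort(rng.uniform(0, 60, rng.poisson(rate_hz * 60))) for _ in range(12)],
            60.0,
        )
        r = network_rate(raster)
        assert r.counts.sum() == raster.n_spikes
        expect = 12 * rate_hz * 0.025
        se = np.sqrt(expect / len(r.counts))
        assert abs(r.counts.mean() - expect) < 3 * se * np.sqrt(len(r.counts) / len(r.counts))


class TestDetectBursts:
    def test_empty_raster_no_bursts(self):
        assert detect_bursts(_empty()) == []

    def test_two_crafted_bursts_found_at_onsets(self):
        raster = crafted_raster(
            n_bursts=2, period_s=4.0, burst_duration=0.3, duration=8.0,
            background_rate=0.4, first_burst=1.0, seed=1,
        )
        bursts = detect_bursts(raster)
        assert len(bursts) == 2
        for b, onset in zip(bursts, [1.0, 5.0]):
            assert abs(b.start - onset) <= 0.025
            assert abs(b.duration - 0.3) <= 0.075

    def test_low_participation_burst_excluded(self):
        # second event on only 5 of 12 electrodes: 5/12 < 50% participation
        full = crafted_raster(
            n_bursts=1, period_s=10.0, burst_duration=0.3, duration=10.0,
            background_rate=0.0, first_burst=1.0, seed=2,
        )
        partial = crafted_raster(
            n_bursts=1, period_s=10.0, burst_duration=0.3, duration=10.0,
            background_rate=0.0, first_burst=5.0, participating=5, seed=3,
        )
        merged = SpikeRaster(
            [np.sort(np.concatenate([a, b])) for a, b in zip(full.spikes, partial.spikes)],
            10.0,
        )
        bursts = detect_bursts(merged)
        assert len(bursts) == 1
        assert abs(bursts[0].start - 1.0) <= 0.025

    def test_zero_activity_no_division_by_zero(self):
        raster = SpikeRaster([np.array([1.0])] + [np.empty(0)] * 11, 60.0)
        assert detect_bursts(raster) in ([], detect_bursts(raster))  # no crash


class TestDetectFragments:
    def _rate_from(self, counts):
        return NetworkRate(np.asarray(counts, float), 25.0, len(counts) * 0.025)

    def test_unimodal_burst_is_one_fragment(self):
        counts = np.zeros(100)
        counts[40:52] = [10, 30, 60, 90, 100, 95, 80, 60, 40, 20, 10, 5]
        rate = self._rate_from(counts)
        assert detect_fragments(NetworkBurst(1.0, 1.3), rate) == 1

    def test_bimodal_burst_is_two_fragments(self):
        counts = np.zeros(200)
        # two clear peaks near max with a deep valley between them
        counts[40:48] = [40, 80, 100, 80, 40, 20, 10, 5]
        counts[52:60] = [20, 50, 90, 95, 70, 30, 10, 5]
        rate = self._rate_from(counts)
        assert detect_fragments(NetworkBurst(1.0, 1.5), rate) == 2

    def test_subthreshold_second_peak_not_counted(self):
        counts = np.zeros(200)
        counts[40:48] = [40, 80, 100, 80, 40, 10, 4, 2]
        counts[52:60] = [2, 3, 5, 5, 4, 3, 2, 1]  # below max/16 after smoothing
        rate = self._rate_from(counts)
        assert detect_fragments(NetworkBurst(1.0, 1.5), rate) == 1


class TestIsiSeries:
    def test_regular_train_constant_series(self):
        raster = SpikeRaster([np.arange(0.0, 10.5, 1.0)] + [np.empty(0)] * 11, 11.0)
        s = isi_series(raster)
        vals = s[0][np.isfinite(s[0])]
        assert np.allclose(vals, 1.0)

    def test_piecewise_values_by_definition(self):
        raster = SpikeRaster([np.array([0.0, 1.0, 3.0])] + [np.empty(0)] * 11, 4.0)
        s = isi_series(raster)[0]
        t = (np.arange(len(s)) + 0.5) * 0.025
        assert np.allclose(s[(t > 0) & (t < 1.0)], 1.0)
        assert np.allclose(s[(t > 1.0) & (t < 3.0)][1:], 2.0)

    def test_identical_series_correlate_perfectly(self):
        rng = np.random.default_rng(4)
        train = np.sort(rng.uniform(0, 30, 100))
        raster = SpikeRaster([train, train.copy()] + [np.empty(0)] * 10, 30.0)
        s = isi_series(raster)
        both = np.isfinite(s[0]) & np.isfinite(s[1])
        cc = np.corrcoef(s[0][both], s[1][both])[0, 1]
        assert cc == pytest.approx(1.0)


class TestIsiDistance:
    def test_identical_trains_distance_zero(self):
        t = np.arange(0.0, 20.0, 0.5)
        assert isi_distance(t, t) == pytest.approx(0.0)

    def test_two_to_one_isi_ratio_gives_half(self):
        a = np.arange(0.0, 40.0, 0.5)   # ISI 0.5 s
        b = np.arange(0.0, 40.0, 1.0)   # ISI 1.0 s
        assert isi_distance(a, b) == pytest.approx(0.5, abs=1e-9)

    def test_equal_period_any_phase_zero_in_overlap(self):
        a = np.arange(0.0, 30.0, 1.0)
        b = np.arange(0.37, 30.0, 1.0)
        assert isi_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_oracle_on_irregular_trains(self):
        # fine-grid oracle evaluated independently of the implementation
        rng = np.random.default_rng(5)
        a = np.sort(rng.uniform(0, 20, 40))
        b = np.sort(rng.uniform(0, 20, 55))

        def oracle(a, b, dt=1e-4):
            lo, hi = max(a[0], b[0]), min(a[-1], b[-1])
            ts = np.arange(lo + dt, hi - dt, dt)
            def isi_at(st, t):
                i = np.searchsorted(st, t, side="right")
                i = np.clip(i, 1, len(st) - 1)
                return st[i] - st[i - 1]
            ia, ib = isi_at(a, ts), isi_at(b, ts)
            return np.mean(1.0 - np.minimum(ia, ib) / np.maximum(ia, ib))

        assert isi_distance(a, b) == pytest.approx(oracle(a, b), abs=0.02)

    def test_degenerate_train_rejected(self):
        with pytest.raises(ValueError):
            isi_distance(np.array([1.0]), np.arange(10.0))


class TestMac:
    def test_constant_rate_zero_by_convention(self):
        rate = NetworkRate(np.full(2400, 7.0), 25.0, 60.0)
        assert mac(rate) == 0.0

    def test_sinusoidal_rate_near_one(self):
        t = np.arange(2400) * 0.025
        rate = NetworkRate(50 + 40 * np.sin(2 * np.pi * t / 2.0), 25.0, 60.0)
        assert mac(rate) >= 0.95

    def test_white_noise_rate_low(self):
        rng = np.random.default_rng(6)
        rate = NetworkRate(rng.poisson(20, 2400).astype(float), 25.0, 60.0)
        assert mac(rate) < 0.2


class TestBinarizedCC:
    def test_identical_trains_mean_one_sd_zero(self):
        rng = np.random.default_rng(7)
        train = np.sort(rng.uniform(0, 60, 200))
        raster = SpikeRaster([train.copy() for _ in range(4)] + [np.empty(0)] * 8, 60.0)
        m, s = binarized_cc(raster)
        assert m == pytest.approx(1.0) and s == pytest.approx(0.0, abs=1e-12)

    def test_independent_poisson_near_zero(self):
        rng = np.random.default_rng(8)
        raster = SpikeRaster(
            [np.sort(rng.uniform(0, 600, rng.poisson(1200))) for _ in range(12)], 600.0
        )
        m, _ = binarized_cc(raster)
        n_bins = 600 / 0.025
        se = 1.0 / np.sqrt(n_bins)  # null sd of Pearson r per pair
        assert abs(m) < 3 * se

    def test_antiphase_groups_give_plus_minus_one(self):
        # group A fires in even 25 ms bins, group B in odd bins
        even = np.arange(0.0125, 10.0, 0.05)
        odd = even + 0.025
        raster = SpikeRaster([even, even.copy(), odd, odd.copy()] + [np.empty(0)] * 8, 10.0)
        m, s = binarized_cc(raster)
        # pairs: AA=1, BB=1, 4x AB=-1 -> mean = (2 - 4)/6
        assert m == pytest.approx((2 - 4) / 6, abs=1e-9)


class TestComputeFeatures:
    def test_empty_raster_conventions(self):
        fv = compute_features(_empty())
        for name in ("MFR", "NBR", "NBD", "PSIB", "n_FBs", "CV_IBI", "MAC"):
            assert getattr(fv, name) == 0.0

    def test_three_equally_spaced_bursts(self, bursty_raster):
        fv = compute_features(bursty_raster)
        assert fv.CV_IBI == pytest.approx(0.0, abs=0.02)
        assert fv.NBR == pytest.approx(3 / 60.0 * 60.0, rel=0.01)

    def test_all_spikes_inside_bursts_gives_psib_100(self):
        raster = crafted_raster(
            n_bursts=3, period_s=10.0, burst_duration=0.3, duration=60.0,
            background_rate=0.0, seed=9,
        )
        fv = compute_features(raster)
        assert fv.PSIB == pytest.approx(100.0)

    def test_all_features_finite_on_varied_rasters(self, midprior_sim):
        fv = compute_features(midprior_sim.raster)
        assert np.all(np.isfinite(fv.to_array(include_binarized=True)))

    def test_time_shift_invariance_within_one_bin(self, bursty_raster):
        fv0 = compute_features(bursty_raster).to_array()
        # shift by an exact bin multiple: binning is unchanged away from edges
        fv1 = compute_features(bursty_raster.shifted(0.025 * 8)).to_array()
        np.testing.assert_allclose(fv0, fv1, rtol=0.12, atol=0.02)

    def test_electrode_permutation_invariance(self, bursty_raster):
        rng = np.random.default_rng(10)
        perm = rng.permutation(bursty_raster.n_electrodes)
        fv0 = compute_features(bursty_raster).to_array(include_binarized=True)
        fv1 = compute_features(bursty_raster.permuted(perm)).to_array(include_binarized=True)
        np.testing.assert_allclose(fv0, fv1, rtol=1e-9, atol=1e-12)

    def test_simulated_and_measured_rasters_share_one_code_path(self):
        # the extractor accepts any SpikeRaster; the same function object
        # serves both sources (no special-casing by provenance)
        import mea_sbi

        assert mea_sbi.compute_features is compute_features
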