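"""Tests of the fragment-size distribution and breaks-per-genome estimator."""

import numpy as np
import pytest
from sklearn.base import clone

from rnmpgel import (
    BreakageEstimator,
    FragmentSizeDistribution,
    GelSimConfig,
    LaneProfile,
    MigrationCalibration,
    compare_lanes,
    estimate_breakage,
    estimate_mean_fragment_size,
    profile_to_size_distribution,
    render_lane,
    sample_fragments,
    smooth_profile,
    subtract_background,
)


def truncated_exp_mean(m: float, lo: float, hi: float) -> float:
    """Closed-form mean of Exponential(m) conditioned on [lo, hi]."""
    el, eh = np.exp(-lo / m), np.exp(-hi / m)
    return m + (lo * el - hi * eh) / (el - eh)


def spike_profile(distances, intensities, n=1000, dx=0.1, **flags):
    x = (np.arange(n) + 0.5) * dx
    y = np.zeros(n)
    for d, i in zip(np.atleast_1d(distances), np.atleast_1d(intensities)):
        y[int(d / dx)] += i
    return LaneProfile(
        distance_mm=x, intensity=y, background_subtracted=True, smoothed=True, **flags
    )


def exponential_bins(
    mean: float, lo: float, hi: float, b: float = -8.686, bin_width: float = 0.05
) -> FragmentSizeDistribution:
    """Bin weights proportional to the closed-form exponential count density
    on a fine distance grid spanning sizes [lo, hi]."""
    d_lo, d_hi = -abs(b) * np.log(hi), -abs(b) * np.log(lo)
    centers_mm = np.arange(d_lo, d_hi, bin_width) + bin_width / 2
    sizes = np.exp(-centers_mm / abs(b))
    # fragment counts per distance bin: f(s) * |ds/dd| * bin_width
    weights = np.exp(-sizes / mean) / mean * sizes / abs(b) * bin_width
    return FragmentSizeDistribution(
        bin_center_mm=centers_mm,
        bin_center_size=sizes,
        bin_intensity=weights * sizes,
        bin_count_weight=weights,
        truncation_range=(lo, hi),
        bin_width_mm=bin_width,
        excluded_mass=0.0,
        total_intensity=float((weights * sizes).sum()),
    )


@pytest.fixture
def wide_calibration():
    """Hull wide enough that an m=1000 exponential lane is untruncated."""
    return MigrationCalibration(
        a=110.0, b=-8.686, size_min=1.0, size_max=10**7, residual_rms=0.0, n_points=8
    )


class TestProfileToSizeDistribution:
    def test_delta_band_weight_is_intensity_over_size(self, true_calibration):
        prof = spike_profile(40.0, 500.0)
        dist = profile_to_size_distribution(prof, true_calibration)
        nz = np.flatnonzero(dist.bin_count_weight)
        assert nz.size == 1
        s = dist.bin_center_size[nz[0]]
        assert dist.bin_count_weight[nz[0]] == pytest.approx(500.0 / s)

    def test_equal_intensity_bands_weighted_inversely_to_size(self):
        """Two bands of equal integrated intensity at 2000 and 1000 nt have
        count weights 1:2 (intensity / size)."""
        # choose (a, b) so both bands sit exactly on 0.5 mm bin centres
        d2000, d1000 = 30.25, 36.25
        b = (d2000 - d1000) / np.log(2000.0 / 1000.0)
        a = d2000 - b * np.log(2000.0)
        cal = MigrationCalibration(
            a=a, b=b, size_min=200, size_max=50_000, residual_rms=0, n_points=2
        )
        prof = spike_profile([d2000, d1000], [300.0, 300.0])
        dist = profile_to_size_distribution(prof, cal)
        w = dist.bin_count_weight[np.flatnonzero(dist.bin_count_weight)]
        assert w[1] / w[0] == pytest.approx(2.0, rel=1e-6)

    def test_matches_exact_expectation_of_forward_model(self, true_calibration):
        """Count weights from a large simulated exponential lane match the
        expected per-bin weights computed by direct summation of the
        exponential pmf over integer sizes through the same migration map."""
        cfg = GelSimConfig(noise_sigma=0, baseline=0, band_sigma=0)
        m0, k = 2 * 10**9, 2 * 10**6
        lane = render_lane(sample_fragments(m0, k, seed=2), cfg).replace(
            background_subtracted=True, smoothed=True
        )
        dist = profile_to_size_distribution(lane, true_calibration)
        m = m0 / (k + 1)

        sizes = np.arange(1, 200_000, dtype=float)
        pmf = np.exp(-sizes / m)
        pmf /= pmf.sum()
        d = cfg.migration_a + cfg.migration_b * np.log(sizes)
        ok = (d >= 0) & (d < cfg.lane_length)
        px = (d[ok] * cfg.pixels_per_mm).astype(int)
        exp_mass = np.bincount(px, weights=sizes[ok] * pmf[ok] * (k + 1), minlength=1000)
        exp_mass_bin = exp_mass.reshape(-1, 5).sum(axis=1)
        centers = 0.25 + 0.5 * np.arange(200)
        s_c = np.exp((centers - true_calibration.a) / true_calibration.b)
        inr = (s_c >= true_calibration.size_min) & (s_c <= true_calibration.size_max)
        oracle = exp_mass_bin[inr] / s_c[inr]
        mask = oracle > 0.3 * oracle.max()
        assert np.abs(dist.bin_count_weight[mask] / oracle[mask] - 1).max() < 0.03

    def test_matches_change_of_variables_density(self, true_calibration):
        """Away from the integer-size lattice's aliasing regime (sizes well
        above the pixel spacing), weights match the continuous density
        f(s) * |ds/dd| evaluated at bin centres within 3%."""
        cfg = GelSimConfig(noise_sigma=0, baseline=0, band_sigma=0)
        m0, k = 2 * 10**9, 2 * 10**6
        lane = render_lane(sample_fragments(m0, k, seed=2), cfg).replace(
            background_subtracted=True, smoothed=True
        )
        dist = profile_to_size_distribution(lane, true_calibration)
        m = m0 / (k + 1)
        s = dist.bin_center_size
        theory = np.exp(-s / m) / m * s / abs(cfg.migration_b) * (k + 1) * dist.bin_width_mm
        mask = (theory > 0.3 * theory.max()) & (s >= 500.0)
        assert np.abs(dist.bin_count_weight[mask] / theory[mask] - 1).max() < 0.03

    def test_bookkeeping_identity(self, true_calibration):
        cfg = GelSimConfig(seed=3)
        lane = subtract_background(
            render_lane(sample_fragments(10**7, 5000, seed=3), cfg, lane_id="s")
        )
        lane = smooth_profile(lane)
        dist = profile_to_size_distribution(lane, true_calibration)
        assert dist.excluded_mass + dist.bin_intensity.sum() == pytest.approx(
            lane.total_intensity, rel=1e-12
        )
        assert (dist.bin_count_weight * dist.bin_center_size).sum() == pytest.approx(
            dist.bin_intensity.sum(), rel=1e-12
        )

    def test_empty_distribution_is_an_error(self):
        cal = MigrationCalibration(
            a=110.0, b=-8.686, size_min=10**6, size_max=10**7, residual_rms=0, n_points=2
        )
        prof = spike_profile(60.0, 100.0)  # maps far below the hull
        with pytest.raises(ValueError, match="empty distribution"):
            profile_to_size_distribution(prof, cal)


class TestEstimateMeanFragmentSize:
    def test_single_bin_returns_its_size(self, true_calibration):
        prof = spike_profile(40.0, 123.0)
        dist = profile_to_size_distribution(prof, true_calibration)
        s = dist.bin_center_size[np.flatnonzero(dist.bin_count_weight)[0]]
        assert estimate_mean_fragment_size(dist, "weighted-mean") == pytest.approx(s)

    @pytest.mark.parametrize("method", ["weighted-mean", "truncated-exponential-mle"])
    def test_untruncated_closed_form_bins_recover_mean(self, method):
        dist = exponential_bins(mean=1000.0, lo=1.0, hi=50_000.0)
        assert estimate_mean_fragment_size(dist, method) == pytest.approx(1000.0, rel=1e-3)

    def test_truncated_bins_mle_corrects_weighted_mean_bias(self):
        """On a [200, 5000] truncation of Exponential(1000), the weighted mean
        equals the closed-form truncated mean (biased high), while the
        truncated MLE recovers the underlying 1000 nt within 2%."""
        dist = exponential_bins(mean=1000.0, lo=200.0, hi=5000.0)
        wm = estimate_mean_fragment_size(dist, "weighted-mean")
        assert wm == pytest.approx(truncated_exp_mean(1000.0, 200.0, 5000.0), rel=5e-3)
        mle = estimate_mean_fragment_size(dist, "truncated-exponential-mle")
        assert mle == pytest.approx(1000.0, rel=0.02)

    def test_zero_weight_rejected(self):
        dist = exponential_bins(mean=1000.0, lo=200.0, hi=5000.0)
        empty = FragmentSizeDistribution(
            bin_center_mm=dist.bin_center_mm,
            bin_center_size=dist.bin_center_size,
            bin_intensity=np.zeros_like(dist.bin_intensity),
            bin_count_weight=np.zeros_like(dist.bin_count_weight),
            truncation_range=dist.truncation_range,
            bin_width_mm=dist.bin_width_mm,
            excluded_mass=0.0,
            total_intensity=0.0,
        )
        with pytest.raises(ValueError):
            estimate_mean_fragment_size(empty, "weighted-mean")

    def test_unknown_method_rejected(self):
        dist = exponential_bins(mean=1000.0, lo=200.0, hi=5000.0)
        with pytest.raises(ValueError):
            estimate_mean_fragment_size(dist, "harmonic")


class TestEstimateBreakage:
    def test_delta_band_gives_m0_over_s(self, true_calibration):
        prof = spike_profile(40.0, 500.0)
        dist = profile_to_size_distribution(prof, true_calibration)
        s = dist.bin_center_size[np.flatnonzero(dist.bin_count_weight)[0]]
        est = estimate_breakage(prof, true_calibration, genome_size=100 * s)
        assert est.breaks_per_genome == pytest.approx(100.0)

    def test_end_to_end_recovery_within_15_percent(self, true_calibration):
        """Simulate m0=1e7 with 5000 breaks at default noise, run the cleaning
        and estimation chain: recovered breaks within [4250, 5750]."""
        cfg = GelSimConfig(seed=21)
        lane = smooth_profile(
            subtract_background(render_lane(sample_fragments(10**7, 5000, seed=21), cfg, lane_id="s"))
        )
        est = estimate_breakage(
            lane, true_calibration, genome_size=10**7, method="truncated-exponential-mle"
        )
        assert 4250 <= est.breaks_per_genome <= 5750

    def test_scale_invariance(self, true_calibration):
        cfg = GelSimConfig(seed=4)
        lane = smooth_profile(
            subtract_background(render_lane(sample_fragments(10**7, 3000, seed=4), cfg, lane_id="s"))
        )
        base = estimate_breakage(lane, true_calibration, genome_size=10**7)
        scaled_lane = lane.replace(intensity=lane.intensity * 137.5)
        scaled = estimate_breakage(scaled_lane, true_calibration, genome_size=10**7)
        assert scaled.breaks_per_genome == pytest.approx(base.breaks_per_genome, rel=1e-12)

    def test_monotone_in_true_break_count(self, true_calibration):
        """Across lanes differing only in break count, estimates are strictly
        increasing (perfect rank ordering over 5 levels)."""
        levels = [500, 1000, 2000, 5000, 10_000]
        estimates = []
        for k in levels:
            cfg = GelSimConfig(seed=100 + k)
            lane = smooth_profile(
                subtract_background(
                    render_lane(sample_fragments(10**7, k, seed=k), cfg, lane_id="s")
                )
            )
            estimates.append(
                estimate_breakage(
                    lane, true_calibration, genome_size=10**7,
                    method="truncated-exponential-mle",
                ).breaks_per_genome
            )
        assert all(a < b for a, b in zip(estimates, estimates[1:]))

    def test_weighted_mean_matches_fragment_sample_mean(self, wide_calibration):
        """Noiseless, effectively untruncated, finely binned lane: the
        weighted-mean estimate matches the generating fragments' sample mean
        within 1%."""
        cfg = GelSimConfig(noise_sigma=0, baseline=0, band_sigma=0)
        fs = sample_fragments(10**7, 10**4, seed=6)
        lane = render_lane(fs, cfg).replace(background_subtracted=True, smoothed=True)
        est = estimate_breakage(
            lane, wide_calibration, genome_size=10**7, bin_width_mm=0.1
        )
        assert est.mean_fragment_size_m == pytest.approx(fs.mean_length, rel=0.01)

    def test_bootstrap_seeds_move_ci_not_point(self, true_calibration):
        cfg = GelSimConfig(seed=8)
        lane = smooth_profile(
            subtract_background(render_lane(sample_fragments(10**7, 4000, seed=8), cfg, lane_id="s"))
        )
        e1 = estimate_breakage(lane, true_calibration, 10**7, n_boot=80, seed=1)
        e2 = estimate_breakage(lane, true_calibration, 10**7, n_boot=80, seed=2)
        assert e1.breaks_per_genome == e2.breaks_per_genome
        assert (e1.ci_low, e1.ci_high) != (e2.ci_low, e2.ci_high)
        assert e1.ci_low <= e1.breaks_per_genome <= e1.ci_high
        assert max(e1.ci_low, e2.ci_low) < min(e1.ci_high, e2.ci_high)  # overlap

    def test_heavy_truncation_warns(self):
        cal = MigrationCalibration(
            a=110.0, b=-8.686, size_min=900.0, size_max=1100.0, residual_rms=0, n_points=2
        )
        cfg = GelSimConfig(noise_sigma=0, baseline=0, band_sigma=0)
        lane = render_lane(sample_fragments(10**7, 5000, seed=5), cfg).replace(
            background_subtracted=True, smoothed=True
        )
        with pytest.warns(UserWarning, match="outside the calibrated"):
            estimate_breakage(lane, cal, 10**7)

    def test_sklearn_estimator_protocol(self, true_calibration):
        est = BreakageEstimator(genome_size=10**7, method="weighted-mean")
        params = est.get_params()
        assert params["genome_size"] == 10**7
        fresh = clone(est).set_params(bin_width_mm=0.25)
        prof = spike_profile(40.0, 500.0)
        fresh.fit(prof, true_calibration)
        assert fresh.breaks_per_genome_ == pytest.approx(
            10**7 / fresh.mean_fragment_size_
        )
        assert fresh.distribution_.bin_width_mm == 0.25
        with pytest.raises(ValueError, match="genome_size"):
            BreakageEstimator().fit(prof, true_calibration)


class TestCompareLanes:
    def _estimate_for_mean(self, m, m0=10**7):
        from rnmpgel.estimator import BreakageEstimate

        return BreakageEstimate(
            mean_fragment_size_m=m, genome_size_m0=m0,
            breaks_per_genome=m0 / m, method="weighted-mean", lane_id=f"m{m:g}",
        )

    def test_identical_estimates_ratio_one(self):
        e = self._estimate_for_mean(2e6)
        table = compare_lanes([e, e])
        assert (table["ratio_to_control"] == 1.0).all()

    def test_halved_mean_doubles_breakage_ratio(self):
        table = compare_lanes([self._estimate_for_mean(2e6), self._estimate_for_mean(1e6)])
        assert table.sort_values("m_nt")["ratio_to_control"].iloc[0] == pytest.approx(2.0)
        assert (table["breaks_per_genome"].diff().dropna() > 0).all()  # sorted

    def test_mixed_genome_size_rejected(self):
        with pytest.raises(ValueError, match="mixed genome sizes"):
            compare_lanes(
                [self._estimate_for_mean(1e6, m0=10**7), self._estimate_for_mean(1e6, m0=2 * 10**7)]
            )

    def test_control_vs_triple_breakage_ratio(self, true_calibration):
        """Lanes with true break densities lambda and 3*lambda give a reported
        ratio within [2.4, 3.6] through the full estimation chain."""
        ests = []
        for k, seed in ((2000, 31), (6000, 32)):
            cfg = GelSimConfig(seed=seed)
            lane = smooth_profile(
                subtract_background(
                    render_lane(sample_fragments(10**7, k, seed=seed), cfg, lane_id=f"k{k}")
                )
            )
            ests.append(
                estimate_breakage(
                    lane, true_calibration, 10**7, method="truncated-exponential-mle"
                )
            )
        ratio = ests[1].breaks_per_genome / ests[0].breaks_per_genome
        assert 2.4 <= ratio <= 3.6
        table = compare_lanes(ests)
        assert table["ratio_to_control"].max() == pytest.approx(ratio)
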