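"""Tracking, MSD, condensation-time and breakage statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetherquant.dynamics import (
    Track,
    breakage_fraction,
    build_kymograph,
    condensation_stat,
    detect_breakage,
    detect_condensation_time,
    msd_analysis,
    time_averaged_msd,
    track_foci_greedy,
)
from tetherquant.synthetic import (
    NoiseModel,
    SimConfig,
    brownian_tracks,
    generate_kymograph,
)

from conftest import make_movie


def _track(positions, dt=0.3):
    positions = np.asarray(positions, dtype=float)
    return Track(
        track_id=0,
        frames=np.arange(len(positions)),
        positions_um=positions,
        intensities=np.ones(len(positions)),
        frame_interval_s=dt,
    )


class TestKymographExtraction:
    def test_static_ridge_gives_identical_columns(self, noiseless):
        movie, _ = make_movie(seed=0, n_frames=8, sigma_nm=0.0, noise=noiseless)
        kymo = build_kymograph(movie, channel="dna", tether_id=0)
        for f in range(1, 8):
            np.testing.assert_allclose(kymo.data[:, f], kymo.data[:, 0])

    def test_drifting_focus_ridge_slope_matches_manifest(self, noiseless):
        cfg = SimConfig(rng_seed=0, n_frames=40, noise=noiseless)
        v = 0.1
        kymo, truth = generate_kymograph(cfg, 1, [0.0], drift_um_s=v, length_um=10.0)
        ridge_px = kymo.data.argmax(axis=0)
        slope_um_s = np.polyfit(np.arange(40) * 0.3, ridge_px * 0.1, 1)[0]
        assert slope_um_s == pytest.approx(v, rel=0.05)

    def test_empty_movie_gives_background_kymograph(self):
        movie, _ = make_movie(
            seed=0, n_frames=5, sigma_nm=0.0,
            noise=NoiseModel(background_mean=9.0, background_sd=0.0, photon_gain=0.0),
        )
        movie.channels["dna"] = np.full_like(movie.channels["dna"], 9.0)
        kymo = build_kymograph(movie, channel="dna")
        np.testing.assert_allclose(kymo.data, 9.0)


class TestGreedyTracking:
    def test_single_stationary_focus(self, snr10_noise):
        cfg = SimConfig(rng_seed=1, n_frames=50, noise=snr10_noise)
        kymo, truth = generate_kymograph(cfg, 1, [0.0], length_um=8.0)
        tracks = track_foci_greedy(kymo)
        assert len(tracks) == 1
        assert len(tracks[0]) == 50
        true_pos = truth.foci[0]["positions_um"][0]
        err = tracks[0].positions_um - true_pos
        assert np.abs(err).max() < 0.1  # within one pixel
        assert err.std() < 0.05

    def test_two_separated_foci_no_identity_swap(self, snr10_noise):
        cfg = SimConfig(rng_seed=2, n_frames=60, noise=snr10_noise)
        kymo, _ = generate_kymograph(cfg, 2, [0.0, 0.0], length_um=9.0)
        tracks = track_foci_greedy(kymo)
        assert len(tracks) == 2
        for tr in tracks:
            assert np.ptp(tr.positions_um) < 0.1

    def test_brownian_population_recovered(self, snr10_noise):
        """Well-separated diffusing foci: at least 90% of manifest positions
        matched within one PSF width."""
        cfg = SimConfig(rng_seed=3, n_frames=200, noise=snr10_noise)
        kymo, truth = generate_kymograph(cfg, 5, [0.002] * 5, length_um=20.0)
        tracks = track_foci_greedy(kymo)
        psf_um = 0.13
        matched = 0
        total = sum(len(f["positions_um"]) for f in truth.foci)
        for focus in truth.foci:
            pos = np.array(focus["positions_um"])
            best = None
            for tr in tracks:
                err = np.abs(pos[tr.frames] - tr.positions_um)
                score = (err < psf_um).sum()
                if best is None or score > best:
                    best = score
            matched += best or 0
        assert matched / total >= 0.9

    def test_empty_kymograph_allows_no_tracks(self, noiseless):
        cfg = SimConfig(rng_seed=0, n_frames=20, noise=NoiseModel(background_mean=5.0))
        kymo, _ = generate_kymograph(cfg, 1, [0.0], length_um=8.0, focus_intensity=0.0)
        assert track_foci_greedy(kymo, detect_threshold=50.0) == []


class TestMSD:
    def test_pure_drift_msd_is_quadratic_and_fit_matches_oracle(self):
        v, dt = 0.2, 0.3
        tr = _track(v * np.arange(100) * dt)
        res = msd_analysis(tr)
        taus = res.lag_times_s
        np.testing.assert_allclose(res.msd_um2, (v * taus) ** 2, rtol=1e-8)
        # independent linear fit of the quadratic over the same lags
        sel = (np.arange(1, len(taus) + 1) >= 2) & (np.arange(1, len(taus) + 1) <= 10)
        slope, icpt = np.polyfit(taus[sel], ((v * taus) ** 2)[sel], 1)
        resid = ((v * taus) ** 2)[sel] - (slope * taus[sel] + icpt)
        ss = ((v * taus) ** 2)[sel]
        r2 = 1 - (resid**2).sum() / ((ss - ss.mean()) ** 2).sum()
        assert res.r_squared == pytest.approx(r2, abs=1e-9)
        assert res.accepted == (r2 > 0.8)

    def test_constant_position_rejected(self):
        res = msd_analysis(_track(np.full(50, 3.0)))
        assert res.D_um2_s == pytest.approx(0.0, abs=1e-12)
        assert not res.accepted

    def test_short_track_rejected(self):
        with pytest.raises(ValueError, match="smoothing window"):
            msd_analysis(_track(np.arange(5.0)))

    def test_brownian_diffusion_recovery(self):
        """200 tracks at D = 0.01 um^2/s, 0.3 s frames, 300 frames, standard
        smoothing and fit settings: median D within 15%."""
        pos = brownian_tracks(200, 300, 0.01, 0.3, rng_seed=10)
        Ds = [msd_analysis(_track(pos[i])).D_um2_s for i in range(200)]
        assert np.median(Ds) == pytest.approx(0.01, rel=0.15)

    def test_acceptance_fraction_drops_for_confined_tracks(self):
        """Confined motion gives a saturating MSD curve that fails the
        linear-fit R^2 filter more often than free diffusion -- the filter
        excludes immobile/confined condensates."""
        rng = np.random.default_rng(11)
        free = brownian_tracks(60, 300, 0.01, 0.3, rng_seed=12)
        step = rng.normal(0, 0.05, (60, 300))
        confined = np.empty_like(step)
        confined[:, 0] = 0.0
        for t in range(1, 300):  # strong mean reversion: ~one-frame memory
            confined[:, t] = 0.2 * confined[:, t - 1] + step[:, t]
        frac_free = np.mean([msd_analysis(_track(p)).accepted for p in free])
        frac_conf = np.mean([msd_analysis(_track(p)).accepted for p in confined])
        assert frac_conf < frac_free

    def test_time_averaged_msd_matches_bruteforce(self):
        x = np.random.default_rng(3).normal(0, 1, 40).cumsum()
        msd = time_averaged_msd(x, 5)
        brute = [np.mean([(x[i + k] - x[i]) ** 2 for i in range(40 - k)]) for k in range(1, 6)]
        np.testing.assert_allclose(msd, brute)


class TestCondensationTime:
    def test_detection_close_to_manifest_truth(self, snr10_noise, condensing_spec):
        errors = []
        for seed in range(6):
            movie, truth = make_movie(
                seed=seed, n_frames=150, noise=snr10_noise, condensate=condensing_spec
            )
            t_det = detect_condensation_time(movie, 0, tensed_floor_nm=50.0)
            errors.append(abs(t_det - truth.tethers[0]["condensation_time_s"]) / 0.3)
        assert np.median(errors) <= 2.0

    def test_no_condensate_censored(self, snr10_noise):
        movie, _ = make_movie(seed=1, n_frames=60, noise=snr10_noise)
        assert detect_condensation_time(movie, 0) is None

    def test_instant_condensation_detected_at_zero(self, snr10_noise):
        from tetherquant.synthetic import CondensateSpec

        movie, truth = make_movie(
            seed=2,
            n_frames=60,
            noise=snr10_noise,
            condensate=CondensateSpec(
                forced_nucleation_time_s=0.0, collapse_time_s=0.0, tensed_floor_nm=50.0
            ),
        )
        assert truth.tethers[0]["condensation_time_s"] == 0.0
        assert detect_condensation_time(movie, 0, tensed_floor_nm=50.0) == 0.0


class TestCondensationStat:
    def test_four_point_example(self):
        st_ = condensation_stat([10.0, 20.0, 30.0, 40.0])
        assert st_.t25_s == pytest.approx(17.5)
        assert st_.t75_s == pytest.approx(32.5)
        assert st_.t_condense_s == pytest.approx(15.0)

    def test_degenerate_all_equal(self):
        assert condensation_stat([5.0] * 6).t_condense_s == 0.0

    def test_exponential_sample_matches_analytic_iqr(self):
        """Exponential(mean 30 s): interquartile spread is 30 ln 3."""
        rng = np.random.default_rng(0)
        times = rng.exponential(30.0, size=200)
        st_ = condensation_stat(times)
        expect = 30.0 * np.log(3.0)
        # Monte-Carlo CI: IQR estimator SD ~ mean * 1.1 / sqrt(n)
        assert abs(st_.t_condense_s - expect) < 3 * 30.0 * 1.1 / np.sqrt(200)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(0, 1e4), min_size=4, max_size=50))
    def test_matches_bruteforce_sorted_interpolation(self, times):
        st_ = condensation_stat(times)
        xs = np.sort(np.asarray(times, dtype=float))

        def q(p):
            h = (len(xs) - 1) * p
            lo = int(np.floor(h))
            hi = min(lo + 1, len(xs) - 1)
            return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

        assert st_.t_condense_s == pytest.approx(q(0.75) - q(0.25), abs=1e-9)

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            condensation_stat([1.0, 2.0, 3.0])


class TestBreakage:
    def test_forced_breakage_detected_close_to_truth(self, snr10_noise, condensing_spec):
        for seed in range(3):
            movie, truth = make_movie(
                seed=100 + seed, n_frames=130, noise=snr10_noise,
                condensate=condensing_spec, nick_fragility=1.0,
            )
            t = detect_breakage(movie, 0)
            assert t is not None
            assert abs(t / 0.3 - truth.tethers[0]["breakage_frame"]) <= 2

    def test_intact_movie_yields_none(self, snr10_noise):
        movie, _ = make_movie(seed=5, n_frames=50, noise=snr10_noise)
        assert detect_breakage(movie, 0) is None

    def test_single_tether_not_evaluated(self, snr10_noise):
        from tetherquant.synthetic import SimConfig, TetherSpec, generate_tether_movie

        cfg = SimConfig(rng_seed=0, n_frames=20, noise=snr10_noise)
        spec = TetherSpec(
            tether_type="single", anchor_a=(24.0, 20.0), anchor_b=None,
            end_to_end_um=10.0, envelope_sigma_nm=200.0,
        )
        movie, _ = generate_tether_movie(cfg, [spec], None, channels=("dna",))
        assert detect_breakage(movie, 0) is None


class TestBreakageFraction:
    def test_all_broken(self):
        res = breakage_fraction({"g": [(10, 10), (8, 8), (5, 5)]})
        assert res.group_means["g"] == 1.0
        assert res.group_sds["g"] == 0.0

    def test_arithmetic_example(self):
        res = breakage_fraction({"g": [(2, 10), (3, 10), (4, 10)]})
        assert res.group_means["g"] == pytest.approx(0.30)
        assert res.group_sds["g"] == pytest.approx(0.10)

    def test_low_field_count_flagged(self):
        res = breakage_fraction({"g": [(1, 10), (2, 10)]})
        assert res.low_field_warning

    def test_simulated_group_contrast_significant(self):
        """p_break 0.4 vs 0.05, five fields of 100 molecules: the t test
        separates the groups in nearly every random draw."""
        rng = np.random.default_rng(42)
        n_sig = 0
        for _ in range(20):
            a = [(int(rng.binomial(100, 0.4)), 100) for _ in range(5)]
            b = [(int(rng.binomial(100, 0.05)), 100) for _ in range(5)]
            res = breakage_fraction({"hi": a, "lo": b}, compare=("hi", "lo"))
            n_sig += res.ttest.pvalue < 0.05
        assert n_sig >= 19
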