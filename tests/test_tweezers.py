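"""Worm-like-chain mechanics and force-trace analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tetherquant.core import ForceTrace
from tetherquant.synthetic import CondensateSpec, SimConfig, generate_force_trace
from tetherquant.tweezers import (
    WLCParams,
    analyze_clamp,
    compare_force_trajectories,
    detect_plateau,
    detect_transitions,
    wlc_extension,
    wlc_extension_fraction,
    wlc_force,
)


def _trace(force, dt=0.3, mode="passive", sep=None):
    n = len(force)
    return ForceTrace(
        time_s=np.arange(n) * dt,
        force_pN=np.asarray(force, dtype=float),
        trap_separation_um=np.full(n, 12.0) if sep is None else np.asarray(sep, float),
        extension_um=np.full(n, 11.9),
        reeled_bp=np.zeros(n),
        mode=mode,
    )


class TestWLC:
    def test_zero_extension_zero_force(self):
        assert wlc_force(0.0) == 0.0

    def test_half_extension_closed_form(self):
        # (4.114/50) * (1/(4*0.25) - 0.25 + 0.5) = 0.08228 * 1.25 = 0.10285
        assert wlc_force(0.5) == pytest.approx(0.1028, abs=2e-4)

    def test_strictly_increasing(self):
        x = np.linspace(0, 0.99, 200)
        f = wlc_force(x, WLCParams(overstretch_force_pN=1e9))
        assert np.all(np.diff(f) > 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            wlc_force(1.0)
        with pytest.raises(ValueError):
            wlc_force(-0.1)

    def test_low_force_entropic_spring_limit(self):
        """dF/dx -> (3/2) kBT/Lp per unit fractional extension as x -> 0."""
        p = WLCParams()
        eps = 1e-6
        slope = (wlc_force(eps, p) - wlc_force(0.0, p)) / eps
        assert slope == pytest.approx(1.5 * p.kBT_pN_nm / p.persistence_length_nm, rel=1e-3)

    def test_overstretch_cap(self):
        p = WLCParams()
        assert wlc_force(0.999999, p) == p.overstretch_force_pN

    def test_inverse_at_zero(self):
        assert wlc_extension_fraction(0.0) == 0.0

    @pytest.mark.parametrize("x", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_inverse_roundtrip(self, x):
        p = WLCParams()
        assert wlc_extension_fraction(wlc_force(x, p), p) == pytest.approx(x, abs=1e-5)

    def test_inverse_undefined_at_cap(self):
        p = WLCParams()
        with pytest.raises(ValueError, match="overstretching"):
            wlc_extension_fraction(p.overstretch_force_pN, p)

    def test_extension_in_um(self):
        p = WLCParams(contour_length_um=10.0)
        f = wlc_force(0.6, p)
        assert wlc_extension(f, p) == pytest.approx(6.0, rel=1e-5)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.01, 0.95))
    def test_inverse_property(self, x):
        p = WLCParams()
        assert wlc_extension_fraction(wlc_force(x, p), p) == pytest.approx(x, abs=1e-5)


class TestPlateau:
    def test_constant_trace(self):
        res = detect_plateau(_trace(np.full(100, 7.0)))
        assert res.plateau_force_pN == pytest.approx(7.0)
        assert res.onset_time_s == 0.0
        assert not res.censored

    def test_linear_ramp_censored(self):
        res = detect_plateau(_trace(np.linspace(0, 30, 200)))
        assert res.censored

    @pytest.mark.parametrize("stall", [1.0, 3.0, 7.0])
    def test_passive_simulation_plateaus_at_stall(self, stall):
        cfg = SimConfig(rng_seed=2, n_frames=600)
        cond = CondensateSpec(stall_force_pN=stall, reel_in_rate_bp_s=600.0)
        tr, _ = generate_force_trace(cfg, "passive", None, cond, {"initial_force_pN": 0.3})
        res = detect_plateau(tr)
        assert not res.censored
        assert res.plateau_force_pN == pytest.approx(stall, rel=0.05)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="two windows"):
            detect_plateau(_trace(np.ones(5)))


class TestClamp:
    def test_clamp_at_stall_no_contraction(self):
        cfg = SimConfig(rng_seed=3, n_frames=300)
        cond = CondensateSpec(stall_force_pN=7.0, reel_in_rate_bp_s=600.0)
        tr, _ = generate_force_trace(cfg, "clamp", None, cond, {"clamp_force_pN": 10.0})
        res = analyze_clamp(tr)
        assert abs(res.contraction_velocity_um_s) < 1e-6
        assert res.total_contraction_um == pytest.approx(0.0, abs=1e-9)

    def test_low_clamp_velocity_matches_model_arithmetic(self):
        """v = reel_rate * (1 - F/stall) * 0.34 nm/bp * (x/Lc at F)."""
        cfg = SimConfig(rng_seed=4, n_frames=300)
        rate, stall, fc = 600.0, 7.0, 0.5
        cond = CondensateSpec(stall_force_pN=stall, reel_in_rate_bp_s=rate)
        tr, _ = generate_force_trace(cfg, "clamp", None, cond, {"clamp_force_pN": fc})
        res = analyze_clamp(tr)
        expect = rate * (1 - fc / stall) * 0.34e-3 * wlc_extension_fraction(fc)
        assert res.contraction_velocity_um_s == pytest.approx(expect, rel=0.02)

    def test_wrong_mode_and_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="clamp"):
            analyze_clamp(_trace(np.ones(10), mode="passive"))
        with pytest.raises(ValueError, match="too short"):
            analyze_clamp(_trace(np.ones(2), mode="clamp"))


class TestTransitions:
    def test_pure_wlc_curve_no_events(self):
        cfg = SimConfig(rng_seed=5, n_frames=200, frame_interval_s=0.1)
        tr, _ = generate_force_trace(
            cfg, "pulling", None, CondensateSpec(),
            {"pull_speed_um_s": 0.1, "force_noise_sd_pN": 0.0},
        )
        assert detect_transitions(tr, min_jump_pN=1.0) == []

    def test_three_dissolution_jumps_recovered(self):
        cfg = SimConfig(rng_seed=6, n_frames=500, frame_interval_s=0.1)
        tr, truth = generate_force_trace(
            cfg, "pulling", None, CondensateSpec(),
            {
                "pull_speed_um_s": 0.1,
                "sequestered_bp": 9000,
                "dissolution_forces_pN": [12.0, 20.0, 30.0],
                "jump_bp": 1500,
            },
        )
        events = detect_transitions(tr, min_jump_pN=1.0)
        assert len(events) == 3
        for ev, man in zip(events, truth.trace["dissolution_events"]):
            assert ev.contour_jump_um == pytest.approx(man["released_um"], rel=0.1)

    def test_jump_below_threshold_not_reported(self):
        cfg = SimConfig(rng_seed=7, n_frames=400, frame_interval_s=0.1)
        tr, _ = generate_force_trace(
            cfg, "pulling", None, CondensateSpec(),
            {
                "pull_speed_um_s": 0.1,
                "sequestered_bp": 300,
                "dissolution_forces_pN": [15.0],
                "jump_bp": 300,
                "force_noise_sd_pN": 0.0,
            },
        )
        big = detect_transitions(tr, min_jump_pN=50.0)
        assert big == []

    def test_wrong_mode_rejected(self):
        with pytest.raises(ValueError, match="pulling"):
            detect_transitions(_trace(np.ones(10), mode="clamp"))


class TestTrajectoryComparison:
    def test_identical_groups_t_zero(self):
        tr = [_trace(np.full(50, 5.0)) for _ in range(3)]
        res = compare_force_trajectories({"a": tr, "b": [t for t in tr]})
        assert res.endpoint_ttest.statistic == 0.0

    def test_bare_vs_sequestration_contrast(self):
        """Condensing tethers plateau at the stall force while pinned
        (sequestration-only, zero reel-in) condensates generate none."""
        bare, seq = [], []
        for seed in range(3):
            cfg = SimConfig(rng_seed=seed, n_frames=500)
            tr_b, _ = generate_force_trace(
                cfg, "passive", None,
                CondensateSpec(stall_force_pN=7.0, reel_in_rate_bp_s=600.0),
                {"initial_force_pN": 0.3},
            )
            tr_s, _ = generate_force_trace(
                cfg, "passive", None,
                CondensateSpec(stall_force_pN=7.0, reel_in_rate_bp_s=0.0),
                {"initial_force_pN": 0.3},
            )
            bare.append(tr_b)
            seq.append(tr_s)
        res = compare_force_trajectories({"condensing": bare, "pinned": seq})
        diff = res.endpoint_forces["condensing"].mean() - res.endpoint_forces["pinned"].mean()
        assert diff == pytest.approx(7.0 - 0.3, abs=0.5)
        assert res.endpoint_ttest.pvalue < 0.01

    def test_resampling_matches_prealigned(self):
        t1 = _trace(np.linspace(0, 5, 100), dt=0.3)
        t2 = _trace(np.linspace(0, 5, 100), dt=0.3)
        res = compare_force_trajectories({"a": [t1, t2], "b": [t1, t2]}, n_grid=100)
        np.testing.assert_allclose(res.group_means["a"], res.group_means["b"])

    def test_single_member_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_force_trajectories({"a": [_trace(np.ones(10))], "b": [_trace(np.ones(10))] * 2})


class TestPullingGeometry:
    def test_condensate_curve_left_of_bare_wlc(self):
        """At every force below the first dissolution, a sequestering tether
        is shorter than bare DNA (contour hidden in the condensate)."""
        cfg = SimConfig(rng_seed=8, n_frames=400, frame_interval_s=0.1)
        kwargs = {"pull_speed_um_s": 0.1, "force_noise_sd_pN": 0.0}
        bare, _ = generate_force_trace(cfg, "pulling", None, CondensateSpec(), dict(kwargs))
        cond, _ = generate_force_trace(
            cfg, "pulling", None, CondensateSpec(),
            dict(kwargs) | {"sequestered_bp": 6000, "start_separation_um": 9.0},
        )
        grid = np.linspace(1.0, 40.0, 30)
        ext_bare = np.interp(grid, bare.force_pN, bare.extension_um)
        ext_cond = np.interp(grid, cond.force_pN, cond.extension_um)
        assert np.all(ext_cond < ext_bare)
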