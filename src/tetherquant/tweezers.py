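"""Worm-like-chain mechanics and dual-trap force-trace analysis.

The elasticity model is the Marko-Siggia interpolation formula

    F(x) = (kBT / Lp) * [ 1 / (4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

with a hard cap at the overstretching plateau force (~65 pN for B-DNA).
Analyses cover the three dual-trap operating modes: plateau detection on
passive-mode traces (condensation force rising to a stall), contraction
velocity under a force clamp, and dissolution transitions on pulling curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as _sps

from .core import KBT_PN_NM, LAMBDA_CONTOUR_UM, ForceTrace
from .stats import TTestResult, two_sample_t


@dataclass
class WLCParams:
    """Worm-like-chain parameters for double-stranded DNA."""

    persistence_length_nm: float = 50.0
    contour_length_um: float = LAMBDA_CONTOUR_UM
    kBT_pN_nm: float = KBT_PN_NM
    overstretch_force_pN: float = 65.0

    def __post_init__(self) -> None:
        if min(self.persistence_length_nm, self.contour_length_um, self.kBT_pN_nm) <= 0:
            raise ValueError("Lp, Lc and kBT must all be positive")


def wlc_force(extension_fraction, params: WLCParams | None = None):
    """Marko-Siggia force (pN) at fractional extension x/Lc in [0, 1).

    Values are capped at ``overstretch_force_pN`` to emulate the
    overstretching plateau.  Accepts scalars or arrays.
    """
    params = params or WLCParams()
    x = np.asarray(extension_fraction, dtype=float)
    if np.any(x < 0) or np.any(x >= 1):
        raise ValueError("extension fraction must satisfy 0 <= x/Lc < 1")
    f = (params.kBT_pN_nm / params.persistence_length_nm) * (
        0.25 / (1.0 - x) ** 2 - 0.25 + x
    )
    f = np.minimum(f, params.overstretch_force_pN)
    return float(f) if np.isscalar(extension_fraction) else f


def wlc_extension_fraction(force_pN: float, params: WLCParams | None = None) -> float:
    """Inverse of :func:`wlc_force`: fractional extension at a given force.

    Solved by bracketed root finding to 1e-6 relative tolerance; only defined
    strictly below the overstretching cap, where the force curve is strictly
    increasing and the root unique.
    """
    params = params or WLCParams()
    if force_pN < 0:
        raise ValueError("force must be >= 0")
    if force_pN >= params.overstretch_force_pN:
        raise ValueError("no unique inverse at or above the overstretching cap")
    if force_pN == 0:
        return 0.0
    g = lambda x: (params.kBT_pN_nm / params.persistence_length_nm) * (
        0.25 / (1.0 - x) ** 2 - 0.25 + x
    ) - force_pN
    return float(optimize.brentq(g, 0.0, 1.0 - 1e-12, rtol=1e-9, xtol=1e-12))


def wlc_extension(force_pN: float, params: WLCParams | None = None) -> float:
    """Extension in um at a given force."""
    params = params or WLCParams()
    return wlc_extension_fraction(force_pN, params) * params.contour_length_um


# --------------------------------------------------------------------------
# Trace analysis
# --------------------------------------------------------------------------
@dataclass
class PlateauResult:
    plateau_force_pN: float
    onset_time_s: float
    plateau_sd_pN: float
    censored: bool = False


def _rolling_slopes(t: np.ndarray, y: np.ndarray, win: int) -> np.ndarray:
    """Least-squares slope of y vs t in each sliding window of length win."""
    n = len(y) - win + 1
    slopes = np.empty(n)
    for i in range(n):
        tt = t[i : i + win]
        yy = y[i : i + win]
        tc = tt - tt.mean()
        slopes[i] = tc @ (yy - yy.mean()) / (tc @ tc)
    return slopes


def detect_plateau(
    trace: ForceTrace, window_s: float = 5.0, slope_tol_pN_s: float = 0.01
) -> PlateauResult:
    """Locate the force plateau of a (typically passive-mode) trace.

    Scans rolling windows of ``window_s`` and takes the earliest window from
    which the slope magnitude stays below ``slope_tol_pN_s`` for at least 90%
    of the remaining trace; the plateau force is the mean over that stable
    tail.  Returns a censored result when the trace never stabilizes.
    """
    t, f = trace.time_s, trace.force_pN
    win = max(int(round(window_s / trace.dt)), 2)
    if len(f) < 2 * win:
        raise ValueError("trace shorter than two windows")
    # suppress measurement noise before slope estimation, else the rolling
    # slope never beats the tolerance on realistic traces
    kernel = np.ones(win) / win
    f_smooth = np.convolve(f, kernel, mode="same")
    f_smooth[: win // 2] = f_smooth[win // 2]
    f_smooth[-(win // 2):] = f_smooth[-(win // 2) - 1]
    slopes = _rolling_slopes(t, f_smooth, win)
    stable = np.abs(slopes) < slope_tol_pN_s
    for i in range(len(stable)):
        if stable[i] and stable[i:].mean() >= 0.9:
            tail = f[i:]
            return PlateauResult(
                plateau_force_pN=float(tail.mean()),
                onset_time_s=float(t[i]),
                plateau_sd_pN=float(tail.std(ddof=1)),
            )
    return PlateauResult(np.nan, np.nan, np.nan, censored=True)


@dataclass
class ClampResult:
    contraction_velocity_um_s: float
    total_contraction_um: float


def analyze_clamp(trace: ForceTrace) -> ClampResult:
    """Contraction velocity and total contraction of a force-clamp trace.

    The velocity is the robust (Theil-Sen) slope of trap separation versus
    time, sign-flipped so contraction is positive.
    """
    if trace.mode != "clamp":
        raise ValueError(f"expected a clamp trace, got mode {trace.mode!r}")
    if len(trace.time_s) < 3:
        raise ValueError("trace too short")
    sep = trace.trap_separation_um
    total = float(sep[0] - sep[-1])
    # restrict the velocity fit to the active contraction phase: up to the
    # point where 95% of the total contraction has been reached (reeling may
    # saturate mid-trace, which would dilute a whole-trace slope)
    if total > 0:
        reached = sep[0] - sep >= 0.95 * total
        end = int(np.argmax(reached)) + 1 if reached.any() else len(sep)
        end = max(end, 3)
    else:
        end = len(sep)
    slope = _sps.theilslopes(sep[:end], trace.time_s[:end]).slope
    return ClampResult(
        contraction_velocity_um_s=float(-slope),
        total_contraction_um=total,
    )


@dataclass
class TransitionEvent:
    extension_um: float
    force_drop_pN: float
    contour_jump_um: float
    direction: str = "release"


def detect_transitions(
    fd_curve: ForceTrace,
    min_jump_pN: float = 1.0,
    deadband_um: float = 0.05,
    wlc: WLCParams | None = None,
) -> list[TransitionEvent]:
    """Discrete force drops on a pulling curve (condensate dissolution).

    Successive-sample force drops exceeding ``min_jump_pN`` are reported,
    with events closer than ``deadband_um`` in extension merged.  For each
    event the apparent contour-length jump is obtained by inverting the WLC
    at the pre- and post-event force.
    """
    if fd_curve.mode != "pulling":
        raise ValueError("transition detection applies to pulling traces")
    wlc = wlc or WLCParams()
    f = fd_curve.force_pN
    x = fd_curve.extension_um
    drops = np.diff(f)
    idx = np.where(drops < -min_jump_pN)[0]
    events: list[TransitionEvent] = []
    for i in idx:
        f_hi, f_lo = float(f[i]), float(f[i + 1])
        jump = 0.0
        if 0 < f_lo < wlc.overstretch_force_pN and 0 < f_hi < wlc.overstretch_force_pN:
            # apparent contour length before/after at the same extension
            jump = x[i + 1] / wlc_extension_fraction(f_lo, wlc) - x[i] / wlc_extension_fraction(
                f_hi, wlc
            )
        ev = TransitionEvent(
            extension_um=float(x[i]),
            force_drop_pN=f_hi - f_lo,
            contour_jump_um=float(jump),
        )
        if events and abs(ev.extension_um - events[-1].extension_um) < deadband_um:
            prev = events[-1]
            events[-1] = TransitionEvent(
                extension_um=prev.extension_um,
                force_drop_pN=prev.force_drop_pN + ev.force_drop_pN,
                contour_jump_um=prev.contour_jump_um + ev.contour_jump_um,
            )
        else:
            events.append(ev)
    events.sort(key=lambda e: e.extension_um)
    return events


@dataclass
class TrajectoryComparison:
    time_s: np.ndarray
    group_means: dict[str, np.ndarray]
    group_sds: dict[str, np.ndarray]
    endpoint_forces: dict[str, np.ndarray]
    endpoint_ttest: TTestResult | None = None


def compare_force_trajectories(
    groups: dict[str, list[ForceTrace]],
    n_grid: int = 200,
    tail_fraction: float = 0.1,
) -> TrajectoryComparison:
    """Group mean +/- SD force-vs-time curves and an endpoint-force t test.

    Traces are resampled onto a common time grid spanning the overlap of all
    traces.  The endpoint force of each trace is its mean over the final
    ``tail_fraction`` of samples; with exactly two groups a Welch t test on
    the endpoint forces is included.
    """
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("every group needs >= 2 traces")
    t_max = min(tr.time_s[-1] for trs in groups.values() for tr in trs)
    t_min = max(tr.time_s[0] for trs in groups.values() for tr in trs)
    grid = np.linspace(t_min, t_max, n_grid)
    means, sds, endpoints = {}, {}, {}
    for name, traces in groups.items():
        mat = np.stack([np.interp(grid, tr.time_s, tr.force_pN) for tr in traces])
        means[name] = mat.mean(axis=0)
        sds[name] = mat.std(axis=0, ddof=1)
        endpoints[name] = np.array(
            [tr.force_pN[-max(int(len(tr.force_pN) * tail_fraction), 1):].mean() for tr in traces]
        )
    ttest = None
    if len(groups) == 2:
        a, b = (endpoints[k] for k in groups)
        ttest = two_sample_t(a, b, equal_var=False)
    return TrajectoryComparison(
        time_s=grid, group_means=means, group_sds=sds, endpoint_forces=endpoints, endpoint_ttest=ttest
    )
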