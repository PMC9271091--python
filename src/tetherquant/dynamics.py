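"""Condensation/breakage event detection and condensate mobility analysis.

Covers the dynamic read-outs of the tethered-DNA condensation assay:

* kymograph extraction along a tether axis;
* greedy nearest-neighbour tracking of foci on kymographs, with sub-sample
  parabolic peak refinement and gap closing;
* 1-D mean-squared-displacement analysis of tracks (Savitzky-Golay smoothed,
  linear fit MSD = 2 D tau + offset, accepted only when R^2 exceeds a
  threshold);
* the condensation-time statistic T_condense = T75 - T25 over a population
  of per-molecule condensation times;
* tether-breakage detection from loss of axial signal continuity, and
  per-field breakage-fraction statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import savgol_filter

from .core import Kymograph, TetherMovie
from .envelope import transverse_station_series
from .stats import TTestResult, two_sample_t

__all__ = [
    "Kymograph",
    "Track",
    "MSDResult",
    "CondensationStats",
    "BreakageStats",
    "build_kymograph",
    "track_foci_greedy",
    "msd_analysis",
    "detect_condensation_time",
    "condensation_stat",
    "detect_breakage",
    "breakage_fraction",
]


# --------------------------------------------------------------------------
# Kymograph extraction
# --------------------------------------------------------------------------
def build_kymograph(
    movie: TetherMovie,
    channel: str = "protein_a",
    tether_id: int = 0,
    linewidth_px: int = 3,
) -> Kymograph:
    """Sample a movie along a tether axis into a space-time map.

    Intensity is averaged over ``linewidth_px`` lines perpendicular to the
    tether axis, at 1-px axial steps between the anchors.
    """
    anchors = movie.tether(tether_id)
    a = np.asarray(anchors.anchor_a, dtype=float)
    b = np.asarray(anchors.anchor_b, dtype=float)
    axis = b - a
    length = float(np.linalg.norm(axis))
    u = axis / length
    nvec = np.array([-u[1], u[0]])
    n_pos = int(length) + 1
    s = np.arange(n_pos)[:, None]
    offs = (np.arange(linewidth_px) - (linewidth_px - 1) / 2.0)[None, :]
    rows = a[0] + s * u[0] + offs * nvec[0]
    cols = a[1] + s * u[1] + offs * nvec[1]
    h, w = movie.image_shape
    if rows.min() < -0.5 or rows.max() > h - 0.5 or cols.min() < -0.5 or cols.max() > w - 0.5:
        raise ValueError("sampling line exits the image")
    data = np.empty((n_pos, movie.n_frames))
    stack = movie.channels[channel]
    for f in range(movie.n_frames):
        vals = ndimage.map_coordinates(
            stack[f].astype(float), [rows.ravel(), cols.ravel()], order=1, mode="nearest"
        ).reshape(rows.shape)
        data[:, f] = vals.mean(axis=1)
    return Kymograph(
        data=data,
        sample_spacing_nm=movie.pixel_size_nm,
        frame_interval_s=movie.frame_interval_s,
        tether_id=tether_id,
    )


# --------------------------------------------------------------------------
# Greedy tracking
# --------------------------------------------------------------------------
@dataclass
class Track:
    """A linked focus trajectory on a kymograph."""

    track_id: int
    frames: np.ndarray
    positions_um: np.ndarray
    intensities: np.ndarray
    frame_interval_s: float
    smoothed_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        return self.frames * self.frame_interval_s


def _detect_peaks(column: np.ndarray, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima above threshold with parabolic sub-sample refinement."""
    c = column
    idx = np.where((c[1:-1] > threshold) & (c[1:-1] >= c[:-2]) & (c[1:-1] > c[2:]))[0] + 1
    pos = idx.astype(float)
    for k, i in enumerate(idx):
        denom = c[i - 1] - 2 * c[i] + c[i + 1]
        if denom < 0:
            pos[k] = i + 0.5 * (c[i - 1] - c[i + 1]) / denom
    return pos, c[idx]


def track_foci_greedy(
    kymo: Kymograph,
    detect_threshold: float | None = None,
    max_step_um: float = 0.5,
    max_gap: int = 2,
    min_length: int = 5,
) -> list[Track]:
    """Greedy nearest-neighbour linking of kymograph peaks into tracks.

    Peaks are local maxima above ``detect_threshold`` (default: background
    mean + 4 SD, with background statistics taken robustly from the
    kymograph median and MAD).  Frame-to-frame links are assigned greedily
    in order of increasing displacement, rejecting steps beyond
    ``max_step_um`` (scaled by the gap length when closing gaps of up to
    ``max_gap`` missed frames).  Ties break deterministically toward the
    smaller displacement, then the lower position.
    """
    if detect_threshold is None:
        med = float(np.median(kymo.data))
        mad = float(np.median(np.abs(kymo.data - med)))
        detect_threshold = med + 4.0 * 1.4826 * mad
    if detect_threshold <= 0 or max_step_um <= 0:
        raise ValueError("thresholds must be positive")
    dx_um = kymo.sample_spacing_nm / 1000.0

    active: list[dict] = []
    done: list[dict] = []
    for f in range(kymo.n_frames):
        pos_px, amps = _detect_peaks(kymo.data[:, f], detect_threshold)
        pos_um = pos_px * dx_um
        # candidate links: (distance, track index, peak index)
        cands = []
        for ti, tr in enumerate(active):
            gap = f - tr["frames"][-1]
            if gap > max_gap + 1:
                continue
            for pi, x in enumerate(pos_um):
                d = abs(x - tr["positions"][-1])
                if d <= max_step_um * gap:
                    cands.append((d, x, ti, pi))
        cands.sort(key=lambda c: (c[0], c[1]))
        used_t: set[int] = set()
        used_p: set[int] = set()
        for d, x, ti, pi in cands:
            if ti in used_t or pi in used_p:
                continue
            used_t.add(ti)
            used_p.add(pi)
            tr = active[ti]
            tr["frames"].append(f)
            tr["positions"].append(pos_um[pi])
            tr["intensities"].append(amps[pi])
        for pi, x in enumerate(pos_um):
            if pi not in used_p:
                active.append({"frames": [f], "positions": [x], "intensities": [amps[pi]]})
        still = []
        for tr in active:
            if f - tr["frames"][-1] > max_gap:
                done.append(tr)
            else:
                still.append(tr)
        active = still
    done.extend(active)
    tracks = [
        Track(
            track_id=i,
            frames=tr["frames"],
            positions_um=tr["positions"],
            intensities=tr["intensities"],
            frame_interval_s=kymo.frame_interval_s,
        )
        for i, tr in enumerate(t for t in done if len(t["frames"]) >= min_length)
    ]
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for f, x, a in zip(tr.frames, tr.positions_um, tr.intensities):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(f),
                    "time_s": f * tr.frame_interval_s,
                    "position_um": x,
                    "intensity": a,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# MSD analysis
# --------------------------------------------------------------------------
@dataclass
class MSDResult:
    """Lag-time MSD curve with its diffusion-coefficient fit.

    ``D_um2_s`` comes from an unweighted linear fit MSD = 2 D tau + c over
    ``fit_lags``; the intercept absorbs static localization noise.  The
    result is ``accepted`` only when the linear fit explains the curve
    (R^2 above the threshold), the criterion used to exclude confined or
    immobile condensates from diffusion statistics.
    """

    lag_times_s: np.ndarray
    msd_um2: np.ndarray
    D_um2_s: float
    r_squared: float
    accepted: bool
    track_id: int = -1


def time_averaged_msd(positions: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged 1-D MSD at lags 1..max_lag (um^2)."""
    return np.array(
        [np.mean((positions[k:] - positions[:-k]) ** 2) for k in range(1, max_lag + 1)]
    )


def msd_analysis(
    track: Track,
    max_delay_s: float = 4.0,
    smooth_window: int = 11,
    smooth_order: int = 3,
    r2_threshold: float = 0.8,
    fit_lags: tuple[int, int] = (2, 10),
) -> MSDResult:
    """Savitzky-Golay smoothed MSD analysis of one track.

    Positions are smoothed with a ``smooth_order``-order polynomial over a
    ``smooth_window``-frame window before the time-averaged MSD is computed
    on the lag grid {dt, 2 dt, ...} up to ``max_delay_s``.  D is half the
    slope of the linear fit over lag indices ``fit_lags`` (inclusive); the
    first lag is skipped by default because localization noise biases it.
    """
    if len(track) < smooth_window + 2:
        raise ValueError("track shorter than the smoothing window + 2")
    frames = track.frames
    positions = track.positions_um
    if np.any(np.diff(frames) != 1):
        # linearly interpolate across closed gaps so the lag grid is uniform
        full = np.arange(frames[0], frames[-1] + 1)
        positions = np.interp(full, frames, positions)
        frames = full
    dt = track.frame_interval_s
    max_lag = int(round(max_delay_s / dt))
    max_lag = min(max_lag, len(frames) - 1)
    if max_lag < 3:
        raise ValueError("fewer than 3 lag points")
    smoothed = savgol_filter(positions, smooth_window, smooth_order)
    track.smoothed_um = smoothed
    msd = time_averaged_msd(smoothed, max_lag)
    lags = np.arange(1, max_lag + 1)
    lo, hi = fit_lags
    sel = (lags >= lo) & (lags <= min(hi, max_lag))
    tau = lags[sel] * dt
    y = msd[sel]
    A = np.vstack([tau, np.ones_like(tau)]).T
    (slope, intercept), *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - (slope * tau + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else -np.inf
    return MSDResult(
        lag_times_s=lags * dt,
        msd_um2=msd,
        D_um2_s=float(slope / 2.0),
        r_squared=r2,
        accepted=bool(r2 > r2_threshold and slope > 0),
        track_id=track.track_id,
    )


# --------------------------------------------------------------------------
# Condensation time
# --------------------------------------------------------------------------
def _station_floor_scales(station_fracs, n_modes: int = 3) -> np.ndarray:
    """Relative transverse-fluctuation SD at each axial station of a tether
    pinned at both ends, under a sine-mode model with amplitude SD
    proportional to 1/n, normalised to 1 at the midpoint."""
    n = np.arange(1, n_modes + 1, dtype=float)
    raw = 1.0 / n
    ref = np.sqrt(np.sum((raw * np.abs(np.sin(n * np.pi * 0.5))) ** 2))
    return np.array(
        [np.sqrt(np.sum((raw * np.sin(n * np.pi * c)) ** 2)) / ref for c in station_fracs]
    )


def detect_condensation_time(
    movie: TetherMovie,
    tether_id: int = 0,
    tensed_floor_nm: float | None = None,
    tolerance: float = 0.2,
    persistence_frames: int = 10,
    sd_window_frames: int = 7,
    station_fracs: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> float | None:
    """Time at which a tether completely loses its slack fluctuations.

    The per-frame fluctuation proxy pools the transverse tether positions
    measured at several axial stations (normalised by each station's
    relative fluctuation scale for a doubly-pinned tether) into a rolling
    pooled SD over a centred ``sd_window_frames`` window.  The condensation
    time is the earliest frame i at which the proxy has fallen below
    ``floor * (1 + tolerance)`` and the following ``persistence_frames``
    proxy values have median below the same threshold; the reported time is
    corrected for the half-window latency of the centred SD estimator.
    A median persistence decision keeps single noisy SD estimates from
    deferring or faking the event.  Returns ``None`` (censored) when the
    tether never condenses.  When ``tensed_floor_nm`` is not given it is
    estimated from the final 10% of frames, which assumes the movie ends
    condensed.
    """
    stations = transverse_station_series(movie, tether_id, station_fracs=station_fracs)
    scales = _station_floor_scales(station_fracs)
    x = stations / scales[:, None]
    n = x.shape[1]
    half = max(sd_window_frames // 2, 1)
    sd = np.empty(n)
    for i in range(n):
        seg = x[:, max(0, i - half) : min(n, i + half + 1)]
        sd[i] = float(np.sqrt(np.mean((seg - seg.mean(axis=1, keepdims=True)) ** 2)))
    if tensed_floor_nm is None:
        tensed_floor_nm = float(np.median(sd[int(0.9 * n):]))
        if tensed_floor_nm <= 0:
            tensed_floor_nm = 1.0
        # self-estimated floor is only meaningful if the movie ends much
        # quieter than it starts; otherwise the molecule never condensed
        early = float(np.median(sd[: max(n // 10, 5)]))
        if tensed_floor_nm > 0.5 * early:
            return None
    thr = tensed_floor_nm * (1.0 + tolerance)
    k = persistence_frames
    for i in range(n - k + 1):
        if np.median(sd[i : i + k]) < thr and sd[i] < thr:
            return max(i - half, 0) * movie.frame_interval_s
    return None


@dataclass
class CondensationStats:
    times_s: np.ndarray
    t25_s: float
    t75_s: float
    t_condense_s: float
    n_censored: int = 0


def condensation_stat(times_s, n_censored: int = 0) -> CondensationStats:
    """Population condensation time T_condense = T75 - T25.

    ``times_s`` are the uncensored per-molecule condensation times; the 25th
    and 75th percentiles use linear interpolation between order statistics.
    """
    times = np.asarray([t for t in times_s if t is not None], dtype=float)
    if len(times) < 4:
        raise ValueError("need >= 4 uncensored condensation times")
    t25, t75 = np.percentile(times, [25, 75], method="linear")
    return CondensationStats(
        times_s=np.sort(times),
        t25_s=float(t25),
        t75_s=float(t75),
        t_condense_s=float(t75 - t25),
        n_censored=n_censored,
    )


# --------------------------------------------------------------------------
# Breakage
# --------------------------------------------------------------------------
def detect_breakage(
    movie: TetherMovie,
    tether_id: int = 0,
    channel: str = "dna",
    gap_threshold_frac: float = 0.5,
    intensity_drop_frac: float = 0.3,
    persistence_frames: int = 2,
    linewidth_px: int = 15,
) -> float | None:
    """First frame at which a double tether loses axial signal continuity.

    Breakage collapses the DNA onto its two anchors, so the axial profile
    between the anchors develops a long dark gap while the anchor-proximal
    signal persists.  The axial profile integrates over ``linewidth_px``
    perpendicular pixels -- wide enough to cover the whole fluctuation
    envelope, so a slack tether wandering off-axis is not mistaken for a
    gap.  A frame is flagged when the longest below-background run exceeds
    ``gap_threshold_frac`` of the tether length and the central-third mean
    intensity falls below ``intensity_drop_frac`` of its initial value; the
    event time is the first of ``persistence_frames`` consecutive flagged
    frames.  Single tethers are outside this detector's definition and
    return ``None``.
    """
    anchors = movie.tether(tether_id)
    if anchors.tether_type != "double" or anchors.anchor_b is None:
        return None
    kymo = build_kymograph(movie, channel=channel, tether_id=tether_id, linewidth_px=linewidth_px)
    prof = kymo.data  # (positions, frames)
    n_pos, n_frames = prof.shape
    baseline = np.median(prof[:, : max(3, n_frames // 20)])
    third = slice(n_pos // 3, 2 * n_pos // 3)
    central0 = float(prof[third, : max(3, n_frames // 20)].mean())
    # per-position dark threshold: halfway between the background floor and
    # the initial central signal
    dark = baseline + 0.25 * (central0 - baseline)
    run = 0
    for f in range(n_frames):
        col = prof[:, f]
        below = col < dark
        # longest dark run
        longest = 0
        cur = 0
        for b in below:
            cur = cur + 1 if b else 0
            longest = max(longest, cur)
        gap_ok = longest > gap_threshold_frac * n_pos
        drop_ok = col[third].mean() - baseline < intensity_drop_frac * (central0 - baseline)
        if gap_ok and drop_ok:
            run += 1
            if run >= persistence_frames:
                return (f - persistence_frames + 1) * movie.frame_interval_s
        else:
            run = 0
    return None


@dataclass
class BreakageStats:
    per_field: pd.DataFrame
    group_means: dict[str, float]
    group_sds: dict[str, float]
    ttest: TTestResult | None = None
    low_field_warning: bool = False


def breakage_fraction(
    field_counts: dict[str, list[tuple[int, int]]],
    compare: tuple[str, str] | None = None,
) -> BreakageStats:
    """Per-field breakage fractions and group statistics.

    ``field_counts`` maps group name -> list of (broken, total) per imaging
    field.  Groups with fewer than 3 fields are flagged but not rejected.
    When ``compare`` names two groups an unpaired Welch t test on the
    per-field fractions is included.
    """
    rows = []
    warn = False
    for g, counts in field_counts.items():
        if len(counts) < 3:
            warn = True
        for i, (broken, total) in enumerate(counts):
            if not (0 <= broken <= total) or total == 0:
                raise ValueError(f"bad field counts ({broken}, {total})")
            rows.append({"group": g, "field": i, "broken": broken, "total": total, "fraction": broken / total})
    df = pd.DataFrame(rows)
    means = df.groupby("group")["fraction"].mean().to_dict()
    sds = df.groupby("group")["fraction"].std(ddof=1).to_dict()
    ttest = None
    if compare is not None:
        ga, gb = compare
        ttest = two_sample_t(
            df.loc[df.group == ga, "fraction"], df.loc[df.group == gb, "fraction"]
        )
    return BreakageStats(per_field=df, group_means=means, group_sds=sds, ttest=ttest, low_field_warning=warn)
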