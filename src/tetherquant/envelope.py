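"""Transverse fluctuation-envelope analysis of tethered DNA.

A slack DNA molecule tethered at both ends explores a transverse envelope
whose time-averaged intensity profile is well described by a Gaussian.  The
envelope width (double tethers) or fluctuation radius (single tethers) is
defined as two times the standard deviation of a Gaussian fitted to the
background-subtracted transverse line profile through the tether midpoint of
a time-averaged projection.  Condensation pulls the molecule taut and
narrows this envelope, which makes the width a direct readout of
condensation state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .core import TetherAnchors, TetherMovie
from .stats import mean_ci, two_sample_t

__all__ = [
    "TetherMovie",
    "TransverseProfile",
    "EnvelopeResult",
    "time_average_projection",
    "extract_transverse_profile",
    "fit_envelope",
    "measure_envelope",
    "transverse_centroid_series",
    "transverse_station_series",
    "population_envelope_summary",
]


@dataclass
class TransverseProfile:
    """Background-subtracted intensity versus perpendicular offset (nm)."""

    offsets_nm: np.ndarray
    intensities: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.offsets_nm = np.asarray(self.offsets_nm, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.offsets_nm) <= 0):
            raise ValueError("offsets must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("profile intensities must be finite")


@dataclass
class EnvelopeResult:
    """Gaussian-fit envelope of one tether.

    ``width_nm`` is 2 sigma of the fitted Gaussian (PSF-deconvolved when a
    ``psf_sigma_nm`` was supplied to the fit).  ``fit_ok`` is False for
    degenerate or non-convergent fits, which downstream summaries exclude.
    """

    width_nm: float
    center_nm: float
    r_squared: float
    fit_ok: bool
    end_to_end_um: float | None = None
    raw_sigma_nm: float | None = None


def time_average_projection(
    movie: TetherMovie, channel: str = "dna", frame_range: tuple[int, int] | None = None
) -> np.ndarray:
    """Per-pixel mean of a channel over ``frame_range`` (half-open)."""
    stack = movie.channels[channel]
    lo, hi = frame_range if frame_range is not None else (0, stack.shape[0])
    if not (0 <= lo < hi <= stack.shape[0]):
        raise ValueError(f"empty or out-of-range frame range ({lo}, {hi})")
    return stack[lo:hi].astype(float).mean(axis=0)


def _tether_frame(anchors: TetherAnchors, movie: TetherMovie) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Axis origin, unit axis vector, unit normal, length (px) of a tether."""
    a = np.asarray(anchors.anchor_a, dtype=float)
    if anchors.anchor_b is None:
        raise ValueError("transverse profiling needs both anchors; supply a virtual end for single tethers")
    b = np.asarray(anchors.anchor_b, dtype=float)
    axis = b - a
    length = float(np.linalg.norm(axis))
    if length < 4:
        raise ValueError("anchor segment shorter than 4 px")
    u = axis / length
    n = np.array([-u[1], u[0]])
    return a, u, n, length


def _sample_transverse_patch(
    projection: np.ndarray,
    anchors: TetherAnchors,
    pixel_size_nm: float,
    max_offset_px: float,
    axial_window_frac: float,
    background_band_px: float,
    offset_step_px: float,
    axial_center_frac: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Sample a (offset x axial) patch perpendicular to the tether midpoint.

    Returns the transverse offsets (px), the sampled values restricted to
    ``|offset| <= max_offset_px`` (shape ``(n_offsets, n_axial)``), and the
    background level: the median over the two flanking bands parallel to the
    tether just outside ``max_offset_px``.
    """
    movie_like = TetherMovie(
        channels={"dna": projection[None]}, pixel_size_nm=pixel_size_nm, frame_interval_s=1.0
    )
    a, u, n, length = _tether_frame(anchors, movie_like)
    s_lo = axial_center_frac - axial_window_frac / 2.0
    n_axial = max(int(round(axial_window_frac * length)), 3)
    s = np.linspace(s_lo, s_lo + axial_window_frac, n_axial)
    t_max = max_offset_px + background_band_px
    t = np.arange(-t_max, t_max + 1e-9, offset_step_px)
    # sample grid: (len(t), len(s), 2)
    pts = (
        a[None, None, :]
        + (s[None, :, None] * length) * u[None, None, :]
        + t[:, None, None] * n[None, None, :]
    )
    h, w = projection.shape
    if (
        pts[..., 0].min() < -0.5
        or pts[..., 0].max() > h - 0.5
        or pts[..., 1].min() < -0.5
        or pts[..., 1].max() > w - 0.5
    ):
        raise ValueError("profile window exits the image; reduce max_offset_px")
    vals = ndimage.map_coordinates(
        projection.astype(float), [pts[..., 0].ravel(), pts[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(pts.shape[:2])
    in_band = np.abs(t) > max_offset_px
    background = float(np.median(vals[in_band]))
    keep = ~in_band
    return t[keep], vals[keep], background


def extract_transverse_profile(
    projection: np.ndarray,
    anchors: TetherAnchors,
    pixel_size_nm: float,
    max_offset_px: float = 15.0,
    axial_window_frac: float = 0.2,
    background_band_px: float = 4.0,
    offset_step_px: float = 0.5,
    axial_center_frac: float = 0.5,
) -> TransverseProfile:
    """Transverse line profile through the tether midpoint.

    Samples the projection on a grid perpendicular to the anchor-anchor axis,
    averaged over an axial window of ``axial_window_frac`` of the tether
    length centred on the midpoint (where a slack tether is widest).  The
    background is the median over two flanking bands parallel to the tether,
    ``background_band_px`` wide, just outside ``max_offset_px``; it is
    subtracted from the returned profile.
    """
    t, vals, background = _sample_transverse_patch(
        projection, anchors, pixel_size_nm,
        max_offset_px, axial_window_frac, background_band_px, offset_step_px,
        axial_center_frac,
    )
    return TransverseProfile(
        offsets_nm=t * pixel_size_nm,
        intensities=vals.mean(axis=1) - background,
        pixel_size_nm=pixel_size_nm,
    )


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_envelope(
    profile: TransverseProfile,
    psf_sigma_nm: float | None = None,
    end_to_end_um: float | None = None,
) -> EnvelopeResult:
    """Least-squares Gaussian fit of a transverse profile.

    The reported width is 2 sigma in nm.  When the imaging PSF width is
    known, pass ``psf_sigma_nm`` to remove its broadening in quadrature
    (sigma_env = sqrt(sigma_fit^2 - sigma_psf^2)), recovering the physical
    fluctuation amplitude rather than the optically blurred one.  Degenerate
    profiles (flat, non-convergent, or sigma beyond half the profile span)
    come back flagged ``fit_ok=False``.
    """
    x = profile.offsets_nm
    y = profile.intensities
    if len(x) < 5:
        raise ValueError("need at least 5 profile samples")
    span = x[-1] - x[0]
    rng_y = y.max() - y.min()
    bad = EnvelopeResult(
        width_nm=np.nan, center_nm=np.nan, r_squared=-np.inf, fit_ok=False,
        end_to_end_um=end_to_end_um,
    )
    if rng_y <= 0 or y.max() <= 0:
        return bad
    # moment-based initialization
    w_pos = np.clip(y, 0, None)
    tot = w_pos.sum()
    mu0 = float((x * w_pos).sum() / tot)
    var0 = float((w_pos * (x - mu0) ** 2).sum() / tot)
    sigma0 = max(np.sqrt(var0), profile.pixel_size_nm / 4.0)
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            x,
            y,
            p0=(y.max(), mu0, sigma0),
            bounds=((0, x[0], profile.pixel_size_nm / 100.0), (np.inf, x[-1], span)),
            xtol=1e-8,
            maxfev=200 * 4,
        )
    except RuntimeError:
        return bad
    amp, mu, sigma = popt
    resid = y - _gauss(x, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else -np.inf
    if sigma > span / 2.0:
        return bad
    sigma_env = sigma
    if psf_sigma_nm is not None:
        sigma_env = float(np.sqrt(max(sigma**2 - psf_sigma_nm**2, 0.0)))
    return EnvelopeResult(
        width_nm=2.0 * sigma_env,
        center_nm=float(mu),
        r_squared=r2,
        fit_ok=True,
        end_to_end_um=end_to_end_um,
        raw_sigma_nm=float(sigma),
    )


def measure_envelope(
    movie: TetherMovie,
    tether_id: int = 0,
    channel: str = "dna",
    frame_range: tuple[int, int] | None = None,
    deconvolve_psf_sigma_nm: float | None = None,
    mode: str = "width",
    **profile_kwargs,
) -> EnvelopeResult:
    """Projection -> transverse profile -> Gaussian fit, in one call.

    ``mode="width"`` (double tethers) profiles through the tether midpoint,
    where a doubly-pinned molecule is widest; ``mode="radius"`` (single
    tethers) profiles near the free end (axial window centred at 95% of the
    anchor-to-end distance), where the fluctuation of a singly-pinned
    molecule is largest, yielding the fluctuation radius.
    """
    if mode not in ("width", "radius"):
        raise ValueError("mode must be 'width' or 'radius'")
    anchors = movie.tether(tether_id)
    proj = time_average_projection(movie, channel, frame_range)
    if mode == "radius":
        profile_kwargs.setdefault("axial_center_frac", 0.95)
        profile_kwargs.setdefault("axial_window_frac", 0.1)
    prof = extract_transverse_profile(proj, anchors, movie.pixel_size_nm, **profile_kwargs)
    a = np.asarray(anchors.anchor_a, float)
    b = np.asarray(anchors.anchor_b, float)
    ee = float(np.linalg.norm(b - a) * movie.pixel_size_nm / 1000.0)
    return fit_envelope(prof, psf_sigma_nm=deconvolve_psf_sigma_nm, end_to_end_um=ee)


def transverse_station_series(
    movie: TetherMovie,
    tether_id: int = 0,
    channel: str = "dna",
    station_fracs: tuple[float, ...] = (0.25, 0.5, 0.75),
    station_halfwidth_frac: float = 0.1,
    max_offset_px: float = 15.0,
) -> np.ndarray:
    """Per-frame transverse tether position (nm) at several axial stations.

    For each station (a fractional position along the anchor-anchor axis) and
    each frame, the axially-averaged, background-subtracted transverse
    profile is localized by a centroid restricted to a +/-3 px window around
    the profile maximum.  Restricting to the peak keeps the estimate
    unbiased when the line intensity changes over time (a full-window
    centroid is diluted toward zero by symmetric background noise).  Axial
    samples dominated by a bright condensate focus are masked (3-MAD
    outlier columns, dilated by 2 samples) so foci do not masquerade as
    tether displacement.  Returns an array of shape
    ``(len(station_fracs), n_frames)``; pooling stations multiplies the
    per-frame information available to the condensation-time detector.
    """
    anchors = movie.tether(tether_id)
    a = np.asarray(anchors.anchor_a, dtype=float)
    if anchors.anchor_b is None:
        raise ValueError("station series needs both anchors")
    b = np.asarray(anchors.anchor_b, dtype=float)
    out = np.empty((len(station_fracs), movie.n_frames))
    peak_halfwidth_px = 3.0
    for si, c in enumerate(station_fracs):
        sub = TetherAnchors(
            tether_id=anchors.tether_id,
            tether_type="double",
            anchor_a=tuple(a + (c - station_halfwidth_frac) * (b - a)),
            anchor_b=tuple(a + (c + station_halfwidth_frac) * (b - a)),
        )
        for f in range(movie.n_frames):
            t, vals, background = _sample_transverse_patch(
                movie.channels[channel][f],
                sub,
                movie.pixel_size_nm,
                max_offset_px=max_offset_px,
                axial_window_frac=1.0,
                background_band_px=4.0,
                offset_step_px=0.5,
            )
            col_tot = vals.sum(axis=0)
            med = np.median(col_tot)
            mad = np.median(np.abs(col_tot - med))
            bright = col_tot > med + 3.0 * 1.4826 * max(mad, 1e-9)
            bright = ndimage.binary_dilation(bright, iterations=2)
            keep = ~bright
            if keep.sum() < 3:
                keep = np.ones(vals.shape[1], dtype=bool)
            y = vals[:, keep].mean(axis=1) - background
            peak = t[int(np.argmax(y))]
            sel = np.abs(t - peak) <= peak_halfwidth_px
            w = np.clip(y[sel], 0, None)
            tot = w.sum()
            out[si, f] = (
                float((t[sel] * w).sum() / tot * movie.pixel_size_nm) if tot > 0 else 0.0
            )
    return out


def transverse_centroid_series(
    movie: TetherMovie,
    tether_id: int = 0,
    channel: str = "dna",
    max_offset_px: float = 15.0,
    axial_window_frac: float = 0.2,
) -> np.ndarray:
    """Per-frame transverse position (nm) of the tether at its midpoint."""
    return transverse_station_series(
        movie,
        tether_id,
        channel,
        station_fracs=(0.5,),
        station_halfwidth_frac=axial_window_frac / 2.0,
        max_offset_px=max_offset_px,
    )[0]


def population_envelope_summary(
    results: list[EnvelopeResult],
    groups: list[str],
    compare: tuple[str, str] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-group mean width with 95% CI, plus an optional two-group t test.

    Unfit results are excluded.  When ``compare`` names two groups, the
    returned frame carries ``t_stat`` / ``p_value`` attributes in
    ``DataFrame.attrs`` (Welch by default, pooled with ``equal_var=True``).
    """
    df = pd.DataFrame(
        {
            "group": groups,
            "width_nm": [r.width_nm for r in results],
            "fit_ok": [r.fit_ok for r in results],
        }
    )
    df = df[df.fit_ok]
    counts = df.groupby("group").size()
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 usable results")
    rows = []
    for g, sub in df.groupby("group"):
        m, lo, hi = mean_ci(sub.width_nm.to_numpy())
        rows.append({"group": g, "n": len(sub), "mean_width_nm": m, "ci_lo_nm": lo, "ci_hi_nm": hi})
    out = pd.DataFrame(rows).set_index("group")
    if compare is not None:
        ga, gb = compare
        res = two_sample_t(
            df.loc[df.group == ga, "width_nm"],
            df.loc[df.group == gb, "width_nm"],
            equal_var=equal_var,
        )
        out.attrs["t_stat"] = res.statistic
        out.attrs["p_value"] = res.pvalue
        out.attrs["df"] = res.df
    return out
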