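"""Synthetic TIRFM movies, kymographs and dual-trap traces with ground truth.

Every generator in this module draws from a single seeded RNG and returns,
next to the rendered data, a :class:`GroundTruth` manifest recording every
parameter actually used: true fluctuation amplitudes, condensate positions
and contents per frame, condensation and breakage times, reeled-in DNA
length.  The manifests are the recovery targets of the test suite -- each
analysis operation is validated by running it on generated data and comparing
against the manifest, never against itself.

Model summary
-------------
A tethered DNA molecule is rendered as a line of fluorescent segments between
its anchor points.  Per frame the line is displaced transversely by a smooth
random curve (a few sine modes with independent Gaussian amplitudes) whose
pointwise standard deviation at the tether midpoint equals the configured
``envelope_sigma``; this quasi-static approximation reproduces the
time-averaged transverse envelope that the analysis measures, without
simulating polymer dynamics.  Slack DNA fluctuates more: in "auto" mode the
envelope SD shrinks monotonically as the end-to-end distance approaches the
contour length.

Protein:DNA co-condensation nucleates as a Poisson process along the tether.
A condensate reels DNA into a focus (redistributing, never creating, DNA
signal), accumulates protein monomers, suppresses the fluctuation envelope
toward a tensed floor, and -- once the molecule is fully condensed -- may
break the tether, collapsing all signal onto the two anchor points.

Dual-trap traces follow worm-like-chain mechanics of the free (non-reeled)
contour with a force-dependent condensation reel-in that stalls at a
configurable force.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    LAMBDA_BP,
    RISE_NM_PER_BP,
    ForceTrace,
    Kymograph,
    TetherAnchors,
    TetherMovie,
)
from .tweezers import WLCParams, wlc_extension_fraction, wlc_force

#: Coefficient of the auto envelope model, nm of transverse SD per um of
#: root-slack sqrt(Lc^2 - R^2).  Chosen to give a few hundred nm of envelope
#: for typical lambda-DNA tether geometries.
AUTO_SIGMA_COEF = 40.0


# --------------------------------------------------------------------------
# Specifications
# --------------------------------------------------------------------------
@dataclass
class NoiseModel:
    """Camera/photon noise: Gaussian background plus Poisson-like shot noise.

    ``photon_gain`` is the number of detected photons per intensity count;
    zero disables shot noise entirely (noiseless rendering).
    """

    background_mean: float = 10.0
    background_sd: float = 0.0
    photon_gain: float = 0.0


@dataclass
class SimConfig:
    """Global imaging parameters shared by all generators."""

    rng_seed: int = 0
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 0.3
    n_frames: int = 100
    image_shape: tuple[int, int] = (48, 160)
    noise: NoiseModel = field(default_factory=NoiseModel)
    psf_sigma_px: float = 1.3

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if isinstance(self.noise, dict):
            self.noise = NoiseModel(**self.noise)
        self.image_shape = tuple(self.image_shape)


@dataclass
class TetherSpec:
    """One tethered DNA molecule.

    ``envelope_sigma_nm=None`` selects the auto model, in which the
    transverse fluctuation SD decreases monotonically with end-to-end
    distance:  sigma = AUTO_SIGMA_COEF * sqrt(Lc^2 - R^2)  (lengths in um).
    ``nick_fragility`` is the per-frame breakage probability once the
    molecule is fully condensed.
    """

    tether_type: str = "double"
    anchor_a: tuple[float, float] = (24.0, 20.0)
    anchor_b: tuple[float, float] | None = (24.0, 140.0)
    contour_length_bp: int = LAMBDA_BP
    end_to_end_um: float | None = None
    envelope_sigma_nm: float | None = None
    nick_fragility: float = 0.0
    total_intensity: float = 20_000.0
    direction: tuple[float, float] = (0.0, 1.0)  # row, col; single tethers only

    def __post_init__(self) -> None:
        if self.tether_type not in ("double", "single"):
            raise ValueError(f"unknown tether_type {self.tether_type!r}")
        if self.tether_type == "single" and self.anchor_b is not None:
            raise ValueError("single-tethered spec must not define anchor_b")
        if self.tether_type == "double" and self.anchor_b is None:
            raise ValueError("double-tethered spec requires anchor_b")
        if self.envelope_sigma_nm is not None and self.envelope_sigma_nm < 0:
            raise ValueError("envelope_sigma_nm must be >= 0")

    @property
    def contour_length_um(self) -> float:
        return self.contour_length_bp * RISE_NM_PER_BP / 1000.0

    def resolved_end_to_end_um(self, pixel_size_nm: float) -> float:
        """End-to-end distance in um, from anchors if not given explicitly."""
        if self.end_to_end_um is not None:
            r = float(self.end_to_end_um)
        elif self.anchor_b is not None:
            a = np.asarray(self.anchor_a, dtype=float)
            b = np.asarray(self.anchor_b, dtype=float)
            r = float(np.linalg.norm(b - a) * pixel_size_nm / 1000.0)
        else:
            raise ValueError("single tether needs an explicit end_to_end_um")
        if r > self.contour_length_um + 1e-9:
            raise ValueError(
                f"end-to-end distance {r:.3f} um exceeds contour length "
                f"{self.contour_length_um:.3f} um"
            )
        return r

    def resolved_sigma_nm(self, pixel_size_nm: float) -> float:
        if self.envelope_sigma_nm is not None:
            return float(self.envelope_sigma_nm)
        lc = self.contour_length_um
        r = self.resolved_end_to_end_um(pixel_size_nm)
        return AUTO_SIGMA_COEF * float(np.sqrt(max(lc**2 - r**2, 0.0)))


@dataclass
class CondensateSpec:
    """Protein:DNA co-condensation parameters.

    ``nucleation_rate`` is in events per um of tether per second.
    ``reel_in_rate_bp_s`` is the zero-force DNA uptake rate; under tension F
    the rate scales as ``max(0, 1 - F/stall_force_pN)`` (linear stall law).
    ``collapse_time_s`` is the interval between nucleation and complete loss
    of slack; the manifest's condensation time is nucleation + collapse.
    After ``maturation_time_s`` the focus mobility decays exponentially with
    time constant ``maturation_tau_s`` (condensate hardening).
    """

    nucleation_rate: float = 0.02
    reel_in_rate_bp_s: float = 600.0
    stall_force_pN: float = 7.0
    protein_monomer_intensity: float = 100.0
    monomers_per_s: float = 0.5
    mobility_D_um2_s: float = 0.01
    maturation_time_s: float | None = None
    maturation_tau_s: float = 60.0
    collapse_time_s: float = 10.0
    tensed_floor_nm: float = 50.0
    forced_nucleation_time_s: float | None = None
    max_condensates: int = 1
    pinned_positions_frac: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.stall_force_pN <= 0:
            raise ValueError("stall_force_pN must be positive")
        if self.reel_in_rate_bp_s < 0:
            raise ValueError("reel_in_rate_bp_s must be >= 0")


# --------------------------------------------------------------------------
# Ground truth
# --------------------------------------------------------------------------
@dataclass
class GroundTruth:
    """Manifest of every generating parameter and latent trajectory.

    ``kind`` is ``"movie"``, ``"kymograph"`` or ``"trace"``; the
    corresponding record lists hold the per-object truth.  Round-trips
    losslessly through JSON.
    """

    kind: str
    rng_seed: int
    frame_interval_s: float
    n_frames: int
    pixel_size_nm: float | None = None
    tethers: list[dict] = field(default_factory=list)
    foci: list[dict] = field(default_factory=list)
    trace: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))


def _aslist(a) -> list:
    return np.asarray(a, dtype=float).tolist()


# --------------------------------------------------------------------------
# Rendering primitives
# --------------------------------------------------------------------------
def render_gaussian_points(
    image: np.ndarray, rows, cols, amplitudes, sigma_px: float
) -> None:
    """Splat normalized 2-D Gaussian spots onto ``image`` in place.

    Each spot deposits a total of ``amplitude`` counts (up to tail clipping
    at the stamp radius of 5 sigma and at the image border), so summed image
    intensity tracks the photon budget.
    """
    rows = np.atleast_1d(np.asarray(rows, dtype=float))
    cols = np.atleast_1d(np.asarray(cols, dtype=float))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), rows.shape)
    h, w = image.shape
    rad = int(np.ceil(5.0 * sigma_px))
    offs = np.arange(-rad, rad + 1)
    r0 = np.round(rows).astype(int)
    c0 = np.round(cols).astype(int)
    # (n, k) per-axis Gaussian factors about each sub-pixel centre
    gr = np.exp(-((r0[:, None] + offs[None, :] - rows[:, None]) ** 2) / (2 * sigma_px**2))
    gc = np.exp(-((c0[:, None] + offs[None, :] - cols[:, None]) ** 2) / (2 * sigma_px**2))
    stamps = (
        amplitudes[:, None, None]
        / (2 * np.pi * sigma_px**2)
        * gr[:, :, None]
        * gc[:, None, :]
    )
    rr = (r0[:, None] + offs[None, :])[:, :, None]
    cc = (c0[:, None] + offs[None, :])[:, None, :]
    rr = np.broadcast_to(rr, stamps.shape)
    cc = np.broadcast_to(cc, stamps.shape)
    inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    np.add.at(image, (rr[inside], cc[inside]), stamps[inside])


def _apply_noise(frame: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    out = frame
    if noise.photon_gain > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.photon_gain) / noise.photon_gain
    out = out + noise.background_mean
    if noise.background_sd > 0:
        out = out + rng.normal(0.0, noise.background_sd, size=frame.shape)
    return out


def _mode_shapes(tether_type: str, s: np.ndarray, n_modes: int = 3) -> np.ndarray:
    """Transverse mode shapes evaluated at fractional axial positions ``s``.

    Double tethers use pinned-pinned modes sin(n pi s); single tethers use
    pinned-free modes sin((n - 1/2) pi s), maximal at the free end.
    """
    n = np.arange(1, n_modes + 1)[:, None]
    if tether_type == "double":
        return np.sin(n * np.pi * s[None, :])
    return np.sin((n - 0.5) * np.pi * s[None, :])


def _mode_sigmas(tether_type: str, sigma_nm: float, n_modes: int = 3) -> np.ndarray:
    """Per-mode amplitude SDs (prop. to 1/n) normalised so the pointwise SD
    at the reference point (midpoint for double, free end for single) equals
    ``sigma_nm``."""
    n = np.arange(1, n_modes + 1, dtype=float)
    raw = 1.0 / n
    if tether_type == "double":
        ref = np.abs(np.sin(n * np.pi * 0.5))  # midpoint
    else:
        ref = np.abs(np.sin((n - 0.5) * np.pi))  # free end
    norm = np.sqrt(np.sum((raw * ref) ** 2))
    return sigma_nm * raw / norm


# --------------------------------------------------------------------------
# Movie generator
# --------------------------------------------------------------------------
def generate_tether_movie(
    config: SimConfig,
    tethers: list[TetherSpec],
    condensate: CondensateSpec | None = None,
    channels: tuple[str, ...] = ("dna", "protein_a"),
) -> tuple[TetherMovie, GroundTruth]:
    """Render a multi-channel movie of tethered DNA, optionally condensing.

    Returns the movie and its ground-truth manifest.  With ``condensate``
    given, foci nucleate stochastically (or at ``forced_nucleation_time_s``),
    reel in DNA and accumulate protein; the fluctuation envelope decays
    linearly to the tensed floor over ``collapse_time_s``; after complete
    condensation the tether may break with per-frame probability
    ``nick_fragility``, collapsing both channels onto the anchors.
    """
    allowed = {"dna", "protein_a", "protein_b"}
    if not set(channels) <= allowed:
        raise ValueError(f"channels must be a subset of {sorted(allowed)}")
    if "dna" not in channels:
        raise ValueError("a dna channel is required")
    h, w = config.image_shape
    for t in tethers:
        for anch in (t.anchor_a, t.anchor_b):
            if anch is not None and not (0 <= anch[0] < h and 0 <= anch[1] < w):
                raise ValueError(f"anchor {anch} outside image {config.image_shape}")

    rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval_s
    px = config.pixel_size_nm
    stacks = {c: np.zeros((config.n_frames, h, w)) for c in channels}
    truth_tethers: list[dict] = []

    for tid, spec in enumerate(tethers):
        a = np.asarray(spec.anchor_a, dtype=float)
        if spec.tether_type == "double":
            b = np.asarray(spec.anchor_b, dtype=float)
        else:
            d = np.asarray(spec.direction, dtype=float)
            d = d / np.linalg.norm(d)
            ee_px = spec.resolved_end_to_end_um(px) * 1000.0 / px
            b = a + d * ee_px
        axis = b - a
        length_px = float(np.linalg.norm(axis))
        if length_px < 4:
            raise ValueError("tether shorter than 4 px")
        u = axis / length_px
        normal = np.array([-u[1], u[0]])
        ee_um = spec.resolved_end_to_end_um(px)
        sigma0 = spec.resolved_sigma_nm(px)

        n_seg = max(int(2 * length_px), 20)
        s = (np.arange(n_seg) + 0.5) / n_seg
        shapes = _mode_shapes(spec.tether_type, s)

        # --- latent condensation trajectory -----------------------------
        cond = condensate
        nuc_times: list[float] = []
        cond_positions: list[float] = []  # fractional axial position at nucleation
        n_cond_max = cond.max_condensates if cond is not None else 0
        floor_nm = cond.tensed_floor_nm if cond is not None else 0.0

        # per-condensate per-frame records
        cond_bp = np.zeros((n_cond_max, config.n_frames))
        cond_mono = np.zeros((n_cond_max, config.n_frames))
        cond_pos_frac = np.full((n_cond_max, config.n_frames), np.nan)

        condensation_time: float | None = None
        breakage_frame: int | None = None
        pos_state: list[float] = []

        amps = rng.normal(size=(config.n_frames, shapes.shape[0]))

        for f in range(config.n_frames):
            t_now = f * dt
            if cond is not None and breakage_frame is None:
                # nucleation
                if len(nuc_times) < n_cond_max:
                    if cond.pinned_positions_frac is not None:
                        want = list(cond.pinned_positions_frac)
                        while len(nuc_times) < min(n_cond_max, len(want)) and (
                            cond.forced_nucleation_time_s is None
                            or t_now >= cond.forced_nucleation_time_s
                        ):
                            pos = want[len(nuc_times)]
                            cond_positions.append(pos)
                            pos_state.append(pos)
                            nuc_times.append(t_now)
                    elif cond.forced_nucleation_time_s is not None:
                        if t_now >= cond.forced_nucleation_time_s and not nuc_times:
                            p = float(rng.uniform(0.25, 0.75))
                            cond_positions.append(p)
                            pos_state.append(p)
                            nuc_times.append(t_now)
                    else:
                        p_nuc = cond.nucleation_rate * ee_um * dt
                        if rng.random() < p_nuc:
                            p = float(rng.uniform(0.25, 0.75))
                            cond_positions.append(p)
                            pos_state.append(p)
                            nuc_times.append(t_now)
                if nuc_times and condensation_time is None:
                    condensation_time = nuc_times[0] + cond.collapse_time_s
                # growth and motion of existing foci
                for ci, t_nuc in enumerate(nuc_times):
                    prev_bp = cond_bp[ci, f - 1] if f > 0 else 0.0
                    prev_mono = cond_mono[ci, f - 1] if f > 0 else 0.0
                    reel = 0.0 if cond.pinned_positions_frac is not None else cond.reel_in_rate_bp_s
                    cond_bp[ci, f] = min(
                        prev_bp + reel * dt, 0.9 * spec.contour_length_bp / max(len(nuc_times), 1)
                    )
                    cond_mono[ci, f] = prev_mono + cond.monomers_per_s * dt
                    d_eff = cond.mobility_D_um2_s
                    if (
                        cond.maturation_time_s is not None
                        and t_now - t_nuc > cond.maturation_time_s
                    ):
                        d_eff *= np.exp(
                            -(t_now - t_nuc - cond.maturation_time_s) / cond.maturation_tau_s
                        )
                    if cond.pinned_positions_frac is None and d_eff > 0:
                        step_um = rng.normal(0.0, np.sqrt(2 * d_eff * dt))
                        newp = pos_state[ci] + step_um / max(ee_um, 1e-9)
                        # reflect inside (0.05, 0.95)
                        lo, hi = 0.05, 0.95
                        span = hi - lo
                        newp = lo + abs((newp - lo) % (2 * span))
                        if newp > hi + span:
                            newp -= 2 * span
                        elif newp > hi:
                            newp = 2 * hi - newp
                        pos_state[ci] = float(np.clip(newp, lo, hi))
                    cond_pos_frac[ci, f] = pos_state[ci]
                # breakage: eligible strictly after complete condensation
                if (
                    condensation_time is not None
                    and t_now > condensation_time
                    and spec.nick_fragility > 0
                    and rng.random() < spec.nick_fragility
                ):
                    breakage_frame = f

            # --- envelope SD at this frame -------------------------------
            if condensation_time is not None and nuc_times:
                t_nuc0 = nuc_times[0]
                if t_now <= t_nuc0:
                    sig_f = sigma0
                elif t_now >= condensation_time:
                    sig_f = floor_nm
                else:
                    # quarter-power profile: slack loss accelerates and ends
                    # sharply, so the condensation time is a crisp transition
                    frac = (t_now - t_nuc0) / (condensation_time - t_nuc0)
                    sig_f = floor_nm + (sigma0 - floor_nm) * (1.0 - frac) ** 0.25
            else:
                sig_f = sigma0

            # --- render ---------------------------------------------------
            if breakage_frame is not None and f >= breakage_frame:
                # all signal collapsed onto the two anchor points
                for ch in channels:
                    if ch == "dna":
                        budget = spec.total_intensity
                    else:
                        budget = float(cond_mono[:, f - 1].sum() if f > 0 else 0.0) * (
                            cond.protein_monomer_intensity if cond else 0.0
                        )
                    if budget <= 0:
                        continue
                    render_gaussian_points(
                        stacks[ch][f],
                        [a[0], b[0]],
                        [a[1], b[1]],
                        [budget / 2, budget / 2],
                        config.psf_sigma_px * 1.5,
                    )
                continue

            mode_sd = _mode_sigmas(spec.tether_type, sig_f)
            w_nm = (amps[f] * mode_sd) @ shapes  # transverse offset per segment, nm
            w_px = w_nm / px
            seg_rc = a[None, :] + s[:, None] * axis[None, :] + w_px[:, None] * normal[None, :]

            reeled_total = float(cond_bp[:, f].sum()) if n_cond_max else 0.0
            free_frac = 1.0 - reeled_total / spec.contour_length_bp
            seg_amp = spec.total_intensity * free_frac / n_seg
            render_gaussian_points(
                stacks["dna"][f], seg_rc[:, 0], seg_rc[:, 1], seg_amp, config.psf_sigma_px
            )
            for ci, t_nuc in enumerate(nuc_times):
                p = cond_pos_frac[ci, f]
                off_nm = float((amps[f] * mode_sd) @ _mode_shapes(spec.tether_type, np.array([p]))[:, 0])
                rc = a + p * axis + (off_nm / px) * normal
                if cond_bp[ci, f] > 0:
                    render_gaussian_points(
                        stacks["dna"][f],
                        rc[0],
                        rc[1],
                        spec.total_intensity * cond_bp[ci, f] / spec.contour_length_bp,
                        config.psf_sigma_px,
                    )
                for ch in ("protein_a", "protein_b"):
                    if ch in channels and cond is not None:
                        render_gaussian_points(
                            stacks[ch][f],
                            rc[0],
                            rc[1],
                            cond_mono[ci, f] * cond.protein_monomer_intensity,
                            config.psf_sigma_px,
                        )

        truth_tethers.append(
            {
                "tether_id": tid,
                "tether_type": spec.tether_type,
                "anchor_a": _aslist(a),
                "anchor_b": _aslist(b),
                "contour_length_bp": int(spec.contour_length_bp),
                "end_to_end_um": ee_um,
                "envelope_sigma_nm": sigma0,
                "tensed_floor_nm": floor_nm,
                "nick_fragility": spec.nick_fragility,
                "total_intensity": spec.total_intensity,
                "nucleation_times_s": list(nuc_times),
                "condensation_time_s": condensation_time,
                "breakage_frame": breakage_frame,
                "breakage_time_s": None if breakage_frame is None else breakage_frame * dt,
                "condensates": [
                    {
                        "t_nuc_s": nuc_times[ci],
                        "position_frac": _aslist(cond_pos_frac[ci]),
                        "bp": _aslist(cond_bp[ci]),
                        "monomers": _aslist(cond_mono[ci]),
                    }
                    for ci in range(len(nuc_times))
                ],
            }
        )

    noisy = {
        c: np.stack([_apply_noise(stacks[c][f], config.noise, rng) for f in range(config.n_frames)])
        for c in channels
    }
    movie = TetherMovie(
        channels=noisy,
        pixel_size_nm=px,
        frame_interval_s=dt,
        tethers=[
            TetherAnchors(
                tether_id=rec["tether_id"],
                tether_type=rec["tether_type"],
                anchor_a=tuple(rec["anchor_a"]),
                anchor_b=tuple(rec["anchor_b"]),
            )
            for rec in truth_tethers
        ],
    )
    truth = GroundTruth(
        kind="movie",
        rng_seed=config.rng_seed,
        frame_interval_s=dt,
        n_frames=config.n_frames,
        pixel_size_nm=px,
        tethers=truth_tethers,
    )
    return movie, truth


# --------------------------------------------------------------------------
# Kymograph generator
# --------------------------------------------------------------------------
def generate_kymograph(
    config: SimConfig,
    n_foci: int,
    D_list,
    drift_um_s: float = 0.0,
    length_um: float = 10.0,
    focus_intensity: float = 500.0,
) -> tuple[Kymograph, GroundTruth]:
    """1-D Brownian foci on a space-time map, with known diffusion constants.

    Each focus performs reflected Brownian motion with its own D plus a
    common drift; positions are recorded exactly in the manifest before
    rendering with the configured PSF and noise model.
    """
    D_list = [float(d) for d in np.atleast_1d(D_list)]
    if len(D_list) != n_foci:
        raise ValueError("D_list length must equal n_foci")
    if any(d < 0 for d in D_list):
        raise ValueError("diffusion coefficients must be >= 0")
    rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval_s
    px_um = config.pixel_size_nm / 1000.0
    n_pos = int(round(length_um / px_um))
    positions = np.zeros((n_foci, config.n_frames))
    x0 = (np.arange(n_foci) + 1.0) / (n_foci + 1.0) * length_um
    for i, d in enumerate(D_list):
        steps = rng.normal(0.0, np.sqrt(2 * d * dt), size=config.n_frames - 1) if d > 0 else np.zeros(config.n_frames - 1)
        x = np.empty(config.n_frames)
        x[0] = x0[i]
        for f in range(1, config.n_frames):
            xn = x[f - 1] + steps[f - 1] + drift_um_s * dt
            # reflect at [0, length_um]
            xn = abs(xn)
            if xn > length_um:
                xn = 2 * length_um - xn
            x[f] = np.clip(xn, 0.0, length_um)
        positions[i] = x

    data = np.zeros((n_pos, config.n_frames))
    grid = np.arange(n_pos) * px_um
    sig_um = config.psf_sigma_px * px_um
    for f in range(config.n_frames):
        prof = np.zeros(n_pos)
        for i in range(n_foci):
            prof += (
                focus_intensity
                / (np.sqrt(2 * np.pi) * (sig_um / px_um))
                * np.exp(-((grid - positions[i, f]) ** 2) / (2 * sig_um**2))
            )
        data[:, f] = _apply_noise(prof, config.noise, rng)

    kymo = Kymograph(
        data=data,
        sample_spacing_nm=config.pixel_size_nm,
        frame_interval_s=dt,
    )
    truth = GroundTruth(
        kind="kymograph",
        rng_seed=config.rng_seed,
        frame_interval_s=dt,
        n_frames=config.n_frames,
        pixel_size_nm=config.pixel_size_nm,
        foci=[
            {
                "focus_id": i,
                "D_um2_s": D_list[i],
                "drift_um_s": drift_um_s,
                "positions_um": _aslist(positions[i]),
            }
            for i in range(n_foci)
        ],
    )
    return kymo, truth


# --------------------------------------------------------------------------
# Force-trace generator
# --------------------------------------------------------------------------
def brownian_tracks(
    n_tracks: int, n_frames: int, D_um2_s: float, dt_s: float, rng_seed: int = 0
) -> np.ndarray:
    """Plain 1-D Brownian position arrays, shape (n_tracks, n_frames)."""
    rng = np.random.default_rng(rng_seed)
    steps = rng.normal(0.0, np.sqrt(2 * D_um2_s * dt_s), size=(n_tracks, n_frames - 1))
    return np.concatenate(
        [np.zeros((n_tracks, 1)), np.cumsum(steps, axis=1)], axis=1
    )


def _solve_passive_force(
    sep_um: float, lc_free_um: float, wlc: WLCParams, k_trap_pN_nm: float
) -> float:
    """Force balance at fixed trap separation: F = WLC((S - 2F/k)/Lc_free)."""
    from scipy.optimize import brentq

    def ext(f: float) -> float:
        return sep_um - 2.0 * f / k_trap_pN_nm / 1000.0

    if ext(0.0) <= 0:
        return 0.0
    if ext(0.0) / lc_free_um >= 1.0:
        # tether taut beyond WLC validity: report the overstretching plateau
        return wlc.overstretch_force_pN

    def g(f: float) -> float:
        x = ext(f)
        frac = min(max(x / lc_free_um, 0.0), 1.0 - 1e-12)
        return wlc_force(frac, wlc) - f

    if g(0.0) <= 0:
        return 0.0
    hi = wlc.overstretch_force_pN
    if g(hi) >= 0:
        return hi
    return float(brentq(g, 0.0, hi, xtol=1e-10))


def generate_force_trace(
    config: SimConfig,
    mode: str,
    wlc: WLCParams | None = None,
    condensate: CondensateSpec | None = None,
    mode_params: dict | None = None,
) -> tuple[ForceTrace, GroundTruth]:
    """Simulate a dual-trap trace under passive, clamp or pulling mode.

    Passive: trap separation fixed; the condensate reels DNA at
    ``reel_in_rate * max(0, 1 - F/stall)`` so the force climbs to a plateau
    at the stall force.  Clamp: force held at ``clamp_force_pN`` and the
    trap separation follows the shrinking tether.  Pulling: separation
    ramped at ``pull_speed_um_s``; sequestered contour is released in
    discrete jumps when the force crosses per-event dissolution thresholds,
    and the force is capped at the overstretching plateau.

    ``mode_params`` keys: ``initial_force_pN`` (passive; default 0.5),
    ``clamp_force_pN`` (clamp), ``pull_speed_um_s`` and
    ``sequestered_bp`` / ``dissolution_forces_pN`` / ``jump_bp`` (pulling),
    ``k_trap_pN_nm`` (default 0.3), ``force_noise_sd_pN`` (default 0.15).
    """
    if mode not in ("passive", "clamp", "pulling"):
        raise ValueError(f"unknown mode {mode!r}")
    wlc = wlc or WLCParams()
    condensate = condensate or CondensateSpec()
    p = dict(mode_params or {})
    k_trap = float(p.pop("k_trap_pN_nm", 0.3))
    noise_sd = float(p.pop("force_noise_sd_pN", 0.15))
    rng = np.random.default_rng(config.rng_seed)
    dt = config.frame_interval_s
    n = config.n_frames
    t = np.arange(n) * dt

    lc0 = wlc.contour_length_um
    stall = condensate.stall_force_pN
    rate = condensate.reel_in_rate_bp_s
    force = np.zeros(n)
    sep = np.zeros(n)
    reeled = np.zeros(n)
    events: list[dict] = []

    if mode == "passive":
        f0 = float(p.pop("initial_force_pN", 0.5))
        sep0 = p.pop("trap_separation_um", None)
        if sep0 is None:
            sep0 = wlc_extension_fraction(f0, wlc) * lc0 + 2 * f0 / k_trap / 1000.0
        sep[:] = sep0
        r_bp = 0.0
        for i in range(n):
            lc_free = lc0 - r_bp * RISE_NM_PER_BP / 1000.0
            f = _solve_passive_force(sep0, lc_free, wlc, k_trap)
            force[i] = f
            reeled[i] = r_bp
            r_bp += rate * max(0.0, 1.0 - f / stall) * dt
        ext = sep - 2 * force / k_trap / 1000.0

    elif mode == "clamp":
        if "clamp_force_pN" not in p:
            raise ValueError("clamp mode requires clamp_force_pN")
        fc = float(p.pop("clamp_force_pN"))
        if fc < 0:
            raise ValueError("clamp_force_pN must be >= 0")
        zfrac = wlc_extension_fraction(fc, wlc)
        v_bp = rate * max(0.0, 1.0 - fc / stall)
        r_bp = 0.0
        for i in range(n):
            lc_free = lc0 - r_bp * RISE_NM_PER_BP / 1000.0
            force[i] = fc
            reeled[i] = r_bp
            sep[i] = zfrac * lc_free + 2 * fc / k_trap / 1000.0
            r_bp = min(r_bp + v_bp * dt, 0.9 * lc0 * 1000.0 / RISE_NM_PER_BP)
        ext = sep - 2 * force / k_trap / 1000.0

    else:  # pulling
        if "pull_speed_um_s" not in p:
            raise ValueError("pulling mode requires pull_speed_um_s")
        v = float(p.pop("pull_speed_um_s"))
        seq_bp = float(p.pop("sequestered_bp", 0.0))
        jump_bp = float(p.pop("jump_bp", 1500.0))
        thresholds = p.pop("dissolution_forces_pN", None)
        if thresholds is None:
            n_jumps = int(p.pop("n_jumps", 0))
            thresholds = sorted(rng.uniform(10.0, 40.0, size=n_jumps)) if n_jumps else []
        thresholds = sorted(float(x) for x in thresholds)
        sep0 = float(p.pop("start_separation_um", 0.7 * (lc0 - seq_bp * RISE_NM_PER_BP / 1000.0)))
        for i in range(n):
            sep[i] = sep0 + v * t[i]
            lc_free = lc0 - seq_bp * RISE_NM_PER_BP / 1000.0
            f = _solve_passive_force(sep[i], lc_free, wlc, k_trap)
            while thresholds and f >= thresholds[0] and seq_bp > 0:
                thr = thresholds.pop(0)
                released = min(jump_bp, seq_bp)
                seq_bp -= released
                lc_free = lc0 - seq_bp * RISE_NM_PER_BP / 1000.0
                f_new = _solve_passive_force(sep[i], lc_free, wlc, k_trap)
                events.append(
                    {
                        "time_s": float(t[i]),
                        "threshold_pN": thr,
                        "released_bp": released,
                        "released_um": released * RISE_NM_PER_BP / 1000.0,
                        "force_before_pN": float(f),
                        "force_after_pN": float(f_new),
                        "extension_um": float(sep[i] - 2 * f / k_trap / 1000.0),
                    }
                )
                f = f_new
            force[i] = min(f, wlc.overstretch_force_pN)
            reeled[i] = seq_bp
        if np.any(sep - 2 * force / k_trap / 1000.0 < 0):
            raise ValueError("pulling produced negative extension")
        ext = sep - 2 * force / k_trap / 1000.0

    if p:
        raise ValueError(f"unknown mode_params keys: {sorted(p)}")
    noisy_force = force + (rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0)
    trace = ForceTrace(
        time_s=t,
        force_pN=noisy_force,
        trap_separation_um=sep,
        extension_um=ext,
        reeled_bp=reeled,
        mode=mode,
    )
    truth = GroundTruth(
        kind="trace",
        rng_seed=config.rng_seed,
        frame_interval_s=dt,
        n_frames=n,
        trace={
            "mode": mode,
            "stall_force_pN": stall,
            "reel_in_rate_bp_s": rate,
            "k_trap_pN_nm": k_trap,
            "force_noise_sd_pN": noise_sd,
            "wlc": {
                "persistence_length_nm": wlc.persistence_length_nm,
                "contour_length_um": wlc.contour_length_um,
                "kBT_pN_nm": wlc.kBT_pN_nm,
                "overstretch_force_pN": wlc.overstretch_force_pN,
            },
            "true_force_pN": _aslist(force),
            "final_reeled_bp": float(reeled[-1]),
            "dissolution_events": events,
        },
    )
    return trace, truth
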