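"""Shared data containers and physical constants.

The containers here are the currency of the whole package: calibrated image
stacks (:class:`TetherMovie`), space-time maps (:class:`Kymograph`) and
dual-trap time series (:class:`ForceTrace`).  They are deliberately thin --
numpy arrays plus the calibration metadata every analysis needs -- and they
round-trip through plain-text-friendly formats (TIFF stacks, CSV, JSON).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Thermal energy at 25 degC, pN nm.
KBT_PN_NM = 4.114
#: Helical rise of B-form DNA, nm per base pair.
RISE_NM_PER_BP = 0.34
#: Length of the bacteriophage lambda genome, bp.
LAMBDA_BP = 48_502
#: Contour length of lambda DNA, um.
LAMBDA_CONTOUR_UM = LAMBDA_BP * RISE_NM_PER_BP / 1000.0

#: Channel names a movie may carry.
CHANNELS = ("dna", "protein_a", "protein_b")


@dataclass
class TetherAnchors:
    """Anchor geometry of one tether within a movie (pixel coordinates, row/col)."""

    tether_id: int
    tether_type: str  # "double" | "single"
    anchor_a: tuple[float, float]
    anchor_b: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "tether_id": self.tether_id,
            "tether_type": self.tether_type,
            "anchor_a": list(self.anchor_a),
            "anchor_b": None if self.anchor_b is None else list(self.anchor_b),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TetherAnchors":
        return cls(
            tether_id=int(d["tether_id"]),
            tether_type=d["tether_type"],
            anchor_a=tuple(d["anchor_a"]),
            anchor_b=None if d.get("anchor_b") is None else tuple(d["anchor_b"]),
        )


@dataclass
class TetherMovie:
    """Calibrated multi-channel fluorescence movie of surface-tethered DNA.

    Parameters
    ----------
    channels
        Mapping channel name -> stack of shape ``(n_frames, n_rows, n_cols)``.
        All channels share shape and calibration; a ``"dna"`` channel must be
        present for any DNA-geometry analysis.
    pixel_size_nm
        Lateral calibration, nm per pixel.
    frame_interval_s
        Time between consecutive frames, seconds.
    tethers
        Anchor coordinates of each tether in the field of view.
    """

    channels: dict[str, np.ndarray]
    pixel_size_nm: float
    frame_interval_s: float
    tethers: list[TetherAnchors] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("movie needs at least one channel")
        shapes = {c: a.shape for c, a in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel stacks disagree in shape: {shapes}")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[1:]

    def tether(self, tether_id: int) -> TetherAnchors:
        for t in self.tethers:
            if t.tether_id == tether_id:
                return t
        raise KeyError(f"no tether with id {tether_id}")

    # ------------------------------------------------------------------ I/O
    def save(self, directory: str | Path) -> Path:
        """Write one ImageJ-compatible TIFF per channel plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, stack in self.channels.items():
            tifffile.imwrite(
                directory / f"{name}.tif",
                np.asarray(stack, dtype=np.float32),
                imagej=True,
                resolution=(1e3 / self.pixel_size_nm, 1e3 / self.pixel_size_nm),
                metadata={
                    "axes": "TYX",
                    "finterval": self.frame_interval_s,
                    "unit": "um",
                },
            )
        meta = {
            "pixel_size_nm": self.pixel_size_nm,
            "frame_interval_s": self.frame_interval_s,
            "channels": sorted(self.channels),
            "tethers": [t.to_dict() for t in self.tethers],
        }
        (directory / "movie.json").write_text(json.dumps(meta, indent=1))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TetherMovie":
        directory = Path(directory)
        meta = json.loads((directory / "movie.json").read_text())
        channels = {
            name: tifffile.imread(directory / f"{name}.tif")
            for name in meta["channels"]
        }
        for name, stack in channels.items():
            if stack.ndim == 2:  # single-frame stacks come back squeezed
                channels[name] = stack[None]
        return cls(
            channels=channels,
            pixel_size_nm=meta["pixel_size_nm"],
            frame_interval_s=meta["frame_interval_s"],
            tethers=[TetherAnchors.from_dict(d) for d in meta["tethers"]],
        )


@dataclass
class Kymograph:
    """Space-time intensity map along one tether axis.

    ``data`` has shape ``(n_positions, n_frames)``: rows are positions along
    the tether, columns are frames.
    """

    data: np.ndarray
    sample_spacing_nm: float
    frame_interval_s: float
    tether_id: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph data must be 2-D (space x time)")
        if self.sample_spacing_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration values must be positive")

    @property
    def n_positions(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        tifffile.imwrite(
            path,
            self.data.astype(np.float32),
            metadata={
                "sample_spacing_nm": self.sample_spacing_nm,
                "frame_interval_s": self.frame_interval_s,
                "tether_id": self.tether_id,
            },
        )
        sidecar = path.with_suffix(".json")
        sidecar.write_text(
            json.dumps(
                {
                    "sample_spacing_nm": self.sample_spacing_nm,
                    "frame_interval_s": self.frame_interval_s,
                    "tether_id": self.tether_id,
                }
            )
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "Kymograph":
        path = Path(path)
        data = tifffile.imread(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(data=data, **meta)


#: Column order of the trace CSV format.
TRACE_COLUMNS = ("time_s", "force_pN", "trap_separation_um", "extension_um", "reeled_bp")


@dataclass
class ForceTrace:
    """Dual-trap time series under one operating mode.

    ``mode`` is one of ``"passive"`` (fixed trap separation), ``"clamp"``
    (force held constant by feedback) or ``"pulling"`` (trap separation
    ramped).  ``reeled_bp`` is only meaningful for simulated traces, where it
    records the DNA length sequestered by the condensate.
    """

    time_s: np.ndarray
    force_pN: np.ndarray
    trap_separation_um: np.ndarray
    extension_um: np.ndarray
    reeled_bp: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in TRACE_COLUMNS:
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (n,):
                raise ValueError(f"column {name} length mismatch")
        if not np.all(np.isfinite(self.force_pN)):
            raise ValueError("force contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0]) if len(self.time_s) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRACE_COLUMNS})

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        path.with_suffix(".mode.json").write_text(json.dumps({"mode": self.mode}))
        return path

    @classmethod
    def load(cls, path: str | Path, mode: str | None = None) -> "ForceTrace":
        path = Path(path)
        df = pd.read_csv(path)
        if mode is None:
            sidecar = path.with_suffix(".mode.json")
            mode = (
                json.loads(sidecar.read_text())["mode"] if sidecar.exists() else "unknown"
            )
        return cls(mode=mode, **{c: df[c].to_numpy() for c in TRACE_COLUMNS})
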