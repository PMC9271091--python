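"""End-to-end orchestration: simulate -> analyze -> report.

A run is described by a YAML/JSON configuration with a single top-level
seed; per-stage and per-object RNG seeds are derived deterministically from
it, so a run is reproducible bit-for-bit.  Unknown configuration keys are
rejected outright (a typo'd parameter must not silently fall back to a
default).  Each stage writes a content hash of its configuration block next
to its outputs; a resumed run recomputes any stage whose block changed and
reuses the rest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import dynamics, envelope, tweezers
from .core import ForceTrace, TetherMovie
from .synthetic import (
    CondensateSpec,
    GroundTruth,
    NoiseModel,
    SimConfig,
    TetherSpec,
    generate_force_trace,
    generate_kymograph,
    generate_tether_movie,
)
from .tweezers import WLCParams

log = logging.getLogger("tetherquant")

STAGES = ("simulate", "analyze", "report")

_TOP_KEYS = {"seed", "out_dir", "stages", "movies", "kymograph", "traces"}
_GROUP_KEYS = {"name", "n_tethers", "condensate", "tether", "sim", "channels"}
_KYMO_KEYS = {"n_foci", "D_list", "drift_um_s", "length_um", "focus_intensity", "sim"}
_TRACE_KEYS = {"name", "mode", "condensate", "wlc", "params", "sim"}


class ConfigError(ValueError):
    pass


def _check_keys(block: dict, allowed: set, context: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {context}")


def _dataclass_from(block: dict | None, cls, context: str):
    block = dict(block or {})
    allowed = {f.name for f in dataclasses.fields(cls)}
    _check_keys(block, allowed, context)
    return cls(**block)


def load_config(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        cfg = source
    else:
        cfg = yaml.safe_load(Path(source).read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("configuration must be a mapping")
    _check_keys(cfg, _TOP_KEYS, "top level")
    for g in cfg.get("movies", {}).get("groups", []) if cfg.get("movies") else []:
        _check_keys(g, _GROUP_KEYS, f"movie group {g.get('name', '?')}")
    if cfg.get("kymograph"):
        _check_keys(cfg["kymograph"], _KYMO_KEYS, "kymograph block")
    for t in cfg.get("traces", []) or []:
        _check_keys(t, _TRACE_KEYS, f"trace block {t.get('name', '?')}")
    return cfg


def derive_seed(base_seed: int, *tokens) -> int:
    """Deterministic sub-seed below 2**31 from a base seed and labels."""
    h = hashlib.sha256(("/".join(map(str, (base_seed, *tokens)))).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _block_hash(block) -> str:
    return hashlib.sha256(json.dumps(block, sort_keys=True, default=str).encode()).hexdigest()


def _stage_fresh(stage_dir: Path, block_hash: str) -> bool:
    mark = stage_dir / ".config_hash"
    return mark.exists() and mark.read_text() == block_hash


def _mark_stage(stage_dir: Path, block_hash: str) -> None:
    (stage_dir / ".config_hash").write_text(block_hash)


def _sim_config(block: dict | None, seed: int) -> SimConfig:
    block = dict(block or {})
    noise = block.pop("noise", None)
    cfg = _dataclass_from(block | {"rng_seed": seed}, SimConfig, "sim block")
    if noise is not None:
        cfg.noise = _dataclass_from(noise, NoiseModel, "noise block")
    return cfg


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------
def _simulate(cfg: dict, out: Path, seed: int) -> None:
    movies_cfg = cfg.get("movies") or {}
    for group in movies_cfg.get("groups", []):
        gname = group["name"]
        channels = tuple(group.get("channels", ("dna", "protein_a")))
        cond = (
            _dataclass_from(group["condensate"], CondensateSpec, f"{gname}.condensate")
            if group.get("condensate")
            else None
        )
        for i in range(int(group.get("n_tethers", 1))):
            mseed = derive_seed(seed, "movie", gname, i)
            sim = _sim_config(group.get("sim"), mseed)
            tether = _dataclass_from(group.get("tether"), TetherSpec, f"{gname}.tether")
            movie, truth = generate_tether_movie(sim, [tether], cond, channels=channels)
            tdir = out / "movies" / gname / f"tether_{i:03d}"
            movie.save(tdir)
            truth.to_json(tdir / "truth.json")
            log.info("simulated movie %s/%d", gname, i)
    if cfg.get("kymograph"):
        kb = cfg["kymograph"]
        sim = _sim_config(kb.get("sim"), derive_seed(seed, "kymo"))
        kymo, truth = generate_kymograph(
            sim,
            n_foci=int(kb["n_foci"]),
            D_list=kb["D_list"],
            drift_um_s=float(kb.get("drift_um_s", 0.0)),
            length_um=float(kb.get("length_um", 10.0)),
            focus_intensity=float(kb.get("focus_intensity", 500.0)),
        )
        kdir = out / "kymographs"
        kdir.mkdir(parents=True, exist_ok=True)
        kymo.save(kdir / "kymo.tif")
        truth.to_json(kdir / "truth.json")
        log.info("simulated kymograph")
    for tb in cfg.get("traces", []) or []:
        tname = tb.get("name", tb["mode"])
        sim = _sim_config(tb.get("sim"), derive_seed(seed, "trace", tname))
        wlc = _dataclass_from(tb.get("wlc"), WLCParams, f"{tname}.wlc")
        cond = _dataclass_from(tb.get("condensate"), CondensateSpec, f"{tname}.condensate")
        trace, truth = generate_force_trace(sim, tb["mode"], wlc, cond, tb.get("params"))
        tdir = out / "traces"
        tdir.mkdir(parents=True, exist_ok=True)
        trace.save(tdir / f"{tname}.csv")
        truth.to_json(tdir / f"{tname}.truth.json")
        log.info("simulated trace %s", tname)


def _analyze(cfg: dict, out: Path) -> None:
    adir = out / "analysis"
    adir.mkdir(parents=True, exist_ok=True)
    rows = []
    movies_root = out / "movies"
    if movies_root.exists():
        for gdir in sorted(movies_root.iterdir()):
            for tdir in sorted(gdir.iterdir()):
                movie = TetherMovie.load(tdir)
                truth = GroundTruth.from_json(tdir / "truth.json")
                psf_nm = None
                if truth.pixel_size_nm:
                    psf_nm = 1.3 * truth.pixel_size_nm  # generator default PSF
                res = envelope.measure_envelope(movie, 0, deconvolve_psf_sigma_nm=psf_nm)
                t_cond = dynamics.detect_condensation_time(movie, 0)
                t_break = dynamics.detect_breakage(movie, 0)
                rows.append(
                    {
                        "group": gdir.name,
                        "tether": tdir.name,
                        "end_to_end_um": res.end_to_end_um,
                        "width_nm": res.width_nm,
                        "r2": res.r_squared,
                        "fit_ok": res.fit_ok,
                        "condensation_time_s": t_cond,
                        "breakage_time_s": t_break,
                    }
                )
        pd.DataFrame(rows).to_csv(adir / "envelope.csv", index=False)
    kfile = out / "kymographs" / "kymo.tif"
    if kfile.exists():
        kymo = dynamics.Kymograph.load(kfile)
        tracks = dynamics.track_foci_greedy(kymo)
        dynamics.tracks_to_frame(tracks).to_csv(adir / "tracks.csv", index=False)
        msd_rows = []
        for tr in tracks:
            if len(tr) < 50:  # short fragments give unreliable D estimates
                continue
            try:
                m = dynamics.msd_analysis(tr)
            except ValueError:
                continue
            msd_rows.append(
                {
                    "track_id": tr.track_id,
                    "D_um2_s": m.D_um2_s,
                    "r2": m.r_squared,
                    "accepted": m.accepted,
                }
            )
        pd.DataFrame(msd_rows).to_csv(adir / "msd.csv", index=False)
    traces_root = out / "traces"
    if traces_root.exists():
        trace_results = {}
        for tfile in sorted(traces_root.glob("*.csv")):
            trace = ForceTrace.load(tfile)
            entry: dict = {"mode": trace.mode}
            if trace.mode in ("passive", "clamp"):
                pl = tweezers.detect_plateau(trace)
                entry |= {
                    "plateau_pN": pl.plateau_force_pN,
                    "onset_s": pl.onset_time_s,
                    "plateau_censored": pl.censored,
                }
            if trace.mode == "clamp":
                cl = tweezers.analyze_clamp(trace)
                entry |= {
                    "contraction_um": cl.total_contraction_um,
                    "contraction_velocity_um_s": cl.contraction_velocity_um_s,
                }
            if trace.mode == "pulling":
                evs = tweezers.detect_transitions(trace)
                entry["transitions"] = [dataclasses.asdict(e) for e in evs]
            trace_results[tfile.stem] = entry
        (adir / "traces.json").write_text(json.dumps(trace_results, indent=1, default=float))


def _report(cfg: dict, out: Path) -> dict:
    adir = out / "analysis"
    summary: dict = {}
    env_csv = adir / "envelope.csv"
    if env_csv.exists():
        df = pd.read_csv(env_csv)
        ok = df[df.fit_ok.astype(bool)]
        summary["envelope"] = {
            g: {
                "n": int(len(sub)),
                "mean_width_nm": float(sub.width_nm.mean()),
                "sd_width_nm": float(sub.width_nm.std(ddof=1)) if len(sub) > 1 else None,
            }
            for g, sub in ok.groupby("group")
        }
        cond = df.dropna(subset=["condensation_time_s"])
        if len(cond) >= 4:
            st = dynamics.condensation_stat(cond.condensation_time_s.tolist())
            summary["condensation"] = {
                "t25_s": st.t25_s,
                "t75_s": st.t75_s,
                "t_condense_s": st.t_condense_s,
                "n": int(len(cond)),
            }
        summary["breakage"] = {
            g: {
                "n_broken": int(sub.breakage_time_s.notna().sum()),
                "n_total": int(len(sub)),
            }
            for g, sub in df.groupby("group")
        }
    msd_csv = adir / "msd.csv"
    if msd_csv.exists():
        m = pd.read_csv(msd_csv)
        if len(m):
            acc = m[m.accepted.astype(bool)]
            summary["mobility"] = {
                "n_tracks": int(len(m)),
                "n_accepted": int(len(acc)),
                "median_D_um2_s": float(acc.D_um2_s.median()) if len(acc) else None,
            }
    traces_json = adir / "traces.json"
    if traces_json.exists():
        summary["tweezers"] = json.loads(traces_json.read_text())
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=float))
    return summary


def run_pipeline(
    config: str | Path | dict,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> dict:
    """Run the requested stages and return the summary report.

    ``out_dir`` and ``seed`` override the configuration values.  Stage
    outputs are reused on re-runs only when the relevant configuration block
    is unchanged (content-hash check) -- stale intermediates are recomputed,
    never silently reused.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg.get("out_dir", "tetherquant_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else cfg.get("seed", 0))
    stages = cfg.get("stages", list(STAGES))
    bad = set(stages) - set(STAGES)
    if bad:
        raise ConfigError(f"unknown stage(s) {sorted(bad)}")
    (out / "config.yaml").write_text(yaml.safe_dump(cfg | {"seed": seed}, sort_keys=False))

    sim_hash = _block_hash(
        {"seed": seed, "movies": cfg.get("movies"), "kymograph": cfg.get("kymograph"), "traces": cfg.get("traces")}
    )
    if "simulate" in stages:
        if _stage_fresh(out, sim_hash):
            log.info("simulate: outputs up to date, skipping")
        else:
            _simulate(cfg, out, seed)
            _mark_stage(out, sim_hash)
    if "analyze" in stages:
        _analyze(cfg, out)
    summary: dict = {}
    if "report" in stages:
        summary = _report(cfg, out)
    return summary
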