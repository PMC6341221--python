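"""Configuration-driven orchestration: simulate -> import/edit -> metrics -> report.

A run is declared as a YAML/JSON config with an ordered ``stages`` list.
Each stage names its kind and parameters; unknown keys are rejected
before any computation so a typo cannot silently fall back to a default.
A single root seed is expanded into per-stage child seeds
deterministically, so any stage can be re-run in isolation and two runs
with the same config and seed produce identical numeric output.  The
report records the package version, the config hash, effective
parameters, and per-stage summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .field import FieldSpec
from .foci import analyze_foci_stack, fit_timecourses
from .kinetics import TrackSet, extract_dwells, fit_dlat, fit_survival, msd_curve
from .metrics import PointPattern, summarize_network, summarize_pattern
from .network_io import (
    fuse_junctions,
    parse_soax,
    prune_snakes,
    read_network_json,
    write_network_json,
)
from . import synthetic

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a run configuration fails validation."""


_STAGE_KEYS = {
    "simulate_pattern": {"name", "stage", "kind", "density", "parent_density",
                         "mean_offspring", "cluster_sd", "jitter_sd", "field"},
    "simulate_dwells": {"name", "stage", "components", "n", "frame_interval", "window",
                        "field"},
    "simulate_tracks": {"name", "stage", "D", "n_tracks", "n_frames", "frame_interval",
                        "loc_noise_sd", "field"},
    "simulate_foci": {"name", "stage", "foci", "background", "noise", "field"},
    "import_soax": {"name", "stage", "path", "pixel_size", "c", "fuse", "fuse_factor",
                    "prune_min_length", "prune_min_intensity"},
    "analyze_pattern": {"name", "stage", "source", "area_mode", "guard"},
    "analyze_network": {"name", "stage", "source", "path", "delta_s", "area_mode",
                        "background"},
    "analyze_foci": {"name", "stage", "source", "times", "intensity_threshold",
                     "min_area"},
    "analyze_tracks": {"name", "stage", "source", "threshold_frames", "model",
                       "min_frames", "max_lag", "fit_lags"},
}


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    allowed_top = {"seed", "out_dir", "log_level", "stages"}
    unknown = set(cfg) - allowed_top
    if unknown:
        raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
    stages = cfg.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigError("config needs a non-empty 'stages' list")
    for i, st in enumerate(stages):
        if not isinstance(st, dict) or "stage" not in st:
            raise ConfigError(f"stage {i} must be a mapping with a 'stage' key")
        kind = st["stage"]
        if kind not in _STAGE_KEYS:
            raise ConfigError(f"stage {i}: unknown stage kind {kind!r}")
        unknown = set(st) - _STAGE_KEYS[kind]
        if unknown:
            raise ConfigError(f"stage {i} ({kind}): unknown keys {sorted(unknown)}")


def config_hash(cfg: dict) -> str:
    canon = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _field_from(cfg_field: dict | None, seed: int) -> FieldSpec:
    d = dict(cfg_field or {"width": 50.0, "height": 50.0})
    d["seed"] = seed
    return FieldSpec.from_dict(d)


def run_pipeline(cfg: dict, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in order and return the run report.

    Intermediates are written under ``out_dir`` when given.  Stage
    failures abort the run with the stage name in the exception message.
    """
    validate_config(cfg)
    seed = int(cfg.get("seed", 0))
    out = Path(out_dir or cfg.get("out_dir", ".")) if (out_dir or cfg.get("out_dir")) else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    child_seeds = [int(s.generate_state(1)[0] % (2**31))
                   for s in np.random.SeedSequence(seed).spawn(len(cfg["stages"]))]

    objects: dict[str, object] = {}
    report: dict = {
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": seed,
        "stage_seeds": child_seeds,
        "stages": {},
    }
    for i, st in enumerate(cfg["stages"]):
        name = st.get("name", f"{st['stage']}_{i}")
        try:
            summary = _run_stage(st, child_seeds[i], objects, name, out)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} ({st['stage']}) failed: {exc}") from exc
        report["stages"][name] = summary
        log.info("stage %s done", name)
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def _resolve_source(st: dict, objects: dict, expected: str):
    src = st.get("source")
    if src is None:
        # default to the most recent object of the expected kind
        for key in reversed(list(objects)):
            if objects[key][0] == expected:
                return objects[key][1]
        raise ConfigError(f"no upstream {expected} stage found and no 'source' given")
    if src in objects:
        return objects[src][1]
    raise ConfigError(f"unknown source {src!r}")


def _run_stage(st: dict, seed: int, objects: dict, name: str, out: Path | None) -> dict:
    kind = st["stage"]
    if kind == "simulate_pattern":
        field = _field_from(st.get("field"), seed)
        pk = st.get("kind", "poisson")
        if pk == "poisson":
            pat = synthetic.gen_poisson_pattern(st["density"], field)
        elif pk == "clustered":
            pat = synthetic.gen_clustered_pattern(
                st["parent_density"], st["mean_offspring"], st["cluster_sd"], field
            )
        elif pk == "hexagonal":
            pat = synthetic.gen_hexagonal_pattern(
                st["density"], field, jitter_sd=st.get("jitter_sd", 0.0)
            )
        else:
            raise ConfigError(f"unknown pattern kind {pk!r}")
        objects[name] = ("pattern", pat)
        if out is not None:
            synthetic.write_pattern_csv(pat, out / f"{name}.csv")
        return {"n_points": len(pat), "ground_truth": pat.ground_truth}

    if kind == "simulate_dwells":
        field = _field_from(st.get("field"), seed)
        dw = synthetic.gen_dwell_times(
            [tuple(c) for c in st["components"]],
            st["n"],
            field,
            frame_interval=st.get("frame_interval", 0.05),
            window=st.get("window", 20.0),
        )
        objects[name] = ("dwells", dw)
        if out is not None:
            synthetic.write_dwells_csv(dw, out / f"{name}.csv")
        return {"n": len(dw), "n_censored": int(dw.censored.sum()),
                "ground_truth": dw.ground_truth}

    if kind == "simulate_tracks":
        field = _field_from(st.get("field"), seed)
        tr = synthetic.gen_tracks(
            st["D"],
            st["n_tracks"],
            st["n_frames"],
            field,
            frame_interval=st.get("frame_interval", 0.05),
            loc_noise_sd=st.get("loc_noise_sd", 0.0),
        )
        objects[name] = ("tracks", tr)
        if out is not None:
            synthetic.write_tracks_csv(tr, out / f"{name}.csv")
        return {"n_tracks": len(tr), "ground_truth": tr.ground_truth}

    if kind == "simulate_foci":
        field = _field_from(st.get("field"), seed)
        foci = [((f[0], f[1]), f[2], f[3]) for f in st["foci"]]
        img, gt = synthetic.gen_foci_image(
            foci, field, background=st.get("background", 100.0), noise=st.get("noise", False)
        )
        objects[name] = ("image", (img, field, gt))
        if out is not None:
            synthetic.write_image_tiff(img, out / f"{name}.tif", field, gt)
        return {"n_foci": gt["n_foci"], "overlapping": gt["overlapping"]}

    if kind == "import_soax":
        net = parse_soax(st["path"], pixel_size=st["pixel_size"], c=st.get("c", 0.625))
        if st.get("fuse", True):
            net = fuse_junctions(net, factor=st.get("fuse_factor", 1.2))
        if "prune_min_length" in st or "prune_min_intensity" in st:
            net = prune_snakes(net, st.get("prune_min_length", 0.0),
                               st.get("prune_min_intensity", 0.0))
        objects[name] = ("network", net)
        if out is not None:
            write_network_json(net, out / f"{name}.json")
        return {"n_snakes": len(net.snakes), "n_junctions": len(net.junctions)}

    if kind == "analyze_pattern":
        pat = _resolve_source(st, objects, "pattern")
        summ = summarize_pattern(pat, area_mode=st.get("area_mode", "field"),
                                 guard=st.get("guard"))
        objects[name] = ("summary", summ)
        if out is not None:
            (out / f"{name}.json").write_text(json.dumps(summ.to_dict(), indent=1,
                                                         default=float))
        return summ.to_dict()

    if kind == "analyze_network":
        if "path" in st:
            net = read_network_json(st["path"])
        else:
            net = _resolve_source(st, objects, "network")
        summ = summarize_network(net, background=st.get("background", 0.0),
                                 delta_s=st.get("delta_s"),
                                 area_mode=st.get("area_mode", "field"))
        objects[name] = ("summary", summ)
        if out is not None:
            (out / f"{name}.json").write_text(json.dumps(summ.to_dict(), indent=1,
                                                         default=float))
        return summ.to_dict()

    if kind == "analyze_foci":
        img, field, gt = _resolve_source(st, objects, "image")
        stack = img[None] if img.ndim == 2 else img
        times = np.asarray(st.get("times", np.arange(len(stack), dtype=float)))
        res = analyze_foci_stack(stack, times, field,
                                 intensity_threshold=st.get("intensity_threshold", "auto"),
                                 min_area=st.get("min_area", 50.0))
        summary = {
            "n_foci": res["n_foci"].tolist(),
            "sum_Q_foci": res["sum_Q_foci"].tolist(),
            "R": res["R"].tolist(),
        }
        if len(times) >= 4:
            summary["fits"] = fit_timecourses(times, r_values=res["R"],
                                              q_values=res["sum_Q_foci"])
        objects[name] = ("foci_series", res)
        return summary

    if kind == "analyze_tracks":
        tr = _resolve_source(st, objects, "tracks")
        dwells, bound = extract_dwells(tr, threshold_frames=st.get("threshold_frames", 6))
        summary: dict = {"n_dwells": len(dwells), "bound_fraction": bound}
        model = st.get("model")
        if model:
            try:
                fit = fit_survival(dwells, model=model, min_frames=st.get("min_frames"),
                                   seed=seed)
                summary["survival"] = fit.to_dict()
            except ValueError as exc:
                summary["survival"] = {"error": str(exc)}
        curve = fit_dlat(msd_curve(tr, max_lag=st.get("max_lag", 10)),
                         fit_lags=st.get("fit_lags", 4))
        summary["D_lat"] = curve.D_lat
        summary["msd_offset"] = curve.offset
        objects[name] = ("kinetics", (dwells, curve))
        if out is not None:
            curve.to_frame().to_csv(out / f"{name}_msd.csv", index=False)
        return summary

    raise ConfigError(f"unhandled stage kind {kind!r}")


__all__ = ["ConfigError", "load_config", "validate_config", "config_hash", "run_pipeline"]
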