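"""Config-driven pipeline runner.

A run is described by a small YAML/JSON config:

.. code-block:: yaml

    out_dir: results/demo
    stages:
      - stage: synth_volume
        name: phantom
        seed: 11
        params: {striola_width_um: 30.0, striola_depth: 0.7}
      - stage: ct_quant
        name: quant
        inputs: {volume: phantom_volume.nii,
                 otolith_roi: phantom_otolith_roi.nii,
                 tissue_roi: phantom_tissue_roi.nii}

Stages execute in order; every randomized stage must carry an explicit seed
(reproducibility is not optional). The whole config is validated — stage
names, seeds, input availability — before any computation starts. Each
stage writes CSV/JSON outputs under ``out_dir``; the run ends with a
``summary.json`` and a ``run_log.json`` recording versions, seeds and
parameters. Two runs with the same config and seeds produce byte-identical
outputs.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from . import ct_morphometry as ct
from . import em_morphometry as em
from . import group_stats as gs
from . import io_formats as io
from . import lvor_analysis as lvor
from . import synthetic as synth
from .types import ConfigurationError, RoiPair

RANDOMIZED_STAGES = {
    "synth_volume",
    "synth_sled",  # deterministic today, but declared randomized so configs stay stable
    "synth_eye",
    "synth_layer_points",
    "synth_cohort",
}

_STAGE_INPUTS = {
    "synth_volume": (),
    "synth_sled": (),
    "synth_eye": ("sled",),
    "synth_layer_points": (),
    "synth_cohort": (),
    "ct_quant": ("volume", "otolith_roi", "tissue_roi"),
    "edge_volume": ("volume", "otolith_roi", "tissue_roi"),
    "layer_angle": ("points",),
    "lvor_index": ("sled", "eye"),
    "stats": ("cohort",),
}


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _validate(config: dict, out_dir: Path) -> list[dict]:
    stages = config.get("stages")
    if not isinstance(stages, list) or not stages:
        raise ConfigurationError("config must contain a non-empty 'stages' list")
    produced: set[str] = set()
    for i, st in enumerate(stages):
        if "stage" not in st:
            raise ConfigurationError(f"stage #{i} has no 'stage' key")
        kind = st["stage"]
        if kind not in _STAGE_INPUTS:
            raise ConfigurationError(f"unknown stage {kind!r}")
        if kind in RANDOMIZED_STAGES and "seed" not in st:
            raise ConfigurationError(
                f"stage {kind!r} is randomized and requires an explicit 'seed'"
            )
        inputs = st.get("inputs", {})
        for key in _STAGE_INPUTS[kind]:
            if key not in inputs:
                raise ConfigurationError(f"stage {kind!r} is missing input {key!r}")
            ref = inputs[key]
            if ref in produced:
                continue
            p = Path(ref)
            if not p.is_absolute():
                p = out_dir / ref
            if not p.exists():
                raise ConfigurationError(
                    f"stage {kind!r}: input {key!r} -> {ref!r} does not exist and is "
                    "not produced by an earlier stage"
                )
        name = st.get("name", kind)
        # register the files each stage will produce, for forward references
        produced.update(_declared_outputs(kind, name))
    return stages


def _declared_outputs(kind: str, name: str) -> list[str]:
    return {
        "synth_volume": [
            f"{name}_volume.nii",
            f"{name}_otolith_roi.nii",
            f"{name}_tissue_roi.nii",
            f"{name}_ground_truth.json",
        ],
        "synth_sled": [f"{name}.csv"],
        "synth_eye": [f"{name}.csv"],
        "synth_layer_points": [f"{name}.csv"],
        "synth_cohort": [f"{name}.csv"],
        "ct_quant": [f"{name}_thresholds.csv", f"{name}_morphometry.csv", f"{name}_mask.nii"],
        "edge_volume": [f"{name}_edge.csv", f"{name}_edge_mask.nii"],
        "layer_angle": [f"{name}.json"],
        "lvor_index": [f"{name}_cycles.csv", f"{name}.json"],
        "stats": [f"{name}_anova.csv", f"{name}.json"],
    }[kind]


def _resolve(ref: str, out_dir: Path) -> Path:
    p = Path(ref)
    return p if p.is_absolute() else out_dir / ref


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute a configured pipeline; returns the summary dict."""
    if not isinstance(config, dict):
        config = io.read_config(config)
    out = Path(out_dir) if out_dir is not None else Path(config.get("out_dir", "otokit_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = _validate(config, out)

    summary: dict = {}
    log: dict = {
        "versions": {
            "otokit": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stages": [],
    }
    for st in stages:
        kind = st["stage"]
        name = st.get("name", kind)
        params = dict(st.get("params", {}))
        inputs = {k: _resolve(v, out) for k, v in st.get("inputs", {}).items()}
        result = _RUNNERS[kind](out, name, params, inputs, st.get("seed"))
        summary[name] = result
        log["stages"].append(
            {"stage": kind, "name": name, "seed": st.get("seed"), "params": params}
        )

    _write_json(out / "summary.json", summary)
    _write_json(out / "run_log.json", log)
    return summary


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _run_synth_volume(out, name, params, inputs, seed):
    p = synth.PhantomParams(**params, seed=seed)
    vol, rois, truth = synth.gen_ct_phantom(p)
    io.write_volume(out / f"{name}_volume.nii", vol)
    io.write_mask(out / f"{name}_otolith_roi.nii", rois.otolith_roi, vol.meta)
    io.write_mask(out / f"{name}_tissue_roi.nii", rois.tissue_roi, vol.meta)
    truth_info = {
        "volume_um3": truth.volume_um3,
        "mean_ct": truth.mean_ct,
        "otolith_voxels": int(truth.otolith_mask.sum()),
        "striola_voxels": int(truth.striola_mask.sum()),
    }
    _write_json(out / f"{name}_ground_truth.json", truth_info)
    return truth_info


def _run_synth_sled(out, name, params, inputs, seed):
    level = params.pop("level", None)
    if level == "1.3G":
        p = synth.SledParams.level_1_3g(**params)
    elif level == "0.7G":
        p = synth.SledParams.level_0_7g(**params)
    else:
        p = synth.SledParams(**params)
    sled = synth.gen_sled_trace(p)
    io.write_trace(out / f"{name}.csv", io.sled_trace_frame(sled))
    return {
        "samples": len(sled.t),
        "max_abs_accel_mm_s2": float(np.max(np.abs(sled.acceleration_mm_s2))),
        "max_abs_vel_mm_s": float(np.max(np.abs(sled.velocity_mm_s))),
    }


def _load_sled(path: Path) -> "synth.SledTrace":
    df = io.read_trace(path)
    from .types import SledTrace

    return SledTrace(
        t=df["t_s"].to_numpy(float),
        position_mm=df["position_mm"].to_numpy(float),
        velocity_mm_s=df["velocity_mm_s"].to_numpy(float),
        acceleration_mm_s2=df["acceleration_mm_s2"].to_numpy(float),
        rate_hz=df.attrs["rate_hz"],
    )


def _run_synth_eye(out, name, params, inputs, seed):
    sled = _load_sled(inputs["sled"])
    p = synth.EyeModelParams(**params, seed=seed)
    eye = synth.gen_eye_trace(sled, p)
    io.write_trace(out / f"{name}.csv", io.eye_trace_frame(eye))
    return {"samples": len(eye.t)}


def _run_synth_layer_points(out, name, params, inputs, seed):
    les, base = synth.gen_layer_points(seed=seed, **params)
    io.write_layer_points(out / f"{name}.csv", les, base)
    return {"n_points": int(len(les))}


def _run_synth_cohort(out, name, params, inputs, seed):
    n = params.pop("n_per_cell", 10)
    if params:
        raise ConfigurationError(f"unknown synth_cohort params: {sorted(params)}")
    cohort = synth.gen_cohort(synth.default_cohort_effects(n_per_cell=n, seed=seed))
    io.write_cohort(out / f"{name}.csv", cohort)
    return {"records": len(cohort)}


def _run_ct_quant(out, name, params, inputs, seed):
    vol, meta = io.read_volume(inputs["volume"])
    rois = RoiPair(io.read_mask(inputs["otolith_roi"]), io.read_mask(inputs["tissue_roi"]))
    thr = ct.compute_threshold(vol, rois, summary=params.get("summary", "mean"))
    seg = ct.segment_otolith(vol, rois.otolith_roi, thr.threshold, params.get("keep_largest", True))
    morph = ct.quantify(vol, seg, meta)
    pd.DataFrame(
        [
            {
                "alpha": thr.alpha,
                "beta": thr.beta,
                "threshold": thr.threshold,
                "edge_lower": thr.edge_lower,
            }
        ]
    ).to_csv(out / f"{name}_thresholds.csv", index=False)
    pd.DataFrame(
        [
            {
                "volume_voxels": morph.volume_voxels,
                "volume_um3": morph.volume_um3,
                "mean_ct": morph.mean_ct,
            }
        ]
    ).to_csv(out / f"{name}_morphometry.csv", index=False)
    io.write_mask(out / f"{name}_mask.nii", seg, meta)
    return {"volume_um3": morph.volume_um3, "mean_ct": morph.mean_ct}


def _run_edge_volume(out, name, params, inputs, seed):
    vol, meta = io.read_volume(inputs["volume"])
    rois = RoiPair(io.read_mask(inputs["otolith_roi"]), io.read_mask(inputs["tissue_roi"]))
    thr = ct.compute_threshold(vol, rois, summary=params.get("summary", "mean"))
    res = ct.striola_edge_volume(vol, rois.otolith_roi, thr, params.get("keep_largest", True))
    pd.DataFrame(
        [{"edge_voxels": res.edge_voxels, "edge_volume_um3": res.edge_volume_um3}]
    ).to_csv(out / f"{name}_edge.csv", index=False)
    io.write_mask(out / f"{name}_edge_mask.nii", res.edge_mask, meta)
    return {"edge_volume_um3": res.edge_volume_um3}


def _run_layer_angle(out, name, params, inputs, seed):
    trace = io.read_layer_points(inputs["points"])
    res = em.layer_angle(trace)
    info = {
        "angle_deg": res.angle_deg,
        "les_rms_um": res.les_rms_um,
        "base_rms_um": res.base_rms_um,
    }
    _write_json(out / f"{name}.json", info)
    return info


def _run_lvor_index(out, name, params, inputs, seed):
    sled = _load_sled(inputs["sled"])
    eye = io.read_eye_trace(inputs["eye"])
    cycles = lvor.segment_cycles(
        sled,
        v_dwell_mm_s=params.get("v_dwell_mm_s", 20.0),
        min_dwell_s=params.get("min_dwell_s", 0.25),
    )
    res = lvor.otolith_function_index(eye, cycles, params.get("exclude_dwells", False))
    labels = lvor.orient_run(
        params.get("orientation", "lateral"), params.get("accel_level", "1.3G")
    )
    pd.DataFrame(
        {"cycle": range(1, len(res.per_cycle) + 1), "index_deg": res.per_cycle}
    ).to_csv(out / f"{name}_cycles.csv", index=False)
    info = {
        "index_deg": res.index,
        "baseline_deg": res.baseline_deg,
        "n_cycles": len(res.per_cycle),
        **labels,
    }
    _write_json(out / f"{name}.json", info)
    return info


def _run_stats(out, name, params, inputs, seed):
    cohort = io.read_cohort(inputs["cohort"])
    measurements = params.get("measurements") or sorted(cohort["measurement"].unique())
    rows = []
    info = {}
    for m in measurements:
        res = gs.analyze_measurement(
            cohort, m, posthoc=params.get("posthoc", "auto"), family=params.get("family", 6)
        )
        a = res["anova"]
        rows.append(
            {
                "measurement": m,
                "f_age": a.f["age"],
                "p_age": a.p["age"],
                "f_sex": a.f["sex"],
                "p_sex": a.p["sex"],
                "f_interaction": a.f["interaction"],
                "p_interaction": a.p["interaction"],
                "n": a.n,
                "shapiro_p": res["normality"].shapiro_p,
                "ks_p": res["normality"].ks_p,
            }
        )
        info[m] = {"p_age": a.p["age"], "p_sex": a.p["sex"], "p_interaction": a.p["interaction"]}
        if res["posthoc"] is not None:
            res["posthoc"].to_csv(out / f"{name}_{m}_posthoc.csv", index=False)
    pd.DataFrame(rows).to_csv(out / f"{name}_anova.csv", index=False)
    _write_json(out / f"{name}.json", info)
    return info


_RUNNERS = {
    "synth_volume": _run_synth_volume,
    "synth_sled": _run_synth_sled,
    "synth_eye": _run_synth_eye,
    "synth_layer_points": _run_synth_layer_points,
    "synth_cohort": _run_synth_cohort,
    "ct_quant": _run_ct_quant,
    "edge_volume": _run_edge_volume,
    "layer_angle": _run_layer_angle,
    "lvor_index": _run_lvor_index,
    "stats": _run_stats,
}


def demo_config(seed: int = 0) -> dict:
    """A full end-to-end demo configuration exercising every stage."""
    return {
        "stages": [
            {
                "stage": "synth_volume",
                "name": "phantom",
                "seed": seed,
                "params": {"striola_width_um": 30.0, "striola_depth": 0.9},
            },
            {
                "stage": "ct_quant",
                "name": "quant",
                "inputs": {
                    "volume": "phantom_volume.nii",
                    "otolith_roi": "phantom_otolith_roi.nii",
                    "tissue_roi": "phantom_tissue_roi.nii",
                },
            },
            {
                "stage": "edge_volume",
                "name": "edge",
                "inputs": {
                    "volume": "phantom_volume.nii",
                    "otolith_roi": "phantom_otolith_roi.nii",
                    "tissue_roi": "phantom_tissue_roi.nii",
                },
            },
            {"stage": "synth_sled", "name": "sled", "seed": seed, "params": {"level": "1.3G"}},
            {
                "stage": "synth_eye",
                "name": "eye",
                "seed": seed + 1,
                "inputs": {"sled": "sled.csv"},
                "params": {"gain_deg_per_g": 2.0, "noise_sd_deg": 0.05},
            },
            {
                "stage": "lvor_index",
                "name": "lvor",
                "inputs": {"sled": "sled.csv", "eye": "eye.csv"},
                "params": {"orientation": "lateral", "accel_level": "1.3G"},
            },
            {
                "stage": "synth_layer_points",
                "name": "layer_points",
                "seed": seed + 2,
                "params": {"angle_deg": 37.0, "n_points": 50, "noise_um": 0.5},
            },
            {
                "stage": "layer_angle",
                "name": "angle",
                "inputs": {"points": "layer_points.csv"},
            },
            {"stage": "synth_cohort", "name": "cohort", "seed": seed + 3},
            {"stage": "stats", "name": "stats", "inputs": {"cohort": "cohort.csv"}},
        ]
    }
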