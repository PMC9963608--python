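"""End-to-end pipeline: simulate → LUR → standardize → weights → index → LISA.

Each stage reads the previous stage's serialized artifacts from the
run directory and writes its own, so any stage can be re-run alone and
reproduce its outputs bit-identically.  A manifest records, per stage,
the parameters used and SHA-256 hashes of inputs and outputs.  All
randomness funnels from one config seed, fanned out per stage by fixed
offsets.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from airhealth import geoio, gridio
from airhealth.ahp import (
    CRITERION_INDICATORS,
    WeightScheme,
    consistency_gate,
    table3_scheme,
    weights_from_matrix,
)
from airhealth.geoio import INDICATOR_COLUMNS
from airhealth.health_index import (
    DEFAULT_ZONES,
    build_health_records,
    crosstab_zones,
    natural_breaks,
    quantile_breaks,
)
from airhealth.indicators import descriptive_stats, spearman_screen, standardize_frame
from airhealth.lur import DEFAULT_RADII, build_buffers, predict_surface, stepwise_fit, zonal_mean
from airhealth.spatial import local_morans, morans_i, queen_weights
from airhealth.synthetic import RegionConfig, generate_region

logger = logging.getLogger(__name__)

#: fixed per-stage seed offsets (all derived seeds stay below 2**31)
SEED_OFFSETS = {"region": 0, "lisa": 104729}

DEFAULT_CONFIG = {
    "seed": 0,
    "region": {},
    "lur": {"radii": list(DEFAULT_RADII), "p_enter": 0.05, "p_remove": 0.10, "min_r2": 0.90},
    "weights": {"source": "table3"},
    "index": {"threshold": 35.0, "erd_weighting": "criterion", "break_method": "natural", "k": 5},
    "lisa": {"permutations": 999, "alpha": 0.05},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return validate_config(doc)


def validate_config(doc: dict) -> dict:
    """Validate and normalise a pipeline config before any stage runs."""
    if not isinstance(doc, dict):
        raise PipelineError("config: document must be a mapping")
    for block in ("lur", "weights", "index", "lisa"):
        if block not in doc:
            raise PipelineError(f"config: missing required block '{block}'")
    if "region" not in doc and "inputs" not in doc:
        raise PipelineError("config: need a 'region' block (simulate) or an 'inputs' block")
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in doc.items():
        if isinstance(val, dict) and key in cfg:
            cfg[key].update(val)
        else:
            cfg[key] = val
    lur = cfg["lur"]
    if not (0 < lur["min_r2"] < 1):
        raise PipelineError("config: lur.min_r2 must lie in (0, 1)")
    if cfg["weights"].get("source") not in ("table3", "matrix"):
        raise PipelineError("config: weights.source must be 'table3' or 'matrix'")
    if cfg["weights"]["source"] == "matrix":
        mp = cfg["weights"].get("matrix_path")
        if not mp or not Path(mp).exists():
            raise PipelineError("config: weights.matrix_path missing or does not exist")
    if "inputs" in cfg:
        for k, p in cfg["inputs"].items():
            if not Path(p).exists():
                raise PipelineError(f"config: inputs.{k} path {p!r} does not exist")
    if cfg["index"]["break_method"] not in ("natural", "quantile"):
        raise PipelineError("config: index.break_method must be 'natural' or 'quantile'")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _hash_tree(paths: list[Path]) -> dict[str, str]:
    out = {}
    for p in sorted(paths):
        if p.is_dir():
            for f in sorted(p.rglob("*")):
                if f.is_file():
                    out[str(f)] = _sha256(f)
        elif p.is_file():
            out[str(p)] = _sha256(p)
    return out


def run_pipeline(config: dict, output_dir: str | Path) -> dict:
    """Execute all stages in order; return (and write) the run manifest."""
    cfg = validate_config(config)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = {"seed": seed, "stages": [], "warnings": []}

    def stage(name, params, inputs, fn):
        t0 = time.monotonic()
        try:
            outputs = fn()
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 — report the failing stage
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        manifest["stages"].append(
            {
                "stage": name,
                "params": params,
                "inputs": _hash_tree([Path(p) for p in inputs]),
                "outputs": _hash_tree([Path(p) for p in outputs]),
                "seconds": round(time.monotonic() - t0, 3),
            }
        )
        return outputs

    # ---- stage 1: obtain region (simulate or load) ----
    region_dir = out / "region"
    region_dir.mkdir(exist_ok=True)
    if "inputs" in cfg:
        units = geoio.units_from_geojson(cfg["inputs"]["units"])
        stations = geoio.stations_from_csv(cfg["inputs"]["stations"])
        surfaces = gridio.read_stack(cfg["inputs"]["surfaces"])
        geoio.validate_units(units)
    else:
        rc = RegionConfig(**{**cfg["region"], "seed": seed + SEED_OFFSETS["region"]})

        def _simulate():
            nonlocal units, stations, surfaces
            units, stations, surfaces, truth = generate_region(rc)
            geoio.units_to_geojson(units, region_dir / "units.geojson")
            geoio.stations_to_csv(stations, region_dir / "stations.csv")
            gridio.write_stack(surfaces, region_dir / "surfaces")
            truth.to_json(region_dir / "ground_truth.json")
            return [region_dir]

        units = stations = surfaces = None
        stage("simulate", {"seed": rc.seed, "n_units": rc.n_rows * rc.n_cols}, [], _simulate)

    # ---- stage 2: LUR ----
    lur_dir = out / "lur"
    lur_dir.mkdir(exist_ok=True)
    lur_cfg = cfg["lur"]
    model = None
    acp = None

    def _lur():
        nonlocal model, acp
        X = build_buffers(stations, surfaces, radii=lur_cfg["radii"])
        model = stepwise_fit(
            X, stations["pm25"].to_numpy(),
            p_enter=lur_cfg["p_enter"], p_remove=lur_cfg["p_remove"],
        )
        if not model.passes_gate(lur_cfg["min_r2"]):
            raise PipelineError(
                f"stage 'lur': model rejected — R² = {model.r2:.4f} does not exceed "
                f"the acceptance gate {lur_cfg['min_r2']:.2f}"
            )
        model.to_json(lur_dir / "model.json")
        surf = predict_surface(model, surfaces)
        gridio.write_grid(surf, lur_dir / "predicted_surface.txt")
        acp = zonal_mean(surf, units)
        acp.rename_axis("unit_id").to_csv(lur_dir / "acp.csv")
        return [lur_dir]

    stage("lur", lur_cfg, [region_dir], _lur)

    # ---- stage 3: indicators ----
    ind_dir = out / "indicators"
    ind_dir.mkdir(exist_ok=True)
    attrs = units.set_index("unit_id")[INDICATOR_COLUMNS]
    attrs_std = None

    def _indicators():
        nonlocal attrs_std
        screen = spearman_screen(attrs, acp.loc[attrs.index].to_numpy())
        screen.to_csv(ind_dir / "spearman.csv", index=False)
        attrs_std = standardize_frame(attrs)
        attrs_std.to_csv(ind_dir / "standardized.csv")
        desc = descriptive_stats(
            acp.loc[units["unit_id"]].to_numpy(), units["city"].to_numpy()
        )
        desc.to_csv(ind_dir / "descriptive.csv", index=False)
        return [ind_dir]

    stage("indicators", {}, [region_dir, lur_dir], _indicators)

    # ---- stage 4: weights ----
    w_dir = out / "weights"
    w_dir.mkdir(exist_ok=True)
    scheme = None

    def _weights():
        nonlocal scheme
        if cfg["weights"]["source"] == "table3":
            scheme = table3_scheme()
        else:
            A = np.loadtxt(cfg["weights"]["matrix_path"], delimiter=",")
            w, _, cr = weights_from_matrix(A)
            if not consistency_gate(cr):
                raise PipelineError(
                    f"stage 'weights': judgment matrix failed consistency (CR={cr:.4f})"
                )
            base = table3_scheme()
            crit = dict(zip(base.criterion_weights, w))
            # rescale the fixed indicator split under each criterion
            ind = {}
            for c, names in CRITERION_INDICATORS.items():
                sub = {k: base.indicator_weights[k] for k in names}
                s = sum(sub.values())
                for k, v in sub.items():
                    ind[k] = v / s * crit[c]
            scheme = WeightScheme(criterion_weights=crit, indicator_weights=ind,
                                  consistency_ratio=cr)
        scheme.to_json(w_dir / "scheme.json")
        return [w_dir]

    stage("weights", cfg["weights"], [], _weights)

    # ---- stage 5: health index + zoning ----
    idx_dir = out / "index"
    idx_dir.mkdir(exist_ok=True)
    icfg = cfg["index"]
    health = None

    def _index():
        nonlocal health
        health = build_health_records(
            acp.loc[attrs.index], attrs_std, scheme,
            threshold=icfg["threshold"], erd_weighting=icfg["erd_weighting"],
        )
        health.rename_axis("unit_id").to_csv(idx_dir / "health.csv")
        cities = units.set_index("unit_id").loc[health.index, "city"]
        tab = crosstab_zones(health["zone"].to_numpy(), cities.to_numpy())
        tab.to_csv(idx_dir / "crosstab.csv")
        breaker = natural_breaks if icfg["break_method"] == "natural" else quantile_breaks
        breaks = breaker(health["ahp"].to_numpy(), icfg["k"])
        (idx_dir / "ahp_breaks.json").write_text(json.dumps({"k": icfg["k"], "breaks": breaks}))
        export = units.merge(health.reset_index(), on="unit_id")
        geoio.units_to_geojson(export, idx_dir / "health.geojson")
        return [idx_dir]

    stage("index", icfg, [lur_dir, ind_dir, w_dir], _index)

    # ---- stage 6: spatial autocorrelation ----
    lisa_dir = out / "lisa"
    lisa_dir.mkdir(exist_ok=True)
    scfg = cfg["lisa"]
    lisa_seed = seed + SEED_OFFSETS["lisa"]

    def _lisa():
        W = queen_weights(units)
        vals = acp.loc[units["unit_id"]].to_numpy()
        I, e_i, p = morans_i(vals, W, permutations=scfg["permutations"], seed=lisa_seed)
        (lisa_dir / "global_moran.json").write_text(
            json.dumps({"I": I, "expected_I": e_i, "pseudo_p": p,
                        "permutations": scfg["permutations"]})
        )
        lisa = local_morans(vals, W, permutations=scfg["permutations"],
                            alpha=scfg["alpha"], seed=lisa_seed)
        lisa.to_csv(lisa_dir / "lisa.csv", index=False)
        export = units.merge(lisa, on="unit_id")
        geoio.units_to_geojson(export, lisa_dir / "lisa.geojson")
        return [lisa_dir]

    stage("lisa", {**scfg, "seed": lisa_seed}, [region_dir, lur_dir], _lisa)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
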