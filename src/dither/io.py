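"""Serialization, configuration, and the end-to-end protocol runner.

Fixtures travel as HDF5 (arrays) plus an optional CSV sidecar (element
metadata); analysis outputs are CSV tables and JSON summaries; configuration
is YAML.  Every protocol run records the package version, a config hash, and
all seeds so reports are regenerable from their inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bounds import apply_pixelwise, fit_pixelwise_mapping
from .greedy import GreedyWorkspace, run_greedy
from .perceptual import joint_patch_optimize
from .protocols import (Fixture, checkerboard_bounds_study, default_fixture,
                        dynamic_jitter_study, fractional_error_increase,
                        make_natural_scene, subsampling_study)
from .synthetic import (CellPopulation, ElectrodeArray, ReconstructionFilter,
                        StimDictionary, make_checkerboard_targets)

__all__ = ["SCHEMA_VERSION", "SchemaError", "save_fixture", "load_fixture",
           "write_element_csv", "read_element_csv", "save_png", "load_image",
           "run_protocol"]

log = logging.getLogger("dither")

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Raised when a fixture file does not match the expected schema version."""


def save_fixture(path, fixture: Fixture) -> None:
    """Write a fixture to HDF5 (datasets /A, /D, /v, /electrode_xy, metadata)."""
    arr, pop, filt, dic = (fixture.array, fixture.population,
                           fixture.filters, fixture.dictionary)
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["package_version"] = __version__
        f.create_dataset("A", data=filt.A)
        f.create_dataset("D", data=dic.D)
        f.create_dataset("v", data=dic.v)
        f.create_dataset("electrode_xy", data=arr.positions)
        f["A"].attrs["grid_shape"] = filt.grid_shape
        f["A"].attrs["pixel_pitch_um"] = filt.pixel_pitch_um
        f["electrode_xy"].attrs["rows"] = arr.rows
        f["electrode_xy"].attrs["cols"] = arr.cols
        f["electrode_xy"].attrs["pitch_um"] = arr.pitch_um
        g = f.create_group("cell_meta")
        g.create_dataset("ids", data=pop.ids)
        g.create_dataset("types", data=pop.types)
        g.create_dataset("rf_center_um", data=pop.rf_center_um)
        g.create_dataset("rf_radius_um", data=pop.rf_radius_um)
        g.create_dataset("soma_um", data=pop.soma_um)
        g.create_dataset("gain", data=pop.gain)
        e = f.create_group("element_meta")
        e.create_dataset("electrode", data=dic.electrode)
        e.create_dataset("amplitude_uA", data=dic.amplitude_uA)
        e.create_dataset("amplitudes_uA", data=dic.amplitudes_uA)
        for col in ("element_id", "electrode_id", "amplitude_uA",
                    "axon_bundle", "retained"):
            e.create_dataset(f"candidates/{col}",
                             data=dic.candidates[col].to_numpy())


def load_fixture(path) -> Fixture:
    """Read a fixture written by :func:`save_fixture`; bit-identical arrays."""
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"fixture schema version {version!r} (expected {SCHEMA_VERSION})")
        required = ["A", "D", "v", "electrode_xy", "cell_meta", "element_meta"]
        missing = [k for k in required if k not in f]
        if missing:
            raise SchemaError(f"fixture file lacks datasets: {missing}")
        arr = ElectrodeArray(
            positions=f["electrode_xy"][()],
            rows=int(f["electrode_xy"].attrs["rows"]),
            cols=int(f["electrode_xy"].attrs["cols"]),
            pitch_um=float(f["electrode_xy"].attrs["pitch_um"]))
        g = f["cell_meta"]
        pop = CellPopulation(
            ids=g["ids"][()], types=g["types"][()],
            rf_center_um=g["rf_center_um"][()],
            rf_radius_um=g["rf_radius_um"][()],
            soma_um=g["soma_um"][()], gain=g["gain"][()])
        filt = ReconstructionFilter(
            A=f["A"][()],
            grid_shape=tuple(int(x) for x in f["A"].attrs["grid_shape"]),
            pixel_pitch_um=float(f["A"].attrs["pixel_pitch_um"]))
        e = f["element_meta"]
        candidates = pd.DataFrame(
            {col: e[f"candidates/{col}"][()]
             for col in ("element_id", "electrode_id", "amplitude_uA",
                         "axon_bundle", "retained")})
        dic = StimDictionary(
            D=f["D"][()], v=f["v"][()], electrode=e["electrode"][()],
            amplitude_uA=e["amplitude_uA"][()],
            electrode_positions=arr.positions.copy(),
            amplitudes_uA=e["amplitudes_uA"][()], candidates=candidates)
    return Fixture(arr, pop, filt, dic)


def write_element_csv(path, dictionary: StimDictionary) -> None:
    """CSV sidecar with the full candidate-element metadata."""
    cols = ["element_id", "electrode_id", "amplitude_uA", "axon_bundle", "retained"]
    dictionary.candidates[cols].to_csv(path, index=False)


def read_element_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["axon_bundle"] = df["axon_bundle"].astype(bool)
    df["retained"] = df["retained"].astype(bool)
    return df


def save_png(path, image: np.ndarray) -> None:
    """8-bit grayscale PNG export; the linear min/max mapping is recorded
    in a JSON sidecar so the export is invertible."""
    from PIL import Image

    img = np.asarray(image, dtype=float)
    finite = np.isfinite(img)
    lo = float(img[finite].min()) if finite.any() else 0.0
    hi = float(img[finite].max()) if finite.any() else 1.0
    scale = (hi - lo) or 1.0
    u8 = np.zeros_like(img, dtype=np.uint8)
    u8[finite] = np.clip((img[finite] - lo) / scale * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(u8, mode="L").save(path)
    Path(str(path) + ".json").write_text(json.dumps({"min": lo, "max": hi}))


def load_image(path) -> np.ndarray:
    """Load a grayscale image (.npy, .png, ...) as floats scaled to [-1, 1]."""
    p = Path(path)
    if p.suffix == ".npy":
        return np.load(p).astype(float)
    from PIL import Image

    img = np.asarray(Image.open(p).convert("L"), dtype=float)
    return img / 127.5 - 1.0


# ---------------------------------------------------------------------------
# protocol runner
# ---------------------------------------------------------------------------

def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()).hexdigest()[:16]


def run_protocol(config) -> dict:
    """Execute the configured pipeline stages and write a report bundle.

    ``config`` is a dict or a YAML path with keys: ``seed`` (int), ``out_dir``
    (path) and ``stages`` (list drawn from generate, encode, bounds, baseline,
    subsample, dynamic, perceptual), plus optional per-stage parameter
    blocks named after the stage.  Returns the JSON-serializable summary.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    seed = int(config.get("seed", 0))
    out_dir = Path(config.get("out_dir", "."))
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", ["generate"])
    known = {"generate", "encode", "bounds", "baseline", "subsample",
             "dynamic", "perceptual"}
    unknown = [s for s in stages if s not in known]
    if unknown:
        raise ValueError(f"unknown protocol stage(s): {unknown}")

    summary: dict = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": seed,
        "stages": list(stages),
    }
    fixture = default_fixture(seed)

    if "generate" in stages:
        save_fixture(out_dir / "fixture.h5", fixture)
        write_element_csv(out_dir / "elements.csv", fixture.dictionary)
        summary["generate"] = {
            "n_elements": fixture.dictionary.n_elements,
            "n_cells": fixture.population.n_cells,
        }

    if "encode" in stages or "bounds" in stages:
        p = config.get("bounds", config.get("encode", {}))
        df = checkerboard_bounds_study(
            seed, n_targets=int(p.get("n_targets", 20)),
            T_max=int(p.get("T_max", 10_000)), fixture=fixture)
        df.to_csv(out_dir / "bounds.csv", index=False)
        summary["bounds"] = {
            "median_err_greedy": float(df.err_greedy.median()),
            "median_gap_greedy_pct": float(df.gap_greedy.median() * 100),
            "median_gap_dictionary_pct": float(df.gap_dictionary.median() * 100),
        }

    if "baseline" in stages:
        p = config.get("baseline", {})
        shape = fixture.filters.grid_shape
        train = make_checkerboard_targets(int(p.get("n_train", 5)), shape, seed + 1)
        test = make_checkerboard_targets(int(p.get("n_test", 5)), shape, seed + 2)
        mapping = fit_pixelwise_mapping(train, fixture.filters,
                                        fixture.dictionary, fixture.array)
        errs = [apply_pixelwise(t, mapping, fixture.dictionary, fixture.filters,
                                fixture.array)[1].relative_mse for t in test]
        summary["baseline"] = {"mean_pixelwise_error": float(np.mean(errs)),
                               "training_error": mapping.training_error}

    if "subsample" in stages:
        p = config.get("subsample", {})
        curve = subsampling_study(seed, n_targets=int(p.get("n_targets", 20)),
                                  T_max=int(p.get("T_max", 10_000)),
                                  fractions=tuple(p.get("fractions", (0.5, 1.0))),
                                  fixture=fixture)
        curve.to_csv(out_dir / "subsample.csv", index=False)
        summary["subsample"] = {
            "error_increase_at_half_pct":
                float(fractional_error_increase(curve) * 100)}

    if "dynamic" in stages:
        p = config.get("dynamic", {})
        df = dynamic_jitter_study(
            seed, n_fixations=int(p.get("n_fixations", 100)),
            choices_per_frame=int(p.get("choices_per_frame", 12)),
            n_replicates=int(p.get("n_replicates", 5)))
        df.to_csv(out_dir / "dynamic.csv", index=False)
        summary["dynamic"] = {"mean_jitter_ratio": float(df.ratio.mean())}

    if "perceptual" in stages:
        p = config.get("perceptual", {})
        scene = make_natural_scene(tuple(p.get("scene_shape", (16, 32))), seed)
        lambdas = list(p.get("lambdas", [0.0, 1e-4, 1e-3]))
        rows = []
        for metric in ("mse", "ssim"):
            for lam in lambdas:
                r = joint_patch_optimize(scene, fixture.filters,
                                         fixture.dictionary, metric=metric,
                                         lambda_=lam)
                rows.append((metric, lam, r.metric_value, r.total_usage))
        pd.DataFrame(rows, columns=["metric", "lambda", "value", "usage"]).to_csv(
            out_dir / "perceptual.csv", index=False)
        summary["perceptual"] = {"n_points": len(rows)}

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("protocol complete: %s", summary["stages"])
    return summary
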