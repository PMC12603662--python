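"""End-to-end split-half reliability experiments.

Mirrors the evaluation design of the reliability study: an acquisition is
randomly split into two halves at every b-value; both halves are pushed
through the same pipeline — either the plain tensor fit ("original") or
free-water fitting followed by free-water elimination and a tensor fit on
the corrected signal ("fwe") — and the per-voxel tensor ODFs of the two
halves are compared with r².  Reports carry per-region medians and
mean ± SEM so the two modes can be contrasted with the symmetric
percent-change statistic.

The experiment is configured by a plain dict (JSON/YAML-friendly); every
threshold, seed, and constant lives in it so runs are archivable and
byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from typing import Any

import numpy as np

from .acquisition import DWIDataset, split_half, subsample_single_shell
from .fit import (
    MultiShellFreeWaterModel,
    SingleShellFreeWaterModel,
    _psd_project,
    fit_tensor_wls,
)
from .model import D_ISO, FreeWaterTensorField, tensor_odf
from .reliability import SphericalFieldPair, fodf_r2, mean_sem, percent_change
from .simulate import REGION_LABELS, simulate_phantom
from .sphere import default_sphere

logger = logging.getLogger(__name__)

__all__ = ["default_config", "run_split_half_experiment", "compare_modes"]


def default_config() -> dict[str, Any]:
    """A complete configuration for the default phantom experiment."""
    return {
        "dataset": {
            "preset": "phantom",
            "shape": [20, 20, 5],
            "snr": 40.0,
            "seed": 7,
            "acquisition": "multishell",  # or "singleshell"
        },
        "mode": "fwe",  # or "original"
        "split_seed": 11,
        "duplicate_halves": False,  # True: bypass the split (degenerate check)
        "d_iso": D_ISO,
        "sphere_vertices": 362,
        "fit": {},  # keyword overrides for the free-water fitter
    }


_SCHEMA: dict[str, type | tuple[type, ...]] = {
    "mode": str,
    "split_seed": int,
    "duplicate_halves": bool,
    "d_iso": float,
    "sphere_vertices": int,
    "fit": dict,
    "dataset": dict,
}


def _validate_config(config: dict[str, Any]) -> dict[str, Any]:
    cfg = default_config()
    for key, value in config.items():
        if key not in cfg:
            raise ValueError(f"config: unknown field {key!r}")
        if key == "dataset" and isinstance(value, dict):
            cfg["dataset"].update(value)
            continue
        cfg[key] = value
    for key, typ in _SCHEMA.items():
        value = cfg[key]
        if typ is float and isinstance(value, int):
            cfg[key] = float(value)
        elif not isinstance(value, typ):
            raise ValueError(
                f"config.{key}: expected {getattr(typ, '__name__', typ)}, "
                f"got {type(value).__name__}"
            )
    if cfg["mode"] not in ("original", "fwe"):
        raise ValueError("config.mode: must be 'original' or 'fwe'")
    acq = cfg["dataset"].get("acquisition", "multishell")
    if acq not in ("multishell", "singleshell"):
        raise ValueError(
            "config.dataset.acquisition: must be 'multishell' or 'singleshell'"
        )
    return cfg


def _build_dataset(cfg: dict[str, Any]):
    ds_cfg = cfg["dataset"]
    if ds_cfg.get("preset") != "phantom":
        raise ValueError("config.dataset.preset: only 'phantom' is built in")
    snr = ds_cfg.get("snr", 40.0)
    ds, truth, labels = simulate_phantom(
        shape=tuple(ds_cfg.get("shape", (20, 20, 5))),
        snr=float(snr) if snr is not None else np.inf,
        seed=int(ds_cfg.get("seed", 0)),
        d_iso=cfg["d_iso"],
    )
    if ds_cfg.get("f_override") is not None:
        # rebuild noiselessly with a constant f (used by the f=0 check)
        from .simulate import PhantomRegion, default_regions

        shape = tuple(ds_cfg.get("shape", (20, 20, 5)))
        f_val = float(ds_cfg["f_override"])
        regions = [
            PhantomRegion(
                "nawm",
                (slice(0, shape[0]), slice(0, shape[1]), slice(0, shape[2])),
                f_free=f_val,
                compartments=((1.0 - f_val, default_regions(shape)[0].compartments[0][1]),),
            )
        ]
        ds, truth, labels = simulate_phantom(
            shape=shape,
            regions=regions,
            snr=float(snr) if snr is not None else np.inf,
            seed=int(ds_cfg.get("seed", 0)),
            d_iso=cfg["d_iso"],
        )
    if ds_cfg.get("acquisition", "multishell") == "singleshell":
        ds = subsample_single_shell(ds, ds_cfg.get("shell", 1000.0))
    return ds, truth, labels


def _plain_tensor_field(ds: DWIDataset, d_iso: float) -> FreeWaterTensorField:
    """Weighted log-linear tensor fit wrapped as a zero-f field."""
    q6, s0 = fit_tensor_wls(ds.data, ds.scheme)
    q6 = _psd_project(q6)
    s0 = np.where(ds.mask & (s0 > 0), s0, 1.0)
    return FreeWaterTensorField(
        q=q6, f=np.zeros(ds.spatial_shape), s0=s0, d_iso=d_iso, mask=ds.mask
    )


def _half_to_odf(half: DWIDataset, cfg: dict[str, Any], sphere):
    """One pipeline arm: (optionally FWE-correct, then) tensor fit -> ODF."""
    mean_f = 0.0
    if cfg["mode"] == "fwe":
        n_shells = len(half.scheme.nonzero_shells())
        if n_shells >= 2:
            fitter = MultiShellFreeWaterModel(d_iso=cfg["d_iso"], **cfg["fit"])
        else:
            fitter = SingleShellFreeWaterModel(d_iso=cfg["d_iso"], **cfg["fit"])
        corrected = fitter.fit(half).transform(half)
        mean_f = float(np.nanmean(fitter.field_.f[half.mask]))
        field = _plain_tensor_field(corrected, cfg["d_iso"])
    else:
        field = _plain_tensor_field(half, cfg["d_iso"])
    odf, valid = tensor_odf(field, sphere)
    return odf, valid, mean_f


def run_split_half_experiment(config: dict[str, Any] | None = None) -> dict[str, Any]:
    """Split, process both halves identically, and score split-half r².

    Returns a report dict with the per-voxel r² map, per-region summaries
    (median, mean ± SEM over defined voxels), QC counters, and the resolved
    configuration.  Fully deterministic given the config seeds.
    """
    cfg = _validate_config(config or {})
    ds, truth, labels = _build_dataset(cfg)
    sphere = default_sphere(cfg["sphere_vertices"])

    if cfg["duplicate_halves"]:
        half_a = half_b = ds
    else:
        half_a, half_b = split_half(ds, seed=cfg["split_seed"])

    odf_a, valid_a, mean_f_a = _half_to_odf(half_a, cfg, sphere)
    odf_b, valid_b, mean_f_b = _half_to_odf(half_b, cfg, sphere)

    pair = SphericalFieldPair(field_a=odf_a, field_b=odf_b, sphere=sphere)
    r2 = fodf_r2(pair)
    r2 = np.where(ds.mask & valid_a & valid_b, r2, np.nan)

    label_names = {v: k for k, v in REGION_LABELS.items()}
    regions: dict[str, Any] = {}
    for code in np.unique(labels):
        if code == 0:
            continue
        name = label_names.get(int(code), f"label{code}")
        vals = r2[labels == code]
        defined = vals[np.isfinite(vals)]
        mean, sem = mean_sem(vals)
        regions[name] = {
            "median_r2": float(np.median(defined)) if len(defined) else float("nan"),
            "mean_r2": mean,
            "sem_r2": sem,
            "n_defined": int(len(defined)),
            "n_undefined": int(np.size(vals) - len(defined)),
        }

    report = {
        "config": cfg,
        "mode": cfg["mode"],
        "r2_map": r2,
        "mean_f_half_a": mean_f_a,
        "mean_f_half_b": mean_f_b,
        "regions": regions,
        "qc": {
            "n_undefined_r2": int(np.count_nonzero(ds.mask & ~np.isfinite(r2))),
            "n_invalid_odf": int(
                np.count_nonzero(ds.mask & (~valid_a | ~valid_b))
            ),
        },
    }
    return report


def compare_modes(
    report_fwe: dict[str, Any], report_original: dict[str, Any]
) -> dict[str, Any]:
    """Symmetric percent change of r², FWE relative to original, per region.

    Reports the percent change of the region median r² plus the mean ± SEM
    of the voxel-wise percent-change values in each region.
    """
    regions_f = report_fwe["regions"]
    regions_o = report_original["regions"]
    if set(regions_f) != set(regions_o):
        raise ValueError(
            f"region label mismatch: {sorted(regions_f)} vs {sorted(regions_o)}"
        )
    r2_f, r2_o = report_fwe["r2_map"], report_original["r2_map"]
    if r2_f.shape != r2_o.shape:
        raise ValueError("reports come from different grids")

    cfg = report_fwe["config"]
    _, _, labels = _build_dataset(cfg)
    label_names = {v: k for k, v in REGION_LABELS.items()}

    out: dict[str, Any] = {"regions": {}}
    with np.errstate(invalid="ignore"):
        pc_map = percent_change(np.nan_to_num(r2_f, nan=np.nan), r2_o)
    for name in regions_f:
        code = REGION_LABELS.get(name)
        med_pc = percent_change(
            regions_f[name]["median_r2"], regions_o[name]["median_r2"]
        )
        sel = labels == code
        mean_pc, sem_pc = mean_sem(pc_map[sel]) if code is not None else (
            float("nan"),
            float("nan"),
        )
        out["regions"][name] = {
            "percent_change_median_r2": float(med_pc),
            "percent_change_mean": mean_pc,
            "percent_change_sem": sem_pc,
        }
    return out


def report_to_json(report: dict[str, Any]) -> str:
    """Serialize a report, replacing array fields by summary statistics."""
    clean = {}
    for key, value in report.items():
        if isinstance(value, np.ndarray):
            finite = value[np.isfinite(value)]
            clean[key] = {
                "shape": list(value.shape),
                "median": float(np.median(finite)) if finite.size else None,
                "mean": float(finite.mean()) if finite.size else None,
            }
        else:
            clean[key] = value
    return json.dumps(clean, indent=2, default=str)
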