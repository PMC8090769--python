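"""Declarative end-to-end runs: color field -> warp -> track -> map.

One config mapping describes one run (paths, gradient parameters, tracking
parameters, seeds); every run writes a provenance record (config digest,
seed, library versions) next to its outputs, and stage outputs are cached
on disk so a re-run with the same config reuses them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .colorfield import GradientSpec, rasterize_gradient, restrict_to_mask, warp_colorvolume
from .spectre import compute_spectre, normalize_for_display
from .tracking import TrackingParams, fit_tensors, make_direction_model

log = logging.getLogger("spectremri")

DEFAULT_CONFIG = {
    "model": "tend",
    "n_seeds": 500,
    "tracking": {"step": 1.0, "noise": 0.05, "max_steps": 250,
                 "angle_threshold": 60.0, "anisotropy_floor": 0.10},
    "seed": 0,
    "template_resolution_mm": 1.0,
    "normalize_display": True,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


def _merge(cfg: dict) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in cfg.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage '{name}' failed: {e}") from e
        return wrapped
    return deco


@_stage("colorfield")
def _stage_colorfield(cfg: dict, out: Path):
    cached = out / "template_color.nii.gz"
    if cached.exists():
        log.info("colorfield: reusing %s", cached)
        return io.read_colorvolume(cached, "template")
    if "color_volume" in cfg:
        cv = io.read_colorvolume(cfg["color_volume"], "template")
    else:
        g = cfg.get("gradient", {})
        spec = GradientSpec(
            np.asarray(g["amplitudes"], float) if "amplitudes" in g else GradientSpec().amplitudes,
            np.asarray(g["centers"], float) if "centers" in g else GradientSpec().centers,
            float(g.get("sigma", GradientSpec().sigma)),
        )
        shape = tuple(g.get("shape", (181, 217, 181)))
        res = float(cfg["template_resolution_mm"])
        affine = np.diag([res, res, res, 1.0])
        # MNI-like origin so voxel centers cover negative coordinates too
        affine[:3, 3] = -(np.array(shape) - 1) * res / 2.0
        cv = rasterize_gradient(spec, shape, affine)
    if "template_mask" in cfg:
        cv = restrict_to_mask(cv, io.read_mask(cfg["template_mask"]).data)
    io.write_colorvolume(cached, cv)
    return cv


@_stage("warp")
def _stage_warp(cfg: dict, cv, out: Path):
    cached = out / "subject_color.nii.gz"
    if cached.exists():
        log.info("warp: reusing %s", cached)
        return io.read_colorvolume(cached, "subject")
    if "deformation" not in cfg:
        raise PipelineError(
            "stage 'warp' failed: no deformation field configured; "
            "an identity warp is never assumed"
        )
    warp = io.read_deformation(cfg["deformation"])
    subject_cv = warp_colorvolume(cv, warp)
    io.write_colorvolume(cached, subject_cv)
    return subject_cv


@_stage("tensors")
def _stage_tensors(cfg: dict, out: Path):
    cached = out / "tensors.nii.gz"
    cached_mask = out / "tensor_mask.nii.gz"
    if cached.exists():
        log.info("tensors: reusing %s", cached)
        return io.read_tensorfield(cached, cached_mask if cached_mask.exists() else None)
    if "tensors" in cfg:
        field = io.read_tensorfield(cfg["tensors"], cfg.get("tensor_mask"))
    elif "dwi" in cfg:
        data, affine = io._load(cfg["dwi"])
        bvals, bvecs = io.read_gradient_table(cfg["bvals"], cfg["bvecs"])
        field = fit_tensors(data, bvals, bvecs, affine)
    else:
        raise PipelineError("stage 'tensors' failed: need 'tensors' or 'dwi' input")
    io.write_tensorfield(cached, field, cached_mask)
    return field


@_stage("spectre")
def _stage_spectre(cfg: dict, field, subject_cv, out: Path):
    region = io.read_target_region(cfg["region_mask"])
    tp = TrackingParams(seed=int(cfg["seed"]), **cfg["tracking"])
    model = make_direction_model(cfg["model"], field)
    tracking_mask = (
        io.read_mask(cfg["tracking_mask"]) if "tracking_mask" in cfg else field.tracking_mask()
    )
    smap = compute_spectre(
        region, model, subject_cv, tp,
        n_seeds=int(cfg["n_seeds"]), tracking_mask=tracking_mask,
    )
    io.write_spectremap(out / "spectre_map.nii.gz", smap)
    if cfg.get("normalize_display", True):
        io.write_spectremap(
            out / "spectre_map_display.nii.gz",
            normalize_for_display(smap, region),
            for_display=True,
        )
    return smap


def run_pipeline(config: dict, out_dir) -> "SpectreMap":
    """Execute the full flow and leave all artifacts in ``out_dir``."""
    cfg = _merge(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cv = _stage_colorfield(cfg, out)
    subject_cv = _stage_warp(cfg, cv, out)
    field = _stage_tensors(cfg, out)
    smap = _stage_spectre(cfg, field, subject_cv, out)
    io.write_provenance(out / "provenance.json", cfg)
    log.info("pipeline complete: %s", out / "spectre_map.nii.gz")
    return smap
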