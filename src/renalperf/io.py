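"""File plumbing: NIfTI images, CSV curves/tables, YAML config.

Images are written as NIfTI-1 with the pixel spacing encoded in the affine
(mm; the cranial pole points toward +y by package convention).  2D slices
are stored as (ny, nx, 1) volumes, multi-echo/dynamic stacks as 4D with the
echo/time axis last.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .asl import ASLParams
from .dce import GammaVariateAIF, PKParams
from .synthetic import CEUSBolusTruth, MaskGeometry, StudyConfig
from .types import (AIFCurve, KidneyMask, MultiEchoSeries, ParametricMap,
                    RegionLabelMap, TimeIntensityCurve)


def _affine(pixel_spacing: tuple[float, float]) -> np.ndarray:
    return np.diag([pixel_spacing[0], pixel_spacing[1], 1.0, 1.0])


def save_image(path, array2d: np.ndarray, pixel_spacing=(1.0, 1.0)) -> None:
    img = nib.Nifti1Image(np.asarray(array2d)[..., None].astype(np.float64),
                          _affine(pixel_spacing))
    nib.save(img, str(path))


def load_image(path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[..., 0]
    sp = img.affine
    return data, (float(sp[0, 0]), float(sp[1, 1]))


def save_mask(path, mask: KidneyMask) -> None:
    img = nib.Nifti1Image(mask.grid[..., None].astype(np.uint8),
                          _affine(mask.pixel_spacing))
    img.header["descrip"] = f"side={mask.side}".encode()
    nib.save(img, str(path))


def load_mask(path, side: str = "left",
              pole_axis_hint=None) -> KidneyMask:
    data, spacing = load_image(path)
    return KidneyMask(grid=data > 0.5, pixel_spacing=spacing, side=side,
                      pole_axis_hint=pole_axis_hint)


def save_map(path, pmap: ParametricMap) -> None:
    save_image(path, pmap.values, pmap.mask.pixel_spacing)


def load_map(path, mask: KidneyMask, kind: str = "RBF") -> ParametricMap:
    data, _ = load_image(path)
    return ParametricMap(values=data, mask=mask, kind=kind)


def save_labels(path, labels: RegionLabelMap) -> None:
    img = nib.Nifti1Image(labels.labels[..., None].astype(np.int16),
                          _affine(labels.mask.pixel_spacing))
    nib.save(img, str(path))


def save_stack(path, stack: np.ndarray, pixel_spacing=(1.0, 1.0)) -> None:
    """(n, ny, nx) stack -> 4D NIfTI (ny, nx, 1, n)."""
    arr = np.moveaxis(np.asarray(stack, dtype=np.float64), 0, -1)[:, :, None, :]
    nib.save(nib.Nifti1Image(arr, _affine(pixel_spacing)), str(path))


def load_stack(path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    return np.moveaxis(data[:, :, 0, :], -1, 0)


def save_multiecho(path, series: MultiEchoSeries) -> None:
    save_stack(path, series.echoes, series.mask.pixel_spacing)


def load_multiecho(path, echo_times, mask: KidneyMask) -> MultiEchoSeries:
    return MultiEchoSeries(echoes=load_stack(path),
                           echo_times=np.asarray(echo_times, dtype=float),
                           mask=mask)


# --- curves -----------------------------------------------------------------

def save_tic(path, tic: TimeIntensityCurve) -> None:
    pd.DataFrame({"t": tic.time, "intensity": tic.intensity}).to_csv(path, index=False)


def load_tic(path, roi_class: str = "cortex",
             baseline_window: int = 5) -> TimeIntensityCurve:
    df = pd.read_csv(path)
    return TimeIntensityCurve(time=df.iloc[:, 0].to_numpy(),
                              intensity=df.iloc[:, 1].to_numpy(),
                              roi_class=roi_class, baseline_window=baseline_window)


def save_curve(path, time: np.ndarray, value: np.ndarray,
               value_name: str = "value") -> None:
    pd.DataFrame({"t": time, value_name: value}).to_csv(path, index=False)


def load_aif(path, placement: str = "Cr25") -> AIFCurve:
    df = pd.read_csv(path)
    return AIFCurve(time=df.iloc[:, 0].to_numpy(),
                    concentration=df.iloc[:, 1].to_numpy(), placement=placement)


# --- config -----------------------------------------------------------------

_NESTED = {
    "asl_params": ASLParams,
    "aif": GammaVariateAIF,
    "geometry": MaskGeometry,
}


def config_from_dict(d: dict) -> StudyConfig:
    """Build a StudyConfig from a plain (YAML-loaded) dictionary."""
    kw = dict(d)
    for key, cls in _NESTED.items():
        if key in kw and isinstance(kw[key], dict):
            kw[key] = cls(**kw[key])
    if "pk_truth" in kw:
        kw["pk_truth"] = {t: PKParams(**v) if isinstance(v, dict) else v
                          for t, v in kw["pk_truth"].items()}
    if "ceus_truth" in kw:
        kw["ceus_truth"] = {c: CEUSBolusTruth(**v) if isinstance(v, dict) else v
                            for c, v in kw["ceus_truth"].items()}
    for key in ("treatments", "sides", "modalities", "echo_times"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    if "aif_placements" in kw:
        kw["aif_placements"] = {k: tuple(v) for k, v in kw["aif_placements"].items()}
    return StudyConfig(**kw)


def load_config(path) -> StudyConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def config_to_dict(config: StudyConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {k: enc(v) for k, v in obj.items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return enc(config)


def save_config(path, config: StudyConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def save_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
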