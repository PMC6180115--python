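"""NIfTI + JSON-sidecar I/O for image series and parametric maps.

The interchange dialect is deliberately minimal: a 4-D NIfTI stack holds
the image series (the reference volume included, its index named in the
sidecar), and a JSON sidecar carries the acquisition axis (offsets in ppm,
b-values, TI or TE lists) at full precision.  Maps are single 3-D NIfTI
volumes with name/units in their sidecar.  Tables travel as UTF-8 CSV with
a header row.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .relaxometry import RelaxometrySeries
from .zspec import ParametricMap, ZSpectrumGrid

_CONTROL_KEYS = {"diffusion": "b_values", "t1": "inversion_times_ms", "t2": "echo_times_ms"}


class SidecarError(ValueError):
    """Raised when a JSON sidecar is missing or names an inconsistent field."""


def _sidecar_path(image_path) -> Path:
    p = Path(image_path)
    name = p.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)] + ".json")
    return p.with_suffix(".json")


def _require(sidecar: dict, key: str):
    if key not in sidecar:
        raise SidecarError(f"sidecar missing required field {key!r}")
    return sidecar[key]


def write_zspectrum_grid(path, grid: ZSpectrumGrid) -> None:
    """Write signal + reference as one 4-D stack with a JSON sidecar."""
    path = Path(path)
    stack = np.concatenate([grid.signal, grid.reference[..., None]], axis=-1)
    nib.save(nib.Nifti1Image(stack[..., None, :].astype(np.float64), np.eye(4)), path)
    sidecar = {
        "modality": "cest",
        "offsets_ppm": [float(v) for v in grid.offsets],
        "reference_index": int(grid.offsets.size),
        "mask": grid.mask.astype(int).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_zspectrum_grid(path) -> ZSpectrumGrid:
    path = Path(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise SidecarError(f"no sidecar found at {side_path}")
    sidecar = json.loads(side_path.read_text())
    offsets = np.asarray(_require(sidecar, "offsets_ppm"), dtype=float)
    ref_idx = int(_require(sidecar, "reference_index"))
    stack = np.asarray(nib.load(path).dataobj, dtype=np.float64)[..., 0, :]
    if stack.shape[-1] != offsets.size + 1:
        raise SidecarError(
            f"volume count {stack.shape[-1]} does not match offsets_ppm "
            f"({offsets.size}) plus one reference")
    reference = stack[..., ref_idx]
    signal = np.delete(stack, ref_idx, axis=-1)
    mask = np.asarray(_require(sidecar, "mask"), dtype=bool)
    return ZSpectrumGrid(offsets=offsets, signal=signal, reference=reference, mask=mask)


def write_relaxometry_series(path, series: RelaxometrySeries) -> None:
    path = Path(path)
    nib.save(nib.Nifti1Image(series.signal[..., None, :].astype(np.float64), np.eye(4)), path)
    sidecar = {
        "modality": series.modality,
        _CONTROL_KEYS[series.modality]: [float(v) for v in series.control],
        "mask": series.mask.astype(int).tolist(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_relaxometry_series(path) -> RelaxometrySeries:
    path = Path(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise SidecarError(f"no sidecar found at {side_path}")
    sidecar = json.loads(side_path.read_text())
    modality = _require(sidecar, "modality")
    if modality not in _CONTROL_KEYS:
        raise SidecarError(f"unknown modality {modality!r}")
    control = np.asarray(_require(sidecar, _CONTROL_KEYS[modality]), dtype=float)
    signal = np.asarray(nib.load(path).dataobj, dtype=np.float64)[..., 0, :]
    if signal.shape[-1] != control.size:
        raise SidecarError("volume count does not match the sidecar control list")
    mask = np.asarray(_require(sidecar, "mask"), dtype=bool)
    return RelaxometrySeries(modality=modality, control=control, signal=signal, mask=mask)


def write_map(path, pmap: ParametricMap, extra: dict | None = None) -> None:
    """Write a parametric map as 2-D NIfTI + sidecar (name, units, provenance)."""
    path = Path(path)
    nib.save(nib.Nifti1Image(pmap.data.astype(np.float64), np.eye(4)), path)
    sidecar = {"name": pmap.name, "units": pmap.units,
               "mask": pmap.mask.astype(int).tolist()}
    if extra:
        sidecar.update(extra)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_map(path) -> ParametricMap:
    path = Path(path)
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise SidecarError(f"no sidecar found at {side_path}")
    sidecar = json.loads(side_path.read_text())
    data = np.asarray(nib.load(path).dataobj, dtype=np.float64)
    return ParametricMap(_require(sidecar, "name"), data, _require(sidecar, "units"),
                         np.asarray(_require(sidecar, "mask"), dtype=bool))


def write_table(path, table: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
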