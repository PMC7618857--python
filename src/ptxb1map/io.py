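"""Container I/O: field sets and k-space runs in HDF5 (or NPZ), NIfTI map
export, and the run manifest.

HDF5 field-set layout (all datasets at the root):

=============  =======================================  =========
dataset        content                                  dtype
=============  =======================================  =========
``b1plus``     per-Tx-channel complex map (deg)         complex
``b1minus``    per-Rx-channel complex sensitivity       complex
``pd``         proton density                           float
``fov``        field of view per spatial axis (mm)      float
``masks/<n>``  named binary ROI masks                   uint8
=============  =======================================  =========

Run containers store the (undersampled) k-space stack, the per-mode sampling
masks, and the resolved configuration as a JSON attribute — enough for exact
replay.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .core import GridSpec
from .fields import FieldSet
from .sampling import SamplingMask

__all__ = ["save_fieldset", "load_fieldset", "save_run", "load_run",
           "export_nifti", "save_manifest"]

_REQUIRED = ("b1plus", "b1minus", "pd", "fov")


def save_fieldset(fs: FieldSet, path) -> None:
    """Write a field set to HDF5 (``.h5``/``.hdf5``) or NPZ (``.npz``)."""
    path = Path(path)
    if path.suffix == ".npz":
        arrays = {"b1plus": fs.b1plus, "b1minus": fs.b1minus,
                  "pd": fs.proton_density, "fov": np.asarray(fs.grid.fov_mm)}
        for name, m in fs.roi_masks.items():
            arrays[f"mask_{name}"] = m.astype(np.uint8)
        np.savez(path, **arrays)
        return
    with h5py.File(path, "w") as f:
        f.create_dataset("b1plus", data=fs.b1plus)
        f.create_dataset("b1minus", data=fs.b1minus)
        f.create_dataset("pd", data=fs.proton_density)
        f.create_dataset("fov", data=np.asarray(fs.grid.fov_mm))
        g = f.create_group("masks")
        for name, m in fs.roi_masks.items():
            g.create_dataset(name, data=m.astype(np.uint8))


def load_fieldset(path) -> FieldSet:
    """Read and validate a field set written by :func:`save_fieldset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if path.suffix == ".npz":
            with np.load(path) as z:
                missing = [k for k in _REQUIRED if k not in z]
                if missing:
                    raise ValueError(f"field-set file missing arrays: {missing}")
                masks = {k[5:]: z[k].astype(bool) for k in z.files
                         if k.startswith("mask_")}
                return _build_fieldset(z["b1plus"], z["b1minus"], z["pd"],
                                       z["fov"], masks)
        with h5py.File(path, "r") as f:
            missing = [k for k in _REQUIRED if k not in f]
            if missing:
                raise ValueError(f"field-set file missing datasets: {missing}")
            masks = {}
            if "masks" in f:
                masks = {k: f["masks"][k][()].astype(bool) for k in f["masks"]}
            return _build_fieldset(f["b1plus"][()], f["b1minus"][()], f["pd"][()],
                                   f["fov"][()], masks)
    except (OSError, KeyError) as exc:
        raise ValueError(f"cannot read field-set container {path}: {exc}") from exc


def _build_fieldset(b1plus, b1minus, pd, fov, masks) -> FieldSet:
    pd = np.asarray(pd, float)
    grid = GridSpec(pd.shape, tuple(np.asarray(fov, float)))
    return FieldSet(b1plus=np.asarray(b1plus, complex),
                    b1minus=np.asarray(b1minus, complex),
                    proton_density=pd, grid=grid, roi_masks=masks)


def save_run(path, ksp: np.ndarray, masks, config_json: str = "{}") -> None:
    """Write an (undersampled) k-space stack plus per-mode masks."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=ksp)
        arrs = [m.mask if isinstance(m, SamplingMask) else np.asarray(m, bool)
                for m in masks]
        f.create_dataset("masks", data=np.stack(arrs).astype(np.uint8))
        f.attrs["config"] = config_json


def load_run(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read a run container; returns (kspace, masks, config dict)."""
    with h5py.File(path, "r") as f:
        if "kspace" not in f or "masks" not in f:
            raise ValueError(f"run container {path} missing kspace/masks datasets")
        ksp = f["kspace"][()]
        masks = f["masks"][()].astype(bool)
        cfg = json.loads(f.attrs.get("config", "{}"))
    return ksp, masks, cfg


def export_nifti(arr: np.ndarray, grid: GridSpec, path) -> None:
    """Write a map as NIfTI; complex input becomes magnitude + phase volumes.

    The affine encodes the voxel size; for a complex array, ``<stem>_mag`` and
    ``<stem>_phase`` files are written instead of ``path`` itself.
    """
    import nibabel as nib

    path = Path(path)
    vox = list(grid.voxel_mm) + [1.0] * (3 - grid.ndim)
    affine = np.diag(vox[:3] + [1.0])
    if np.iscomplexobj(arr):
        for suffix, vol in (("_mag", np.abs(arr)), ("_phase", np.angle(arr))):
            out = path.with_name(path.name.replace(".nii", f"{suffix}.nii"))
            nib.save(nib.Nifti1Image(np.asarray(vol, np.float32), affine), out)
        return
    nib.save(nib.Nifti1Image(np.asarray(arr, np.float32), affine), path)


def save_manifest(path, cfg, seed: int, extra: dict | None = None) -> None:
    """JSON manifest of the resolved configuration and seed for exact replay."""
    payload = {"config": cfg.model_dump(), "seed": int(seed)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
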