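"""NIfTI readers/writers and manifest handling.

On-disk layout (written by :func:`refless4dflow.phantom.make_dataset`): one
4D NIfTI per encoding per component named ``{subject}_enc{e}_{real|imag}.nii.gz``
with time as the 4th dimension, a JSON sidecar with acquisition metadata, and
a JSON manifest listing subjects and train/test splits.  Real/imaginary is
the canonical dialect; magnitude/phase volumes are converted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .recon import EncodingSet


def load_manifest(path: str | Path) -> dict:
    path = Path(path)
    manifest = json.loads(path.read_text())
    manifest.setdefault("out_dir", str(path.parent))
    return manifest


def _load_4d(path: Path) -> np.ndarray:
    """NIfTI (X, Y, Z, T) -> (T, X, Y, Z)."""
    if not path.exists():
        raise FileNotFoundError(f"missing volume: {path}")
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if arr.ndim != 4:
        raise ValueError(f"{path} is not a 4D volume (shape {arr.shape})")
    return np.moveaxis(arr, -1, 0)


def read_subject(manifest_entry: dict | str, data_dir: str | Path,
                 dialect: str = "real_imag") -> EncodingSet:
    """Load one subject's four encodings into an :class:`EncodingSet`.

    ``manifest_entry`` is the manifest's subject record (or the sidecar file
    name).  ``dialect`` selects the stored components: ``real_imag``
    (canonical) or ``mag_phase`` (converted on read, file keys
    ``enc{e}_mag`` / ``enc{e}_phase``).
    """
    data_dir = Path(data_dir)
    meta_name = manifest_entry["meta"] if isinstance(manifest_entry, dict) \
        else manifest_entry
    meta = json.loads((data_dir / meta_name).read_text())
    if "venc_m_s" not in meta or meta["venc_m_s"] <= 0:
        raise ValueError(f"missing or invalid VENC in {meta_name}")
    files = meta["files"]
    real, imag = [], []
    for e in range(4):
        if dialect == "real_imag":
            re = _load_4d(data_dir / files[f"enc{e}_real"])
            im = _load_4d(data_dir / files[f"enc{e}_imag"])
        elif dialect == "mag_phase":
            mag = _load_4d(data_dir / files[f"enc{e}_mag"])
            ph = _load_4d(data_dir / files[f"enc{e}_phase"])
            re, im = mag * np.cos(ph), mag * np.sin(ph)
        else:
            raise ValueError("dialect must be 'real_imag' or 'mag_phase'")
        if real and re.shape != real[0].shape:
            raise ValueError(
                f"dimension mismatch for encoding {e} of {meta['subject_id']}: "
                f"{re.shape} vs {real[0].shape}")
        real.append(re)
        imag.append(im)
    return EncodingSet(real=np.stack(real), imag=np.stack(imag),
                       venc_m_s=meta["venc_m_s"],
                       voxel_size_mm=tuple(meta["voxel_size_mm"]),
                       dt_s=meta["dt_s"])


def read_ground_truth(manifest_entry: dict | str, data_dir: str | Path) -> dict:
    """Load ground-truth fields written by make_dataset; arrays time-first."""
    data_dir = Path(data_dir)
    meta_name = manifest_entry["meta"] if isinstance(manifest_entry, dict) \
        else manifest_entry
    meta = json.loads((data_dir / meta_name).read_text())
    gtf = meta["ground_truth"]

    def load(name):
        return np.asarray(nib.load(str(data_dir / gtf[name])).dataobj, dtype=float)

    vel = np.moveaxis(load("gt_velocity"), (-1, -2), (0, 1))       # (3,T,X,Y,Z)
    sigma = np.moveaxis(load("gt_sigma"), -1, 0)
    background = np.moveaxis(load("gt_background"), -1, 0)
    masks_arr = load("gt_masks") > 0.5
    masks = {name: masks_arr[..., i] for i, name in enumerate(meta["mask_names"])}
    return {"velocity": vel, "sigma": sigma, "magnitude": load("gt_magnitude"),
            "background_phase": background, "masks": masks, "meta": meta}


def write_velocity(vf_v: np.ndarray, voxel_size_mm, dt_s: float,
                   out_dir: str | Path, subject_id: str) -> list[Path]:
    """Write (3, T, X, Y, Z) velocity as {subject}_vel_{ap|rl|fh}.nii.gz."""
    from .recon import DIRECTIONS

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    affine = np.diag(list(voxel_size_mm) + [1.0])
    for d, name in enumerate(DIRECTIONS):
        img = nib.Nifti1Image(np.moveaxis(vf_v[d], 0, -1).astype(np.float32),
                              affine)
        img.header.set_zooms(tuple(voxel_size_mm) + (dt_s,))
        p = out_dir / f"{subject_id}_vel_{name}.nii.gz"
        nib.save(img, str(p))
        paths.append(p)
    return paths


def write_scalar_map(arr_t_first: np.ndarray, voxel_size_mm, dt_s: float,
                     path: str | Path) -> Path:
    """Write a (T, X, Y, Z) scalar map (e.g. TKE) as a 4D NIfTI."""
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.moveaxis(arr_t_first, 0, -1).astype(np.float32),
                          affine)
    img.header.set_zooms(tuple(voxel_size_mm) + (dt_s,))
    nib.save(img, str(path))
    return Path(path)
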