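"""On-disk formats: NIfTI-1 images and an HDF5 raw k-space container.

Images travel as NIfTI (.nii/.nii.gz) with the voxel size in the header
(values stored float32).  Raw k-space uses a simple HDF5 layout:

    /kspace_real, /kspace_imag : float64 (Nx, Ny, Nz)
    /mask                      : uint8 (Ny, Nz), optional (absent = full)
    attrs: fov_mm (3,), tr_s, te_s, bw_hz_per_px, nsa, seed (optional)

Configuration files are YAML mirroring the dataclasses in the modelling
modules.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .errors import FormatError
from .recon import ImageVolume, KSpaceVolume
from .sampling import SamplingPattern, elliptical_window

__all__ = [
    "read_image",
    "write_image",
    "read_kspace",
    "write_kspace",
    "read_config",
]

_REQUIRED_KSPACE_ATTRS = ("fov_mm", "bw_hz_per_px", "nsa")


def write_image(path, image: ImageVolume) -> None:
    """Write an image as NIfTI-1 (float32) with voxel size in the header."""
    affine = np.diag(list(image.voxel_size) + [1.0])
    img = nib.Nifti1Image(np.asarray(image.values, dtype=np.float32), affine)
    img.header.set_zooms(image.voxel_size)
    nib.save(img, str(path))


def read_image(path) -> ImageVolume:
    """Read a NIfTI image; raises FormatError for missing/malformed files."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image file: {path}")
    try:
        img = nib.load(str(path))
        values = np.asarray(img.dataobj, dtype=np.float32)
        zooms = img.header.get_zooms()[:3]
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    return ImageVolume(
        values=values,
        voxel_size=tuple(float(z) for z in zooms),
        provenance={"source": str(path)},
    )


def write_kspace(path, kspace: KSpaceVolume, *, tr_s: float | None = None,
                 te_s: float | None = None, bw_hz_per_px: float | None = None,
                 nsa: int = 1, seed: int | None = None) -> None:
    """Write a k-space volume to the HDF5 container."""
    geom = kspace.geometry
    fov = tuple(geom.fov) if geom is not None else tuple(
        float(s) for s in kspace.data.shape
    )
    with h5py.File(str(path), "w") as f:
        f.create_dataset("kspace_real", data=kspace.data.real)
        f.create_dataset("kspace_imag", data=kspace.data.imag)
        if kspace.mask is not None:
            f.create_dataset("mask", data=kspace.mask.mask.astype(np.uint8))
            f.attrs["accel_target"] = kspace.mask.accel_target
            f.attrs["center_block"] = list(kspace.mask.center_block)
            f.attrs["pattern_seed"] = kspace.mask.seed
        f.attrs["fov_mm"] = list(fov)
        f.attrs["bw_hz_per_px"] = float(bw_hz_per_px or 0.0)
        f.attrs["nsa"] = int(nsa)
        if tr_s is not None:
            f.attrs["tr_s"] = float(tr_s)
        if te_s is not None:
            f.attrs["te_s"] = float(te_s)
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if kspace.noise_sigma is not None:
            f.attrs["noise_sigma"] = float(kspace.noise_sigma)


def read_kspace(path) -> KSpaceVolume:
    """Read the HDF5 k-space container; validates layout and attributes."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such k-space file: {path}")
    with h5py.File(str(path), "r") as f:
        for name in ("kspace_real", "kspace_imag"):
            if name not in f:
                raise FormatError(f"{path}: missing dataset /{name}")
        for attr in _REQUIRED_KSPACE_ATTRS:
            if attr not in f.attrs:
                raise FormatError(f"{path}: missing attribute {attr}")
        data = np.asarray(f["kspace_real"]) + 1j * np.asarray(f["kspace_imag"])
        if data.ndim != 3:
            raise FormatError(f"{path}: k-space must be 3D")
        mask = None
        if "mask" in f:
            m = np.asarray(f["mask"]).astype(bool)
            if m.shape != data.shape[1:]:
                raise FormatError(f"{path}: mask shape mismatch")
            window = elliptical_window(*m.shape)
            n = int(m.sum())
            mask = SamplingPattern(
                mask=m,
                window=window,
                accel_target=float(f.attrs.get("accel_target", window.sum() / max(n, 1))),
                accel_achieved=float(window.sum()) / max(n, 1),
                center_block=tuple(f.attrs.get("center_block", (0, 0))),
                seed=int(f.attrs.get("pattern_seed", 0)),
                n_sampled=n,
            )
        fov = tuple(float(v) for v in f.attrs["fov_mm"])
        noise_sigma = float(f.attrs["noise_sigma"]) if "noise_sigma" in f.attrs else None

    from .phantom import _PhantomGeometry

    return KSpaceVolume(
        data=data,
        mask=mask,
        geometry=_PhantomGeometry(fov=fov, matrix=data.shape),
        noise_sigma=noise_sigma,
    )


def read_config(path) -> dict:
    """Load a YAML/JSON configuration file into a plain dict."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such config file: {path}")
    with open(path) as f:
        cfg = yaml.safe_load(f)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    return cfg
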