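"""Synthetic 3D lung-ventilation phantoms and simulated noisy acquisitions.

The phantom emulates a breath-hold fluorinated-gas ventilation image: two
ellipsoidal lungs with roughly uniform gas signal, a central trachea with
main bronchi (full signal, but excluded from ventilated-volume analysis via
the airway mask), optional spherical ventilation defects of zero signal,
and a smooth multiplicative shading field emulating coil inhomogeneity.
Axes follow the acquisition convention (x, y, z) = (readout
/superior-inferior, right-left, anterior-posterior).

k-space simulation applies the unitary centred FFT and adds i.i.d. complex
Gaussian noise; with this convention the per-channel image-domain noise has
the same sigma, and the background of the magnitude image is
Rayleigh-distributed with standard deviation sqrt(2 - pi/2) * sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError
from .metrics import RoiSpec, measure_snr
from .recon import KSpaceVolume, fft_centered, ifft_reconstruct

__all__ = [
    "DefectSpec",
    "LungPhantom",
    "make_lung_phantom",
    "simulate_kspace",
    "calibrate_noise_for_snr",
    "default_rois",
]

LITRES_PER_MM3 = 1e-6


@dataclass(frozen=True)
class DefectSpec:
    """Ventilation-defect specification: how many spheres, radius (mm), seed."""

    count: int = 0
    radius_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise InvalidParameterError("defect count must be >= 0")
        if self.count > 0 and self.radius_mm <= 0:
            raise InvalidParameterError("defect radius must be > 0")


@dataclass(frozen=True)
class LungPhantom:
    """Ground-truth intensity volume plus masks and true volumes (litres).

    ``lung_mask`` includes defect voxels (they are lung tissue that is not
    ventilated); ``values`` are zero there.  The airway mask is disjoint
    from the lung mask and carries full signal.
    """

    values: np.ndarray
    lung_mask: np.ndarray
    defect_mask: np.ndarray
    airway_mask: np.ndarray
    voxel_size: tuple[float, float, float]
    true_total_volume: float
    true_ventilated_volume: float
    seed: int = 0

    @property
    def voxel_volume_l(self) -> float:
        return float(np.prod(self.voxel_size)) * LITRES_PER_MM3


def _frac_grids(matrix):
    """Voxel-centre coordinates as fractions of the FOV, one grid per axis."""
    return np.meshgrid(
        *[(np.arange(n) + 0.5) / n for n in matrix], indexing="ij", sparse=True
    )


def _ellipsoid(grids, center, semi):
    x, y, z = grids
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


# Fractional lung geometry (of FOV per axis): two ellipsoids left/right of
# the midline, a trachea descending along x at the midline, two bronchi.
_LUNG_SEMI = (0.33, 0.16, 0.30)
_RIGHT_CENTER = (0.50, 0.28, 0.50)
_LEFT_CENTER = (0.50, 0.72, 0.50)
_TRACHEA_RADIUS = 0.045  # fraction of FOVy
_TRACHEA_END_X = 0.38


def make_lung_phantom(
    matrix: tuple[int, int, int] = (64, 32, 25),
    fov: tuple[float, float, float] = (400.0, 320.0, 250.0),
    defect_spec: DefectSpec = DefectSpec(),
    smoothness: float = 0.15,
    seed: int = 0,
    lung_scale: float = 1.0,
) -> LungPhantom:
    """Build a two-lung phantom with airways, defects and coil shading.

    ``smoothness`` is the peak fractional amplitude of the multiplicative
    low-frequency shading field (default +/-15%).  ``lung_scale`` scales the
    lung semi-axes, emulating between-subject total-lung-capacity spread
    (volume goes as the cube).  The default 64 x 32 x 25 grid keeps
    simulation fast; pass the acquisition matrix for full-size phantoms.
    """
    if any(n < 8 for n in matrix):
        raise InvalidParameterError("matrix too small for a lung phantom")
    if any(f <= 0 for f in fov):
        raise InvalidParameterError("fov must be positive")
    if not 0 <= smoothness < 1:
        raise InvalidParameterError("smoothness must lie in [0, 1)")
    if not 0.5 <= lung_scale <= 1.3:
        raise InvalidParameterError("lung_scale must lie in [0.5, 1.3]")
    grids = _frac_grids(matrix)
    x, y, z = grids

    semi = tuple(s * lung_scale for s in _LUNG_SEMI)
    lungs = _ellipsoid(grids, _RIGHT_CENTER, semi) | _ellipsoid(
        grids, _LEFT_CENTER, semi
    )

    # Trachea: a tube along x at the midline; bronchi: tubes along y from the
    # carina toward each lung apex region.
    r2_yz = ((y - 0.5) / _TRACHEA_RADIUS) ** 2 + (
        (z - 0.5) / (_TRACHEA_RADIUS * fov[1] / fov[2])
    ) ** 2
    trachea = (r2_yz <= 1.0) & (x <= _TRACHEA_END_X)
    r2_xz = ((x - _TRACHEA_END_X) / (_TRACHEA_RADIUS * fov[1] / fov[0])) ** 2 + (
        (z - 0.5) / (_TRACHEA_RADIUS * fov[1] / fov[2])
    ) ** 2
    bronchi = (r2_xz <= 1.0) & (np.abs(y - 0.5) <= 0.22)
    airway = (trachea | bronchi) & ~lungs

    voxel_size = tuple(f / n for f, n in zip(fov, matrix))

    # Ventilation defects: spheres carved out of the lungs at seeded centres.
    defect = np.zeros(np.broadcast_shapes(*(g.shape for g in grids)), dtype=bool)
    if defect_spec.count > 0:
        if defect_spec.radius_mm >= min(s * f for s, f in zip(_LUNG_SEMI, fov)):
            raise InvalidParameterError("defect radius exceeds lung extent")
        rng = np.random.default_rng(defect_spec.seed)
        lung_idx = np.argwhere(np.broadcast_to(lungs, defect.shape))
        picks = lung_idx[rng.choice(len(lung_idx), size=defect_spec.count, replace=False)]
        xs = (x - 0.0) * fov[0]  # voxel-centre mm coordinates
        ys = (y - 0.0) * fov[1]
        zs = (z - 0.0) * fov[2]
        for c in picks:
            cx = (c[0] + 0.5) * voxel_size[0]
            cy = (c[1] + 0.5) * voxel_size[1]
            cz = (c[2] + 0.5) * voxel_size[2]
            d2 = (xs - cx) ** 2 + (ys - cy) ** 2 + (zs - cz) ** 2
            defect |= d2 <= defect_spec.radius_mm**2
        defect &= np.broadcast_to(lungs, defect.shape)

    lungs = np.broadcast_to(lungs, defect.shape).copy()
    airway = np.broadcast_to(airway, defect.shape).copy()

    # Smooth multiplicative shading: one low-order cosine per axis, summed.
    # An additive combination keeps the in-lung deviation within ~2.5 SD of
    # its spread, so the mean-3SD ventilation threshold never clips clean
    # lung signal on a noiseless phantom (exact-recovery property).
    rng = np.random.default_rng(seed)
    shade = np.zeros(defect.shape)
    for grid in (x, y, z):
        freq = int(rng.integers(1, 3))
        phase = float(rng.uniform(0, 2 * np.pi))
        shade = shade + np.cos(2 * np.pi * freq * grid + phase)
    peak = float(np.abs(shade).max()) or 1.0
    field_mult = 1.0 + smoothness * shade / peak

    values = np.where(lungs | airway, field_mult, 0.0)
    values[defect] = 0.0

    vox_l = float(np.prod(voxel_size)) * LITRES_PER_MM3
    n_lung = int(lungs.sum())
    n_defect = int(defect.sum())
    return LungPhantom(
        values=values,
        lung_mask=lungs,
        defect_mask=defect,
        airway_mask=airway,
        voxel_size=voxel_size,
        true_total_volume=n_lung * vox_l,
        true_ventilated_volume=(n_lung - n_defect) * vox_l,
        seed=int(seed),
    )


@dataclass(frozen=True)
class _PhantomGeometry:
    """Minimal geometry adapter so KSpaceVolume can report voxel sizes."""

    fov: tuple[float, float, float]
    matrix: tuple[int, int, int]


def simulate_kspace(
    phantom: LungPhantom,
    noise_sigma: float = 0.0,
    seed: int = 0,
    nsa: int = 1,
) -> KSpaceVolume:
    """Simulate a noisy k-space acquisition of the phantom.

    Each of the ``nsa`` averages is the unitary centred FFT of the phantom
    plus i.i.d. complex Gaussian noise with per-channel standard deviation
    ``noise_sigma``; the delivered k-space is their complex mean, so the
    effective noise level is noise_sigma / sqrt(nsa).
    """
    if noise_sigma < 0:
        raise InvalidParameterError("noise_sigma must be >= 0")
    if nsa < 1:
        raise InvalidParameterError("nsa must be >= 1")
    k0 = fft_centered(phantom.values.astype(complex))
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(k0)
    for _ in range(nsa):
        noise = noise_sigma * (
            rng.standard_normal(k0.shape) + 1j * rng.standard_normal(k0.shape)
        )
        acc += k0 + noise
    matrix = phantom.values.shape
    fov = tuple(v * n for v, n in zip(phantom.voxel_size, matrix))
    return KSpaceVolume(
        data=acc / nsa,
        mask=None,
        geometry=_PhantomGeometry(fov=fov, matrix=matrix),
        noise_sigma=noise_sigma / np.sqrt(nsa) if noise_sigma else 0.0,
    )


def default_rois(phantom: LungPhantom, diameter_mm: float = 40.0) -> tuple[RoiSpec, RoiSpec]:
    """Standard SNR ROIs: a disc in the left-lung centre and one below the lungs.

    Both are 2D discs (default 4 cm diameter) on the mid anterior-posterior
    (coronal) slice; the noise ROI sits inferior to the lungs where only
    background noise is present.
    """
    vox = phantom.voxel_size
    shape = phantom.values.shape
    extent = tuple(s * v for s, v in zip(shape, vox))
    plane = shape[2] // 2
    left = np.argwhere(phantom.lung_mask[:, :, plane])
    if len(left) == 0:
        raise InvalidParameterError("phantom has no lung voxels on the mid slice")
    # left lung = larger y (subject left); centroid of that half
    half = left[left[:, 1] >= shape[1] // 2]
    cx, cy = half.mean(axis=0) if len(half) else left.mean(axis=0)
    signal = RoiSpec(
        center=((cx + 0.5) * vox[0], (cy + 0.5) * vox[1], (plane + 0.5) * vox[2]),
        diameter=min(diameter_mm, 0.25 * extent[0], 0.25 * extent[1]),
        plane=plane,
    )
    # background strip inferior to the lungs; shrink the disc on small
    # volumes so it stays inside both the strip and the volume bounds
    lung_x_max = int(np.argwhere(phantom.lung_mask.any(axis=(1, 2))).max())
    x_lo = (lung_x_max + 1.5) * vox[0]
    r_noise = min(diameter_mm / 2.0, 0.5 * (extent[0] - x_lo) - vox[0], 0.45 * extent[1])
    if r_noise <= 0:
        raise InvalidParameterError("volume too small for a background noise ROI")
    noise = RoiSpec(
        center=(0.5 * (x_lo + extent[0]), 0.5 * extent[1], (plane + 0.5) * vox[2]),
        diameter=2.0 * r_noise,
        plane=plane,
    )
    return signal, noise


def calibrate_noise_for_snr(
    phantom: LungPhantom,
    target_snr: float,
    roi_spec: tuple[RoiSpec, RoiSpec] | None = None,
    seed: int = 0,
    nsa: int = 1,
    rel_tol: float = 0.02,
) -> float:
    """Find the k-space noise sigma that yields a target measured image SNR.

    Bisection on sigma with a fixed simulation seed; the returned sigma
    reproduces ``target_snr`` (as measured by the Rayleigh-corrected ROI
    estimator on the magnitude reconstruction) to within ``rel_tol``.
    """
    if target_snr <= 0:
        raise InvalidParameterError("target_snr must be > 0")
    signal_roi, noise_roi = roi_spec or default_rois(phantom)

    def measured(sigma: float) -> float:
        ksp = simulate_kspace(phantom, sigma, seed=seed, nsa=nsa)
        img = ifft_reconstruct(ksp)
        return measure_snr(img, signal_roi, noise_roi)

    lo, hi = 1e-6, 10.0 * float(np.abs(phantom.values).max() or 1.0)
    if measured(lo) < target_snr:
        raise InvalidParameterError(f"target SNR {target_snr} unattainable (too high)")
    if measured(hi) > target_snr:
        raise InvalidParameterError(f"target SNR {target_snr} unattainable (too low)")
    for _ in range(60):
        mid = np.sqrt(lo * hi)  # geometric: SNR ~ 1/sigma spans decades
        snr = measured(mid)
        if abs(snr - target_snr) <= rel_tol * target_snr:
            return float(mid)
        if snr > target_snr:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
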