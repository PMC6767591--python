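"""Image reconstruction: zero-filled inverse FFT and wavelet-regularized CS.

Compressed-sensing reconstruction recovers the image ``m`` from
undersampled k-space ``y`` by minimizing

    || y - D F m ||_2^2  +  lambda * || Psi m ||_1

where ``F`` is the (unitary, centred) Fourier transform, ``D`` the
phase-encode selection operator of the sampling pattern, and ``Psi`` a
Daubechies-4 wavelet transform.  The solver is proximal gradient (ISTA)
with unit step — valid because D F has spectral norm 1 for a unitary F and
a binary mask — alternating a data-consistency gradient step with wavelet
soft-thresholding.  A fresh random circular shift is applied to the image
before each thresholding (cycle spinning) to approximate a
translation-invariant wavelet transform and suppress blocky artefacts.

The regularization weight is defined on a normalized intensity scale: the
data are scaled so the zero-filled reconstruction's 99th-percentile
magnitude is 1, which makes a given lambda (e.g. 0.05) transferable across
datasets of different raw intensity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pywt

from .errors import DivergenceError, InvalidParameterError
from .sampling import SamplingPattern, undersample

__all__ = [
    "KSpaceVolume",
    "ReconConfig",
    "ImageVolume",
    "fft_centered",
    "ifft_centered",
    "ifft_reconstruct",
    "wavelet_analysis",
    "wavelet_synthesis",
    "soft_threshold",
    "cs_reconstruct",
    "select_lambda",
    "DEFAULT_LAMBDA_GRID",
]

#: Default lambda grid for RMSE-based selection; includes the working value 0.05.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = (0.0, 0.01, 0.025, 0.05, 0.1, 0.2, 0.4)


@dataclass(frozen=True)
class KSpaceVolume:
    """Complex 3D k-space (Nx x Ny x Nz) with optional sampling mask.

    ``mask`` is a :class:`SamplingPattern` for undersampled data or ``None``
    for a full acquisition.  ``geometry`` carries FOV/matrix metadata (any
    object with ``fov`` and ``matrix``); ``noise_sigma`` the per-channel
    complex-Gaussian noise level if known.
    """

    data: np.ndarray
    mask: SamplingPattern | None = None
    geometry: object | None = None
    noise_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise InvalidParameterError("k-space data must be 3D")
        if self.mask is not None and self.mask.mask.shape != self.data.shape[1:]:
            raise InvalidParameterError("mask shape does not match phase-encode dims")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        if self.geometry is None:
            return (1.0, 1.0, 1.0)
        return tuple(f / n for f, n in zip(self.geometry.fov, self.geometry.matrix))


@dataclass(frozen=True)
class ReconConfig:
    """CS solver configuration: lambda, iterations, wavelet, shift seed."""

    lam: float = 0.05
    n_iter: int = 50
    wavelet: str = "db4"
    shift_seed: int = 0
    level: int = 2

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise InvalidParameterError("lam must be >= 0")
        if self.n_iter < 1:
            raise InvalidParameterError("n_iter must be >= 1")
        if self.wavelet not in pywt.wavelist(kind="discrete"):
            raise InvalidParameterError(f"unknown wavelet {self.wavelet!r}")
        if self.level < 1:
            raise InvalidParameterError("level must be >= 1")


@dataclass(frozen=True)
class ImageVolume:
    """A reconstructed 3D image with voxel size (mm) and provenance metadata."""

    values: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise InvalidParameterError("voxel_size must be positive")
        if not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("image values must be finite")


def fft_centered(image: np.ndarray) -> np.ndarray:
    """Unitary forward FFT with DC at N//2 on every axis."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(image), norm="ortho"))


def ifft_centered(kspace: np.ndarray) -> np.ndarray:
    """Unitary inverse FFT, inverse of :func:`fft_centered`."""
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(kspace), norm="ortho"))


def _zero_fill(data: np.ndarray, shape: Sequence[int]) -> np.ndarray:
    """Symmetrically zero-pad k-space so DC stays at N//2 of the new grid."""
    shape = tuple(shape)
    if any(s < d for s, d in zip(shape, data.shape)):
        raise InvalidParameterError("zero_fill_to must be >= data shape on every axis")
    out = np.zeros(shape, dtype=data.dtype)
    idx = tuple(
        slice(s // 2 - d // 2, s // 2 - d // 2 + d) for s, d in zip(shape, data.shape)
    )
    out[idx] = data
    # keep voxel intensities on the original scale despite the larger grid
    return out * np.sqrt(np.prod(shape) / np.prod(data.shape))


def ifft_reconstruct(
    kspace: KSpaceVolume, zero_fill_to: Sequence[int] | None = None
) -> ImageVolume:
    """Magnitude image from the centred inverse FFT (zero-filled recon).

    ``zero_fill_to`` optionally pads k-space symmetrically to a finer
    reconstruction grid before the transform; intensities are rescaled so
    the interpolation does not change the image scale.
    """
    data = kspace.data
    vox = kspace.voxel_size
    if zero_fill_to is not None:
        old = data.shape
        data = _zero_fill(data, zero_fill_to)
        vox = tuple(v * o / n for v, o, n in zip(vox, old, data.shape))
    img = np.abs(ifft_centered(data))
    return ImageVolume(
        values=img,
        voxel_size=vox,
        provenance={"method": "ifft", "zero_fill_to": tuple(data.shape)},
    )


def _padded_shape(shape: Sequence[int], level: int, filter_len: int = 8) -> tuple[int, ...]:
    """Per-axis zero-pad target: a multiple of 2**level that is large enough
    for ``level`` decompositions without the final band dropping below the
    filter length (which would incur boundary effects)."""
    m = 2**level
    floor = (filter_len - 1) * m
    return tuple(int(np.ceil(max(n, floor) / m)) * m for n in shape)


@dataclass(frozen=True)
class WaveletCoeffs:
    """Wavelet coefficient set plus the bookkeeping to invert it exactly."""

    coeffs: list
    shape: tuple[int, ...]
    shift: tuple[int, ...]
    wavelet: str
    level: int

    def ravel(self) -> np.ndarray:
        arr, _ = pywt.coeffs_to_array(self.coeffs)
        return arr.ravel()


def wavelet_analysis(
    image: np.ndarray,
    wavelet: str = "db4",
    shift: Sequence[int] | None = None,
    level: int = 2,
) -> WaveletCoeffs:
    """Orthogonal wavelet decomposition with an optional circular pre-shift.

    The image is circularly shifted, zero-padded per axis to a multiple of
    2**level, and decomposed with periodization boundary handling, which
    keeps the transform orthonormal (Parseval holds exactly) and perfectly
    invertible.
    """
    if wavelet not in pywt.wavelist(kind="discrete"):
        raise InvalidParameterError(f"unknown wavelet {wavelet!r}")
    shift = tuple(0 for _ in image.shape) if shift is None else tuple(shift)
    shifted = np.roll(image, shift, axis=tuple(range(image.ndim)))
    target = _padded_shape(image.shape, level)
    pad = [(0, t - n) for t, n in zip(target, image.shape)]
    padded = np.pad(shifted, pad)
    coeffs = pywt.wavedecn(padded, wavelet, mode="periodization", level=level)
    return WaveletCoeffs(
        coeffs=coeffs, shape=tuple(image.shape), shift=shift, wavelet=wavelet, level=level
    )


def wavelet_synthesis(wc: WaveletCoeffs) -> np.ndarray:
    """Inverse of :func:`wavelet_analysis` (crop padding, undo the shift)."""
    rec = pywt.waverecn(wc.coeffs, wc.wavelet, mode="periodization")
    rec = rec[tuple(slice(0, n) for n in wc.shape)]
    return np.roll(rec, tuple(-s for s in wc.shift), axis=tuple(range(rec.ndim)))


def soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    """Complex soft-thresholding, the proximal operator of t * ||.||_1.

    Shrinks magnitudes by ``t`` and zeroes anything smaller, preserving
    phase: sign(x) * max(|x| - t, 0).
    """
    if t < 0:
        raise InvalidParameterError("threshold must be >= 0")
    x = np.asarray(x)
    mag = np.abs(x)
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(mag > t, 1.0 - t / np.where(mag > 0, mag, 1.0), 0.0)
    return x * scale


def _threshold_coeffs(wc: WaveletCoeffs, t: float) -> WaveletCoeffs:
    out = [soft_threshold(wc.coeffs[0], t)]
    for band in wc.coeffs[1:]:
        out.append({k: soft_threshold(v, t) for k, v in band.items()})
    return replace(wc, coeffs=out)


def _l1_coeffs(wc: WaveletCoeffs) -> float:
    total = float(np.abs(wc.coeffs[0]).sum())
    for band in wc.coeffs[1:]:
        total += float(sum(np.abs(v).sum() for v in band.values()))
    return total


def cs_reconstruct(
    kspace_under: KSpaceVolume,
    pattern: SamplingPattern | None = None,
    config: ReconConfig = ReconConfig(),
) -> ImageVolume:
    """Wavelet-regularized CS reconstruction by proximal gradient descent.

    Runs exactly ``config.n_iter`` iterations of: data-consistency gradient
    step (unit step size), random circular shift, wavelet soft-thresholding
    at ``config.lam`` on the normalized intensity scale, inverse transform
    and unshift.  Because the randomized shift changes the effective
    regularizer each iteration, the objective is mildly nonmonotone near
    convergence; the iterate with the lowest objective is returned.
    Deterministic given inputs and ``config.shift_seed``.  Raises
    :class:`DivergenceError` if the objective exceeds 10x its initial value.
    """
    pattern = kspace_under.mask if pattern is None else pattern
    if pattern is not None and pattern.mask.shape != kspace_under.data.shape[1:]:
        raise InvalidParameterError("pattern does not match k-space dims")
    mask3 = (
        np.ones(kspace_under.data.shape, dtype=bool)
        if pattern is None
        else np.broadcast_to(pattern.mask[None, :, :], kspace_under.data.shape)
    )
    y = np.where(mask3, kspace_under.data, 0.0)

    m = ifft_centered(y)
    scale = float(np.percentile(np.abs(m), 99.0))
    if scale <= 0:
        scale = float(np.abs(m).max()) or 1.0
    y = y / scale
    m = m / scale

    rng = np.random.default_rng(config.shift_seed)
    shape = m.shape

    def objective(mm: np.ndarray) -> float:
        resid = np.where(mask3, fft_centered(mm) - y, 0.0)
        wc = wavelet_analysis(mm, config.wavelet, None, config.level)
        return float(np.sum(np.abs(resid) ** 2)) + config.lam * _l1_coeffs(wc)

    obj0 = objective(m)
    obj_first = None
    best_obj, best_m = np.inf, m
    for _ in range(config.n_iter):
        resid = np.where(mask3, fft_centered(m) - y, 0.0)
        m = m - ifft_centered(resid)
        if config.lam > 0:
            shift = tuple(int(rng.integers(0, n)) for n in shape)
            wc = wavelet_analysis(m, config.wavelet, shift, config.level)
            m = wavelet_synthesis(_threshold_coeffs(wc, config.lam))
        obj = objective(m)
        if obj_first is None:
            obj_first = obj
        # the per-iteration random shift makes the objective mildly
        # nonmonotone near convergence; keep the best iterate seen
        if obj < best_obj:
            best_obj, best_m = obj, m
        if obj0 > 0 and obj > 10.0 * obj0:
            raise DivergenceError(
                "CS objective diverged",
                details={"objective": obj, "initial": obj0},
            )

    return ImageVolume(
        values=np.abs(best_m) * scale,
        voxel_size=kspace_under.voxel_size,
        provenance={
            "method": "cs",
            "lam": config.lam,
            "n_iter": config.n_iter,
            "wavelet": config.wavelet,
            "shift_seed": config.shift_seed,
            "objective_first": obj_first,
            "objective_final": best_obj,
            "scale": scale,
        },
    )


def select_lambda(
    kspace_full: KSpaceVolume,
    pattern: SamplingPattern,
    lam_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    config: ReconConfig = ReconConfig(),
    lung_threshold: float | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pick lambda by minimizing RMSE against the fully sampled reconstruction.

    The full k-space is retrospectively undersampled with ``pattern`` and
    reconstructed once per candidate lambda; the RMSE against the fully
    sampled magnitude image is evaluated only over voxels above
    ``lung_threshold`` (default: 10% of the reference's 99th-percentile
    magnitude) so that only lung signal drives the choice.  Returns
    (lambda*, lam_grid, rmse_curve); ties go to the smaller lambda.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0:
        raise InvalidParameterError("lam_grid must be non-empty")
    ref = ifft_reconstruct(kspace_full).values
    if lung_threshold is None:
        lung_threshold = 0.1 * float(np.percentile(ref, 99.0))
    eval_mask = ref >= lung_threshold
    if not eval_mask.any():
        eval_mask = np.ones_like(ref, dtype=bool)
    under = undersample(kspace_full, pattern)
    rmse = np.empty(lam_grid.size)
    for i, lam in enumerate(lam_grid):
        img = cs_reconstruct(under, pattern, replace(config, lam=float(lam))).values
        rmse[i] = float(np.sqrt(np.mean((img[eval_mask] - ref[eval_mask]) ** 2)))
    best = int(np.argmin(rmse))
    return float(lam_grid[best]), lam_grid, rmse
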