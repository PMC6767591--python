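"""Image quantification: SNR, ventilated volume, VDP, RMSE and agreement.

SNR of a magnitude MR image is estimated from a signal ROI and a background
(noise) ROI as 0.66 x mean(signal) / std(noise): the background of a
magnitude image is Rayleigh-distributed, whose standard deviation is
sqrt(2 - pi/2) ~ 0.655 times the per-channel Gaussian sigma, and 0.66 is
the conventional two-decimal rounding of that correction.

Ventilated volume (VV) is the volume of voxels whose signal exceeds a
threshold of (mean - 3 SD) of the image's signal statistics region, with
the trachea and main bronchi excluded; the ventilation defect percentage
(VDP) is the complement of VV as a percentage of total lung volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidParameterError

__all__ = [
    "RoiSpec",
    "VentilationResult",
    "AgreementStats",
    "rayleigh_correction",
    "RAYLEIGH_CORRECTION_2DP",
    "roi_mask",
    "measure_snr",
    "ventilated_volume",
    "vdp",
    "rmse_images",
    "agreement_stats",
]

#: Two-decimal Rayleigh correction factor as used in SNR reports.
RAYLEIGH_CORRECTION_2DP = 0.66


def rayleigh_correction(ndigits: int | None = None) -> float:
    """The Rayleigh noise correction sqrt(2 - pi/2) ~ 0.6551.

    With ``ndigits=2`` returns the conventional printed value 0.66.
    """
    value = float(np.sqrt(2.0 - np.pi / 2.0))
    return round(value, ndigits) if ndigits is not None else value


@dataclass(frozen=True)
class RoiSpec:
    """A circular 2D region of interest on a coronal (fixed-z) slice.

    ``center`` is in millimetres from the volume origin, ``diameter`` in mm
    (default 40 mm, i.e. the conventional 4 cm disc), ``plane`` the z slice
    index.  Set ``spherical=True`` for a 3D spherical ROI instead.
    """

    center: tuple[float, float, float]
    diameter: float = 40.0
    plane: int | None = None
    spherical: bool = False

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise InvalidParameterError("diameter must be > 0")


@dataclass(frozen=True)
class VentilationResult:
    """Summary ventilation metrics for one image."""

    snr: float | None
    ventilated_volume: float
    vdp: float
    threshold: float
    rois: tuple[RoiSpec, RoiSpec] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.vdp <= 100.0:
            raise InvalidParameterError("vdp must lie in [0, 100]")
        if self.ventilated_volume < 0:
            raise InvalidParameterError("ventilated_volume must be >= 0")


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman bias/limits plus correlation and the paired t-test."""

    bias: float
    loa_lower: float
    loa_upper: float
    correlation: float
    t_statistic: float
    p_value: float
    n: int

    @property
    def loa_halfwidth(self) -> float:
        return 0.5 * (self.loa_upper - self.loa_lower)


def _image_values(image) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Accept an ImageVolume or a bare array (voxel size 1 mm)."""
    if hasattr(image, "values") and hasattr(image, "voxel_size"):
        return np.asarray(image.values), tuple(image.voxel_size)
    return np.asarray(image), (1.0, 1.0, 1.0)


def roi_mask(shape: Sequence[int], voxel_size: Sequence[float], roi: RoiSpec) -> np.ndarray:
    """Boolean voxel mask of an ROI; raises if it does not fit in the volume."""
    shape = tuple(shape)
    vox = tuple(voxel_size)
    r = roi.diameter / 2.0
    for ax in range(3):
        if roi.center[ax] - r < 0 - 1e-9 and (ax < 2 or roi.spherical):
            raise InvalidParameterError("ROI extends outside the volume")
        if roi.center[ax] + r > shape[ax] * vox[ax] + 1e-9 and (ax < 2 or roi.spherical):
            raise InvalidParameterError("ROI extends outside the volume")
    coords = [(np.arange(n) + 0.5) * v for n, v in zip(shape, vox)]
    x = coords[0][:, None, None]
    y = coords[1][None, :, None]
    z = coords[2][None, None, :]
    if roi.spherical:
        d2 = (
            (x - roi.center[0]) ** 2
            + (y - roi.center[1]) ** 2
            + (z - roi.center[2]) ** 2
        )
        return d2 <= r**2
    plane = roi.plane if roi.plane is not None else int(roi.center[2] / vox[2])
    if not 0 <= plane < shape[2]:
        raise InvalidParameterError("ROI plane outside the volume")
    d2 = (x - roi.center[0]) ** 2 + (y - roi.center[1]) ** 2
    mask = np.zeros(shape, dtype=bool)
    mask[:, :, plane] = (d2 <= r**2)[:, :, 0]
    return mask


def measure_snr(image, signal_roi: RoiSpec, noise_roi: RoiSpec) -> float:
    """Rayleigh-corrected SNR: 0.66 x mean(signal ROI) / std(noise ROI)."""
    values, vox = _image_values(image)
    sig = values[roi_mask(values.shape, vox, signal_roi)]
    noise = values[roi_mask(values.shape, vox, noise_roi)]
    if sig.size == 0 or noise.size == 0:
        raise InvalidParameterError("empty ROI")
    sd = float(np.std(noise))
    if sd == 0:
        raise InvalidParameterError("noise ROI has zero variance; SNR undefined")
    return RAYLEIGH_CORRECTION_2DP * float(np.mean(sig)) / sd


def default_stats_region(values: np.ndarray, fraction: float = 0.5) -> np.ndarray:
    """Crude signal foreground: voxels above ``fraction`` of the 99th percentile.

    The '3 SD below the mean' threshold needs a region over which mean and
    SD of the signal are taken; this foreground proxy stands in for a lung
    segmentation and is configurable wherever it is used.  The default
    fraction of 0.5 keeps the Rayleigh background tail out of the
    statistics down to single-breath-hold SNR levels (~5); a looser
    fraction lets background voxels deflate the mean and inflate the SD
    until the threshold drops below the noise floor.
    """
    return values >= fraction * float(np.percentile(values, 99.0))


def ventilated_volume(
    image,
    airway_mask: np.ndarray | None = None,
    stats_region: np.ndarray | None = None,
    voxel_size: Sequence[float] | None = None,
) -> tuple[float, float, np.ndarray]:
    """Threshold-based ventilated volume in litres.

    The threshold is mean - 3 SD of the image over ``stats_region``
    (default: the 10%-of-99th-percentile foreground); voxels at or above it
    and outside ``airway_mask`` count as ventilated.  Returns
    (volume_litres, threshold, ventilation_mask).
    """
    values, vox = _image_values(image)
    if voxel_size is not None:
        vox = tuple(voxel_size)
    region = default_stats_region(values) if stats_region is None else stats_region
    if not np.any(region):
        raise InvalidParameterError("stats_region is empty")
    sel = values[region]
    threshold = float(np.mean(sel) - 3.0 * np.std(sel))
    vent = values >= threshold
    if airway_mask is not None:
        vent &= ~airway_mask
    volume = float(vent.sum()) * float(np.prod(vox)) * 1e-6
    return volume, threshold, vent


def vdp(total_volume: float, ventilated: float) -> float:
    """Ventilation defect percentage: 100 (total - ventilated) / total."""
    if total_volume <= 0:
        raise InvalidParameterError("total_volume must be > 0")
    if ventilated < 0 or ventilated > total_volume + 1e-12:
        raise InvalidParameterError("need 0 <= ventilated <= total")
    return 100.0 * (total_volume - ventilated) / total_volume


def rmse_images(
    reference,
    test,
    eval_mask: np.ndarray | None = None,
    scale_to: float | None = None,
) -> tuple[float, float | None]:
    """RMSE between two images over a mask, optionally relative to a baseline.

    Returns (rmse, rmse/scale_to) where ``scale_to`` is typically the RMSE
    of a reference comparison (e.g. the lowest acceleration), making the
    second value a relative index of similarity.
    """
    ref, _ = _image_values(reference)
    tst, _ = _image_values(test)
    if ref.shape != tst.shape:
        raise InvalidParameterError("image shapes differ")
    mask = np.ones(ref.shape, dtype=bool) if eval_mask is None else eval_mask
    if not np.any(mask):
        raise InvalidParameterError("eval_mask is empty")
    rmse = float(np.sqrt(np.mean((ref[mask] - tst[mask]) ** 2)))
    rel = rmse / scale_to if scale_to else None
    return rmse, rel


def agreement_stats(a: Sequence[float], b: Sequence[float] | None = None) -> AgreementStats:
    """Bland-Altman agreement between paired measurements.

    Accepts either an (n, 2) array of pairs or two equal-length vectors;
    differences are second minus first.  bias = mean difference, limits of
    agreement = bias +/- 1.96 SD(differences) (sample SD, ddof=1), Pearson
    correlation, and the paired t statistic t = bias / (SD/sqrt(n)) with
    its two-sided p-value.
    """
    if b is None:
        pairs = np.asarray(a, dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise InvalidParameterError("pairs must be (n, 2)")
        first, second = pairs[:, 0], pairs[:, 1]
    else:
        first = np.asarray(a, dtype=float)
        second = np.asarray(b, dtype=float)
        if first.shape != second.shape or first.ndim != 1:
            raise InvalidParameterError("paired vectors must be equal-length 1D")
    n = first.size
    if n < 2:
        raise InvalidParameterError("need at least 2 pairs for dispersion statistics")
    diff = second - first
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    loa = 1.96 * sd
    if np.std(first) == 0 or np.std(second) == 0:
        corr = 1.0 if np.allclose(first + bias, second) else float("nan")
    else:
        corr = float(np.corrcoef(first, second)[0, 1])
    if sd == 0:
        t_stat = 0.0 if bias == 0 else float(np.inf) * np.sign(bias)
        p = 1.0 if bias == 0 else 0.0
    else:
        t_stat = bias / (sd / np.sqrt(n))
        p = float(2.0 * stats.t.sf(abs(t_stat), df=n - 1))
    return AgreementStats(
        bias=bias,
        loa_lower=bias - loa,
        loa_upper=bias + loa,
        correlation=corr,
        t_statistic=float(t_stat),
        p_value=p,
        n=int(n),
    )
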