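"""Phase-encode window and Poisson-disc undersampling patterns.

A 3D Cartesian gradient-echo scan encodes a (ky, kz) grid of phase-encode
lines (right-left and anterior-posterior); the readout axis kx is always
fully sampled.  An elliptical shutter discards the corner encodes outside
the inscribed ellipse; compressed sensing then undersamples the remaining
encodes with a uniform-density Poisson-disc pattern whose minimum pairwise
distance makes the aliasing incoherent, while a small central block is kept
fully sampled to preserve image contrast.

Index convention: the DC line sits at index N//2 on each axis (the
``fftshift`` centre) and the shutter semi-axes are ⌊N/2⌋, boundary inclusive.
On a 32 x 25 grid this retains exactly 592 encodes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleSamplingError, InvalidParameterError

__all__ = [
    "SamplingPattern",
    "elliptical_window",
    "poisson_disc_pattern",
    "pattern_scan_time",
    "undersample",
]


@dataclass(frozen=True)
class SamplingPattern:
    """Binary phase-encode sampling mask over a (Ny, Nz) grid.

    ``mask`` is a subset of ``window`` (the elliptical shutter); the
    centred ``center_block`` (height x width, ky x kz) is always fully
    sampled.  ``accel_achieved`` is window count / sampled count.
    """

    mask: np.ndarray
    window: np.ndarray
    accel_target: float
    accel_achieved: float
    center_block: tuple[int, int]
    seed: int
    n_sampled: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _signed_axis(n: int) -> np.ndarray:
    """Signed k indices with DC at n//2: -⌊n/2⌋ .. ⌈n/2⌉-1."""
    return np.arange(n) - n // 2


def elliptical_window(ny: int, nz: int) -> np.ndarray:
    """Boolean elliptical shutter over the (ky, kz) phase-encode grid.

    Keeps (ky, kz) with (ky/ry)^2 + (kz/rz)^2 <= 1 in signed indices with
    radii ry = ⌊Ny/2⌋, rz = ⌊Nz/2⌋.  An axis of length 1 contributes zero
    (the DC line is always inside).  Deterministic.
    """
    if ny < 1 or nz < 1:
        raise InvalidParameterError("ny and nz must be >= 1")
    ky = _signed_axis(ny)[:, None].astype(float)
    kz = _signed_axis(nz)[None, :].astype(float)
    ty = np.zeros_like(ky) if ny == 1 else (ky / (ny // 2)) ** 2
    tz = np.zeros_like(kz) if nz == 1 else (kz / (nz // 2)) ** 2
    return (ty + tz) <= 1.0


def _center_block_mask(ny: int, nz: int, block: tuple[int, int]) -> np.ndarray:
    h, w = block
    if h > ny or w > nz:
        raise InvalidParameterError("center block larger than grid")
    y0 = ny // 2 - h // 2
    z0 = nz // 2 - w // 2
    out = np.zeros((ny, nz), dtype=bool)
    out[y0 : y0 + h, z0 : z0 + w] = True
    return out


def _dart_throw(
    coords: np.ndarray, forced: np.ndarray, radius: float, rng: np.random.Generator
) -> np.ndarray:
    """Greedy dart throwing: accept candidates at >= radius from all accepted.

    ``coords`` are (n, 2) window coordinates, ``forced`` a boolean over them
    marking always-accepted (centre block) points.  Returns a boolean accept
    vector.  O(n^2) but n <= a few thousand for realistic encode grids.
    """
    accepted = forced.copy()
    order = rng.permutation(np.flatnonzero(~forced))
    acc_pts = coords[accepted]
    r2 = radius * radius
    acc_list = list(acc_pts)
    for i in order:
        p = coords[i]
        ok = True
        for q in acc_list:
            d0 = p[0] - q[0]
            d1 = p[1] - q[1]
            if d0 * d0 + d1 * d1 < r2:
                ok = False
                break
        if ok:
            accepted[i] = True
            acc_list.append(p)
    return accepted


def poisson_disc_pattern(
    ny: int,
    nz: int,
    accel: float,
    center_block: tuple[int, int] = (8, 7),
    seed: int = 0,
) -> SamplingPattern:
    """Uniform-density Poisson-disc undersampling with a fully sampled centre.

    Exactly ``round(window_count / accel)`` encodes are sampled: the disc
    radius is tuned by bisection to approach the target count, then points
    are randomly trimmed or filled (under the same seed) to hit it exactly.
    Reproducible bit-for-bit given (ny, nz, accel, seed).
    """
    if accel < 1.0:
        raise InvalidParameterError("accel must be >= 1")
    window = elliptical_window(ny, nz)
    n_window = int(window.sum())
    n_target = int(round(n_window / accel))
    block = _center_block_mask(ny, nz, center_block) & window
    n_block = int(block.sum())
    if n_target < n_block:
        raise InfeasibleSamplingError(
            f"accel={accel} leaves {n_target} samples, fewer than the "
            f"{n_block}-point fully sampled centre block"
        )

    mask = np.zeros((ny, nz), dtype=bool)
    if n_target >= n_window:
        mask[:] = window
    else:
        coords = np.argwhere(window).astype(float)
        forced = block[window]
        rng = np.random.default_rng(seed)
        # Bisection on the disc radius; re-seeded identically per evaluation
        # so the final pattern depends only on (grid, accel, seed).
        sub = int(rng.integers(0, 2**31 - 1))
        lo, hi = 0.0, float(max(ny, nz))
        best = None
        for _ in range(25):
            mid = 0.5 * (lo + hi)
            acc = _dart_throw(coords, forced, mid, np.random.default_rng(sub))
            n_acc = int(acc.sum())
            if best is None or abs(n_acc - n_target) < abs(int(best.sum()) - n_target):
                best = acc
            if n_acc > n_target:
                lo = mid
            else:
                hi = mid
        acc = best
        # Exact trim/fill, never touching the centre block.
        n_acc = int(acc.sum())
        if n_acc > n_target:
            removable = np.flatnonzero(acc & ~forced)
            drop = rng.choice(removable, size=n_acc - n_target, replace=False)
            acc[drop] = False
        elif n_acc < n_target:
            addable = np.flatnonzero(~acc)
            add = rng.choice(addable, size=n_target - n_acc, replace=False)
            acc[add] = True
        mask[window] = acc

    n_sampled = int(mask.sum())
    return SamplingPattern(
        mask=mask,
        window=window,
        accel_target=float(accel),
        accel_achieved=n_window / n_sampled,
        center_block=tuple(center_block),
        seed=int(seed),
        n_sampled=n_sampled,
    )


def pattern_scan_time(pattern: SamplingPattern, tr: float, nsa: int = 1) -> float:
    """Scan duration in seconds: sampled encodes x TR x averages."""
    if tr <= 0:
        raise InvalidParameterError("tr must be > 0")
    if nsa < 1:
        raise InvalidParameterError("nsa must be >= 1")
    return pattern.n_sampled * tr * nsa


def undersample(kspace, pattern: SamplingPattern):
    """Apply the phase-encode selection operator D to a k-space volume.

    Zeroes every (ky, kz) line not in ``pattern.mask`` across the full
    readout axis and attaches the mask to the result.  Idempotent.
    """
    from .recon import KSpaceVolume  # local import to avoid a cycle

    if kspace.data.shape[1:] != pattern.mask.shape:
        raise InvalidParameterError(
            f"pattern shape {pattern.mask.shape} does not match k-space "
            f"phase-encode dims {kspace.data.shape[1:]}"
        )
    data = kspace.data * pattern.mask[None, :, :]
    return KSpaceVolume(
        data=data,
        mask=pattern,
        geometry=kspace.geometry,
        noise_sigma=kspace.noise_sigma,
    )
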