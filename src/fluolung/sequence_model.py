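"""Steady-state SPGR signal model and SNR-optimal acquisition parameter search.

The signal of a spoiled gradient echo (SPGR) sequence in steady state is

    S(theta, TR, TE) = (1 - E1) sin(theta) / (1 - E1 cos(theta)) * exp(-TE/T2*),

with ``E1 = exp(-TR/T1)``.  For imaging a fixed field of view in a fixed
total scan time the *relative* SNR of a 3D Cartesian SPGR acquisition is

    SNR ∝ sqrt( FOVx FOVy FOVz T_scan / (Nx^2 Ny^2 Nz^2 TR BW) ) * S,

so short-T1 nuclei (perfluoropropane, T1 ≈ 12 ms at 3 T) reward short TR
and heavy averaging, while short T2* (≈ 2 ms) penalises long echo times and
hence low receiver bandwidths and long RF pulses.  The achievable TR is
bounded below by pulse/encode/readout timing and, at high B1 amplitude and
duty cycle, by IEC 60601-2-33 specific-absorption-rate (SAR) limits, which
force TR extension.  :func:`optimize_parameters` grids over flip angle,
bandwidth and optionally B1 and returns the SNR surface and its argmax.

All quantities are SI internally: seconds, tesla, Hz.  Flip angles are in
degrees at the API boundary because that is how protocols are written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping, Sequence

import numpy as np

from .errors import ConstraintViolationError, InvalidParameterError

__all__ = [
    "GAMMA_19F",
    "GAMMA_1H",
    "RelaxationParams",
    "HardwareModel",
    "AcquisitionGeometry",
    "SequenceParams",
    "SnrSurface",
    "spgr_signal",
    "ernst_angle_deg",
    "rf_pulse_duration",
    "te_min",
    "tr_min",
    "sar_estimate",
    "sar_limited_tr",
    "snr_spgr",
    "optimize_parameters",
    "default_hardware",
]

#: Gyromagnetic ratio of 19F, Hz per tesla.
GAMMA_19F = 40.05e6
#: Gyromagnetic ratio of 1H, Hz per tesla (for reuse with proton protocols).
GAMMA_1H = 42.577e6

#: IEC 60601-2-33 SAR limits in W/kg by operating mode.
SAR_LIMITS: Mapping[str, float] = MappingProxyType(
    {
        "whole-body-normal": 2.0,
        "whole-body-first-level": 4.0,
        "local-torso": 10.0,
    }
)


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not np.all(np.asarray(value) > 0):
            raise InvalidParameterError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class RelaxationParams:
    """Longitudinal and effective transverse relaxation times, in seconds.

    Defaults are the in vivo values for inhaled perfluoropropane at 3 T
    (T1 = 12.4 ms, T2* = 2.2 ms).
    """

    t1: float = 12.4e-3
    t2_star: float = 2.2e-3

    def __post_init__(self) -> None:
        _require_positive(t1=self.t1, t2_star=self.t2_star)
        if self.t2_star > self.t1:
            raise InvalidParameterError(
                f"t2_star ({self.t2_star}) must not exceed t1 ({self.t1})"
            )


@dataclass(frozen=True)
class HardwareModel:
    """Scanner/coil timing and RF-power model.

    ``encode_overhead`` lumps phase-encode and readout-prewind gradient time
    into a single configurable constant; ``sar_coefficient`` maps the
    time-averaged squared B1 (tesla^2 x duty cycle) to W/kg for the coil in
    use.  Both are hardware dependent and deliberately exposed as plain
    configuration: printed optima such as "500 Hz/pixel, 40 degrees" shift
    with these constants.
    """

    gamma: float = GAMMA_19F
    b1_max: float = 10e-6
    encode_overhead: float = 0.5e-3
    spoiler_duration: float = 1.0e-3
    sar_coefficient: float = 0.0  # set by default_hardware(); 0 disables SAR
    sar_limits: Mapping[str, float] = field(default_factory=lambda: dict(SAR_LIMITS))

    def __post_init__(self) -> None:
        _require_positive(gamma=self.gamma, b1_max=self.b1_max)
        if self.encode_overhead < 0 or self.spoiler_duration < 0:
            raise InvalidParameterError("durations must be >= 0")
        if self.sar_coefficient < 0:
            raise InvalidParameterError("sar_coefficient must be >= 0")
        for mode, limit in self.sar_limits.items():
            if limit <= 0:
                raise InvalidParameterError(f"sar_limits[{mode!r}] must be > 0")


def default_hardware(
    *,
    calibration_b1: float = 4e-6,
    calibration_flip_deg: float = 50.0,
    calibration_tr: float = 7.5e-3,
    calibration_sar: float = 10.0,
    **overrides,
) -> HardwareModel:
    """Hardware model with the SAR coefficient calibrated to a reference protocol.

    No coil-specific SAR coefficient is publicly available for the 19F chest
    birdcage, so the default is pinned by assuming the reference in vivo
    protocol (B1 = 4 uT block pulse, 50 degree flip, TR = 7.5 ms) operates
    exactly at the 10 W/kg local-torso limit.  This is a calibration
    assumption, not a measurement; override ``sar_coefficient`` for a real
    coil.
    """
    hw = HardwareModel(**{k: v for k, v in overrides.items() if k != "sar_coefficient"})
    if "sar_coefficient" in overrides:
        coeff = overrides["sar_coefficient"]
    else:
        tau = rf_pulse_duration(calibration_flip_deg, calibration_b1, hw)
        duty = tau / calibration_tr
        coeff = calibration_sar / (calibration_b1**2 * duty)
    return HardwareModel(
        **{**{k: getattr(hw, k) for k in ("gamma", "b1_max", "encode_overhead", "spoiler_duration", "sar_limits")},
           "sar_coefficient": coeff}
    )


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Imaging geometry and the fixed scan-time budget for optimization.

    fov is (x, y, z) in millimetres with x the readout direction; matrix is
    the (Nx, Ny, Nz) encode counts; bw is receiver bandwidth in Hz/pixel;
    nsa the number of signal averages; t_scan the total scan budget in
    seconds.  Defaults mirror a breath-hold 19F protocol (FOV
    400x320x250 mm, matrix 112x90x25, 500 Hz/px, 18 s).
    """

    fov: tuple[float, float, float] = (400.0, 320.0, 250.0)
    matrix: tuple[int, int, int] = (112, 90, 25)
    bw: float = 500.0
    nsa: int = 4
    t_scan: float = 18.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.matrix):
            raise InvalidParameterError("matrix entries must be >= 1")
        _require_positive(bw=self.bw, t_scan=self.t_scan)
        if any(f <= 0 for f in self.fov):
            raise InvalidParameterError("fov must be positive")
        if self.nsa < 1:
            raise InvalidParameterError("nsa must be >= 1")

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        """Acquired voxel size in mm."""
        return tuple(f / n for f, n in zip(self.fov, self.matrix))


@dataclass(frozen=True)
class SequenceParams:
    """A concrete SPGR parameter set (degrees / tesla / seconds)."""

    flip_deg: float
    b1: float
    tr: float
    te: float
    pulse_duration: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_deg <= 90.0:
            raise InvalidParameterError("flip_deg must lie in [0, 90]")
        if self.te >= self.tr:
            raise InvalidParameterError("te must be < tr")
        if self.flip_deg > 0 and self.pulse_duration <= 0:
            raise InvalidParameterError("pulse_duration must be > 0 for nonzero flip")


@dataclass(frozen=True)
class SnrSurface:
    """Relative-SNR surface over a (flip, bw, b1) grid with its argmax.

    ``snr``, ``sar`` and ``tr_used`` are arrays of shape
    (len(flip_deg), len(bw), len(b1)).  ``optimum`` is a dict with keys
    flip_deg, bw, b1, tr, te, snr.  Ties in the argmax are broken toward
    smaller flip, then smaller bw, then smaller b1.
    """

    flip_deg: np.ndarray
    bw: np.ndarray
    b1: np.ndarray
    snr: np.ndarray
    sar: np.ndarray
    tr_used: np.ndarray
    te_used: np.ndarray
    sar_limit: float
    optimum: dict


def spgr_signal(flip_deg, tr, te, relax: RelaxationParams):
    """Relative steady-state SPGR signal amplitude (dimensionless).

    Accepts scalars or broadcastable arrays for flip_deg/tr/te.
    """
    tr = np.asarray(tr, dtype=float)
    te = np.asarray(te, dtype=float)
    if np.any(tr <= 0):
        raise InvalidParameterError("tr must be > 0")
    if np.any(te < 0):
        raise InvalidParameterError("te must be >= 0")
    theta = np.deg2rad(np.asarray(flip_deg, dtype=float))
    e1 = np.exp(-tr / relax.t1)
    sig = (1.0 - e1) * np.sin(theta) / (1.0 - e1 * np.cos(theta))
    out = sig * np.exp(-te / relax.t2_star)
    return out if out.ndim else float(out)


def ernst_angle_deg(tr: float, t1: float) -> float:
    """Flip angle (degrees) maximizing SPGR signal at fixed TR: arccos(e^(-TR/T1))."""
    _require_positive(tr=tr, t1=t1)
    return float(np.rad2deg(np.arccos(np.exp(-tr / t1))))


def rf_pulse_duration(flip_deg, b1, hardware: HardwareModel):
    """Duration (s) of a nonselective block pulse achieving ``flip_deg`` at ``b1``.

    tau = (flip/360) / (gamma * B1): a full 360-degree rotation takes one
    period of the Rabi frequency gamma*B1.
    """
    b1 = np.asarray(b1, dtype=float)
    if np.any(b1 <= 0):
        raise InvalidParameterError("b1 must be > 0")
    flip = np.asarray(flip_deg, dtype=float)
    if np.any(flip <= 0):
        raise InvalidParameterError("flip_deg must be > 0")
    out = (flip / 360.0) / (hardware.gamma * b1)
    return out if out.ndim else float(out)


def te_min(geometry: AcquisitionGeometry, pulse_duration, hardware: HardwareModel):
    """Minimum echo time: half the RF pulse + encode overhead + half the readout.

    The readout duration is Nx dwell times = Nx / (BW * Nx) = 1/BW for BW in
    Hz/pixel.
    """
    if geometry.bw <= 0:
        raise InvalidParameterError("bw must be > 0")
    t_ro = 1.0 / geometry.bw
    tau = np.asarray(pulse_duration, dtype=float)
    out = tau / 2.0 + hardware.encode_overhead + t_ro / 2.0
    return out if out.ndim else float(out)


def tr_min(te, geometry: AcquisitionGeometry, hardware: HardwareModel):
    """Minimum TR: finish the readout after TE, then the spoiler."""
    if geometry.bw <= 0:
        raise InvalidParameterError("bw must be > 0")
    te = np.asarray(te, dtype=float)
    if np.any(te < 0):
        raise InvalidParameterError("te must be >= 0")
    out = te + 0.5 / geometry.bw + hardware.spoiler_duration
    return out if out.ndim else float(out)


def sar_estimate(b1, pulse_duration, tr, hardware: HardwareModel):
    """Time-averaged SAR (W/kg) of the block-pulse train: C * B1^2 * tau/TR."""
    tr = np.asarray(tr, dtype=float)
    if np.any(tr <= 0):
        raise InvalidParameterError("tr must be > 0")
    b1 = np.asarray(b1, dtype=float)
    tau = np.asarray(pulse_duration, dtype=float)
    out = hardware.sar_coefficient * b1**2 * tau / tr
    return out if out.ndim else float(out)


def sar_limited_tr(tr_minimum, b1, pulse_duration, sar_limit: float, hardware: HardwareModel):
    """Extend TR beyond its timing minimum where needed to respect ``sar_limit``."""
    if sar_limit <= 0:
        raise InvalidParameterError("sar_limit must be > 0")
    b1 = np.asarray(b1, dtype=float)
    tau = np.asarray(pulse_duration, dtype=float)
    tr_sar = hardware.sar_coefficient * b1**2 * tau / sar_limit
    out = np.maximum(np.asarray(tr_minimum, dtype=float), tr_sar)
    return out if out.ndim else float(out)


def snr_spgr(
    geometry: AcquisitionGeometry,
    sequence: SequenceParams,
    relax: RelaxationParams,
    hardware: HardwareModel | None = None,
) -> float:
    """Relative SNR of a full 3D SPGR acquisition in the fixed scan budget.

    If ``hardware`` is given, TE is validated against the configuration's
    minimum echo time.  Only ratios of returned values are meaningful.
    """
    if hardware is not None and sequence.flip_deg > 0:
        floor = te_min(geometry, sequence.pulse_duration, hardware)
        if sequence.te < floor - 1e-12:
            raise ConstraintViolationError(
                f"te={sequence.te} below te_min={floor} for this configuration"
            )
    fx, fy, fz = geometry.fov
    nx, ny, nz = geometry.matrix
    radical = (fx * fy * fz * geometry.t_scan) / (
        nx**2 * ny**2 * nz**2 * sequence.tr * geometry.bw
    )
    return float(
        np.sqrt(radical)
        * spgr_signal(sequence.flip_deg, sequence.tr, sequence.te, relax)
    )


def _default_grids() -> tuple[np.ndarray, np.ndarray]:
    return np.arange(0.0, 90.0 + 0.5, 1.0), np.arange(10.0, 1500.0 + 5.0, 10.0)


def optimize_parameters(
    geometry: AcquisitionGeometry,
    relax: RelaxationParams,
    hardware: HardwareModel,
    sar_limit: float,
    flip_grid: Sequence[float] | None = None,
    bw_grid: Sequence[float] | None = None,
    b1_grid: Sequence[float] | None = None,
) -> SnrSurface:
    """Grid-search the relative SNR over (flip, bw, b1) under the SAR limit.

    For every grid point the pulse duration, minimum TE, minimum TR and
    SAR-extended TR are derived before evaluating the SNR.  Grid points with
    bw <= 0 or b1 <= 0 are assigned SNR 0 (flip = 0 yields SNR 0 naturally).
    Default grids: flip 0..90 deg step 1, bw 10..1500 Hz/px step 10, b1
    fixed at 4 uT.  The argmax is deterministic: first maximum in
    (flip, bw, b1) order, i.e. ties go to smaller flip, then bw, then b1.
    """
    if sar_limit <= 0:
        raise InvalidParameterError("sar_limit must be > 0")
    dflip, dbw = _default_grids()
    flips = np.asarray(dflip if flip_grid is None else flip_grid, dtype=float)
    bws = np.asarray(dbw if bw_grid is None else bw_grid, dtype=float)
    b1s = np.asarray([4e-6] if b1_grid is None else b1_grid, dtype=float)
    if flips.size == 0 or bws.size == 0 or b1s.size == 0:
        raise InvalidParameterError("grids must be non-empty")

    F = flips[:, None, None]
    B = bws[None, :, None]
    B1 = b1s[None, None, :]
    valid = (F > 0) & (B > 0) & (B1 > 0)

    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(valid, (F / 360.0) / (hardware.gamma * np.where(B1 > 0, B1, 1.0)), 0.0)
        t_ro = np.where(B > 0, 1.0 / np.where(B > 0, B, 1.0), np.inf)
        te = tau / 2.0 + hardware.encode_overhead + t_ro / 2.0
        trm = te + t_ro / 2.0 + hardware.spoiler_duration
        tr_sar = hardware.sar_coefficient * B1**2 * tau / sar_limit
        tr = np.maximum(trm, tr_sar)
        theta = np.deg2rad(F)
        e1 = np.exp(-tr / relax.t1)
        sig = (1.0 - e1) * np.sin(theta) / (1.0 - e1 * np.cos(theta))
        sig = sig * np.exp(-te / relax.t2_star)
        fx, fy, fz = geometry.fov
        nx, ny, nz = geometry.matrix
        radical = (fx * fy * fz * geometry.t_scan) / (nx**2 * ny**2 * nz**2 * tr * B)
        snr = np.where(valid, np.sqrt(np.where(radical > 0, radical, 0.0)) * sig, 0.0)
        sar = np.where(valid, hardware.sar_coefficient * B1**2 * tau / tr, 0.0)

    snr = np.nan_to_num(snr, nan=0.0, posinf=0.0, neginf=0.0)
    sar = np.nan_to_num(sar, nan=0.0, posinf=0.0, neginf=0.0)
    if not np.any(snr > 0):
        raise InvalidParameterError("no feasible grid point yields positive SNR")
    idx = np.unravel_index(int(np.argmax(snr)), snr.shape)
    optimum = {
        "flip_deg": float(flips[idx[0]]),
        "bw": float(bws[idx[1]]),
        "b1": float(b1s[idx[2]]),
        "tr": float(tr[idx]),
        "te": float(te[idx]),
        "snr": float(snr[idx]),
    }
    return SnrSurface(
        flip_deg=flips,
        bw=bws,
        b1=b1s,
        snr=snr,
        sar=sar,
        tr_used=tr,
        te_used=np.broadcast_to(te, snr.shape).copy(),
        sar_limit=float(sar_limit),
        optimum=optimum,
    )
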