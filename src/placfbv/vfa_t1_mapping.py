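"""Spoiled-GRE signal model and variable-flip-angle (VFA) T1 estimation.

The steady-state spoiled gradient-recalled-echo signal at flip angle alpha is

    S(alpha) = M0 * (1 - E1) * exp(-TE/T2) * sin(alpha) / (1 - cos(alpha)*E1),
    E1 = exp(-TR/T1).

In the T1-weighted regime (TE << T2) the exp(-TE/T2) factor is ~1 and drops
out; since it is flip-angle independent it only rescales all signals by a
common factor, which the VFA estimator is exactly invariant to.  The
estimator uses the classic linearization (DESPOT1): plotting
y = S/sin(alpha) against x = S/tan(alpha) over flip angles at fixed TR gives
a straight line with slope E1 and intercept M0*(1-E1), so an ordinary
least-squares fit yields T1 = -TR/ln(slope) and M0 = intercept/(1-slope).

ROI-mean fitting (pool the mean signal per flip angle, then fit once) is the
primary path used for FBV; voxelwise maps are provided for inspection.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .core_io import (
    T1_INVALID,
    AcquisitionParams,
    ImageVolume,
    Modality,
    PipelineError,
    ROIMask,
)

#: fitted T1 values outside this window (ms) are flagged invalid; guards
#: against ln() of slopes driven to ~1 or ~0 by noise
T1_VALID_RANGE_MS = (1.0, 10000.0)


@dataclasses.dataclass
class VFASignalSet:
    """Signals observed at each flip angle of one VFA acquisition."""

    flip_angles_deg: tuple[float, ...]
    signals: tuple[float, ...]
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        self.flip_angles_deg = tuple(float(a) for a in self.flip_angles_deg)
        self.signals = tuple(float(s) for s in self.signals)
        if len(self.flip_angles_deg) != len(self.signals):
            raise PipelineError("flip-angle and signal lists differ in length")
        if len(self.signals) < 2:
            raise PipelineError(">= 2 flip angles required")
        if any(s < 0 for s in self.signals):
            raise PipelineError("signals must be >= 0")


@dataclasses.dataclass
class T1FitResult:
    """One VFA fit: T1/M0 plus linear-fit diagnostics.

    ``slope`` is the fitted estimate of exp(-TR/T1); ``valid`` requires
    0 < slope < 1 and T1 inside :data:`T1_VALID_RANGE_MS`.  Invalid fits
    carry a human-readable ``reason`` instead of raising.
    """

    t1_ms: float
    m0: float
    slope: float
    intercept: float
    r_squared: float
    valid: bool
    reason: str | None = None


def gre_signal(
    m0,
    t1_ms,
    acq: AcquisitionParams,
    alpha_deg,
    t2_ms=None,
):
    """Evaluate the spoiled-GRE steady-state signal.

    With ``t2_ms`` given, the full model including exp(-TE/T2) is used;
    without it, the TE << T2 approximation applies.  Broadcasts over numpy
    arrays in any argument.
    """
    t1 = np.asarray(t1_ms, dtype=np.float64)
    if np.any(t1 <= 0):
        raise PipelineError("t1_ms must be > 0")
    m0a = np.asarray(m0, dtype=np.float64)
    if np.any(m0a < 0):
        raise PipelineError("m0 must be >= 0")
    alpha = np.deg2rad(np.asarray(alpha_deg, dtype=np.float64))
    e1 = np.exp(-acq.tr_ms / t1)
    s = m0a * (1.0 - e1) * np.sin(alpha) / (1.0 - np.cos(alpha) * e1)
    if t2_ms is not None:
        t2 = np.asarray(t2_ms, dtype=np.float64)
        if np.any(t2 <= 0):
            raise PipelineError("t2_ms must be > 0")
        s = s * np.exp(-acq.te_ms / t2)
    if s.ndim == 0:
        return float(s)
    return s


def ernst_angle_deg(t1_ms: float, tr_ms: float) -> float:
    """Flip angle maximizing the spoiled-GRE signal: arccos(exp(-TR/T1))."""
    return math.degrees(math.acos(math.exp(-tr_ms / t1_ms)))


def linearize_vfa(signal_set: VFASignalSet) -> list[tuple[float, float]]:
    """Map a signal set to (x, y) = (S*cos/sin, S/sin) pairs, order preserved.

    x is computed as S*cos(alpha)/sin(alpha) so that alpha = 90 deg yields
    x = 0 exactly rather than a division by tan's pole.
    """
    pairs = []
    for a_deg, s in zip(signal_set.flip_angles_deg, signal_set.signals):
        a = math.radians(a_deg)
        # cos(pi/2) is not exactly zero in floats; pin the 90 deg case
        cot = 0.0 if a_deg == 90.0 else math.cos(a) / math.sin(a)
        pairs.append((s * cot, s / math.sin(a)))
    return pairs


def fit_t1_vfa(signal_set: VFASignalSet) -> T1FitResult:
    """Ordinary least squares on the linearized VFA relation.

    Degenerate inputs (all-zero signals, coincident x values, slope outside
    (0, 1), T1 outside the validity window) produce an invalid result with a
    reason rather than an exception.
    """
    pairs = linearize_vfa(signal_set)
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx <= np.finfo(float).tiny * max(1.0, float(np.sum(x**2))):
        return T1FitResult(
            t1_ms=math.nan, m0=math.nan, slope=math.nan, intercept=math.nan,
            r_squared=math.nan, valid=False, reason="degenerate flip-angle response",
        )
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    r_squared = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot

    if not 0.0 < slope < 1.0:
        return T1FitResult(
            t1_ms=math.nan, m0=math.nan, slope=slope, intercept=intercept,
            r_squared=r_squared, valid=False,
            reason=f"slope {slope:.4g} outside (0, 1)",
        )
    t1_ms = -signal_set.acq.tr_ms / math.log(slope)
    m0 = intercept / (1.0 - slope)
    lo, hi = T1_VALID_RANGE_MS
    if not lo < t1_ms < hi:
        return T1FitResult(
            t1_ms=t1_ms, m0=m0, slope=slope, intercept=intercept,
            r_squared=r_squared, valid=False,
            reason=f"T1 {t1_ms:.4g} ms outside validity window ({lo}, {hi})",
        )
    return T1FitResult(
        t1_ms=t1_ms, m0=m0, slope=slope, intercept=intercept,
        r_squared=r_squared, valid=True,
    )


def roi_mean_signal(vol: ImageVolume, mask: ROIMask, label: int) -> float:
    """Arithmetic mean of the volume over one labelled ROI."""
    mask.check_companion(vol)
    sel = mask.labels == label
    if not np.any(sel):
        raise PipelineError(f"label {label} selects no voxels")
    return float(vol.data[sel].mean())


def roi_signal_set(
    series: Sequence[ImageVolume], mask: ROIMask, label: int, acq: AcquisitionParams
) -> VFASignalSet:
    """Pool ROI-mean signals across a flip-angle series into one signal set."""
    ordered = _ordered_series(series, acq)
    sigs = [roi_mean_signal(v, mask, label) for v in ordered]
    return VFASignalSet(
        flip_angles_deg=acq.flip_angles_deg, signals=tuple(sigs), acq=acq
    )


def fit_t1_roi(
    series: Sequence[ImageVolume], mask: ROIMask, label: int, acq: AcquisitionParams
) -> T1FitResult:
    """ROI-mean VFA fit: pool mean signal per flip angle, then fit once."""
    return fit_t1_vfa(roi_signal_set(series, mask, label, acq))


def _ordered_series(
    series: Sequence[ImageVolume], acq: AcquisitionParams
) -> list[ImageVolume]:
    by_fa: dict[float, ImageVolume] = {}
    for vol in series:
        if vol.modality is not Modality.MR_SIGNAL or vol.flip_angle_deg is None:
            raise PipelineError("VFA series must be MR_SIGNAL volumes with flip angles")
        by_fa[float(vol.flip_angle_deg)] = vol
    missing = [a for a in acq.flip_angles_deg if a not in by_fa]
    if missing:
        raise PipelineError(f"series is missing flip angles {missing}")
    shapes = {by_fa[a].data.shape for a in acq.flip_angles_deg}
    if len(shapes) != 1:
        raise PipelineError(f"series volumes have mismatched shapes: {shapes}")
    return [by_fa[a] for a in acq.flip_angles_deg]


def fit_t1_voxelwise(
    series: Sequence[ImageVolume], acq: AcquisitionParams
) -> ImageVolume:
    """Per-voxel VFA fit over a co-registered flip-angle series.

    Returns a T1 map in milliseconds with invalid voxels (zero signal,
    degenerate or out-of-range fits) set to the -1 sentinel.
    """
    ordered = _ordered_series(series, acq)
    alphas = np.deg2rad(np.asarray(acq.flip_angles_deg))[:, None, None, None]
    s = np.stack([v.data for v in ordered], axis=0)
    y = s / np.sin(alphas)
    x = s * np.cos(alphas) / np.sin(alphas)
    xm = x.mean(axis=0)
    ym = y.mean(axis=0)
    sxx = np.sum((x - xm) ** 2, axis=0)
    sxy = np.sum((x - xm) * (y - ym), axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        ok = np.isfinite(slope) & (slope > 0.0) & (slope < 1.0) & (sxx > 0.0)
        t1 = np.where(ok, -acq.tr_ms / np.log(np.where(ok, slope, 0.5)), T1_INVALID)
    lo, hi = T1_VALID_RANGE_MS
    ok &= (t1 > lo) & (t1 < hi)
    t1 = np.where(ok, t1, T1_INVALID)
    ref = ordered[0]
    state = ref.contrast_state
    return ImageVolume(
        data=t1,
        voxel_size_mm=ref.voxel_size_mm,
        modality=Modality.T1_MAP,
        contrast_state=state,
    )
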