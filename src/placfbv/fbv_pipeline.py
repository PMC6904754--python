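"""Per-placenta fractional blood volume (FBV) estimation and cohort summaries.

MRI arm: FBV = dR1_P / dR1_IVC, the contrast-induced change in placental
longitudinal relaxation rate normalized by the change in pure blood (IVC).
CT arm: FBV = dHU_P / dHU_IVC on ROI-mean Hounsfield units.  Both are
unbiased under the fast-exchange linear-mixing model of a blood-pool agent.

Every placenta of a subject shares that subject's single IVC reference.
Out-of-range estimates (outside [0, 1]) are flagged, never clipped or
censored.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np

from .core_io import (
    AcquisitionParams,
    CompartmentRole,
    ContrastState,
    ImageVolume,
    PipelineError,
    ROIMask,
    StudyManifest,
    read_mask,
    read_volume,
)
from .vfa_t1_mapping import T1FitResult, fit_t1_roi, roi_mean_signal

#: default smallest acceptable blood-reference enhancement
DELTA_R1_MIN = 1e-6  # 1/ms
DELTA_HU_MIN = 1.0  # HU

FLAG_OUT_OF_RANGE = "OUT_OF_RANGE"
FLAG_INVALID_FIT = "INVALID_FIT"


class NoEnhancementError(PipelineError):
    """The blood reference shows no usable contrast enhancement."""


class StudyError(PipelineError):
    """A whole subject fails (e.g. the IVC T1 fit is invalid)."""


def relaxation_rate(t1_ms: float) -> float:
    """Longitudinal relaxation rate R1 = 1/T1, in 1/ms."""
    if not (isinstance(t1_ms, (int, float)) and math.isfinite(t1_ms) and t1_ms > 0):
        raise PipelineError(f"t1_ms must be a finite positive number, got {t1_ms}")
    return 1.0 / t1_ms


@dataclasses.dataclass
class RelaxometryPair:
    """Pre/post-contrast T1 of one compartment, with derived rates."""

    t1_pre_ms: float
    t1_post_ms: float
    compartment: CompartmentRole

    def __post_init__(self) -> None:
        if self.t1_pre_ms <= 0 or self.t1_post_ms <= 0:
            raise PipelineError("T1 values must be > 0")

    @property
    def r1_pre(self) -> float:
        return relaxation_rate(self.t1_pre_ms)

    @property
    def r1_post(self) -> float:
        return relaxation_rate(self.t1_post_ms)

    @property
    def delta_r1(self) -> float:
        return self.r1_post - self.r1_pre

    @classmethod
    def from_fits(
        cls, fit_pre: T1FitResult, fit_post: T1FitResult, compartment: CompartmentRole
    ) -> "RelaxometryPair":
        for state, fit in (("pre", fit_pre), ("post", fit_post)):
            if not fit.valid:
                raise PipelineError(
                    f"invalid {state}-contrast T1 fit for {compartment.value}: "
                    f"{fit.reason}"
                )
        return cls(fit_pre.t1_ms, fit_post.t1_ms, compartment)


@dataclasses.dataclass
class FBVEstimate:
    """One placenta's FBV with its provenance.

    ``numerator``/``denominator`` are dR1 (1/ms) for MRI or dHU (HU) for CT;
    ``fbv`` is exactly their ratio.
    """

    subject_id: str
    fpu_index: int | None
    modality: str  # "MRI" or "CT"
    fbv: float
    numerator: float
    denominator: float
    gestational_age_label: str = ""
    flags: list[str] = dataclasses.field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "subject": self.subject_id,
            "fpu": self.fpu_index,
            "gestational_age": self.gestational_age_label,
            "modality": self.modality,
            "fbv": self.fbv,
            "numerator": self.numerator,
            "denominator": self.denominator,
            "flags": ";".join(self.flags),
        }


@dataclasses.dataclass
class CohortSummary:
    """Mean and sample SD of FBV over one (gestational age, modality) group."""

    gestational_age_label: str
    modality: str
    n_fpu: int
    mean_fbv: float
    sd_fbv: float | None

    def as_row(self) -> dict:
        return {
            "gestational_age": self.gestational_age_label,
            "modality": self.modality,
            "n_fpu": self.n_fpu,
            "mean_fbv": self.mean_fbv,
            "sd_fbv": self.sd_fbv,
        }


def compute_fbv_mri(
    placenta: RelaxometryPair,
    ivc: RelaxometryPair,
    subject_id: str = "",
    fpu_index: int | None = None,
    gestational_age_label: str = "",
    delta_r1_min: float = DELTA_R1_MIN,
) -> FBVEstimate:
    """FBV from relaxation-rate changes: (dR1 placenta) / (dR1 IVC).

    A negative placental dR1 yields an estimate flagged OUT_OF_RANGE rather
    than an error; a vanishing IVC dR1 is an error, since the blood
    reference is then uninformative.
    """
    den = ivc.delta_r1
    if abs(den) <= delta_r1_min:
        raise NoEnhancementError(
            f"no blood enhancement: |dR1_IVC| = {abs(den):.3g} <= {delta_r1_min:.3g}"
        )
    num = placenta.delta_r1
    fbv = num / den
    flags = [] if 0.0 <= fbv <= 1.0 else [FLAG_OUT_OF_RANGE]
    return FBVEstimate(
        subject_id=subject_id,
        fpu_index=fpu_index,
        modality="MRI",
        fbv=fbv,
        numerator=num,
        denominator=den,
        gestational_age_label=gestational_age_label,
        flags=flags,
    )


def compute_fbv_ct(
    pre: ImageVolume,
    post: ImageVolume,
    mask: ROIMask,
    placenta_label: int,
    ivc_label: int,
    subject_id: str = "",
    gestational_age_label: str = "",
    delta_hu_min: float = DELTA_HU_MIN,
) -> FBVEstimate:
    """FBV from ROI-mean HU enhancement: (dHU placenta) / (dHU IVC)."""
    num = roi_mean_signal(post, mask, placenta_label) - roi_mean_signal(
        pre, mask, placenta_label
    )
    den = roi_mean_signal(post, mask, ivc_label) - roi_mean_signal(
        pre, mask, ivc_label
    )
    if abs(den) <= delta_hu_min:
        raise NoEnhancementError(
            f"no blood enhancement: |dHU_IVC| = {abs(den):.3g} <= {delta_hu_min:.3g}"
        )
    fbv = num / den
    flags = [] if 0.0 <= fbv <= 1.0 else [FLAG_OUT_OF_RANGE]
    return FBVEstimate(
        subject_id=subject_id,
        fpu_index=mask.fpu_index(placenta_label),
        modality="CT",
        fbv=fbv,
        numerator=num,
        denominator=den,
        gestational_age_label=gestational_age_label,
        flags=flags,
    )


def percent_t1_change(pre_ms: float, post_ms: float) -> float:
    """Percent decrease of T1 from pre- to post-contrast: 100*(pre-post)/pre."""
    if pre_ms <= 0 or post_ms <= 0:
        raise PipelineError("T1 values must be > 0")
    return 100.0 * (pre_ms - post_ms) / pre_ms


# ---------------------------------------------------------------------------
# Study-level drivers


def fit_study_t1(
    volumes_by_state: dict[ContrastState, Sequence[ImageVolume]],
    mask: ROIMask,
    acq: AcquisitionParams,
    subject_id: str = "",
) -> list[dict]:
    """ROI-mean VFA fits for every labelled compartment in every state.

    Returns CSV-ready rows (subject, fpu, compartment, state, t1_ms, m0,
    r_squared, valid, reason).
    """
    rows = []
    for state, series in volumes_by_state.items():
        for label, info in sorted(mask.label_table.items()):
            fit = fit_t1_roi(series, mask, label, acq)
            rows.append(
                {
                    "subject": subject_id,
                    "label": label,
                    "fpu": info.fpu_index,
                    "compartment": info.role.value,
                    "state": ContrastState(state).value,
                    "t1_ms": fit.t1_ms,
                    "m0": fit.m0,
                    "r_squared": fit.r_squared,
                    "valid": fit.valid,
                    "reason": fit.reason or "",
                }
            )
    return rows


def estimate_study_fbv_mri(
    pre_series: Sequence[ImageVolume],
    post_series: Sequence[ImageVolume],
    mask: ROIMask,
    acq: AcquisitionParams,
    subject_id: str = "",
    gestational_age_label: str = "",
) -> list[FBVEstimate]:
    """MRI FBV for every placenta of one subject, sharing one IVC reference.

    An invalid IVC fit fails the whole subject (StudyError); an invalid
    placental fit yields a NaN estimate flagged INVALID_FIT.
    """
    ivc_label = mask.ivc_label()
    fits_ivc = {}
    for state, series in ((ContrastState.PRE, pre_series),
                          (ContrastState.POST, post_series)):
        fit = fit_t1_roi(series, mask, ivc_label, acq)
        if not fit.valid:
            raise StudyError(
                f"subject {subject_id or '<unnamed>'}: IVC T1 fit invalid in "
                f"{state.value} state ({fit.reason})"
            )
        fits_ivc[state] = fit
    ivc_pair = RelaxometryPair.from_fits(
        fits_ivc[ContrastState.PRE], fits_ivc[ContrastState.POST], CompartmentRole.IVC
    )
    estimates = []
    for label in mask.placenta_labels():
        fit_pre = fit_t1_roi(pre_series, mask, label, acq)
        fit_post = fit_t1_roi(post_series, mask, label, acq)
        fpu = mask.fpu_index(label)
        if not (fit_pre.valid and fit_post.valid):
            estimates.append(
                FBVEstimate(
                    subject_id=subject_id, fpu_index=fpu, modality="MRI",
                    fbv=math.nan, numerator=math.nan,
                    denominator=ivc_pair.delta_r1,
                    gestational_age_label=gestational_age_label,
                    flags=[FLAG_INVALID_FIT],
                )
            )
            continue
        pl_pair = RelaxometryPair.from_fits(
            fit_pre, fit_post, CompartmentRole.PLACENTA
        )
        estimates.append(
            compute_fbv_mri(
                pl_pair, ivc_pair,
                subject_id=subject_id, fpu_index=fpu,
                gestational_age_label=gestational_age_label,
            )
        )
    return estimates


def estimate_study_fbv_ct(
    pre: ImageVolume,
    post: ImageVolume,
    mask: ROIMask,
    subject_id: str = "",
    gestational_age_label: str = "",
) -> list[FBVEstimate]:
    """CT FBV for every placenta of one subject."""
    ivc_label = mask.ivc_label()
    return [
        compute_fbv_ct(
            pre, post, mask, label, ivc_label,
            subject_id=subject_id, gestational_age_label=gestational_age_label,
        )
        for label in mask.placenta_labels()
    ]


def run_study(manifest: StudyManifest, modality: str = "mri") -> list[FBVEstimate]:
    """Run the FBV pipeline for one subject from its manifest.

    ``modality`` selects "mri", "ct", or "both".  Deterministic given the
    input files.
    """
    modality = modality.lower()
    if modality not in ("mri", "ct", "both"):
        raise PipelineError(f"modality must be mri/ct/both, got {modality!r}")
    mask = read_mask(manifest.mask_path)
    if not mask.placenta_labels():
        raise StudyError(f"subject {manifest.subject_id}: mask has no placenta labels")
    estimates: list[FBVEstimate] = []
    if modality in ("mri", "both"):
        series = {}
        for state in (ContrastState.PRE, ContrastState.POST):
            if state not in manifest.mr_volumes:
                raise StudyError(
                    f"subject {manifest.subject_id}: manifest lacks MRI "
                    f"{state.value} volumes"
                )
            vols = []
            for fa, path in manifest.mr_volumes[state].items():
                vol = read_volume(path, flip_angle_deg=fa, contrast_state=state)
                mask.check_companion(vol)
                vols.append(vol)
            series[state] = vols
        estimates += estimate_study_fbv_mri(
            series[ContrastState.PRE], series[ContrastState.POST], mask,
            manifest.acquisition,
            subject_id=manifest.subject_id,
            gestational_age_label=manifest.gestational_age_label,
        )
    if modality in ("ct", "both"):
        for state in (ContrastState.PRE, ContrastState.POST):
            if state not in manifest.ct_volumes:
                raise StudyError(
                    f"subject {manifest.subject_id}: manifest lacks CT "
                    f"{state.value} volume"
                )
        pre = read_volume(manifest.ct_volumes[ContrastState.PRE])
        post = read_volume(manifest.ct_volumes[ContrastState.POST])
        mask.check_companion(pre)
        mask.check_companion(post)
        estimates += estimate_study_fbv_ct(
            pre, post, mask,
            subject_id=manifest.subject_id,
            gestational_age_label=manifest.gestational_age_label,
        )
    return estimates


def summarize_cohort(estimates: Iterable[FBVEstimate]) -> list[CohortSummary]:
    """Mean and sample SD of FBV per (gestational age, modality) group.

    NaN estimates (invalid fits) are excluded from the statistics; a group
    with a single estimate reports no SD.
    """
    groups: dict[tuple[str, str], list[float]] = {}
    for est in estimates:
        if math.isnan(est.fbv):
            continue
        groups.setdefault((est.gestational_age_label, est.modality), []).append(
            est.fbv
        )
    if not groups:
        raise PipelineError("no finite FBV estimates to summarize")
    out = []
    for (age, modality), values in sorted(groups.items()):
        arr = np.asarray(values)
        out.append(
            CohortSummary(
                gestational_age_label=age,
                modality=modality,
                n_fpu=len(values),
                mean_fbv=float(arr.mean()),
                sd_fbv=float(arr.std(ddof=1)) if len(values) >= 2 else None,
            )
        )
    return out


def estimates_from_dataframe(df) -> list[FBVEstimate]:
    """Rebuild FBVEstimate objects from a CSV table written by the pipeline."""
    out = []
    for _, row in df.iterrows():
        flags = row.get("flags", "")
        out.append(
            FBVEstimate(
                subject_id=str(row["subject"]),
                fpu_index=int(row["fpu"]) if not _isna(row["fpu"]) else None,
                modality=str(row["modality"]),
                fbv=float(row["fbv"]),
                numerator=float(row.get("numerator", math.nan)),
                denominator=float(row.get("denominator", math.nan)),
                gestational_age_label=str(row.get("gestational_age", "") or ""),
                flags=[f for f in str(flags or "").split(";") if f and f != "nan"],
            )
        )
    return out


def _isna(value) -> bool:
    try:
        return bool(np.isnan(value))
    except TypeError:
        return value is None
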