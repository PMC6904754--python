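"""Shared data types and file I/O for the FBV pipeline.

Volumes and label masks travel as NIfTI-1 files with a small JSON sidecar
carrying acquisition metadata (modality, contrast state, flip angle) that the
NIfTI header has no standard slot for.  Tabular outputs are plain CSV; study
manifests and phantom configurations are YAML (JSON is accepted, being a YAML
subset).  All stages of the pipeline assume co-registered voxel grids: there
is no resampling anywhere, so shape agreement between a volume and its mask is
checked eagerly at load time.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

#: sentinel value marking voxels where a T1 fit was not possible
T1_INVALID = -1.0


class PipelineError(ValueError):
    """Base class for input-validation failures in this package."""


class ManifestError(PipelineError):
    """A study manifest is missing keys, references absent files, or is
    inconsistent with its acquisition parameters."""


class Modality(str, enum.Enum):
    MR_SIGNAL = "MR_SIGNAL"
    CT_HU = "CT_HU"
    T1_MAP = "T1_MAP"


class ContrastState(str, enum.Enum):
    PRE = "PRE"
    POST = "POST"


class CompartmentRole(str, enum.Enum):
    PLACENTA = "PLACENTA"
    IVC = "IVC"
    AMNIOTIC_FLUID = "AMNIOTIC_FLUID"
    BACKGROUND = "BACKGROUND"


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar field with voxel geometry and a modality/units tag.

    ``data`` units depend on ``modality``: arbitrary units for MR signal,
    Hounsfield units for CT, milliseconds for T1 maps (with ``T1_INVALID``
    marking failed voxels).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    modality: Modality
    contrast_state: ContrastState | None = None
    flip_angle_deg: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise PipelineError(
                f"expected 3D volume, got {self.data.ndim} dimensions"
            )
        if min(self.data.shape) < 1:
            raise PipelineError("all three dimensions must be >= 1")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise PipelineError(f"voxel sizes must be positive: {self.voxel_size_mm}")
        self.modality = Modality(self.modality)
        if self.contrast_state is not None:
            self.contrast_state = ContrastState(self.contrast_state)
        if self.modality is Modality.T1_MAP:
            d = self.data
            if not np.all((d >= 0) | (d == T1_INVALID)):
                raise PipelineError(
                    "T1_MAP values must be >= 0 or the invalid sentinel -1"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        return np.diag(list(self.voxel_size_mm) + [1.0])


@dataclasses.dataclass
class LabelInfo:
    role: CompartmentRole
    fpu_index: int | None = None


@dataclasses.dataclass
class ROIMask:
    """Integer-labelled compartments on the same grid as companion volumes.

    Label 0 means unlabeled.  Each PLACENTA label carries a distinct
    feto-placental-unit (FPU) index; a study has exactly one IVC label that
    serves as the 100 %-blood reference.
    """

    labels: np.ndarray
    label_table: dict[int, LabelInfo]
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise PipelineError("mask labels must be integers")
        if self.labels.ndim != 3:
            raise PipelineError("mask must be a 3D label grid")
        if 0 in self.label_table:
            raise PipelineError("label 0 is reserved for unlabeled voxels")
        fpus = [
            info.fpu_index
            for info in self.label_table.values()
            if info.role is CompartmentRole.PLACENTA
        ]
        if len(fpus) != len(set(fpus)) or None in fpus:
            raise PipelineError("each PLACENTA label needs a distinct FPU index")
        n_ivc = sum(
            1 for info in self.label_table.values() if info.role is CompartmentRole.IVC
        )
        if n_ivc != 1:
            raise PipelineError(f"exactly one IVC label required, found {n_ivc}")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    def placenta_labels(self) -> list[int]:
        """Placenta labels ordered by FPU index."""
        items = [
            (info.fpu_index, lbl)
            for lbl, info in self.label_table.items()
            if info.role is CompartmentRole.PLACENTA
        ]
        return [lbl for _, lbl in sorted(items)]

    def ivc_label(self) -> int:
        return next(
            lbl
            for lbl, info in self.label_table.items()
            if info.role is CompartmentRole.IVC
        )

    def fpu_index(self, label: int) -> int | None:
        return self.label_table[label].fpu_index

    def check_companion(self, vol: ImageVolume) -> None:
        if vol.data.shape != self.labels.shape:
            raise PipelineError(
                f"volume shape {vol.data.shape} does not match mask shape "
                f"{self.labels.shape}"
            )


@dataclasses.dataclass
class AcquisitionParams:
    """Spoiled-GRE acquisition: repetition time, echo time, flip-angle list."""

    tr_ms: float = 20.0
    te_ms: float = 3.5
    flip_angles_deg: tuple[float, ...] = (8.0, 15.0, 25.0, 35.0, 45.0)

    def __post_init__(self) -> None:
        self.tr_ms = float(self.tr_ms)
        self.te_ms = float(self.te_ms)
        self.flip_angles_deg = tuple(float(a) for a in self.flip_angles_deg)
        if self.tr_ms <= 0:
            raise PipelineError("tr_ms must be > 0")
        if self.te_ms < 0:
            raise PipelineError("te_ms must be >= 0")
        if len(set(self.flip_angles_deg)) < 2:
            raise PipelineError(">= 2 distinct flip angles required")
        if any(not 0 < a <= 90 for a in self.flip_angles_deg):
            raise PipelineError("flip angles must lie in (0, 90] degrees")


@dataclasses.dataclass
class StudyManifest:
    """Paths and acquisition parameters for one subject's imaging study."""

    subject_id: str
    gestational_age_label: str
    acquisition: AcquisitionParams
    mask_path: Path
    mr_volumes: dict[ContrastState, dict[float, Path]] = dataclasses.field(
        default_factory=dict
    )
    ct_volumes: dict[ContrastState, Path] = dataclasses.field(default_factory=dict)
    truth_path: Path | None = None

    def save(self, path: str | Path) -> None:
        path = Path(path)
        root = path.parent

        def rel(p: Path) -> str:
            try:
                return str(Path(p).relative_to(root))
            except ValueError:
                return str(p)

        doc: dict = {
            "subject_id": self.subject_id,
            "gestational_age_label": self.gestational_age_label,
            "acquisition": {
                "tr_ms": self.acquisition.tr_ms,
                "te_ms": self.acquisition.te_ms,
                "flip_angles_deg": list(self.acquisition.flip_angles_deg),
            },
            "mask": rel(self.mask_path),
        }
        if self.mr_volumes:
            doc["mri"] = {
                state.value: {str(fa): rel(p) for fa, p in by_fa.items()}
                for state, by_fa in self.mr_volumes.items()
            }
        if self.ct_volumes:
            doc["ct"] = {state.value: rel(p) for state, p in self.ct_volumes.items()}
        if self.truth_path is not None:
            doc["truth"] = rel(self.truth_path)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# NIfTI volume / mask I/O

_SIDE_SUFFIXES = (".nii.gz", ".nii")


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suf in _SIDE_SUFFIXES:
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    """Write an ImageVolume as NIfTI-1 (float64) plus a JSON metadata sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.voxel_size_mm)
    nib.save(img, str(path))
    meta = {
        "modality": vol.modality.value,
        "contrast_state": vol.contrast_state.value if vol.contrast_state else None,
        "flip_angle_deg": vol.flip_angle_deg,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(
    path: str | Path,
    modality: Modality | str | None = None,
    contrast_state: ContrastState | str | None = None,
    flip_angle_deg: float | None = None,
) -> ImageVolume:
    """Read a NIfTI-1 volume.

    Modality and contrast state come from the JSON sidecar written by
    :func:`write_volume`, or from the explicit arguments (which take
    precedence, e.g. when driven by a manifest).  They are never inferred
    from voxel intensities.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise PipelineError(f"expected 3D volume, got {img.ndim}D file: {path}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise PipelineError(f"non-positive voxel size in header of {path}")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    modality = modality or meta.get("modality")
    if modality is None:
        raise PipelineError(
            f"modality unknown for {path}: pass modality= or provide a sidecar"
        )
    if contrast_state is None:
        contrast_state = meta.get("contrast_state")
    if flip_angle_deg is None:
        flip_angle_deg = meta.get("flip_angle_deg")
    return ImageVolume(
        data=np.asarray(img.dataobj, dtype=np.float64),
        voxel_size_mm=zooms,
        modality=Modality(modality),
        contrast_state=ContrastState(contrast_state) if contrast_state else None,
        flip_angle_deg=flip_angle_deg,
    )


def write_mask(mask: ROIMask, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag(list(mask.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.int32), affine)
    img.header.set_zooms(mask.voxel_size_mm)
    nib.save(img, str(path))
    table = {
        str(lbl): {"role": info.role.value, "fpu_index": info.fpu_index}
        for lbl, info in mask.label_table.items()
    }
    _sidecar_path(path).write_text(json.dumps({"labels": table}, indent=1))


def read_mask(path: str | Path) -> ROIMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"mask file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise PipelineError(f"expected 3D label grid, got {img.ndim}D file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ManifestError(f"label-table sidecar missing for mask: {sidecar}")
    table_doc = json.loads(sidecar.read_text())["labels"]
    table = {
        int(lbl): LabelInfo(CompartmentRole(d["role"]), d.get("fpu_index"))
        for lbl, d in table_doc.items()
    }
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ROIMask(
        labels=np.asarray(img.dataobj).astype(np.int64),
        label_table=table,
        voxel_size_mm=zooms,
    )


# ---------------------------------------------------------------------------
# Manifests


def load_manifest(path: str | Path) -> StudyManifest:
    """Load and eagerly validate a YAML/JSON study manifest.

    Every referenced file must resolve (relative to the manifest's directory)
    and the flip angles listed under ``mri`` must match the acquisition's
    flip-angle list exactly, per contrast state.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, Mapping):
        raise ManifestError(f"manifest is not a mapping: {path}")
    for key in ("subject_id", "acquisition", "mask"):
        if key not in doc:
            raise ManifestError(f"manifest missing key '{key}': {path}")
    acq_doc = doc["acquisition"]
    try:
        acq = AcquisitionParams(
            tr_ms=acq_doc["tr_ms"],
            te_ms=acq_doc["te_ms"],
            flip_angles_deg=acq_doc["flip_angles_deg"],
        )
    except KeyError as exc:
        raise ManifestError(f"acquisition missing key {exc} in {path}") from exc

    root = path.parent

    def resolve(p: str) -> Path:
        q = (root / p).resolve() if not Path(p).is_absolute() else Path(p)
        if not q.exists():
            raise ManifestError(f"manifest references missing file: {q}")
        return q

    mr_volumes: dict[ContrastState, dict[float, Path]] = {}
    for state_key, by_fa in (doc.get("mri") or {}).items():
        state = ContrastState(state_key)
        vols = {float(fa): resolve(p) for fa, p in by_fa.items()}
        if sorted(vols) != sorted(acq.flip_angles_deg):
            raise ManifestError(
                f"flip-angle mismatch for {state.value} in {path}: manifest has "
                f"{sorted(vols)}, acquisition lists {sorted(acq.flip_angles_deg)}"
            )
        mr_volumes[state] = vols
    ct_volumes = {
        ContrastState(state_key): resolve(p)
        for state_key, p in (doc.get("ct") or {}).items()
    }
    return StudyManifest(
        subject_id=str(doc["subject_id"]),
        gestational_age_label=str(doc.get("gestational_age_label", "")),
        acquisition=acq,
        mask_path=resolve(doc["mask"]),
        mr_volumes=mr_volumes,
        ct_volumes=ct_volumes,
        truth_path=resolve(doc["truth"]) if "truth" in doc else None,
    )


# ---------------------------------------------------------------------------
# Tables


def write_table(
    rows: Sequence[Mapping], path: str | Path, columns: Sequence[str] | None = None
) -> None:
    """Write homogeneous records as a CSV with a header row.

    Floats are written with Python's shortest round-tripping repr, which
    preserves well over 12 significant digits on re-read.
    """
    df = pd.DataFrame(list(rows), columns=columns)
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
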