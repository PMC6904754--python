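"""Digital pregnant-mouse phantom and pre/post-contrast image simulation.

The phantom is a parametric 3D label grid holding several feto-placental
units (an ellipsoidal amniotic-fluid sac capped by a discoid placenta), a
cylindrical inferior-vena-cava (IVC) segment of ~2 mm diameter that serves as
the pure-blood reference, and an ellipsoidal maternal-body background; voxels
outside the body are air.  Geometry is schematic on purpose: the downstream
analysis consumes ROI statistics, not anatomy.

Enhancement follows the fast-exchange linear-mixing model of a blood-pool
contrast agent that stays intravascular: a tissue compartment containing a
blood volume fraction f changes its longitudinal relaxation rate by
dR1 = f * dR1_blood and its CT attenuation by dHU = f * dHU_blood.  Amniotic
fluid never enhances (the agent does not cross the placental barrier), and
the IVC enhances with f = 1 by construction.  Under this generative model the
ratio estimators dR1_P/dR1_IVC and dHU_P/dHU_IVC are exact inverses of the
generator in the noiseless limit, which is what the round-trip test suite
exercises.

Default tissue parameters describe late-gestation mice at 1 T: per
gestational day presets carry placental and blood T1 before and after a
liposomal-gadolinium injection, with blood-fraction cohort statistics drawn
from the same literature.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .core_io import (
    AcquisitionParams,
    CompartmentRole,
    ContrastState,
    ImageVolume,
    LabelInfo,
    Modality,
    PipelineError,
    ROIMask,
    StudyManifest,
    write_mask,
    write_volume,
)

import enum


class NoiseModel(str, enum.Enum):
    NONE = "NONE"
    GAUSSIAN = "GAUSSIAN"
    RICIAN = "RICIAN"


#: gestational-day presets (mouse, 1 T): mean T1 (ms) of placenta and IVC
#: blood pre/post contrast, and reported cohort blood-fraction statistics
GESTATIONAL_PRESETS: dict[str, dict[str, float]] = {
    "E14.5": {
        "placenta_t1_pre_ms": 1300.0,
        "blood_t1_pre_ms": 1020.0,
        "blood_t1_post_ms": 690.0,
        "fbv_mri_mean": 0.47,
        "fbv_mri_sd": 0.06,
        "fbv_ct_mean": 0.48,
    },
    "E16.5": {
        "placenta_t1_pre_ms": 1240.0,
        "blood_t1_pre_ms": 1150.0,
        "blood_t1_post_ms": 600.0,
        "fbv_mri_mean": 0.50,
        "fbv_mri_sd": 0.04,
        "fbv_ct_mean": 0.48,
    },
    "E18.5": {
        "placenta_t1_pre_ms": 1200.0,
        "blood_t1_pre_ms": 1060.0,
        "blood_t1_post_ms": 480.0,
        "fbv_mri_mean": 0.52,
        "fbv_mri_sd": 0.04,
        "fbv_ct_mean": 0.51,
    },
}

#: dams carry this many feto-placental units
FPU_RANGE_DEFAULT = (6, 10)


@dataclasses.dataclass
class CompartmentProps:
    """True tissue properties of one compartment in both contrast states."""

    t1_pre_ms: float
    t1_post_ms: float
    t2_ms: float
    m0: float
    hu_pre: float
    hu_post: float

    def t1_ms(self, state: ContrastState) -> float:
        return self.t1_pre_ms if state is ContrastState.PRE else self.t1_post_ms

    def hu(self, state: ContrastState) -> float:
        return self.hu_pre if state is ContrastState.PRE else self.hu_post


#: air outside the body: no protons, CT value of air
AIR_PROPS = CompartmentProps(
    t1_pre_ms=1000.0, t1_post_ms=1000.0, t2_ms=50.0, m0=0.0,
    hu_pre=-1000.0, hu_post=-1000.0,
)


@dataclasses.dataclass
class PhantomConfig:
    """Everything needed to build one subject's phantom and simulate it.

    Per-placenta blood fractions come either from an explicit
    ``fpu_fractions`` list (length ``n_fpu``) or are drawn from a normal
    distribution with ``f_mean``/``f_sd`` clipped to [0, 1].  Blood
    properties are shared across all of a subject's FPUs, mirroring a single
    maternal IVC reference per animal.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 0.5)
    n_fpu: int = 8
    gestational_age_label: str = "E14.5"
    # placenta (pre-contrast; post follows from f and blood enhancement)
    placenta_t1_pre_ms: float = 1300.0
    placenta_t2_ms: float = 50.0
    placenta_m0: float = 1000.0
    placenta_hu_pre: float = 55.0
    # amniotic fluid (never enhances)
    af_t1_ms: float = 2500.0
    af_t2_ms: float = 200.0
    af_m0: float = 900.0
    af_hu: float = 15.0
    # maternal background tissue (modelled as non-enhancing)
    background_t1_ms: float = 1000.0
    background_t2_ms: float = 50.0
    background_m0: float = 800.0
    background_hu: float = 45.0
    # blood (the IVC is pure blood, f = 1)
    blood_t1_pre_ms: float = 1020.0
    blood_t1_post_ms: float = 690.0
    blood_t2_ms: float = 100.0
    blood_m0: float = 1000.0
    blood_hu_pre: float = 55.0
    blood_hu_post: float = 555.0
    # per-placenta blood fractions
    fpu_fractions: tuple[float, ...] | None = None
    f_mean: float = 0.5
    f_sd: float = 0.0
    # noise
    noise_model: NoiseModel = NoiseModel.NONE
    snr: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.noise_model = NoiseModel(self.noise_model)
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if self.fpu_fractions is not None:
            self.fpu_fractions = tuple(float(f) for f in self.fpu_fractions)

    def validate(self) -> None:
        if self.n_fpu < 1:
            raise PipelineError("n_fpu must be >= 1")
        for t1 in (
            self.placenta_t1_pre_ms, self.af_t1_ms, self.background_t1_ms,
            self.blood_t1_pre_ms, self.blood_t1_post_ms,
        ):
            if t1 <= 0:
                raise PipelineError("all T1 values must be > 0")
        for t2 in (self.placenta_t2_ms, self.af_t2_ms, self.background_t2_ms,
                   self.blood_t2_ms):
            if t2 <= 0:
                raise PipelineError("all T2 values must be > 0")
        if self.fpu_fractions is not None:
            if len(self.fpu_fractions) != self.n_fpu:
                raise PipelineError("fpu_fractions length must equal n_fpu")
            if any(not 0.0 <= f <= 1.0 for f in self.fpu_fractions):
                raise PipelineError("blood fractions must lie in [0, 1]")
        if self.noise_model is not NoiseModel.NONE and self.snr <= 0:
            raise PipelineError("snr must be > 0 when noise is enabled")

    @classmethod
    def for_age(cls, age: str, **overrides) -> "PhantomConfig":
        """Config preset for a gestational day (E14.5 / E16.5 / E18.5)."""
        if age not in GESTATIONAL_PRESETS:
            raise PipelineError(
                f"unknown gestational age {age!r}; known: {sorted(GESTATIONAL_PRESETS)}"
            )
        p = GESTATIONAL_PRESETS[age]
        kwargs = dict(
            gestational_age_label=age,
            placenta_t1_pre_ms=p["placenta_t1_pre_ms"],
            blood_t1_pre_ms=p["blood_t1_pre_ms"],
            blood_t1_post_ms=p["blood_t1_post_ms"],
            f_mean=p["fbv_mri_mean"],
            f_sd=p["fbv_mri_sd"],
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclasses.dataclass
class PhantomGroundTruth:
    """True per-label tissue properties and per-FPU blood fractions."""

    label_props: dict[int, CompartmentProps]
    fpu_fractions: dict[int, float]
    gestational_age_label: str = ""

    def placenta_t1_post_ms(self, mask: ROIMask, fpu_index: int) -> float:
        for lbl, info in mask.label_table.items():
            if info.role is CompartmentRole.PLACENTA and info.fpu_index == fpu_index:
                return self.label_props[lbl].t1_post_ms
        raise KeyError(fpu_index)

    def to_dict(self) -> dict:
        return {
            "gestational_age_label": self.gestational_age_label,
            "label_props": {
                str(lbl): dataclasses.asdict(p) for lbl, p in self.label_props.items()
            },
            "fpu_fractions": {str(i): f for i, f in self.fpu_fractions.items()},
        }

    def save_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, doc: dict) -> "PhantomGroundTruth":
        return cls(
            label_props={
                int(lbl): CompartmentProps(**p)
                for lbl, p in doc["label_props"].items()
            },
            fpu_fractions={int(i): float(f) for i, f in doc["fpu_fractions"].items()},
            gestational_age_label=doc.get("gestational_age_label", ""),
        )

    @classmethod
    def load_json(cls, path: str | Path) -> "PhantomGroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


def post_contrast_tissue_r1(r1_pre: float, f: float, delta_r1_blood: float) -> float:
    """Post-contrast tissue R1 under fast-exchange linear mixing.

    A tissue whose volume fraction ``f`` is blood picks up the fraction ``f``
    of the blood's relaxation-rate increase: R1_post = R1_pre + f*dR1_blood.
    Units are 1/ms throughout.
    """
    if r1_pre <= 0:
        raise PipelineError("r1_pre must be > 0")
    if not 0.0 <= f <= 1.0:
        raise PipelineError("blood fraction f must lie in [0, 1]")
    if delta_r1_blood < 0:
        raise PipelineError("delta_r1_blood must be >= 0")
    return r1_pre + f * delta_r1_blood


# ---------------------------------------------------------------------------
# Geometry helpers


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _cylinder_mask_z(shape, cx, cy, radius, z0, z1) -> np.ndarray:
    xx, yy = np.ogrid[0 : shape[0], 0 : shape[1]]
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    out = np.zeros(shape, dtype=bool)
    out[:, :, int(z0) : int(z1)] = disk[:, :, None]
    return out


def build_phantom(config: PhantomConfig) -> tuple[ROIMask, PhantomGroundTruth]:
    """Build the label grid and ground-truth properties for one subject.

    Deterministic given ``config.seed``.  FPUs are placed on a 3x3x2 cell
    lattice (one cell column is reserved for the IVC), with small seeded
    positional jitter.  Raises if shapes do not fit the grid with the
    required minimum compartment sizes (>= 50 placental voxels per FPU,
    >= 30 IVC voxels).
    """
    config.validate()
    nx, ny, nz = config.grid_shape
    rng = np.random.default_rng(config.seed)
    labels = np.zeros(config.grid_shape, dtype=np.int64)

    n = config.n_fpu
    lbl_placenta = {i: i + 1 for i in range(n)}
    lbl_af = {i: n + 1 + i for i in range(n)}
    lbl_ivc = 2 * n + 1
    lbl_body = 2 * n + 2

    # maternal body
    body = _ellipsoid_mask(
        config.grid_shape,
        center=((nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2),
        semi_axes=(0.48 * nx, 0.48 * ny, 0.48 * nz),
    )
    labels[body] = lbl_body

    # IVC: z-oriented cylinder, ~2 mm diameter
    ivc_radius_vox = max(2.0, 1.0 / config.voxel_size_mm[0])
    ivc_cx, ivc_cy = 0.2 * nx, 0.5 * ny
    ivc = _cylinder_mask_z(
        config.grid_shape, ivc_cx, ivc_cy, ivc_radius_vox, 0.1 * nz, 0.9 * nz
    )
    labels[ivc] = lbl_ivc

    # FPU cell lattice: 3x3 columns x 2 z-layers, minus the IVC's column
    cx, cy, cz = nx / 3.0, ny / 3.0, nz / 2.0
    cells = [
        (i, j, k)
        for k in range(2)
        for i in range(3)
        for j in range(3)
        if not (i == 0 and j == 1)  # IVC column
    ]
    if n > len(cells):
        raise PipelineError(
            f"phantom geometry does not fit grid: {n} FPUs > {len(cells)} cells"
        )
    af_r = max(3, round(0.19 * min(cx, cy)))
    pl_r = (af_r, af_r, max(2, af_r // 2 + 1))

    for i in range(n):
        ci, cj, ck = cells[i]
        jitter = rng.integers(-2, 3, size=3)
        center = (
            (ci + 0.5) * cx + jitter[0],
            (cj + 0.5) * cy + jitter[1],
            (ck + 0.45) * cz + jitter[2],
        )
        af = _ellipsoid_mask(config.grid_shape, center, (af_r, af_r, af_r))
        if np.any((labels[af] != 0) & (labels[af] != lbl_body)):
            raise PipelineError("phantom geometry does not fit grid: AF collision")
        labels[af] = lbl_af[i]
        pl_center = (center[0], center[1], center[2] + af_r + pl_r[2])
        pl = _ellipsoid_mask(config.grid_shape, pl_center, pl_r)
        pl &= labels != lbl_af[i]
        if np.any((labels[pl] != 0) & (labels[pl] != lbl_body)):
            raise PipelineError("phantom geometry does not fit grid: placenta collision")
        labels[pl] = lbl_placenta[i]
        if int(pl.sum()) < 50:
            raise PipelineError(
                "phantom geometry does not fit grid: placenta has < 50 voxels"
            )
    if int(np.sum(labels == lbl_ivc)) < 30:
        raise PipelineError("phantom geometry does not fit grid: IVC has < 30 voxels")

    # blood fractions
    if config.fpu_fractions is not None:
        fractions = np.asarray(config.fpu_fractions, dtype=np.float64)
    else:
        fractions = np.clip(rng.normal(config.f_mean, config.f_sd, size=n), 0.0, 1.0)

    delta_r1_blood = 1.0 / config.blood_t1_post_ms - 1.0 / config.blood_t1_pre_ms
    delta_hu_blood = config.blood_hu_post - config.blood_hu_pre

    label_table: dict[int, LabelInfo] = {}
    props: dict[int, CompartmentProps] = {0: AIR_PROPS}
    for i in range(n):
        f = float(fractions[i])
        r1_post = post_contrast_tissue_r1(
            1.0 / config.placenta_t1_pre_ms, f, delta_r1_blood
        )
        props[lbl_placenta[i]] = CompartmentProps(
            t1_pre_ms=config.placenta_t1_pre_ms,
            t1_post_ms=1.0 / r1_post,
            t2_ms=config.placenta_t2_ms,
            m0=config.placenta_m0,
            hu_pre=config.placenta_hu_pre,
            hu_post=config.placenta_hu_pre + f * delta_hu_blood,
        )
        label_table[lbl_placenta[i]] = LabelInfo(CompartmentRole.PLACENTA, i)
        props[lbl_af[i]] = CompartmentProps(
            t1_pre_ms=config.af_t1_ms, t1_post_ms=config.af_t1_ms,
            t2_ms=config.af_t2_ms, m0=config.af_m0,
            hu_pre=config.af_hu, hu_post=config.af_hu,
        )
        label_table[lbl_af[i]] = LabelInfo(CompartmentRole.AMNIOTIC_FLUID, i)
    props[lbl_ivc] = CompartmentProps(
        t1_pre_ms=config.blood_t1_pre_ms, t1_post_ms=config.blood_t1_post_ms,
        t2_ms=config.blood_t2_ms, m0=config.blood_m0,
        hu_pre=config.blood_hu_pre, hu_post=config.blood_hu_post,
    )
    label_table[lbl_ivc] = LabelInfo(CompartmentRole.IVC)
    props[lbl_body] = CompartmentProps(
        t1_pre_ms=config.background_t1_ms, t1_post_ms=config.background_t1_ms,
        t2_ms=config.background_t2_ms, m0=config.background_m0,
        hu_pre=config.background_hu, hu_post=config.background_hu,
    )
    label_table[lbl_body] = LabelInfo(CompartmentRole.BACKGROUND)

    mask = ROIMask(
        labels=labels, label_table=label_table, voxel_size_mm=config.voxel_size_mm
    )
    truth = PhantomGroundTruth(
        label_props=props,
        fpu_fractions={i: float(fractions[i]) for i in range(n)},
        gestational_age_label=config.gestational_age_label,
    )
    return mask, truth


# ---------------------------------------------------------------------------
# Forward simulation


def _lut(truth: PhantomGroundTruth, labels: np.ndarray, attr) -> np.ndarray:
    max_label = int(labels.max())
    table = np.zeros(max_label + 1, dtype=np.float64)
    for lbl in range(max_label + 1):
        props = truth.label_props.get(lbl, AIR_PROPS)
        table[lbl] = attr(props)
    return table[labels]


def _check_labels_covered(truth: PhantomGroundTruth, labels: np.ndarray) -> None:
    present = set(int(v) for v in np.unique(labels))
    missing = present - set(truth.label_props)
    if missing:
        raise PipelineError(f"labels without ground-truth properties: {sorted(missing)}")


def _noiseless_vfa(mask, truth, acq, state):
    from .vfa_t1_mapping import gre_signal

    labels = mask.labels
    t1 = _lut(truth, labels, lambda p: p.t1_ms(state))
    t2 = _lut(truth, labels, lambda p: p.t2_ms)
    m0 = _lut(truth, labels, lambda p: p.m0)
    return [gre_signal(m0, t1, acq, a, t2_ms=t2) for a in acq.flip_angles_deg]


def simulate_vfa_series(
    mask: ROIMask,
    truth: PhantomGroundTruth,
    acq: AcquisitionParams,
    state: ContrastState,
    noise_model: NoiseModel = NoiseModel.NONE,
    snr: float = 50.0,
    seed: int = 0,
) -> list[ImageVolume]:
    """Simulate one spoiled-GRE volume per flip angle for a contrast state.

    Each voxel's noiseless value is the full steady-state signal (including
    the exp(-TE/T2) factor) of its compartment's true (M0, T1, T2) in the
    given state.  Gaussian or Rician noise of standard deviation
    sigma = max(noiseless pre-contrast signal)/snr is then added, seeded and
    reproducible; the sigma is anchored to the PRE state regardless of the
    simulated state so both states share one noise level.
    """
    state = ContrastState(state)
    noise_model = NoiseModel(noise_model)
    _check_labels_covered(truth, mask.labels)
    arrays = _noiseless_vfa(mask, truth, acq, state)
    if noise_model is not NoiseModel.NONE:
        pre_arrays = (
            arrays
            if state is ContrastState.PRE
            else _noiseless_vfa(mask, truth, acq, ContrastState.PRE)
        )
        sigma = max(float(a.max()) for a in pre_arrays) / snr
        rng = np.random.default_rng(seed)
        if noise_model is NoiseModel.GAUSSIAN:
            arrays = [a + rng.normal(0.0, sigma, a.shape) for a in arrays]
        else:  # RICIAN: magnitude of complex signal + circular Gaussian noise
            arrays = [
                np.hypot(a + rng.normal(0.0, sigma, a.shape),
                         rng.normal(0.0, sigma, a.shape))
                for a in arrays
            ]
    return [
        ImageVolume(
            data=a,
            voxel_size_mm=mask.voxel_size_mm,
            modality=Modality.MR_SIGNAL,
            contrast_state=state,
            flip_angle_deg=float(alpha),
        )
        for a, alpha in zip(arrays, acq.flip_angles_deg)
    ]


def simulate_ct_pair(
    mask: ROIMask,
    truth: PhantomGroundTruth,
    noise_model: NoiseModel = NoiseModel.NONE,
    snr: float = 50.0,
    seed: int = 0,
) -> tuple[ImageVolume, ImageVolume]:
    """Simulate the pre/post-contrast CT volume pair (Hounsfield units).

    Post-contrast placental HU is pre + f * (blood HU enhancement) through
    the ground-truth per-label properties; amniotic fluid and background are
    unchanged.  Gaussian noise uses sigma = max|pre-contrast HU|/snr.
    """
    noise_model = NoiseModel(noise_model)
    _check_labels_covered(truth, mask.labels)
    labels = mask.labels
    out = []
    hu_pre = _lut(truth, labels, lambda p: p.hu_pre)
    sigma = float(np.abs(hu_pre).max()) / snr
    rng = np.random.default_rng(seed)
    for state in (ContrastState.PRE, ContrastState.POST):
        hu = _lut(truth, labels, lambda p, s=state: p.hu(s))
        if noise_model is not NoiseModel.NONE:
            # CT noise is additive Gaussian on reconstructed HU either way
            hu = hu + rng.normal(0.0, sigma, hu.shape)
        out.append(
            ImageVolume(
                data=hu,
                voxel_size_mm=mask.voxel_size_mm,
                modality=Modality.CT_HU,
                contrast_state=state,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Cohorts


def generate_cohort(
    n_subjects: int,
    template: PhantomConfig,
    out_dir: str | Path,
    seed: int = 0,
    fpu_counts: Sequence[int] | None = None,
    acq: AcquisitionParams | None = None,
    write_ct: bool = True,
) -> list[tuple[StudyManifest, PhantomGroundTruth]]:
    """Generate a cohort of subjects and write volumes/masks/manifests to disk.

    Per-subject seeds derive deterministically from the master ``seed``.  FPU
    counts come from ``fpu_counts`` when given, otherwise they are drawn
    uniformly from the litter-size range 6-10.
    """
    if n_subjects < 1:
        raise PipelineError("n_subjects must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    acq = acq or AcquisitionParams()
    master = np.random.SeedSequence(seed)
    subject_seeds = [
        int(ss.generate_state(1)[0] % (2**31)) for ss in master.spawn(n_subjects)
    ]
    if fpu_counts is not None and len(fpu_counts) != n_subjects:
        raise PipelineError("fpu_counts length must equal n_subjects")

    results = []
    for s in range(n_subjects):
        sub_rng = np.random.default_rng(subject_seeds[s])
        n_fpu = (
            int(fpu_counts[s])
            if fpu_counts is not None
            else int(sub_rng.integers(FPU_RANGE_DEFAULT[0], FPU_RANGE_DEFAULT[1] + 1))
        )
        cfg = dataclasses.replace(
            template, n_fpu=n_fpu, seed=int(sub_rng.integers(0, 2**31))
        )
        sid = f"subj{s + 1:02d}"
        mask, truth = build_phantom(cfg)
        mask_path = out_dir / f"{sid}_mask.nii.gz"
        write_mask(mask, mask_path)
        truth_path = out_dir / f"{sid}_truth.json"
        truth.save_json(truth_path)

        mr_volumes: dict[ContrastState, dict[float, Path]] = {}
        for state in (ContrastState.PRE, ContrastState.POST):
            series = simulate_vfa_series(
                mask, truth, acq, state,
                noise_model=cfg.noise_model, snr=cfg.snr,
                seed=int(sub_rng.integers(0, 2**31)),
            )
            by_fa = {}
            for vol in series:
                p = out_dir / f"{sid}_{state.value.lower()}_fa{int(vol.flip_angle_deg):02d}.nii.gz"
                write_volume(vol, p)
                by_fa[vol.flip_angle_deg] = p
            mr_volumes[state] = by_fa

        ct_volumes: dict[ContrastState, Path] = {}
        if write_ct:
            ct_pre, ct_post = simulate_ct_pair(
                mask, truth, noise_model=cfg.noise_model, snr=cfg.snr,
                seed=int(sub_rng.integers(0, 2**31)),
            )
            for vol in (ct_pre, ct_post):
                p = out_dir / f"{sid}_ct_{vol.contrast_state.value.lower()}.nii.gz"
                write_volume(vol, p)
                ct_volumes[vol.contrast_state] = p

        manifest = StudyManifest(
            subject_id=sid,
            gestational_age_label=cfg.gestational_age_label,
            acquisition=acq,
            mask_path=mask_path,
            mr_volumes=mr_volumes,
            ct_volumes=ct_volumes,
            truth_path=truth_path,
        )
        manifest.save(out_dir / f"{sid}_manifest.yaml")
        results.append((manifest, truth))
    return results
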