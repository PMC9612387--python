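"""Synthetic dynamic-PET phantom cohort.

Generates seeded digital patients on a 64×64×48 grid of 3 mm isotropic
voxels: an ellipsoidal tumor strictly in one hemisphere, a midline ventricle
with blood-pool-like kinetics, a crescent-shaped normalization region in the
contralateral hemisphere, and healthy background everywhere else. Tumors are
either *isometabolic* (late uptake equal to background, ascending kinetics —
visually FET-negative but kinetically late) or *photopenic* (uptake below
background). Default cohort mix follows the clinical cohort the analysis is
designed for: 29 isometabolic and 17 photopenic of 46.

Each voxel's frame value is the duration-weighted mean of its region's
noiseless curve over the frame, plus zero-mean Gaussian noise with
sd = noise_scale * sqrt(level / frame_duration_min) — an approximation to the
count statistics of reconstructed frames (short early frames are noisier).
Simulated activity is clipped at zero, as negative radioactivity has no
physical meaning. Everything is reproducible bit-for-bit from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import KineticParams, default_params, tac_model
from .maps import DynamicImage
from .schedule import FrameSchedule, default_frame_schedule
from .voi import VOISet, mirror_mask

__all__ = [
    "PhantomSpec",
    "SyntheticPatient",
    "default_phantom_spec",
    "simulate_patient",
    "simulate_cohort",
    "cohort_recipes",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry + noise description of one digital patient."""

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    midsagittal_index: float = 31.5
    tumor_center: tuple[float, float, float] = (45.0, 32.0, 24.0)
    tumor_radii: tuple[float, float, float] = (5.0, 5.0, 5.0)
    ventricle_center: tuple[float, float, float] = (32.0, 32.0, 24.0)
    ventricle_radii: tuple[float, float, float] = (5.0, 7.0, 5.0)
    crescent_center: tuple[float, float, float] = (18.0, 46.0, 24.0)
    crescent_radius: float = 8.0
    crescent_notch_offset: tuple[float, float, float] = (3.0, 0.0, 0.0)
    noise_scale: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        shape = np.asarray(self.grid_shape)
        for name, c, r in (
            ("tumor", self.tumor_center, self.tumor_radii),
            ("ventricle", self.ventricle_center, self.ventricle_radii),
        ):
            c, r = np.asarray(c), np.asarray(r)
            if np.any(c - r < 0) or np.any(c + r >= shape):
                raise ValueError(f"{name} ellipsoid leaves the grid")
        lo = self.tumor_center[0] - self.tumor_radii[0]
        hi = self.tumor_center[0] + self.tumor_radii[0]
        if lo <= self.midsagittal_index <= hi:
            raise ValueError("tumor intersects the mid-sagittal plane")
        if (self.crescent_center[0] - self.midsagittal_index) * (
            self.tumor_center[0] - self.midsagittal_index
        ) >= 0:
            raise ValueError("crescent must lie contralateral to the tumor")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


@dataclass
class SyntheticPatient:
    """One simulated patient: dynamic image, VOIs and ground-truth kinetics."""

    patient_id: str
    dynamic_image: DynamicImage
    voi_set: VOISet
    truth: dict[str, KineticParams]
    seed: int
    phenotype: str


def default_phantom_spec(seed: int = 0, noise_scale: float = 0.05, **overrides) -> PhantomSpec:
    return replace(PhantomSpec(), seed=seed, noise_scale=noise_scale, **overrides)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    c = np.asarray(center, dtype=float).reshape(3, 1, 1, 1)
    r = np.asarray(radii, dtype=float).reshape(3, 1, 1, 1)
    return np.sum(((idx - c) / r) ** 2, axis=0) <= 1.0


def build_masks(spec: PhantomSpec) -> VOISet:
    """Construct the VOISet implied by the phantom geometry."""
    spec.validate()
    tumor = _ellipsoid(spec.grid_shape, spec.tumor_center, spec.tumor_radii)
    ventricle = _ellipsoid(spec.grid_shape, spec.ventricle_center, spec.ventricle_radii)
    if (tumor & ventricle).any():
        raise ValueError("tumor and ventricle regions overlap")
    outer = _ellipsoid(spec.grid_shape, spec.crescent_center, (spec.crescent_radius,) * 3)
    notch_center = np.asarray(spec.crescent_center) + np.asarray(spec.crescent_notch_offset)
    inner = _ellipsoid(spec.grid_shape, notch_center, (spec.crescent_radius,) * 3)
    crescent = outer & ~inner & ~ventricle
    mirrored, _ = mirror_mask(tumor, spec.midsagittal_index, exclusion_mask=ventricle)
    crescent &= ~mirrored
    return VOISet(
        tumor_mask=tumor,
        mirrored_mask=mirrored,
        crescent_mask=crescent,
        ventricle_mask=ventricle,
        midsagittal_index=spec.midsagittal_index,
    )


def _frame_averaged_curve(params: KineticParams, schedule: FrameSchedule) -> np.ndarray:
    """Duration-weighted mean of the noiseless curve per frame (1 s sub-grid)."""
    out = np.empty(schedule.n_frames)
    for i, (s, d) in enumerate(zip(schedule.frame_starts, schedule.frame_durations)):
        t = np.arange(s, s + d + 1e-9, 1.0) / 60.0
        out[i] = np.trapezoid(tac_model(params, t, schedule), t) / (t[-1] - t[0])
    return out


def simulate_patient(
    spec: PhantomSpec,
    tissue_params: dict[str, KineticParams] | None = None,
    seed: int | None = None,
    schedule: FrameSchedule | None = None,
    patient_id: str = "P000",
) -> SyntheticPatient:
    """Simulate one patient from a phantom spec and per-region kinetics.

    ``tissue_params`` maps {"background", "tumor", "ventricle"} to
    :class:`~fetrad.kinetics.KineticParams`; missing entries fall back to the
    phenotype defaults (isometabolic tumor).
    """
    schedule = schedule or default_frame_schedule()
    seed = spec.seed if seed is None else seed
    params = {
        "background": default_params("background"),
        "tumor": default_params("isometabolic"),
        "ventricle": default_params("ventricle"),
    }
    if tissue_params:
        params.update(tissue_params)
    voi_set = build_masks(spec)

    # region label volume: 0 background, 1 tumor, 2 ventricle
    labels = np.zeros(spec.grid_shape, dtype=np.int8)
    labels[voi_set.tumor_mask] = 1
    labels[voi_set.ventricle_mask] = 2
    curves = np.stack(
        [_frame_averaged_curve(params[k], schedule) for k in ("background", "tumor", "ventricle")]
    )
    noiseless = curves[labels]  # (x, y, z, frame)

    rng = np.random.default_rng(seed)
    if spec.noise_scale > 0:
        durs_min = np.asarray(schedule.frame_durations) / 60.0
        sd = spec.noise_scale * np.sqrt(np.maximum(noiseless, 0.0) / durs_min)
        voxels = np.maximum(noiseless + rng.normal(0.0, 1.0, noiseless.shape) * sd, 0.0)
    else:
        voxels = noiseless.copy()

    dyn = DynamicImage(voxels, schedule, voxel_size_mm=spec.voxel_size_mm)
    return SyntheticPatient(
        patient_id=patient_id,
        dynamic_image=dyn,
        voi_set=voi_set,
        truth=params,
        seed=seed,
        phenotype=params["tumor"].phenotype,
    )


def _patient_seed(child: np.random.SeedSequence) -> int:
    return int(child.generate_state(1)[0] % (2**31))


def cohort_recipes(
    n_patients: int,
    phenotype_mix: tuple[float, float],
    base_seed: int,
    noise_scale: float = 0.05,
) -> list[dict]:
    """Deterministic per-patient specs/params for a cohort, without simulating.

    ``phenotype_mix`` gives the (isometabolic, photopenic) fractions; counts
    are the rounded fractions. Per-patient seeds and kinetic-parameter jitter
    derive deterministically from ``base_seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    mix = np.asarray(phenotype_mix, dtype=float)
    if mix.size != 2 or np.any(mix < 0) or not np.isclose(mix.sum(), 1.0):
        raise ValueError("phenotype_mix must be two non-negative fractions summing to 1")
    n_iso = int(round(mix[0] * n_patients))
    phenotypes = ["isometabolic"] * n_iso + ["photopenic"] * (n_patients - n_iso)

    children = np.random.SeedSequence(base_seed).spawn(n_patients)
    recipes = []
    for i, (phen, child) in enumerate(zip(phenotypes, children)):
        seed = _patient_seed(child)
        rng = np.random.default_rng(child)
        amplitude = float(rng.uniform(0.8, 1.2))  # injected-dose variation
        bg = replace(
            default_params("background"),
            amplitude=amplitude,
            peak_time=float(rng.uniform(4.0, 6.0)),
        )
        vent = replace(default_params("ventricle"), amplitude=amplitude)
        tumor = default_params(phen)
        if phen == "isometabolic":
            late = float(np.clip(rng.normal(1.0, 0.03), 0.92, 1.08))
        else:
            late = float(np.clip(rng.normal(0.65, 0.08), 0.40, 0.85))
        tumor = replace(
            tumor,
            amplitude=amplitude,
            late_level=late,
            peak_time=float(rng.uniform(33.0, 39.6)),
        )
        radii = tuple(rng.uniform(4.0, 6.0, size=3))
        spec = default_phantom_spec(seed=seed, noise_scale=noise_scale, tumor_radii=radii)
        recipes.append(
            {
                "patient_id": f"P{i + 1:03d}",
                "phenotype": phen,
                "seed": seed,
                "spec": spec,
                "tissue_params": {"background": bg, "tumor": tumor, "ventricle": vent},
            }
        )
    return recipes


def simulate_cohort(
    n_patients: int,
    phenotype_mix: tuple[float, float] = (29 / 46, 17 / 46),
    base_seed: int = 0,
    noise_scale: float = 0.05,
) -> list[SyntheticPatient]:
    """Simulate a full cohort (default mix: 29/46 isometabolic, 17/46 photopenic)."""
    return [
        simulate_patient(
            r["spec"], r["tissue_params"], r["seed"], patient_id=r["patient_id"]
        )
        for r in cohort_recipes(n_patients, phenotype_mix, base_seed, noise_scale)
    ]
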