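"""Synthetic paired scan-rescan FDG-PET phantoms.

Patient scan-rescan data cannot be shared, so this module generates a
configurable digital stand-in: a torso-like arrangement of compartments at
distinct activity concentrations (soft tissue ~1.8 kBq/mL, lungs ~0.4,
liver ~4.5 — the range a 2 MBq/kg FDG injection produces about an hour
post-injection), optional embedded "natural" lesions, system-specific PSF
blur and voxel grids, radioactive decay across the inter-scan delay, and
Poisson count noise at matched count levels.

The noise model is voxelwise Poisson on expected counts in image space:
reconstruction-domain noise correlation is deliberately out of scope, and
voxelwise Poisson preserves exactly the count-matching logic the toolkit is
built to exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

from . import isl
from .count_matching import F18_HALF_LIFE_MIN, expected_counts, solve_duration
from .errors import GeometryError, InfeasibleError, ValidationError
from .systems import SystemModel
from .volume import Volume3D, blur_volume, resample_to_grid

#: Counts registered per kBq of activity per second at unit sensitivity.
#: Sets the absolute noise level of the simulation; PET scanners detect a
#: small percentage of decays after solid angle and attenuation losses.
BASE_EFFICIENCY_CPS_PER_BQ = 0.01


@dataclass
class ScanMeta:
    """Injection and acquisition bookkeeping for one exam."""

    injected_activity_mbq: float
    injection_time: datetime
    scan_start: datetime
    duration_s: float
    patient_weight_kg: float
    half_life_min: float = F18_HALF_LIFE_MIN

    def __post_init__(self) -> None:
        if self.scan_start < self.injection_time:
            raise ValidationError("scan start must be at or after injection")
        for name in ("injected_activity_mbq", "duration_s", "patient_weight_kg", "half_life_min"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @property
    def uptake_min(self) -> float:
        return (self.scan_start - self.injection_time).total_seconds() / 60.0

    @property
    def decay_constant_per_min(self) -> float:
        return math.log(2.0) / self.half_life_min

    @property
    def decayed_activity_mbq(self) -> float:
        """Injected activity decay-corrected to scan start."""
        return self.injected_activity_mbq * 2.0 ** (-self.uptake_min / self.half_life_min)

    def to_dict(self) -> dict:
        return {
            "injected_activity_mbq": self.injected_activity_mbq,
            "injection_time": self.injection_time.isoformat(),
            "scan_start": self.scan_start.isoformat(),
            "duration_s": self.duration_s,
            "patient_weight_kg": self.patient_weight_kg,
            "half_life_min": self.half_life_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanMeta":
        d = dict(d)
        d["injection_time"] = datetime.fromisoformat(d["injection_time"])
        d["scan_start"] = datetime.fromisoformat(d["scan_start"])
        return cls(**d)


@dataclass
class Compartment:
    """One organ-like region painted at a uniform activity concentration.

    ``geometry`` is either ``"box"`` (params: ``lo``/``hi`` world-mm corners)
    or ``"ellipsoid"`` (params: ``centre`` and ``semi_axes`` in world mm).
    """

    label: str
    geometry: str
    params: dict
    ac_kbq_ml: float

    def __post_init__(self) -> None:
        if self.geometry not in ("box", "ellipsoid"):
            raise ValidationError(f"unknown compartment geometry {self.geometry!r}")
        if self.ac_kbq_ml < 0:
            raise ValidationError(f"{self.label}: AC must be >= 0")

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        if self.geometry == "box":
            return (np.asarray(self.params["lo"], float), np.asarray(self.params["hi"], float))
        c = np.asarray(self.params["centre"], float)
        a = np.asarray(self.params["semi_axes"], float)
        return c - a, c + a

    def mask(self, vol: Volume3D) -> np.ndarray:
        ii, jj, kk = np.meshgrid(
            np.arange(vol.shape[0]), np.arange(vol.shape[1]), np.arange(vol.shape[2]),
            indexing="ij",
        )
        idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        world = vol.voxel_to_world(idx)
        if self.geometry == "box":
            lo = np.asarray(self.params["lo"], float)
            hi = np.asarray(self.params["hi"], float)
            inside = np.all((world >= lo) & (world <= hi), axis=1)
        else:
            c = np.asarray(self.params["centre"], float)
            a = np.asarray(self.params["semi_axes"], float)
            inside = np.sum(((world - c) / a) ** 2, axis=1) <= 1.0
        return inside.reshape(vol.shape)


@dataclass
class PhantomSpec:
    """Recipe for one noiseless phantom: grid, compartments, natural lesions."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    background_ac: float = 0.0
    compartments: list[Compartment] = field(default_factory=list)
    natural_lesions: list[isl.LesionSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.spacing_mm, float) <= 0):
            raise ValidationError("spacing must be > 0 on every axis")
        if self.background_ac < 0:
            raise ValidationError("background AC must be >= 0")
        extent = np.asarray(self.shape, float) * np.asarray(self.spacing_mm, float)
        for comp in self.compartments:
            lo, hi = comp.world_bounds()
            if np.any(lo < 0) or np.any(hi > extent):
                raise GeometryError(
                    f"compartment {comp.label!r} extends outside the grid "
                    f"(bounds {lo}..{hi}, extent {extent})"
                )

    @property
    def world_extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape, float) * np.asarray(self.spacing_mm, float)


def default_phantom_spec(
    shape: tuple[int, int, int] = (64, 64, 48),
    spacing_mm: tuple[float, float, float] = (2.34, 2.34, 3.26),
    natural_lesions: list | None = None,
    seed: int = 0,
) -> PhantomSpec:
    """A torso-like phantom: body ellipsoid, two low-AC lungs, a hot liver box.

    Compartment ACs sit in the range a standard FDG protocol produces, so
    that lesions at design contrasts 2-14 land in realistic absolute ACs.
    """
    extent = np.asarray(shape, float) * np.asarray(spacing_mm, float)
    c = extent / 2.0
    body = Compartment(
        "body", "ellipsoid",
        {"centre": c.tolist(), "semi_axes": (0.45 * extent).tolist()},
        ac_kbq_ml=1.8,
    )
    lung_ax = (0.13 * extent[0], 0.16 * extent[1], 0.30 * extent[2])
    lung_l = Compartment(
        "lung_left", "ellipsoid",
        {"centre": [c[0] - 0.2 * extent[0], c[1], c[2] + 0.08 * extent[2]],
         "semi_axes": list(lung_ax)},
        ac_kbq_ml=0.4,
    )
    lung_r = Compartment(
        "lung_right", "ellipsoid",
        {"centre": [c[0] + 0.2 * extent[0], c[1], c[2] + 0.08 * extent[2]],
         "semi_axes": list(lung_ax)},
        ac_kbq_ml=0.4,
    )
    liver = Compartment(
        "liver", "box",
        {"lo": [c[0] + 0.05 * extent[0], c[1] - 0.18 * extent[1], c[2] - 0.35 * extent[2]],
         "hi": [c[0] + 0.38 * extent[0], c[1] + 0.18 * extent[1], c[2] - 0.08 * extent[2]]},
        ac_kbq_ml=4.5,
    )
    return PhantomSpec(
        shape=tuple(shape),
        spacing_mm=tuple(spacing_mm),
        background_ac=0.05,
        compartments=[body, lung_l, lung_r, liver],
        natural_lesions=list(natural_lesions or []),
        seed=seed,
    )


def default_scan_meta(
    weight_kg: float = 70.0,
    uptake_min: float = 60.0,
    duration_s: float = 120.0,
    dose_mbq_per_kg: float = 2.0,
) -> ScanMeta:
    """Standard protocol: 2 MBq/kg injection, ~60 min uptake, 2 min/bed."""
    injection = datetime(2021, 1, 1, 9, 0, 0)
    return ScanMeta(
        injected_activity_mbq=dose_mbq_per_kg * weight_kg,
        injection_time=injection,
        scan_start=injection + timedelta(minutes=uptake_min),
        duration_s=duration_s,
        patient_weight_kg=weight_kg,
    )


# ---------------------------------------------------------------------------
# generation


def generate_phantom(
    spec: PhantomSpec, system: SystemModel, meta: ScanMeta | None = None
) -> Volume3D:
    """Noiseless phantom for one system: paint, blur, insert natural lesions.

    Compartments are painted in list order (later ones overwrite earlier),
    the compartment field is blurred with the system PSF, and any natural
    lesions are then batch-inserted through the standard insertion path, so
    they carry exactly one PSF blur.  Deterministic given the spec.
    """
    data = np.full(spec.shape, spec.background_ac, dtype=np.float64)
    vol = Volume3D.from_spacing(data, spec.spacing_mm)
    for comp in spec.compartments:
        vol.data[comp.mask(vol)] = comp.ac_kbq_ml
    vol = blur_volume(vol, system.fwhm_vector)
    if spec.natural_lesions:
        vol, _ = isl.insert_lesions(vol, spec.natural_lesions, system)
    return vol


def add_acquisition_noise(
    vol: Volume3D,
    system: SystemModel,
    meta: ScanMeta,
    seed: int,
    base_efficiency: float = BASE_EFFICIENCY_CPS_PER_BQ,
) -> Volume3D:
    """One Poisson realization of the acquisition, returned on the AC scale.

    Voxel AC (taken as physical AC at scan start) is converted to expected
    counts — AC x voxel volume x sensitivity x efficiency x the decay
    integral over the acquisition window — a Poisson draw replaces the
    expectation, and the draw is converted back to AC.  Reproducible under a
    fixed seed.
    """
    if not np.all(np.isfinite(vol.data)):
        raise ValidationError("volume contains non-finite voxels")
    if np.any(vol.data < 0):
        raise ValidationError("volume contains negative AC")
    lam = meta.decay_constant_per_min
    integral_s = expected_counts(0.0, meta.duration_s / 60.0, lam) * 60.0
    # kBq/mL * mL = kBq = 1000 decays/s
    factor = (vol.voxel_volume_mm3 / 1000.0) * 1000.0 * system.sensitivity \
        * base_efficiency * integral_s
    expected = vol.data * factor
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(expected).astype(np.float64)
    return vol.with_data(noisy / factor)


def generate_paired_exams(
    spec: PhantomSpec,
    systems: tuple[SystemModel, SystemModel],
    meta1: ScanMeta,
    delay_min: float = 25.0,
    seed: int = 0,
    add_noise: bool = True,
    independent_noise: bool = True,
    max_duration_min: float | None = None,
) -> tuple[Volume3D, Volume3D, ScanMeta]:
    """The scan-rescan pair: decay, grid change, count matching, noise.

    Exam 1 is the noiseless phantom for the first system plus one noise
    realization.  Exam 2 is the same activity decayed by ``2^(-delay/T1/2)``,
    resampled onto the second system's voxel grid, acquired for the extended
    duration returned by count matching, with an independent noise
    realization (set ``independent_noise=False`` to reuse the seed, which
    makes a delay-0 identical-system pair bit-identical).

    Returns ``(exam1, exam2, meta2)`` where ``meta2`` carries the updated
    scan start and solved duration.
    """
    if delay_min < 0:
        raise ValidationError("delay must be >= 0")
    s1, s2 = systems
    lam = meta1.decay_constant_per_min
    t2_min = solve_duration(meta1.duration_s / 60.0, delay_min, lam)
    if max_duration_min is not None and t2_min > max_duration_min:
        raise InfeasibleError(
            f"matched duration {t2_min:.2f} min exceeds the configured "
            f"maximum {max_duration_min:.2f} min"
        )
    meta2 = replace(
        meta1,
        scan_start=meta1.scan_start + timedelta(minutes=delay_min),
        duration_s=t2_min * 60.0,
    )

    clean1 = generate_phantom(spec, s1, meta1)
    decay = 2.0 ** (-delay_min / meta1.half_life_min)
    decayed = clean1.with_data(clean1.data * decay)

    # target grid from the second system's voxel dims, covering the same FOV
    spacing2 = np.asarray(s2.voxel_dims_mm, float)
    extent = spec.world_extent_mm
    shape2 = tuple(int(round(e / s)) for e, s in zip(extent, spacing2))
    affine2 = np.eye(4)
    affine2[:3, :3] = np.diag(spacing2)
    clean2 = resample_to_grid(decayed, affine2, shape2)

    if not add_noise:
        return clean1, clean2, meta2
    seed2 = seed + 1 if independent_noise else seed
    exam1 = add_acquisition_noise(clean1, s1, meta1, seed)
    exam2 = add_acquisition_noise(clean2, s2, meta2, seed2)
    return exam1, exam2, meta2
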