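"""Insertion of synthetic lesions (ISL) into reconstructed PET volumes.

The method creates a controlled ground truth on clinical-looking images:

1. measure the local background activity concentration (AC) with a small
   spherical VOI at the insertion site, on the pristine image;
2. convert the desired contrast into a lesion AC,
   ``AC_lesion = AC_background * (1 + contrast)``;
3. rasterize the spherical lesion with sub-voxel partial-volume fractions;
4. blur the resulting delta image with the system PSF;
5. add the blurred delta to the volume.

Because the background is measured per volume and the *contrast* (not the
absolute AC) is what a lesion specification prescribes, inserting the same
lesion into two consecutive exams of the same subject automatically tracks
the local AC of each exam — e.g. the radioactive decay between a scan and a
rescan.

Insertion happens in image space: the delta is blurred with an effective
Gaussian PSF rather than being forward-projected and reconstructed.  This
preserves every quantity the downstream detection and semi-quantitation
statistics consume (local contrast, inserted activity, partial-volume
behaviour) without requiring a vendor reconstruction chain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptySupportError,
    InsufficientSupportError,
    OutOfBoundsError,
    RegistrationError,
    ValidationError,
)
from .systems import SystemModel
from .volume import (
    Volume3D,
    _voxel_bbox,
    blur_volume,
    sphere_inside_grid,
    sphere_mask,
    voi_radius_mm,
)

#: Recommended design ranges for synthetic lesions; violations warn, never error.
RECOMMENDED_DIAMETER_MM = (5.0, 11.0)
RECOMMENDED_CONTRAST = (2.0, 14.0)

ANATOMICAL_LABELS = (
    "lungs",
    "bone",
    "liver",
    "mediastinum",
    "retroperitoneal",
    "lymph_node",
    "other",
)


@dataclass
class LesionSpec:
    """One spherical lesion to insert: where, how big, how hot."""

    lesion_id: str
    centre_mm: tuple[float, float, float]
    diameter_mm: float
    contrast: float
    label: str = "other"
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValidationError(f"{self.lesion_id}: diameter must be > 0")
        if self.contrast <= -1:
            raise ValidationError(
                f"{self.lesion_id}: contrast must be > -1 so that the lesion AC is >= 0"
            )
        if self.label not in ANATOMICAL_LABELS:
            raise ValidationError(
                f"{self.lesion_id}: unknown anatomical label {self.label!r}"
            )
        if self.provenance not in ("synthetic", "natural"):
            raise ValidationError(f"{self.lesion_id}: provenance must be synthetic|natural")
        lo, hi = RECOMMENDED_DIAMETER_MM
        if not lo <= self.diameter_mm <= hi:
            warnings.warn(
                f"{self.lesion_id}: diameter {self.diameter_mm} mm outside the "
                f"recommended design range [{lo}; {hi}] mm",
                stacklevel=2,
            )
        lo, hi = RECOMMENDED_CONTRAST
        if not lo <= self.contrast <= hi:
            warnings.warn(
                f"{self.lesion_id}: contrast {self.contrast} outside the "
                f"recommended design range [{lo}; {hi}]",
                stacklevel=2,
            )

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    @property
    def analytic_volume_mm3(self) -> float:
        """Sphere volume (pi/6) d^3."""
        return float(np.pi / 6.0 * self.diameter_mm**3)


@dataclass
class InsertionEntry:
    """Per-volume record of one insertion."""

    system: str
    background_ac: float
    lesion_ac: float
    rasterized_volume_mm3: float
    inserted_activity_kbq: float


@dataclass
class InsertionReport:
    """What was inserted where, with the measured backgrounds."""

    lesion_id: str
    entries: list[InsertionEntry] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "lesion_id": self.lesion_id,
            "entries": [vars(e) for e in self.entries],
        }


# ---------------------------------------------------------------------------
# contrast arithmetic


def contrast_to_ac(background_ac: float, contrast: float) -> float:
    """Lesion AC from background AC and contrast: ``bg * (1 + contrast)``."""
    if background_ac < 0:
        raise ValidationError("background AC must be >= 0")
    if contrast <= -1:
        raise ValidationError("contrast must be > -1")
    return background_ac * (1.0 + contrast)


def ac_to_contrast(lesion_ac: float, background_ac: float) -> float:
    """Contrast from lesion and background AC: ``(lesion - bg) / bg``."""
    if background_ac == 0:
        raise ValidationError("background AC is 0: contrast undefined")
    return (lesion_ac - background_ac) / background_ac


# ---------------------------------------------------------------------------
# measurement VOI


def measure_background_ac(
    vol: Volume3D, centre_mm, voi_volume_cm3: float = 2.0
) -> float:
    """Mean AC over a spherical VOI of the given volume at a world position.

    The VOI radius is ``(3V / 4 pi)^(1/3)`` (2 cm^3 -> 7.8159 mm); a voxel
    belongs to the VOI when its centre lies inside the sphere, mimicking
    clinical VOI tools.
    """
    radius = voi_radius_mm(voi_volume_cm3)
    if not sphere_inside_grid(vol, centre_mm, radius):
        raise OutOfBoundsError(
            f"background VOI (r={radius:.2f} mm) extends beyond the volume grid"
        )
    mask = sphere_mask(vol, centre_mm, radius)
    n = int(mask.sum())
    if n < 8:
        raise InsufficientSupportError(
            f"background VOI contains only {n} voxel centres (need >= 8)"
        )
    return float(vol.data[mask].mean())


# ---------------------------------------------------------------------------
# sphere rasterization


def rasterize_sphere(
    vol: Volume3D, centre_mm, diameter_mm: float, supersampling: int = 3
) -> np.ndarray:
    """Fractional-occupancy map of a world-space sphere on the voxel grid.

    Each voxel's fraction in [0, 1] is estimated from ``supersampling^2``
    sub-voxel columns in the transverse plane with the through-column
    intersection length integrated analytically along the third axis, so
    the discretisation error lives only in the transverse plane.  On
    axis-aligned grids the total fractional volume agrees with the analytic
    (pi/6) d^3 to well under 1% at the default supersampling for clinical
    lesion sizes.  Grids with rotated/sheared affines fall back to pure
    ``supersampling^3`` point sampling.
    """
    if supersampling < 1:
        raise ValidationError("supersampling must be >= 1")
    if diameter_mm <= 0:
        raise ValidationError("diameter must be > 0")
    centre_mm = np.asarray(centre_mm, dtype=float)
    radius = diameter_mm / 2.0
    frac = np.zeros(vol.shape, dtype=np.float64)
    lo, hi = _voxel_bbox(vol, centre_mm, radius)
    if np.any(lo >= hi):
        raise EmptySupportError("sphere lies entirely outside the voxel grid")
    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0]),
        np.arange(lo[1], hi[1]),
        np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    axis_aligned = np.allclose(
        vol.affine[:3, :3], np.diag(np.diag(vol.affine[:3, :3])), atol=1e-9
    )
    s = supersampling
    off1d = (np.arange(s) + 0.5) / s - 0.5
    if axis_aligned:
        # analytic z-integration leaves only transverse discretisation error;
        # a 4x finer transverse subdivision keeps rim-cell error well below
        # the contract at the default supersampling, at negligible cost
        st = 4 * s
        off_t = (np.arange(st) + 0.5) / st - 0.5
        fr = _column_fractions(vol, idx, centre_mm, radius, off_t)
    else:
        ox, oy, oz = np.meshgrid(off1d, off1d, off1d, indexing="ij")
        offsets = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
        counts = np.zeros(len(idx), dtype=np.int64)
        r2 = radius**2
        for off in offsets:
            world = vol.voxel_to_world(idx + off)
            counts += np.sum((world - centre_mm) ** 2, axis=1) <= r2
        fr = counts / float(s**3)
    if not np.any(fr > 0):
        raise EmptySupportError("sphere covers no voxel of the grid")
    ijk = idx.astype(int)
    frac[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = fr
    return frac


def _column_fractions(
    vol: Volume3D, idx: np.ndarray, centre_mm: np.ndarray, radius: float, off1d
) -> np.ndarray:
    """Per-voxel fractions from s^2 transverse sub-columns, exact along z."""
    spacing = np.diag(vol.affine[:3, :3])
    origin = vol.affine[:3, 3]
    world = idx * spacing + origin  # voxel centres (axis-aligned)
    dz = abs(spacing[2])
    z_lo = world[:, 2] - dz / 2.0
    acc = np.zeros(len(idx), dtype=np.float64)
    for ox in off1d:
        for oy in off1d:
            x = world[:, 0] + ox * spacing[0] - centre_mm[0]
            y = world[:, 1] + oy * spacing[1] - centre_mm[1]
            rho2 = radius**2 - x**2 - y**2
            rho = np.sqrt(np.clip(rho2, 0.0, None))
            a = np.maximum(z_lo, centre_mm[2] - rho)
            b = np.minimum(z_lo + dz, centre_mm[2] + rho)
            acc += np.clip(b - a, 0.0, None) * (rho2 > 0)
    fr = np.clip(acc / (dz * len(off1d) ** 2), 0.0, 1.0)
    fr[fr > 1.0 - 1e-12] = 1.0  # snap interior voxels hit by float round-off
    return fr


# ---------------------------------------------------------------------------
# insertion


def _insert_with_background(
    vol: Volume3D,
    spec: LesionSpec,
    system: SystemModel,
    background_ac: float,
    supersampling: int = 3,
) -> tuple[np.ndarray, InsertionEntry]:
    """Blurred delta image + report entry for one lesion at a known background."""
    lesion_ac = contrast_to_ac(background_ac, spec.contrast)
    frac = rasterize_sphere(vol, spec.centre_mm, spec.diameter_mm, supersampling)
    delta_ac = lesion_ac - background_ac
    delta = frac * delta_ac
    blurred = blur_volume(vol.with_data(delta), system.fwhm_vector).data
    volume_mm3 = float(frac.sum() * vol.voxel_volume_mm3)
    entry = InsertionEntry(
        system=system.name,
        background_ac=background_ac,
        lesion_ac=lesion_ac,
        rasterized_volume_mm3=volume_mm3,
        inserted_activity_kbq=delta_ac * volume_mm3 / 1000.0,
    )
    return blurred, entry


def insert_lesion(
    vol: Volume3D,
    spec: LesionSpec,
    system: SystemModel,
    voi_volume_cm3: float = 2.0,
    supersampling: int = 3,
) -> tuple[Volume3D, InsertionReport]:
    """Insert one synthetic lesion; the input volume is left untouched.

    The background is measured on the pristine volume with the standard VOI,
    the lesion AC is set from the requested contrast, and the partial-volume
    rasterized delta is PSF-blurred before addition.
    """
    background = measure_background_ac(vol, spec.centre_mm, voi_volume_cm3)
    delta, entry = _insert_with_background(vol, spec, system, background, supersampling)
    report = InsertionReport(lesion_id=spec.lesion_id, entries=[entry])
    return vol.with_data(vol.data + delta), report


def insert_lesions(
    vol: Volume3D,
    specs: list[LesionSpec],
    system: SystemModel,
    voi_volume_cm3: float = 2.0,
    supersampling: int = 3,
) -> tuple[Volume3D, list[InsertionReport]]:
    """Insert a batch of lesions with backgrounds frozen at batch start.

    All background VOIs are measured on the pristine volume before any delta
    is added, which makes multi-lesion insertion independent of ordering.
    """
    backgrounds = [
        measure_background_ac(vol, s.centre_mm, voi_volume_cm3) for s in specs
    ]
    out = vol.data.copy()
    reports = []
    for spec, bg in zip(specs, backgrounds):
        delta, entry = _insert_with_background(vol, spec, system, bg, supersampling)
        out += delta
        reports.append(InsertionReport(lesion_id=spec.lesion_id, entries=[entry]))
    return vol.with_data(out), reports


def insert_matched(
    pair: tuple[Volume3D, Volume3D],
    spec: LesionSpec,
    systems: tuple[SystemModel, SystemModel],
    voi_volume_cm3: float = 2.0,
    supersampling: int = 3,
) -> tuple[tuple[Volume3D, Volume3D], InsertionReport]:
    """Insert the same lesion at the same world location into both exams.

    The background is measured independently per volume and the *same
    contrast* is applied to each, so each exam receives its own absolute
    lesion AC that tracks its local background (e.g. after decay).  The two
    volumes may live on different voxel grids (different systems); when they
    share a grid their affines must agree to 1e-3, otherwise a registration
    error is raised.
    """
    v1, v2 = pair
    s1, s2 = systems
    if v1.shape == v2.shape and not np.allclose(v1.affine, v2.affine, atol=1e-3):
        raise RegistrationError(
            "paired volumes share a grid shape but their world frames differ "
            "by more than 1e-3 mm"
        )
    out1, rep1 = insert_lesion(v1, spec, s1, voi_volume_cm3, supersampling)
    out2, rep2 = insert_lesion(v2, spec, s2, voi_volume_cm3, supersampling)
    report = InsertionReport(
        lesion_id=spec.lesion_id, entries=[rep1.entries[0], rep2.entries[0]]
    )
    return (out1, out2), report


def insert_matched_batch(
    pair: tuple[Volume3D, Volume3D],
    specs: list[LesionSpec],
    systems: tuple[SystemModel, SystemModel],
    voi_volume_cm3: float = 2.0,
    supersampling: int = 3,
) -> tuple[tuple[Volume3D, Volume3D], list[InsertionReport]]:
    """Batch variant of :func:`insert_matched` with backgrounds frozen per volume."""
    v1, v2 = pair
    s1, s2 = systems
    out1, reps1 = insert_lesions(v1, specs, s1, voi_volume_cm3, supersampling)
    out2, reps2 = insert_lesions(v2, specs, s2, voi_volume_cm3, supersampling)
    reports = [
        InsertionReport(lesion_id=a.lesion_id, entries=[a.entries[0], b.entries[0]])
        for a, b in zip(reps1, reps2)
    ]
    return (out1, out2), reports
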