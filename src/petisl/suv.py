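"""SUV normalisation, per-lesion SUV metrics, and relative differences.

SUV = AC (kBq/mL) x body weight (kg) / injected activity decay-corrected to
scan start (MBq); with the usual ~1 g/mL tissue density convention the
result is dimensionless.

Per-lesion metrics follow common clinical definitions:

* ``suv_max`` — maximum voxel value in a spherical search region centred on
  the lesion (diameter = lesion diameter + 2 x margin);
* ``suv_mean`` — mean over voxels inside the search region at or above 50%
  of ``suv_max`` (a relative isocontour);
* ``suv_peak`` — the largest mean over a 1 cm^3 sphere, maximised over
  sphere positions on the voxel lattice within the search region.

The relative difference between the two systems' readings of the same
lesion is the signed percentage referenced to the first system:
``RD = (SUV_sys2 - SUV_sys1) / SUV_sys1 x 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateLesionError, ValidationError
from .isl import LesionSpec
from .phantom import ScanMeta
from .volume import Volume3D, sphere_mask, voi_radius_mm


@dataclass(frozen=True)
class SUVTriple:
    """The three per-lesion SUV readings."""

    suv_max: float
    suv_mean: float
    suv_peak: float


@dataclass
class RDSummary:
    """Distribution summary of relative differences for one SUV metric."""

    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    degenerate: bool = False  # True when n == 1 and the SD is reported as 0


def ac_to_suv(vol: Volume3D, meta: ScanMeta) -> Volume3D:
    """Voxelwise SUV volume from an AC volume and scan metadata."""
    dose = meta.decayed_activity_mbq
    if dose <= 0:
        raise ValidationError("decayed injected activity must be > 0")
    return vol.with_data(vol.data * meta.patient_weight_kg / dose)


def _peak_means(vol: Volume3D, peak_volume_cm3: float) -> tuple[np.ndarray, int]:
    """Spherical-mean map for the SUVpeak sphere, via correlation."""
    r = voi_radius_mm(peak_volume_cm3)
    # kernel of voxel centres within the sphere, in voxel units
    half = np.ceil(r / vol.spacing).astype(int)
    ax = [np.arange(-h, h + 1) * s for h, s in zip(half, vol.spacing)]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    kernel = (gx**2 + gy**2 + gz**2 <= r**2).astype(np.float64)
    nvox = int(kernel.sum())
    kernel /= nvox
    means = ndimage.correlate(vol.data, kernel, mode="nearest")
    return means, nvox


def extract_suv(
    vol: Volume3D,
    spec: LesionSpec,
    margin_mm: float = 5.0,
    peak_volume_cm3: float = 1.0,
    isocontour: float = 0.5,
) -> SUVTriple:
    """SUVmax / SUVmean / SUVpeak for one lesion on a SUV (or AC) volume."""
    search_radius = spec.radius_mm + margin_mm
    mask = sphere_mask(vol, spec.centre_mm, search_radius)
    if not mask.any():
        raise DegenerateLesionError(
            f"{spec.lesion_id}: measurement region covers no voxel"
        )
    region = vol.data[mask]
    suv_max = float(region.max())
    iso = region[region >= isocontour * suv_max]
    if iso.size == 0:
        raise DegenerateLesionError(f"{spec.lesion_id}: empty isocontour")
    suv_mean = float(iso.mean())
    means, _ = _peak_means(vol, peak_volume_cm3)
    suv_peak = float(means[mask].max())
    return SUVTriple(suv_max=suv_max, suv_mean=suv_mean, suv_peak=suv_peak)


def relative_difference(suv_ref: float, suv_other: float) -> float:
    """Signed percentage difference of *other* vs *ref*: ``(other-ref)/ref*100``."""
    if suv_ref <= 0:
        raise ValidationError("reference SUV must be > 0")
    return (suv_other - suv_ref) / suv_ref * 100.0


def summarize_rd(pairs) -> RDSummary:
    """Summary of the RD distribution for one metric.

    ``pairs`` is a sequence of ``(suv_ref, suv_other)`` per lesion, typically
    restricted by the caller to lesions detected on both systems.  The SD
    uses the n-1 sample denominator; with a single pair the SD is reported
    as 0 and the summary flagged degenerate.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("summarize_rd requires at least one pair")
    rds = np.array([relative_difference(a, b) for a, b in pairs])
    degenerate = rds.size == 1
    sd = 0.0 if degenerate else float(rds.std(ddof=1))
    return RDSummary(
        n=int(rds.size),
        mean=float(rds.mean()),
        sd=sd,
        median=float(np.median(rds)),
        min=float(rds.min()),
        max=float(rds.max()),
        degenerate=degenerate,
    )


def rd_table(triples) -> dict[str, RDSummary]:
    """Per-metric RD summaries from paired SUV triples.

    ``triples`` is a sequence of ``(SUVTriple_ref, SUVTriple_other)``.
    """
    triples = list(triples)
    out = {}
    for metric in ("suv_max", "suv_mean", "suv_peak"):
        pairs = [(getattr(a, metric), getattr(b, metric)) for a, b in triples]
        out[metric] = summarize_rd(pairs)
    return out
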