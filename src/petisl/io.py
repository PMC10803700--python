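"""File formats: NIfTI volumes with JSON sidecars, manifests, reading sheets.

The canonical interchange is NIfTI-1 with the affine encoding spacing and
origin in world millimetres (RAS+); scan metadata travels in a JSON sidecar
next to the volume (``exam.nii`` -> ``exam.json``).  Lesion manifests and
reading sheets are plain CSV (JSON is accepted for manifests).  Volumes are
written in float64 so that a write-then-read round-trip is bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .isl import LesionSpec
from .phantom import ScanMeta
from .volume import Volume3D

MANIFEST_COLUMNS = (
    "id", "x_mm", "y_mm", "z_mm", "diameter_mm", "contrast", "label", "provenance",
)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_volume(vol: Volume3D, path, meta: ScanMeta | None = None) -> Path:
    """Write a volume as NIfTI-1 (+ JSON sidecar when metadata is given)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_xyzt_units(xyz="mm")
    nib.save(img, str(path))
    if meta is not None:
        _sidecar_path(path).write_text(json.dumps(meta.to_dict(), indent=1))
    return path


def read_volume(path) -> tuple[Volume3D, ScanMeta | None]:
    """Read a NIfTI volume and its JSON sidecar if present.

    Without a sidecar (or with an incomplete one) the volume is returned
    with ``meta=None`` and a degraded-mode warning: AC statistics remain
    available but SUV conversion is not.
    """
    path = Path(path)
    img = nib.load(str(path))
    vol = Volume3D(np.asarray(img.get_fdata(), dtype=np.float64), img.affine)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        warnings.warn(
            f"{path.name}: no JSON sidecar found; SUV conversion unavailable",
            stacklevel=2,
        )
        return vol, None
    try:
        meta = ScanMeta.from_dict(json.loads(sidecar.read_text()))
    except (KeyError, TypeError, ValueError) as exc:
        warnings.warn(
            f"{sidecar.name}: sidecar incomplete ({exc}); SUV conversion unavailable",
            stacklevel=2,
        )
        return vol, None
    return vol, meta


# ---------------------------------------------------------------------------
# lesion manifests


def read_lesion_manifest(path) -> list[LesionSpec]:
    """Lesion manifest from CSV or JSON with the documented column schema."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        rows = pd.read_csv(path).to_dict("records")
    specs = []
    for row in rows:
        missing = [c for c in MANIFEST_COLUMNS[:6] if c not in row]
        if missing:
            raise ValidationError(f"manifest row missing columns: {missing}")
        specs.append(
            LesionSpec(
                lesion_id=str(row["id"]),
                centre_mm=(float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
                diameter_mm=float(row["diameter_mm"]),
                contrast=float(row["contrast"]),
                label=str(row.get("label", "other")),
                provenance=str(row.get("provenance", "synthetic")),
            )
        )
    return specs


def write_lesion_manifest(specs: list[LesionSpec], path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "id": [s.lesion_id for s in specs],
            "x_mm": [s.centre_mm[0] for s in specs],
            "y_mm": [s.centre_mm[1] for s in specs],
            "z_mm": [s.centre_mm[2] for s in specs],
            "diameter_mm": [s.diameter_mm for s in specs],
            "contrast": [s.contrast for s in specs],
            "label": [s.label for s in specs],
            "provenance": [s.provenance for s in specs],
        }
    )
    df.to_csv(path, index=False)
    return path


def read_reading_sheet(path) -> pd.DataFrame:
    """Reading-session sheet CSV (long format, one row per lesion x reader x system)."""
    df = pd.read_csv(path)
    required = {"lesion_id", "reader_id", "system", "detected"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"reading sheet lacks columns: {sorted(missing)}")
    if df["detected"].dtype == object:
        df["detected"] = df["detected"].map(
            {"True": True, "False": False, "true": True, "false": False, 1: True, 0: False}
        )
    return df


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Top-level configuration for a simulation + evaluation run."""

    output_dir: str = "petisl_out"
    seed: int = 0
    consensus_rule: str = "and"
    ci_method: str = "auto"
    reader_threshold: float = 4.0
    phantom_spec: str | None = None
    lesion_manifest: str | None = None
    systems: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
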