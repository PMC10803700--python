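"""PET system models: the imaging contract of one scanner.

A :class:`SystemModel` abstracts a scanner into the quantities the image-space
simulation consumes: reconstructed voxel grid, effective point-spread
function, time-of-flight capability and a relative count sensitivity.  Two
presets mirror the BGO/PMT and LYSO/SiPM scanner classes compared in
scan-rescan studies: a non-TOF system on a 2.34 x 2.34 x 3.26 mm grid and a
TOF system on a 2.34 x 2.34 x 2.8 mm grid.

The effective FWHM values (5.0 / 4.0 mm) and the TOF sensitivity multiplier
(2.0) are explicit configuration, not measured constants: reconstructed
resolution depends on the reconstruction chain and is rarely published per
protocol.  Tests never assert these defaults as physical truths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class SystemModel:
    """Imaging contract of one PET system."""

    name: str
    voxel_dims_mm: tuple[float, float, float]
    psf_fwhm_mm: float | tuple[float, float, float] = 5.0
    tof: bool = False
    sensitivity: float = 1.0

    def __post_init__(self) -> None:
        dims = np.asarray(self.voxel_dims_mm, dtype=float)
        if dims.shape != (3,) or np.any(dims <= 0):
            raise ValidationError("voxel dims must be three positive lengths (mm)")
        fwhm = np.broadcast_to(np.asarray(self.psf_fwhm_mm, dtype=float), (3,))
        if np.any(fwhm <= 0):
            raise ValidationError("PSF FWHM must be > 0")
        if self.sensitivity <= 0:
            raise ValidationError("sensitivity must be > 0")

    @property
    def fwhm_vector(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.psf_fwhm_mm, dtype=float), (3,)).copy()


#: Non-TOF BGO-class system (wider effective PSF, unit sensitivity).
DIQ_LIKE = SystemModel(
    name="DIQ-like", voxel_dims_mm=(2.34, 2.34, 3.26), psf_fwhm_mm=5.0, tof=False, sensitivity=1.0
)

#: TOF LYSO-class system (narrower effective PSF, higher effective sensitivity).
DMI_LIKE = SystemModel(
    name="DMI-like", voxel_dims_mm=(2.34, 2.34, 2.8), psf_fwhm_mm=4.0, tof=True, sensitivity=2.0
)
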