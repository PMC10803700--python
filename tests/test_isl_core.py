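"""Unit and property tests for the lesion-insertion core."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import petisl
from petisl.errors import (
    EmptySupportError,
    InsufficientSupportError,
    OutOfBoundsError,
    RegistrationError,
    ValidationError,
)

CENTRE = (46.8, 46.8, 48.9)  # well inside the 40x40x30 fixture grids


class TestContrast:
    @pytest.mark.parametrize(
        "bg, contrast, expected",
        [(2.0, 0.0, 2.0), (1.0, 2.0, 3.0), (2.34, (6.16 - 2.34) / 2.34, 6.16)],
    )
    def test_contrast_to_ac(self, bg, contrast, expected):
        assert petisl.contrast_to_ac(bg, contrast) == pytest.approx(expected, rel=1e-12)

    @given(
        bg=st.floats(0.1, 50.0, allow_nan=False),
        contrast=st.floats(-0.99, 20.0, allow_nan=False),
    )
    def test_roundtrip(self, bg, contrast):
        """contrast -> AC -> contrast round-trips to 1e-12 relative."""
        lesion = petisl.contrast_to_ac(bg, contrast)
        back = petisl.ac_to_contrast(lesion, bg)
        assert back == pytest.approx(contrast, rel=1e-12, abs=1e-12)

    def test_guards(self):
        with pytest.raises(ValidationError):
            petisl.contrast_to_ac(2.0, -1.5)
        with pytest.raises(ValidationError):
            petisl.ac_to_contrast(6.0, 0.0)


class TestBackgroundVOI:
    def test_voi_radius_for_2cm3(self):
        """A 2 cm^3 sphere has radius (3*2000/4pi)^(1/3) = 7.8159 mm."""
        assert petisl.voi_radius_mm(2.0) == pytest.approx(7.8159, abs=5e-5)

    def test_uniform_field(self, uniform_vol):
        assert petisl.measure_background_ac(uniform_vol, CENTRE) == pytest.approx(5.0)

    def test_gradient_matches_bruteforce(self, gradient_vol):
        """VOI mean equals an independently enumerated voxel-centre average."""
        measured = petisl.measure_background_ac(gradient_vol, CENTRE)
        r = petisl.voi_radius_mm(2.0)
        vals = []
        sp = (2.34, 2.34, 3.26)
        for i in range(40):
            for j in range(40):
                for k in range(30):
                    pos = np.array([i * sp[0], j * sp[1], k * sp[2]])
                    if np.sum((pos - np.array(CENTRE)) ** 2) <= r**2:
                        vals.append(gradient_vol.data[i, j, k])
        assert len(vals) >= 8
        assert measured == pytest.approx(np.mean(vals), rel=1e-12)

    def test_out_of_bounds(self, uniform_vol):
        with pytest.raises(OutOfBoundsError):
            petisl.measure_background_ac(uniform_vol, (2.0, 46.8, 48.9))

    def test_insufficient_support(self):
        vol = petisl.Volume3D.from_spacing(np.full((9, 9, 9), 1.0), (20.0, 20.0, 20.0))
        with pytest.raises(InsufficientSupportError):
            petisl.measure_background_ac(vol, (90.0, 90.0, 90.0))


class TestRasterizeSphere:
    @pytest.mark.parametrize("spacing", [(2.34, 2.34, 3.26), (2.34, 2.34, 2.8)])
    @pytest.mark.parametrize("d", [5.0, 7.0, 9.4, 11.0])
    def test_total_volume_within_1pct(self, spacing, d):
        """Rasterized volume matches (pi/6) d^3 on both clinical grids."""
        vol = petisl.Volume3D.from_spacing(np.zeros((40, 40, 40)), spacing)
        centre = np.array(spacing) * 20 + [0.7, -0.4, 1.1]
        frac = petisl.rasterize_sphere(vol, centre, d)
        total = frac.sum() * vol.voxel_volume_mm3
        assert total == pytest.approx(np.pi / 6 * d**3, rel=0.01)
        assert frac.min() >= 0 and frac.max() <= 1.0

    def test_d94_analytic(self):
        vol = petisl.Volume3D.from_spacing(np.zeros((40, 40, 40)), (2.34, 2.34, 3.26))
        frac = petisl.rasterize_sphere(vol, (46.8, 46.8, 65.2), 9.4)
        assert frac.sum() * vol.voxel_volume_mm3 == pytest.approx(434.89, rel=0.01)

    def test_interior_voxel_full(self):
        vol = petisl.Volume3D.from_spacing(np.zeros((40, 40, 40)), (2.34, 2.34, 2.8))
        centre = (46.8, 46.8, 56.0)
        frac = petisl.rasterize_sphere(vol, centre, 11.0)
        idx = np.round(vol.world_to_voxel(centre)[0]).astype(int)
        assert frac[tuple(idx)] == pytest.approx(1.0)

    def test_supersampling_convergence(self):
        """Totals at supersampling 3 and 7 agree within 0.5%."""
        vol = petisl.Volume3D.from_spacing(np.zeros((40, 40, 40)), (2.34, 2.34, 3.26))
        centre = (45.0, 48.0, 63.0)
        t3 = petisl.rasterize_sphere(vol, centre, 7.0, supersampling=3).sum()
        t7 = petisl.rasterize_sphere(vol, centre, 7.0, supersampling=7).sum()
        assert t3 == pytest.approx(t7, rel=0.005)

    def test_sphere_outside_grid(self):
        vol = petisl.Volume3D.from_spacing(np.zeros((20, 20, 20)), (2.0, 2.0, 2.0))
        with pytest.raises(EmptySupportError):
            petisl.rasterize_sphere(vol, (200.0, 200.0, 200.0), 8.0)


class TestInsertLesion:
    def test_zero_contrast_is_identity(self, uniform_vol):
        spec = petisl.LesionSpec("L0", CENTRE, 10.0, 0.0)
        out, _ = petisl.insert_lesion(uniform_vol, spec, petisl.DIQ_LIKE)
        np.testing.assert_array_equal(out.data, uniform_vol.data)

    def test_activity_conservation_and_closed_form(self, diq):
        """bg=2, contrast=4, d=10: inserted activity 8 kBq/mL x (pi/6)d^3."""
        vol = petisl.Volume3D.from_spacing(
            np.full((40, 40, 30), 2.0), (2.34, 2.34, 3.26)
        )
        spec = petisl.LesionSpec("L1", CENTRE, 10.0, 4.0)
        out, report = petisl.insert_lesion(vol, spec, diq)
        entry = report.entries[0]
        assert entry.background_ac == pytest.approx(2.0)
        assert entry.lesion_ac == pytest.approx(10.0)
        # closed form: 8 kBq/mL x 523.6 mm^3 = 4.189 kBq
        assert entry.inserted_activity_kbq == pytest.approx(4.189, rel=0.01)
        # conservation through the PSF blur, 1e-6 relative
        added = (out.data - vol.data).sum() * vol.voxel_volume_mm3 / 1000.0
        assert added == pytest.approx(entry.inserted_activity_kbq, rel=1e-6)

    def test_input_volume_untouched(self, uniform_vol, diq):
        before = uniform_vol.data.copy()
        spec = petisl.LesionSpec("L1", CENTRE, 8.0, 3.0)
        petisl.insert_lesion(uniform_vol, spec, diq)
        np.testing.assert_array_equal(uniform_vol.data, before)

    def test_blur_locality(self, uniform_vol, diq):
        """Background far from the lesion (>= 5 FWHM) is unchanged to 1e-9."""
        spec = petisl.LesionSpec("L1", (30.0, 30.0, 35.0), 8.0, 4.0)
        out, _ = petisl.insert_lesion(uniform_vol, spec, diq)
        far = (75.0, 75.0, 70.0)  # ~70 mm away, FWHM 5 mm
        bg_after = petisl.measure_background_ac(out, far)
        assert bg_after == pytest.approx(5.0, abs=1e-9)

    def test_linearity_in_contrast(self, uniform_vol, diq):
        """Contrast 2c yields exactly twice the delta image of contrast c."""
        s1 = petisl.LesionSpec("L1", CENTRE, 9.0, 3.0)
        s2 = petisl.LesionSpec("L2", CENTRE, 9.0, 6.0)
        out1, _ = petisl.insert_lesion(uniform_vol, s1, diq)
        out2, _ = petisl.insert_lesion(uniform_vol, s2, diq)
        d1 = out1.data - uniform_vol.data
        d2 = out2.data - uniform_vol.data
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-10, atol=1e-12)

    def test_batch_order_independence(self, uniform_vol, diq):
        a = petisl.LesionSpec("A", (30.0, 30.0, 30.0), 8.0, 3.0)
        b = petisl.LesionSpec("B", (65.0, 65.0, 65.0), 8.0, 5.0)
        out_ab, _ = petisl.insert_lesions(uniform_vol, [a, b], diq)
        out_ba, _ = petisl.insert_lesions(uniform_vol, [b, a], diq)
        np.testing.assert_allclose(out_ab.data, out_ba.data, rtol=0, atol=1e-12)

    def test_contrast_recovery_preblur(self, uniform_vol):
        """Mean AC over the full-occupancy core / background = 1 + contrast."""
        contrast, bg = 4.0, 5.0
        frac = petisl.rasterize_sphere(uniform_vol, CENTRE, 10.0)
        delta = frac * (petisl.contrast_to_ac(bg, contrast) - bg)
        core = frac >= 1.0
        assert core.any()
        pre_blur = uniform_vol.data + delta
        assert pre_blur[core].mean() / bg == pytest.approx(1 + contrast, rel=1e-6)


class TestInsertMatched:
    def test_identical_volumes_symmetric(self, uniform_vol, diq):
        spec = petisl.LesionSpec("L1", CENTRE, 9.0, 3.0)
        (o1, o2), rep = petisl.insert_matched(
            (uniform_vol, uniform_vol.copy()), spec, (diq, diq)
        )
        np.testing.assert_array_equal(o1.data, o2.data)
        e1, e2 = rep.entries
        assert e1.background_ac == e2.background_ac
        assert e1.lesion_ac == e2.lesion_ac

    def test_decayed_pair_scales_lesion_ac(self, uniform_vol, diq, dmi):
        """With volume 2 = volume 1 x 0.854, lesion ACs scale by 0.854."""
        decay = 0.854
        v2 = uniform_vol.with_data(uniform_vol.data * decay)
        spec = petisl.LesionSpec("L1", CENTRE, 9.0, 4.0)
        (_, _), rep = petisl.insert_matched((uniform_vol, v2), spec, (diq, diq))
        e1, e2 = rep.entries
        assert e2.lesion_ac / e1.lesion_ac == pytest.approx(decay, rel=1e-9)
        # Eq. 1 recovery per entry: same prescribed contrast on both exams
        for e in rep.entries:
            assert petisl.ac_to_contrast(e.lesion_ac, e.background_ac) == pytest.approx(
                spec.contrast, rel=1e-12
            )

    def test_registration_error(self, uniform_vol, diq):
        shifted = petisl.Volume3D.from_spacing(
            uniform_vol.data.copy(), (2.34, 2.34, 3.26), origin=(0.01, 0, 0)
        )
        spec = petisl.LesionSpec("L1", CENTRE, 9.0, 3.0)
        with pytest.raises(RegistrationError):
            petisl.insert_matched((uniform_vol, shifted), spec, (diq, diq))


class TestLesionSpecValidation:
    def test_design_range_warnings(self):
        with pytest.warns(UserWarning, match="diameter"):
            petisl.LesionSpec("L1", (0, 0, 0), 4.0, 3.0)
        with pytest.warns(UserWarning, match="contrast"):
            petisl.LesionSpec("L2", (0, 0, 0), 8.0, 20.0)

    def test_invalid_contrast_raises(self):
        with pytest.raises(ValidationError):
            petisl.LesionSpec("L1", (0, 0, 0), 8.0, -1.2)

    def test_unknown_label_raises(self):
        with pytest.raises(ValidationError):
            petisl.LesionSpec("L1", (0, 0, 0), 8.0, 3.0, label="spleen")
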