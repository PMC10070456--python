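"""Stitching, crystallinity integral and pole-figure FWHM."""

import numpy as np
import pytest

from wallwaxs import reduction, synthetic
from wallwaxs.polefigure import (
    PoleFigure,
    StitchError,
    crystallinity_index,
    floor_level,
    polefigure_fwhm,
    stitch,
)
from wallwaxs.reduction import AzimuthalProfile


def _gauss_profile(chi, fwhm=38.3, height=1.0, offset=0.0):
    return offset + height * np.exp(-4 * np.log(2) * (chi / fwhm) ** 2)


def _azprofile(chi, inten, invalid_below=None):
    valid = np.ones(len(chi), bool)
    if invalid_below is not None:
        valid &= chi >= invalid_below
    vals = np.where(valid, inten, np.nan)
    return AzimuthalProfile(np.asarray(chi, float), vals, valid)


class TestStitch:
    chi = np.arange(0.5, 90.0, 1.0)

    def test_recovers_known_scale(self):
        img = _azprofile(self.chi, _gauss_profile(self.chi), invalid_below=8.0)
        c = 3.7
        # same grid: exact; finer grid: limited by linear interpolation
        rchi = self.chi[self.chi < 20.0]
        rock = _azprofile(rchi, _gauss_profile(rchi) / c)
        pf = stitch(img, rock, overlap=(8, 15))
        assert pf.scale == pytest.approx(c, abs=1e-10)
        assert np.all(np.isfinite(pf.intensity))
        rchi2 = np.arange(0.25, 20.0, 0.5)
        rock2 = _azprofile(rchi2, _gauss_profile(rchi2) / c)
        assert stitch(img, rock2, overlap=(8, 15)).scale == pytest.approx(
            c, rel=1e-3
        )

    def test_full_range_image_identity_outside_overlap(self):
        inten = _gauss_profile(self.chi)
        img = _azprofile(self.chi, inten)
        rchi = np.arange(0.25, 20.0, 0.5)
        rock = _azprofile(rchi, _gauss_profile(rchi))
        pf = stitch(img, rock, overlap=(8, 15))
        outside = (pf.chi > 15.5)
        assert np.allclose(pf.intensity[outside], inten[outside])
        assert set(pf.provenance[outside]) == {"image"}

    def test_signed_profile_folded_by_averaging(self):
        chi = np.arange(-89.5, 90.0, 1.0)
        asym = _gauss_profile(chi) + 0.01 * np.sign(chi)
        img = AzimuthalProfile(chi, asym, np.ones(len(chi), bool))
        rchi = np.arange(0.25, 20.0, 0.5)
        rock = _azprofile(rchi, _gauss_profile(rchi))
        pf = stitch(img, rock, overlap=(8, 15))
        assert pf.chi.min() >= 0
        # the antisymmetric part averages out on the image-only region
        sel = pf.chi > 15.5
        assert np.allclose(pf.intensity[sel],
                           _gauss_profile(pf.chi[sel]), atol=1e-12)

    def test_insufficient_overlap_rejected(self):
        img = _azprofile(self.chi, _gauss_profile(self.chi), invalid_below=8.0)
        rock = _azprofile(np.arange(0.25, 5.0, 0.5),
                          _gauss_profile(np.arange(0.25, 5.0, 0.5)))
        with pytest.raises(StitchError):
            stitch(img, rock, overlap=(8, 15))

    def test_negative_scale_falls_back_to_absolute_value(self):
        img = _azprofile(self.chi, _gauss_profile(self.chi), invalid_below=8.0)
        rchi = np.arange(0.25, 20.0, 0.5)
        rock = _azprofile(rchi, -_gauss_profile(rchi))
        with pytest.warns(UserWarning):
            pf = stitch(img, rock, overlap=(8, 15))
        assert pf.scale > 0
        assert pf.scale_flipped

    def test_prescaling_invariance(self):
        img = _azprofile(self.chi, _gauss_profile(self.chi), invalid_below=8.0)
        rchi = np.arange(0.25, 20.0, 0.5)
        base = _gauss_profile(rchi)
        pf1 = stitch(img, _azprofile(rchi, base), overlap=(8, 15))
        pf2 = stitch(img, _azprofile(rchi, 10.0 * base), overlap=(8, 15))
        assert np.allclose(pf1.intensity, pf2.intensity, rtol=1e-12)


class TestCrystallinityIndex:
    def test_uniform_intensity_integrates_to_one(self):
        chi = np.linspace(0.0, 90.0, 901)
        pf = PoleFigure(chi, np.ones(len(chi)), np.full(len(chi), "image"))
        assert crystallinity_index(pf) == pytest.approx(1.0, abs=1e-6)

    def test_sine_intensity_integrates_to_pi_over_4(self):
        chi = np.linspace(0.0, 90.0, 901)
        pf = PoleFigure(chi, np.sin(np.radians(chi)), np.full(len(chi), "image"))
        assert crystallinity_index(pf) == pytest.approx(np.pi / 4, abs=1e-6)

    def test_gaussian_kernel_matches_dense_quadrature(self):
        chi = np.linspace(0.0, 90.0, 91)
        pf = PoleFigure(chi, _gauss_profile(chi), np.full(len(chi), "image"))
        dense = np.linspace(0.0, 90.0, 200001)
        oracle = np.trapezoid(
            np.sin(np.radians(dense)) * _gauss_profile(dense), np.radians(dense)
        )
        assert crystallinity_index(pf) == pytest.approx(oracle, abs=1e-4)

    def test_linear_in_amplitude(self):
        chi = np.linspace(0.0, 90.0, 181)
        inten = _gauss_profile(chi)
        pf1 = PoleFigure(chi, inten, np.full(len(chi), "image"))
        pf2 = PoleFigure(chi, 5.0 * inten, np.full(len(chi), "image"))
        assert crystallinity_index(pf2) == pytest.approx(
            5.0 * crystallinity_index(pf1), rel=1e-12
        )

    def test_gaps_rejected_unless_allowed(self):
        chi = np.linspace(0.0, 90.0, 91)
        inten = _gauss_profile(chi)
        inten[3] = np.nan
        pf = PoleFigure(chi, inten, np.full(len(chi), "image"))
        with pytest.raises(ValueError):
            crystallinity_index(pf)
        with pytest.warns(UserWarning):
            crystallinity_index(pf, allow_gaps=True)


class TestFWHM:
    def test_exact_gaussian_on_dense_grid(self):
        chi = np.linspace(0.0, 90.0, 9001)
        pf = PoleFigure(chi, _gauss_profile(chi, fwhm=41.7),
                        np.full(len(chi), "image"))
        assert polefigure_fwhm(pf) == pytest.approx(41.7, abs=0.1)

    def test_offset_does_not_change_width(self):
        chi = np.linspace(0.0, 90.0, 9001)
        pf = PoleFigure(chi, _gauss_profile(chi, fwhm=30.0, offset=5.0),
                        np.full(len(chi), "image"))
        assert polefigure_fwhm(pf) == pytest.approx(30.0, abs=0.1)

    def test_coarse_grid_matches_dense_oracle_within_one_bin(self):
        coarse = np.arange(0.5, 90.0, 2.0)
        dense = np.arange(0.05, 90.0, 0.2)
        w_coarse = polefigure_fwhm(
            PoleFigure(coarse, _gauss_profile(coarse, fwhm=33.3),
                       np.full(len(coarse), "image"))
        )
        w_dense = polefigure_fwhm(
            PoleFigure(dense, _gauss_profile(dense, fwhm=33.3),
                       np.full(len(dense), "image"))
        )
        assert abs(w_coarse - w_dense) < 2.0

    def test_flat_profile_has_no_fwhm(self):
        chi = np.linspace(0.0, 90.0, 91)
        pf = PoleFigure(chi, np.ones(len(chi)), np.full(len(chi), "image"))
        with pytest.raises(ValueError):
            polefigure_fwhm(pf)


class TestEndToEnd:
    def test_stitched_polefigure_matches_generating_kernel(self, hydrated_spec):
        geom = synthetic.GeometryConfig(missing_wedge_halfangle=8.0)
        img = synthetic.render_qspace_image(hydrated_spec, geom)
        azim = reduction.azimuthal_profile(img)
        rock = synthetic.render_rocking_profile(hydrated_spec, scale=0.35)
        pf = stitch(azim, rock, overlap=(8, 15))
        assert np.all(np.isfinite(pf.intensity))
        assert polefigure_fwhm(pf) == pytest.approx(38.3, abs=0.5)
        # kernel shape above the floor matches the generating chi Gaussian
        floor = floor_level(pf)
        shape = (pf.intensity - floor)
        kernel = _gauss_profile(pf.chi, fwhm=38.3)
        scale = shape.max()
        sel = pf.chi < 60
        assert np.abs(shape[sel] / scale - kernel[sel]).max() < 0.05

    def test_hydrated_dried_index_within_5pct_at_matched_content(
        self, hydrated_spec, dried_spec
    ):
        """Generator emulates unchanged oriented crystalline content."""
        vals = {}
        for name, spec in (("hydrated", hydrated_spec), ("dried", dried_spec)):
            geom = synthetic.GeometryConfig(missing_wedge_halfangle=8.0)
            img = synthetic.render_qspace_image(spec, geom)
            azim = reduction.azimuthal_profile(img)
            rock = synthetic.render_rocking_profile(spec, scale=0.35)
            pf = stitch(azim, rock, overlap=(8, 15))
            flat = PoleFigure(pf.chi, pf.intensity - floor_level(pf),
                              pf.provenance)
            vals[name] = crystallinity_index(flat, allow_gaps=True)
        rel = abs(vals["hydrated"] - vals["dried"]) / vals["hydrated"]
        assert rel < 0.05
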