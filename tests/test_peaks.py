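"""Deconvolution: exact recovery, constraints, derived metrics, paired test."""

import math

import numpy as np
import pandas as pd
import pytest

from wallwaxs import synthetic
from wallwaxs.peaks import (
    ScherrerParams,
    VARIANTS,
    area_ratio,
    compare_states,
    d_spacing,
    fit_profile,
    intensity_ratio,
    scherrer_length,
)
from wallwaxs.reduction import Profile1D


def _chi_sector_factor(fwhm_chi, half_angle=17.0):
    from scipy.special import erf

    k = math.sqrt(4 * math.log(2)) / fwhm_chi
    return math.sqrt(math.pi) / (2 * k * half_angle) * erf(k * half_angle)


class TestFit:
    @pytest.mark.parametrize("state", ["hydrated", "dried"])
    def test_noiseless_recovery_to_1e6_relative(self, state):
        spec = synthetic.preset(state)
        prof = synthetic.render_sector_profile1d(spec)
        res = fit_profile(prof)
        for kind in ("amorphous1", "amorphous2", "110", "200"):
            truth = spec.component(kind)
            got = res.components[kind]
            assert got.center == pytest.approx(truth.center_q, rel=1e-6)
            assert got.fwhm == pytest.approx(truth.fwhm_q, rel=1e-6)
            fac = (1.0 if truth.texture is None
                   else _chi_sector_factor(truth.texture[1]))
            assert got.height == pytest.approx(truth.height * fac, rel=1e-6)
        assert res.baseline_slope == pytest.approx(spec.baseline_slope, rel=1e-6)

    def test_amorphous2_center_fixed_at_1p41(self, hydrated_spec):
        prof = synthetic.render_sector_profile1d(hydrated_spec)
        res = fit_profile(prof)
        assert res.components["amorphous2"].center == 1.41
        res12 = fit_profile(prof, variant="amorphous2-at-1.2")
        assert res12.components["amorphous2"].center == 1.2

    def test_rescaling_invariance(self, hydrated_spec):
        prof = synthetic.render_sector_profile1d(hydrated_spec)
        res1 = fit_profile(prof)
        scaled = Profile1D(prof.q, 3.7 * prof.intensity, prof.counts)
        res2 = fit_profile(scaled)
        for kind in ("110", "200"):
            assert res2.components[kind].center == pytest.approx(
                res1.components[kind].center, rel=1e-8
            )
            assert res2.components[kind].fwhm == pytest.approx(
                res1.components[kind].fwhm, rel=1e-8
            )
            assert res2.components[kind].height == pytest.approx(
                3.7 * res1.components[kind].height, rel=1e-8
            )

    def test_noisy_recovery_over_seeds(self):
        """Poisson noise at default exposure: centers +-0.01 1/A, ratio +-0.04."""
        from wallwaxs import reduction

        spec0 = synthetic.preset("hydrated")
        truth110 = spec0.component("110").center_q
        truth200 = spec0.component("200").center_q
        geom = synthetic.GeometryConfig()
        centers110, centers200, ratios = [], [], []
        for seed in range(10):
            spec = synthetic.preset("hydrated")
            spec.seed = seed
            img = synthetic.render_qspace_image(spec, geom)
            prof = reduction.linear_baseline_subtract(
                reduction.sector_profile(img, -17, 17)
            )
            res = fit_profile(prof)
            centers110.append(res.components["110"].center)
            centers200.append(res.components["200"].center)
            ratios.append(intensity_ratio(res))
        assert abs(np.mean(centers110) - truth110) < 0.01
        assert abs(np.mean(centers200) - truth200) < 0.01
        assert abs(np.mean(ratios) - 0.52) < 0.04

    def test_variant_trend_preservation(self):
        """Hydrated->dried signs of the d110 and ratio changes survive all
        fitting-model variants."""
        for variant in VARIANTS:
            vals = {}
            for state in ("hydrated", "dried"):
                prof = synthetic.render_sector_profile1d(synthetic.preset(state))
                res = fit_profile(prof, variant=variant)
                vals[state] = (
                    d_spacing(res.components["110"].center),
                    intensity_ratio(res),
                )
            assert vals["hydrated"][0] > vals["dried"][0], variant
            assert vals["hydrated"][1] < vals["dried"][1], variant

    def test_unknown_variant_rejected(self, hydrated_spec):
        prof = synthetic.render_sector_profile1d(hydrated_spec)
        with pytest.raises(ValueError):
            fit_profile(prof, variant="nonsense")


class TestDSpacing:
    def test_worked_examples(self):
        assert round(d_spacing(0.85), 1) == 7.4
        assert round(d_spacing(0.89), 1) == 7.1
        assert d_spacing(2 * math.pi) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            d_spacing(0.0)


class TestIntensityRatio:
    def test_equal_heights_give_unity(self, hydrated_spec):
        prof = synthetic.render_sector_profile1d(hydrated_spec)
        res = fit_profile(prof)
        res.components["110"].height = res.components["200"].height
        assert intensity_ratio(res) == pytest.approx(1.0)

    def test_preset_ratios(self, hydrated_spec, dried_spec):
        for spec, expect in ((hydrated_spec, 0.52), (dried_spec, 0.86)):
            prof = synthetic.render_sector_profile1d(spec)
            assert intensity_ratio(fit_profile(prof)) == pytest.approx(
                expect, abs=1e-6
            )

    def test_zero_200_height_undefined(self, hydrated_spec):
        prof = synthetic.render_sector_profile1d(hydrated_spec)
        res = fit_profile(prof)
        res.components["200"].height = 0.0
        with pytest.raises(ZeroDivisionError):
            intensity_ratio(res)
        with pytest.raises(ZeroDivisionError):
            area_ratio(res)


class TestScherrer:
    def test_closed_form_value(self):
        L = scherrer_length(0.240, ScherrerParams(K=0.9))
        assert L == pytest.approx(2 * math.pi * 0.9 / 0.240, rel=1e-12)
        assert L == pytest.approx(23.56, abs=0.01)

    def test_unit_width(self):
        assert scherrer_length(2 * math.pi * 0.9) == pytest.approx(1.0)

    def test_angular_route_matches_q_route(self):
        p = ScherrerParams(K=0.9, wavelength=0.9763)
        assert scherrer_length(0.24, p, center_q=1.128) == pytest.approx(
            scherrer_length(0.24, p), rel=1e-12
        )

    def test_quadrature_instrumental_correction(self):
        p = ScherrerParams(instrumental_fwhm_q=0.1)
        expect = 2 * math.pi * 0.9 / math.sqrt(0.24**2 - 0.1**2)
        assert scherrer_length(0.24, p) == pytest.approx(expect)

    def test_observed_not_exceeding_instrumental_rejected(self):
        p = ScherrerParams(instrumental_fwhm_q=0.24)
        with pytest.raises(ValueError):
            scherrer_length(0.24, p)


class TestCompareStates:
    def test_identical_pairs_give_t0_p1(self):
        df = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        out = compare_states(df, df.copy())
        assert out.loc[0, "t"] == 0.0
        assert out.loc[0, "p"] == 1.0

    def test_constant_nonzero_difference_flagged_degenerate(self):
        a = pd.DataFrame({"m": [1.0, 2.0, 3.0]})
        b = a + 0.5
        out = compare_states(a, b)
        assert out.loc[0, "flag"] == "degenerate-test"

    def test_matches_textbook_paired_t_formula(self):
        rng = np.random.default_rng(0)
        a = pd.DataFrame({"m": rng.normal(5, 1, 8)})
        b = pd.DataFrame({"m": rng.normal(5.5, 1, 8)})
        out = compare_states(a, b)
        d = a["m"].to_numpy() - b["m"].to_numpy()
        t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        from scipy import stats

        p = 2 * stats.t.sf(abs(t), len(d) - 1)
        assert out.loc[0, "t"] == pytest.approx(t, abs=1e-10)
        assert out.loc[0, "p"] == pytest.approx(p, abs=1e-10)

    def test_single_replicate_no_test(self):
        a = pd.DataFrame({"m": [1.0]})
        out = compare_states(a, pd.DataFrame({"m": [2.0]}))
        assert out.loc[0, "flag"] == "no-test"
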