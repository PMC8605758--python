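"""Density curves, extrema, type classification, gamma fits, MAD."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sporemorph.distributions import (classify_types, decompose_bimodal,
                                      density_estimate, find_extrema,
                                      fit_gamma, hipass_threshold_norm,
                                      mad_between, summarize_sample,
                                      type_split)
from sporemorph.fixtures import (bimodal_size_model, default_size_model,
                                 gamma_from_mode_sd, sample_diameters)


def _draw(model, n, seed):
    return np.array([d for d, _ in sample_diameters(model, n, seed=seed)])


class TestDensityEstimate:
    def test_degenerate_sample_fails_with_message(self):
        with pytest.raises(ValueError, match="at least 2"):
            density_estimate([12.0])
        with pytest.raises(ValueError, match="zero spread"):
            density_estimate([12.0, 12.0])

    def test_unimodal_peak_location(self):
        vals = _draw(default_size_model(), 30_000, seed=1)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        assert ex.maxima[0][0] == pytest.approx(599 / 50, abs=0.05)

    def test_integrates_to_one(self):
        vals = _draw(default_size_model(), 5_000, seed=3)
        assert density_estimate(vals).integral() == pytest.approx(1.0, abs=1e-3)


class TestFindExtrema:
    def test_unimodal_single_maximum(self):
        vals = _draw(default_size_model(), 20_000, seed=4)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        assert len(ex.maxima) == 1
        assert ex.minima == []

    def test_bimodal_maxima_near_component_modes(self):
        model = bimodal_size_model(0.2)
        vals = _draw(model, 20_000, seed=5)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        assert len(ex.maxima) == 2
        assert ex.maxima[0][0] == pytest.approx(model[0].mode, abs=0.2)
        assert ex.maxima[1][0] == pytest.approx(model[1].mode, abs=0.2)
        assert len(ex.minima) == 1
        assert ex.maxima[0][0] < ex.minima[0][0] < ex.maxima[1][0]

    def test_threshold_above_curve_gives_no_signal(self):
        vals = _draw(default_size_model(), 1_000, seed=6)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold=10.0)
        assert ex.no_signal

    def test_limits_bracket_the_maxima(self):
        vals = _draw(default_size_model(), 10_000, seed=7)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        assert ex.left_limit < ex.maxima[0][0] < ex.right_limit


class TestClassifyTypes:
    def _records(self, vals):
        return pd.DataFrame({"diameter_um": vals, "Type": 0,
                             "Indiv": "sp1"})

    def test_unimodal_all_in_limits_type1(self):
        vals = _draw(default_size_model(), 10_000, seed=8)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        out = classify_types(self._records(vals), ex)
        in_limits = (vals >= ex.left_limit) & (vals <= ex.right_limit)
        assert (out.loc[in_limits, "Type"] == 1).all()
        assert (out["Type"] != 2).all()

    def test_bimodal_proportions_match_generator(self):
        model = bimodal_size_model(0.2)
        vals = _draw(model, 20_000, seed=9)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        out = classify_types(self._records(vals), ex)
        frac2 = (out["Type"] == 2).mean()
        assert frac2 == pytest.approx(0.2, abs=0.03)

    def test_boundary_value_is_type2(self):
        vals = _draw(bimodal_size_model(0.3), 20_000, seed=10)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        boundary = type_split(ex).boundary
        out = classify_types(self._records(np.array([boundary])), ex)
        assert out["Type"].iloc[0] == 2


class TestFitGamma:
    def test_parameter_recovery(self):
        vals = _draw(default_size_model(), 30_000, seed=11)
        fit = fit_gamma(vals)
        assert fit.shape == pytest.approx(600, rel=0.10)
        assert fit.peak_diameter == pytest.approx(599 / 50, abs=0.1)

    def test_skewness_closed_form(self):
        rng = np.random.default_rng(12)
        vals = rng.gamma(4.0, 1.0, size=5_000)
        fit = fit_gamma(vals)
        assert 2 / np.sqrt(fit.shape) == fit.skewness
        assert fit.skewness == pytest.approx(1.0, rel=0.1)

    def test_scale_equivariance(self):
        vals = _draw(default_size_model(), 10_000, seed=13)
        a, b = fit_gamma(vals), fit_gamma(vals * 3.0)
        assert b.shape == pytest.approx(a.shape, rel=0.01)
        assert b.rate == pytest.approx(a.rate / 3.0, rel=0.01)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="at least 30"):
            fit_gamma(np.ones(10))
        with pytest.raises(ValueError, match="positive"):
            fit_gamma(np.concatenate([np.ones(40), [-1.0]]))

    def test_peak_below_mean_for_right_skew(self):
        for sd in (0.3, 0.6, 0.9):
            comp = gamma_from_mode_sd(12.0, sd)
            vals = _draw([comp], 30_000, seed=int(sd * 100))
            fit = fit_gamma(vals)
            assert fit.peak_diameter < fit.mean

    def test_recovery_across_sd_range(self):
        # the observed spread of real samples: sd 0.3-0.9 µm
        rng = np.random.default_rng(14)
        for sd in (0.3, 0.5, 0.7, 0.9):
            comp = gamma_from_mode_sd(12.0, sd)
            vals = rng.gamma(comp.shape, 1 / comp.rate, size=30_000)
            fit = fit_gamma(vals)
            assert abs(fit.shape / comp.shape - 1) <= 0.10


class TestDecomposeBimodal:
    def test_published_peak_volumes_ratio(self):
        from sporemorph.morphometry import sphere_volume
        # two fitted peaks with spherical volumes 1,013 and 1,959 µm³
        d1 = (6 * 1013 / np.pi) ** (1 / 3)
        d2 = (6 * 1959 / np.pi) ** (1 / 3)
        assert sphere_volume(d2) / sphere_volume(d1) == pytest.approx(
            1.93, abs=0.005)

    def test_identical_components_ratio_one(self):
        vals = _draw(default_size_model(), 20_000, seed=15)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        with pytest.raises(ValueError, match="2 surviving maxima"):
            decompose_bimodal(vals, ex)

    def test_mixture_volume_ratio_matches_cube_of_modes(self):
        model = [gamma_from_mode_sd(12.0, 0.5, weight=0.8),
                 gamma_from_mode_sd(15.1, 0.5, weight=0.2,
                                    klass="spore_oversized")]
        vals = _draw(model, 20_000, seed=16)
        curve = density_estimate(vals)
        ex = find_extrema(curve, hipass_threshold_norm(curve.n))
        _, _, ratio = decompose_bimodal(vals, ex)
        assert ratio == pytest.approx((15.1 / 12.0) ** 3, rel=0.05)


class TestMad:
    def test_constant_sample(self):
        assert mad_between([2, 2, 2]) == 0.0

    def test_hand_computed(self):
        assert mad_between([1, 2, 3]) == pytest.approx(2 / 3)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(17)
        v = rng.normal(10, 2, size=1_000)
        brute = sum(abs(x - v.mean()) for x in v) / len(v)
        assert mad_between(v) == pytest.approx(brute, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad_between([])


class TestSummarizeSample:
    def _records(self, groups):
        frames = []
        for name, vals in groups.items():
            frames.append(pd.DataFrame({
                "Indiv": name, "diameter_um": vals, "Type": 1}))
        return pd.concat(frames, ignore_index=True)

    def test_single_sporocarp_mad_zero(self):
        recs = self._records({"a": _draw(default_size_model(), 500, seed=18)})
        assert summarize_sample(recs).mad_um == 0.0

    def test_common_distribution_mad_small(self):
        groups = {f"s{i}": _draw(default_size_model(), 30_000, seed=20 + i)
                  for i in range(5)}
        summary = summarize_sample(self._records(groups))
        assert summary.mad_um < 0.02

    def test_shifted_groups_mad_half_offset(self):
        base = _draw(default_size_model(), 30_000, seed=30)
        recs = self._records({"a": base, "b": base + 1.0})
        assert summarize_sample(recs).mad_um == pytest.approx(0.5, abs=0.01)

    def test_type2_excluded_from_mad(self):
        base = _draw(default_size_model(), 5_000, seed=31)
        recs = self._records({"a": base, "b": base})
        recs.loc[(recs["Indiv"] == "b") & (recs.index % 2 == 0), "Type"] = 2
        summary = summarize_sample(recs)
        assert summary.mad_um < 0.05
        assert set(summary.per_sporocarp["type"]) == {1, 2}

    def test_skewness_is_bias_corrected_empirical(self):
        vals = _draw(default_size_model(), 10_000, seed=32)
        summary = summarize_sample(self._records({"a": vals}))
        expected = float(stats.skew(vals, bias=False))
        got = summary.per_sporocarp.iloc[0]["skewness"]
        assert got == pytest.approx(expected, abs=1e-12)
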