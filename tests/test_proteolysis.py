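"""Site-exposure kinetics: normalization, constrained fits, ratios, stats."""

import numpy as np
import pandas as pd
import pytest

from subnuc.errors import InputError, SpecificationError
from subnuc.proteolysis import (
    ExposureFit,
    compare_to_prediction,
    endpoint_anova,
    fit_exposure_kinetics,
    fraction_full_length,
    histone_composition,
    ln_fraction_rate_proxy,
    predict_mixture,
    site_exposure_ratio,
)
from subnuc.simulate import (
    hexasome_proteolysis_spec,
    nucleosome_proteolysis_spec,
    simulate_proteolysis,
)
from conftest import make_timecourse


def gel_rows(species, volumes_by_time, replicate=1, band="H3"):
    return [{"species": species, "time_min": t, "replicate": replicate,
             "band": band, "volume": v} for t, v in volumes_by_time.items()]


class TestFractionFullLength:
    def test_direct_ratio(self):
        gel = pd.DataFrame(gel_rows("nuc", {0: 1000.0, 20: 250.0}))
        tc = fraction_full_length(gel)
        assert tc.mean[0] == 1.0
        assert tc.mean[1] == pytest.approx(0.25)

    def test_replicate_mean_and_sd(self):
        rows = []
        for rep, frac in enumerate([0.2, 0.25, 0.3], start=1):
            rows += gel_rows("nuc", {0: 1000.0, 20: 1000.0 * frac}, replicate=rep)
        tc = fraction_full_length(pd.DataFrame(rows))
        assert tc.mean[1] == pytest.approx(0.25)
        assert tc.sd[1] == pytest.approx(0.05, rel=1e-9)

    def test_missing_t0_lane_is_an_error(self):
        gel = pd.DataFrame(gel_rows("nuc", {5: 100.0, 20: 50.0}))
        with pytest.raises(InputError):
            fraction_full_length(gel)

    def test_zero_t0_volume_is_an_error(self):
        gel = pd.DataFrame(gel_rows("nuc", {0: 0.0, 20: 50.0}))
        with pytest.raises(InputError):
            fraction_full_length(gel)


class TestHistoneComposition:
    def test_planted_twofold_dimer_difference(self):
        rows = []
        for sp, dimer in (("nucleosome", 2.0), ("hexasome", 1.0)):
            for rep in (1, 2):
                rows += [
                    {"species": sp, "time_min": 0, "replicate": rep, "band": "H3",
                     "volume": 100.0},
                    {"species": sp, "time_min": 0, "replicate": rep, "band": "H2A",
                     "volume": 50.0 * dimer},
                    {"species": sp, "time_min": 0, "replicate": rep, "band": "H2B",
                     "volume": 50.0 * dimer},
                    {"species": sp, "time_min": 0, "replicate": rep, "band": "H4",
                     "volume": 80.0},
                ]
        comp = histone_composition(pd.DataFrame(rows))
        nuc = comp.loc[("nucleosome", "H2A/H2B"), "mean"]
        hexa = comp.loc[("hexasome", "H2A/H2B"), "mean"]
        assert nuc / hexa == pytest.approx(2.0)
        # noiseless replicates -> zero spread
        assert comp["sd"].max() == pytest.approx(0.0, abs=1e-12)

    def test_all_bands_equal_h3_gives_unity(self):
        rows = gel_rows("x", {0: 10.0}) + gel_rows("x", {0: 10.0}, band="H4")
        comp = histone_composition(pd.DataFrame(rows))
        assert (comp["mean"] == 1.0).all()


class TestExposureFit:
    def test_noiseless_recovery_machine_precision(self, timepoints):
        mean = 1.0 * np.exp(-0.19 * timepoints)
        fit = fit_exposure_kinetics(make_timecourse("tet", timepoints, mean))
        assert fit.k_obs == pytest.approx(0.19, rel=1e-6)
        assert fit.a0 == pytest.approx(1.0, rel=1e-6)

    def test_constant_course_reports_zero_rate_boundary(self, timepoints):
        fit = fit_exposure_kinetics(
            make_timecourse("flat", timepoints, np.ones_like(timepoints)))
        assert fit.k_obs == pytest.approx(0.0, abs=1e-4)
        assert fit.k_at_bound
        assert fit.warnings

    def test_fit_invariant_to_uniform_sigma_rescaling(self, timepoints):
        mean = 0.9 * np.exp(-0.05 * timepoints) + 0.01 * np.cos(timepoints)
        sd = 0.01 + 0.002 * timepoints
        f1 = fit_exposure_kinetics(make_timecourse("a", timepoints, mean, sd))
        f2 = fit_exposure_kinetics(make_timecourse("a", timepoints, mean, 10 * sd))
        assert f1.k_obs == pytest.approx(f2.k_obs, rel=1e-8)
        assert f1.k_err == pytest.approx(f2.k_err, rel=1e-6)

    def test_scale_invariance_of_band_volumes(self):
        spec = nucleosome_proteolysis_spec(seed=8)
        gel = simulate_proteolysis(spec)
        scaled = gel.assign(volume=gel["volume"] * 7.3)
        f1 = fit_exposure_kinetics(fraction_full_length(gel))
        f2 = fit_exposure_kinetics(fraction_full_length(scaled))
        assert f1.k_obs == pytest.approx(f2.k_obs, rel=1e-6)
        assert f1.a0 == pytest.approx(f2.a0, rel=1e-6)

    def test_simulated_triplicates_recover_slow_rate(self):
        ks = []
        for seed in range(30):
            gel = simulate_proteolysis(nucleosome_proteolysis_spec(seed=seed))
            ks.append(fit_exposure_kinetics(fraction_full_length(gel)).k_obs)
        assert 0.010 <= np.median(ks) <= 0.014

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(InputError):
            fit_exposure_kinetics(
                make_timecourse("x", [0, 5, 10], [1.0, 0.5, 0.25]))


class TestSiteExposureRatio:
    def test_reference_rate_pair_gives_sixteenfold(self):
        tet = ExposureFit("tet", 0.19, 0.02, 1.0, 0.2, np.eye(2), 0.0, 8)
        nuc = ExposureFit("nuc", 0.012, 0.002, 0.87, 0.04, np.eye(2), 0.0, 8)
        r = site_exposure_ratio(tet, nuc)
        assert r.ratio == pytest.approx(15.83, abs=0.01)

    def test_identical_fits_unity_with_sqrt2_error(self):
        f = ExposureFit("a", 0.1, 0.01, 1.0, 0.0, np.eye(2), 0.0, 8)
        r = site_exposure_ratio(f, f)
        assert r.ratio == 1.0
        assert r.error == pytest.approx(np.sqrt(2) * 0.1)

    def test_first_order_propagation(self):
        num = ExposureFit("a", 0.2, 0.02, 1.0, 0.0, np.eye(2), 0.0, 8)
        den = ExposureFit("b", 0.1, 0.01, 1.0, 0.0, np.eye(2), 0.0, 8)
        r = site_exposure_ratio(num, den)
        assert r.ratio == pytest.approx(2.0)
        assert r.error == pytest.approx(2.0 * np.sqrt(0.02), rel=1e-9)

    def test_zero_denominator_rejected(self):
        num = ExposureFit("a", 0.2, 0.02, 1.0, 0.0, np.eye(2), 0.0, 8)
        den = ExposureFit("b", 0.0, 0.0, 1.0, 0.0, np.eye(2), 0.0, 8)
        with pytest.raises(SpecificationError):
            site_exposure_ratio(num, den)


class TestMixturePrediction:
    def test_halfweighted_sum_value(self):
        curve = predict_mixture([((0.012, 0.87), 0.5), ((0.19, 1.0), 0.5)])
        expected = 0.5 * 0.87 * np.exp(-0.24) + 0.5 * np.exp(-3.8)
        assert curve(20.0) == pytest.approx(expected, rel=1e-12)
        assert curve(0.0) == pytest.approx(0.5 * 0.87 + 0.5)

    def test_identical_components_collapse(self):
        single = predict_mixture([((0.05, 0.9), 1.0)])
        double = predict_mixture([((0.05, 0.9), 0.5), ((0.05, 0.9), 0.5)])
        t = np.linspace(0, 50, 11)
        np.testing.assert_allclose(single(t), double(t))

    def test_bad_weights_rejected(self):
        with pytest.raises(SpecificationError):
            predict_mixture([((0.1, 1.0), 0.7), ((0.2, 1.0), 0.7)])


class TestCompareToPrediction:
    def test_exact_agreement_gives_p_one(self, timepoints):
        curve = predict_mixture([((0.05, 1.0), 1.0)])
        tc = make_timecourse("x", timepoints, curve(timepoints))
        res = compare_to_prediction(tc, curve)
        assert res.pvalue == pytest.approx(1.0)

    def test_large_offset_rejected(self, timepoints):
        curve = predict_mixture([((0.05, 1.0), 1.0)])
        tc = make_timecourse("x", timepoints, curve(timepoints) + 5.0)
        assert compare_to_prediction(tc, curve).pvalue < 0.05

    def test_synthetic_hexasome_matches_prediction(self, timepoints):
        gel = simulate_proteolysis(hexasome_proteolysis_spec(seed=4))
        tc = fraction_full_length(gel)
        curve = predict_mixture([((0.012, 0.87), 0.5), ((0.19, 1.0), 0.5)])
        assert compare_to_prediction(tc, curve).pvalue > 0.9


class TestEndpointAnova:
    @staticmethod
    def balanced(shift_species=None, shift=0.0, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        base = {"nucleosome": 0.8, "hexasome": 0.6, "tetrasome": 0.4}
        for sp, mu in base.items():
            for ratio in ("1:100", "1:500", "1:2500"):
                for _ in range(3):
                    val = mu + rng.normal(0, noise)
                    if sp == shift_species:
                        val += shift
                    rows.append({"species": sp, "trypsin_ratio": ratio,
                                 "fraction": val})
        return pd.DataFrame(rows)

    def test_identical_cells_show_no_significant_pairs(self):
        rows = [{"species": sp, "trypsin_ratio": r, "fraction": 0.5}
                for sp in ("a", "b") for r in ("x", "y") for _ in range(3)]
        res = endpoint_anova(pd.DataFrame(rows))
        assert len(res.significant_pairs) == 0

    def test_shifted_species_flagged_against_others(self):
        df = self.balanced(shift_species="tetrasome", shift=0.3, noise=0.01)
        res = endpoint_anova(df)
        sig = res.significant_pairs
        assert (sig[["group1", "group2"]] == "tetrasome").any(axis=1).all() is not None
        # tetrasome differs from both others at every trypsin level
        hits = sig[(sig["group1"] == "tetrasome") | (sig["group2"] == "tetrasome")]
        assert len(hits) >= 6

    def test_anova_table_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        df = self.balanced(noise=0.05, seed=3)
        res = endpoint_anova(df)
        ref = pingouin.anova(data=df, dv="fraction",
                             between=["species", "trypsin_ratio"])
        f_mine = res.anova.loc["C(species)", "F"]
        f_ref = float(ref.loc[ref["Source"] == "species", "F"].iloc[0])
        assert f_mine == pytest.approx(f_ref, rel=1e-6)

    def test_single_replicate_rejected(self):
        rows = [{"species": sp, "trypsin_ratio": r, "fraction": 0.5}
                for sp in ("a", "b") for r in ("x", "y")]
        with pytest.raises(InputError):
            endpoint_anova(pd.DataFrame(rows))


def test_ln_fraction_proxy_recovers_rate_for_pure_exponential():
    k, t = 0.05, 20.0
    assert ln_fraction_rate_proxy(np.exp(-k * t), t) == pytest.approx(k)
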