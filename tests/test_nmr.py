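"""Chemical-shift differences, peak classification, relaxation fitting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from subnuc.errors import InputError
from subnuc.nmr import (
    PeakList,
    T1_DELAYS_MS,
    T2_DELAYS_MS,
    chemical_shift_difference,
    classify_hexasome_peaks,
    csd,
    fit_relaxation_time,
    het_noe,
    intensity_asymmetry,
    t1_t2_ratio,
)
from subnuc.simulate import PeakSimSpec, simulate_peak_lists, simulate_relaxation


def peaks(species, table):
    return PeakList(species, pd.DataFrame(table))


class TestCSD:
    @pytest.mark.parametrize("dh, dn, expected", [
        (0.03, 0.0, 0.03),
        (0.0, 0.5, 0.077),
        (0.06, 0.3, np.sqrt(0.06 ** 2 + (0.154 * 0.3) ** 2)),
    ])
    def test_combined_difference_values(self, dh, dn, expected):
        assert csd(dh, dn) == pytest.approx(expected, rel=1e-9)

    def test_profile_and_unmatched_reporting(self):
        a = peaks("a", {"residue": [1, 2, 3], "dH_ppm": [8.0, 8.1, 8.2],
                        "dN_ppm": [110.0, 111.0, 112.0], "height": [1, 1, 1]})
        b = peaks("b", {"residue": [2, 3, 4], "dH_ppm": [8.1, 8.26, 8.0],
                        "dN_ppm": [111.0, 112.0, 120.0], "height": [1, 1, 1]})
        prof = chemical_shift_difference(a, b)
        assert prof.unmatched_a == [1]
        assert prof.unmatched_b == [4]
        row3 = prof.data.set_index("residue").loc[3]
        assert row3["csd"] == pytest.approx(0.06, abs=1e-9)

    def test_no_matches_rejected(self):
        a = peaks("a", {"residue": [1], "dH_ppm": [8.0], "dN_ppm": [110.0],
                        "height": [1]})
        b = peaks("b", {"residue": [2], "dH_ppm": [8.0], "dN_ppm": [110.0],
                        "height": [1]})
        with pytest.raises(InputError):
            chemical_shift_difference(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.tuples(st.floats(-1, 1), st.floats(-5, 5),
                  st.floats(-1, 1), st.floats(-5, 5),
                  st.floats(-1, 1), st.floats(-5, 5)),
        min_size=1, max_size=8))
    def test_symmetry_and_triangle_bound(self, rows):
        res = list(range(len(rows)))
        def plist(name, cols):
            return peaks(name, {
                "residue": res,
                "dH_ppm": [8.0 + r[cols] for r in rows],
                "dN_ppm": [115.0 + r[cols + 1] for r in rows],
                "height": [1.0] * len(rows)})
        a, b, c = plist("a", 0), plist("b", 2), plist("c", 4)
        ab = chemical_shift_difference(a, b).data["csd"].to_numpy()
        ba = chemical_shift_difference(b, a).data["csd"].to_numpy()
        np.testing.assert_allclose(ab, ba)
        ac = chemical_shift_difference(a, c).data["csd"].to_numpy()
        bc = chemical_shift_difference(b, c).data["csd"].to_numpy()
        assert (ac <= ab + bc + 1e-12).all()


class TestClassification:
    def test_coincident_peak_labeled_hex_n(self):
        nuc = peaks("nuc", {"residue": [1], "dH_ppm": [8.0], "dN_ppm": [110.0],
                            "height": [1]})
        tet = peaks("tet", {"residue": [1], "dH_ppm": [8.3], "dN_ppm": [112.0],
                            "height": [1]})
        hexa = peaks("hex", {"residue": [1], "dH_ppm": [8.0], "dN_ppm": [110.0],
                             "height": [1]})
        labeled = classify_hexasome_peaks(hexa, nuc, tet)
        assert labeled.data["subset"].iloc[0] == "hex-N"
        assert not labeled.data["ambiguous"].iloc[0]

    def test_equidistant_peak_flagged_and_sent_to_hex_n(self):
        nuc = peaks("nuc", {"residue": [1], "dH_ppm": [8.0], "dN_ppm": [110.0],
                            "height": [1]})
        tet = peaks("tet", {"residue": [1], "dH_ppm": [8.2], "dN_ppm": [110.0],
                            "height": [1]})
        hexa = peaks("hex", {"residue": [1], "dH_ppm": [8.1], "dN_ppm": [110.0],
                             "height": [1]})
        labeled = classify_hexasome_peaks(hexa, nuc, tet)
        assert labeled.data["subset"].iloc[0] == "hex-N"
        assert labeled.data["ambiguous"].iloc[0]

    def test_full_recovery_on_separated_synthetic_hexasome(self):
        spec = PeakSimSpec(seed=6, min_separation_ppm=0.02, shift_noise_ppm=0.002)
        lists = simulate_peak_lists(spec)
        unlabeled = PeakList("hexasome",
                             lists["hexasome"].data.drop(columns=["subset"]))
        labeled = classify_hexasome_peaks(unlabeled, lists["nucleosome"],
                                          lists["tetrasome"])
        truth = lists["hexasome"].data
        merged = labeled.data.merge(truth, on=["residue", "dH_ppm"],
                                    suffixes=("", "_truth"))
        assert len(merged) == len(truth)
        assert (merged["subset"] == merged["subset_truth"]).all()

    def test_consistency_of_mean_csd_contrasts(self):
        lists = simulate_peak_lists(PeakSimSpec(seed=10, shift_noise_ppm=0.002))
        hex_n = PeakList("hex-N", lists["hexasome"].subset("hex-N")
                         .drop(columns=["subset"]).reset_index(drop=True))
        hex_t = PeakList("hex-T", lists["hexasome"].subset("hex-T")
                         .drop(columns=["subset"]).reset_index(drop=True))
        nuc, tet = lists["nucleosome"], lists["tetrasome"]
        assert (chemical_shift_difference(hex_n, nuc).mean_csd
                < chemical_shift_difference(hex_n, tet).mean_csd)
        assert (chemical_shift_difference(hex_t, tet).mean_csd
                < chemical_shift_difference(hex_t, nuc).mean_csd)

    def test_three_peaks_per_residue_rejected(self):
        nuc = peaks("nuc", {"residue": [1], "dH_ppm": [8.0], "dN_ppm": [110.0],
                            "height": [1]})
        with pytest.raises(InputError):
            peaks("hex", {"residue": [1, 1, 1], "dH_ppm": [8.0, 8.1, 8.2],
                          "dN_ppm": [110.0] * 3, "height": [1] * 3})


class TestIntensityAsymmetry:
    @staticmethod
    def labeled(heights_n, heights_t, overlap=None):
        res = list(range(1, len(heights_n) + 1))
        data = pd.DataFrame({
            "residue": res + res,
            "dH_ppm": [8.0] * (2 * len(res)),
            "dN_ppm": [110.0] * (2 * len(res)),
            "height": list(heights_n) + list(heights_t),
            "subset": ["hex-N"] * len(res) + ["hex-T"] * len(res),
        })
        if overlap is not None:
            data["overlap"] = overlap + overlap
        return PeakList("hex", data)

    def test_equal_heights_give_unity(self):
        res = intensity_asymmetry(self.labeled([2.0, 3.0], [2.0, 3.0]), [1, 2])
        assert res.mean == 1.0

    def test_per_residue_ratios_and_window_mean(self):
        res = intensity_asymmetry(self.labeled([1.0, 2.0], [2.0, 6.0]), [1, 2])
        assert sorted(res.per_residue["ratio"]) == [2.0, 3.0]
        assert res.mean == pytest.approx(2.5)

    def test_planted_uniform_fold_recovered_exactly(self):
        res = intensity_asymmetry(self.labeled([1.0] * 5, [2.4] * 5), range(1, 6))
        assert res.mean == pytest.approx(2.4)
        assert res.sd == pytest.approx(0.0)

    def test_overlap_flagged_residues_excluded(self):
        res = intensity_asymmetry(
            self.labeled([1.0, 1.0], [2.0, 9.0], overlap=[False, True]), [1, 2])
        assert res.mean == pytest.approx(2.0)
        assert res.skipped == [2]

    def test_empty_window_after_exclusions_rejected(self):
        with pytest.raises(InputError):
            intensity_asymmetry(
                self.labeled([1.0], [2.0], overlap=[True]), [1])


class TestRelaxationFits:
    def test_noiseless_t1_schedule_recovers_time_constant(self):
        series = simulate_relaxation({1: 100.0}, T1_DELAYS_MS, 0.0, seed=0)
        fit = fit_relaxation_time(series, "T1")
        assert fit["T_ms"].iloc[0] == pytest.approx(100.0, rel=1e-9)
        assert fit["R_s"].iloc[0] == pytest.approx(10.0, rel=1e-9)

    def test_noiseless_cpmg_schedule_recovers_time_constant(self):
        series = simulate_relaxation({1: 67.84}, T2_DELAYS_MS, 0.0, seed=0)
        fit = fit_relaxation_time(series, "T2")
        assert fit["T_ms"].iloc[0] == pytest.approx(67.84, rel=1e-9)

    def test_noisy_recovery_median_within_three_percent(self):
        fitted = []
        for seed in range(100):
            series = simulate_relaxation({1: 100.0}, T1_DELAYS_MS,
                                         noise_sd=2.0, seed=seed)
            fitted.append(fit_relaxation_time(series)["T_ms"].iloc[0])
        assert np.median(fitted) == pytest.approx(100.0, rel=0.03)

    def test_too_few_delays_rejected(self):
        series = simulate_relaxation({1: 50.0}, [0.0, 10.0], 0.0, seed=0)
        with pytest.raises(InputError):
            fit_relaxation_time(series)


class TestHetNoe:
    @staticmethod
    def pair(h_sat, h_ref):
        sat = peaks("sat", {"residue": [1], "dH_ppm": [8.0], "dN_ppm": [110.0],
                            "height": [h_sat]})
        ref = peaks("ref", {"residue": [1], "dH_ppm": [8.0], "dN_ppm": [110.0],
                            "height": [h_ref]})
        return sat, ref

    def test_equal_heights_give_unity(self):
        res = het_noe(*self.pair(5.0, 5.0))
        assert res["noe"].iloc[0] == pytest.approx(1.0)

    def test_value_and_propagated_error(self):
        res = het_noe(*self.pair(40.0, 100.0), sigma_sat=2.0, sigma_ref=2.0)
        assert res["noe"].iloc[0] == pytest.approx(0.4)
        assert res["noe_err"].iloc[0] == pytest.approx(
            0.4 * np.sqrt(0.0025 + 0.0004), rel=1e-9)

    def test_zero_reference_flagged(self):
        res = het_noe(*self.pair(40.0, 0.0))
        assert res["undefined"].iloc[0]
        assert np.isnan(res["noe"].iloc[0])


class TestT1T2Ratio:
    @staticmethod
    def fit_frame(residues, t, t_err):
        return pd.DataFrame({"residue": residues, "T_ms": t, "T_err_ms": t_err,
                             "at_bound": False})

    def test_equal_times_give_unity(self):
        r = t1_t2_ratio(self.fit_frame([1], [100.0], [0.0]),
                        self.fit_frame([1], [100.0], [0.0]))
        assert r["t1_t2"].iloc[0] == pytest.approx(1.0)

    def test_propagated_error(self):
        r = t1_t2_ratio(self.fit_frame([1], [1000.0], [50.0]),
                        self.fit_frame([1], [100.0], [5.0]))
        assert r["t1_t2"].iloc[0] == pytest.approx(10.0)
        assert r["t1_t2_err"].iloc[0] == pytest.approx(
            10.0 * np.sqrt(0.05 ** 2 + 0.05 ** 2), rel=1e-9)

    def test_unmatched_residues_skipped_and_reported(self):
        r = t1_t2_ratio(self.fit_frame([1, 2], [100.0, 200.0], [1.0, 1.0]),
                        self.fit_frame([2, 3], [100.0, 100.0], [1.0, 1.0]))
        assert list(r["residue"]) == [2]
        assert r.attrs["skipped"] == [1, 3]
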