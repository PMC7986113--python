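"""Assay reductions: dissolved pools, biomass, enzyme plates, PLFA."""

import numpy as np
import pandas as pd
import pytest

from soilncycle.assays import (BACTERIAL_MARKERS, FUNGAL_MARKERS, AssayError,
                               BiomassExtract, EnzymePlate,
                               derive_dissolved_pools, hydrolytic_activity,
                               microbial_biomass, peroxidase_activity,
                               plfa_concentration, plfa_group_sums)


class TestDissolvedPools:
    def test_don_by_difference(self):
        p = derive_dissolved_pools(nh4=10, no3=5, tdn=100, doc=200)
        assert p.don == 85
        assert p.cn_ratio == pytest.approx(2.0)
        assert p.don + p.nh4 + p.no3 == p.tdn  # identity holds bit-exactly

    def test_zero_don_and_cn(self):
        p = derive_dissolved_pools(nh4=10, no3=5, tdn=15, doc=150)
        assert p.don == 0
        assert p.cn_ratio == pytest.approx(10.0)

    def test_negative_don_flagged_not_clamped(self):
        p = derive_dissolved_pools(nh4=10, no3=10, tdn=15, doc=10)
        assert p.don == -5
        assert "negative_don" in p.qc_flags

    def test_cn_undefined_at_zero_tdn(self):
        p = derive_dissolved_pools(nh4=0, no3=0, tdn=0, doc=10)
        assert p.cn_ratio is None
        assert "cn_undefined" in p.qc_flags


class TestMicrobialBiomass:
    def test_no_flush_means_zero_biomass(self):
        bc, bn, cn, flags = microbial_biomass(
            BiomassExtract(5.5, 5.5, 1.2, 1.2))
        assert bc == 0 and bn == 0

    def test_extraction_coefficients(self):
        bc, bn, cn, _ = microbial_biomass(BiomassExtract(10.0, 5.5, 2.0, 1.2))
        assert bc == pytest.approx(10.0)   # (10-5.5)/0.45
        assert bn == pytest.approx(2.0)    # (2-1.2)/0.4
        assert cn == pytest.approx(5.0)

    def test_inverted_pair_flagged(self):
        bc, _, _, flags = microbial_biomass(BiomassExtract(5.0, 6.0, 2.0, 1.0))
        assert bc < 0 and "negative_biomass_c" in flags

    def test_coefficient_bounds(self):
        with pytest.raises(ValueError):
            BiomassExtract(1, 0, 1, 0, kec=0.0)


def make_plate(sample=600.0, gain=200.0, blank=100.0, inc=4.0, soil=0.002):
    nmol = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
    return EnzymePlate(sample_rfu=[sample] * 3, standard_nmol=nmol,
                       standard_rfu=[blank + gain * n for n in nmol],
                       blank_rfu=[blank] * 4, incubation_h=inc,
                       soil_g_per_well=soil)


class TestHydrolyticActivity:
    def test_sample_equal_blank_is_zero(self):
        a, flags = hydrolytic_activity(make_plate(sample=100.0))
        assert a == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # slope 200 RFU/nmol; (600-100)/200 = 2.5 nmol; /4 h /0.002 g
        a, _ = hydrolytic_activity(make_plate())
        assert a == pytest.approx(312.5)

    def test_generator_inversion_noiseless(self):
        true_activity = 50.0
        inc, soil, gain, blank = 4.0, 0.0008, 200.0, 100.0
        rfu = blank + gain * true_activity * inc * soil
        a, _ = hydrolytic_activity(make_plate(sample=rfu, gain=gain,
                                              blank=blank, inc=inc, soil=soil))
        assert a == pytest.approx(true_activity, rel=1e-12)

    def test_detector_gain_invariance(self):
        # an affine detector gain applied to samples and standards alike
        # cancels in the slope-normalized activity
        p1 = make_plate()
        p2 = EnzymePlate(sample_rfu=[3 * v + 10 for v in p1.sample_rfu],
                         standard_nmol=p1.standard_nmol,
                         standard_rfu=[3 * v + 10 for v in p1.standard_rfu],
                         blank_rfu=[3 * v + 10 for v in p1.blank_rfu],
                         incubation_h=p1.incubation_h,
                         soil_g_per_well=p1.soil_g_per_well)
        a1, _ = hydrolytic_activity(p1)
        a2, _ = hydrolytic_activity(p2)
        assert a2 == pytest.approx(a1, rel=1e-12)

    def test_nonpositive_slope_is_assay_failure(self):
        p = make_plate()
        bad = EnzymePlate(sample_rfu=p.sample_rfu, standard_nmol=p.standard_nmol,
                          standard_rfu=p.standard_rfu[::-1],
                          blank_rfu=p.blank_rfu, incubation_h=4.0,
                          soil_g_per_well=0.002)
        with pytest.raises(AssayError):
            hydrolytic_activity(bad)

    def test_out_of_range_sample_flagged(self):
        a, flags = hydrolytic_activity(make_plate(sample=2000.0))
        assert "extrapolation" in flags

    def test_replicate_minimum_enforced(self):
        with pytest.raises(AssayError):
            EnzymePlate(sample_rfu=[1.0, 2.0], standard_nmol=[0, 1, 2, 3, 4, 5],
                        standard_rfu=[0, 1, 2, 3, 4, 5], blank_rfu=[0.0],
                        incubation_h=1.0, soil_g_per_well=0.001)


class TestPeroxidase:
    def test_no_peroxide_response_is_zero(self):
        a, _ = peroxidase_activity(0.5, 0.5)
        assert a == 0.0

    def test_extinction_division(self):
        a, _ = peroxidase_activity(0.79, 0.0, extinction=7.9)
        assert a == pytest.approx(0.1)

    def test_generator_inversion(self):
        true = 0.8  # umol g-1 h-1
        ext, inc, mass, vol = 7.9, 4.0, 0.004, 2.0
        delta = true * ext * inc * mass / vol
        a, _ = peroxidase_activity(0.2 + delta, 0.2, extinction=ext,
                                   incubation_h=inc, soil_mass_g=mass,
                                   assay_volume_ml=vol)
        assert a == pytest.approx(true, rel=1e-12)

    def test_negative_flagged(self):
        a, flags = peroxidase_activity(0.1, 0.5)
        assert a < 0 and "negative_activity" in flags


class TestPlfa:
    def test_zero_peak(self):
        assert plfa_concentration(0.0, 1e6, 10.0, 0.5) == 0.0

    def test_is_ratio_arithmetic(self):
        assert plfa_concentration(1e6, 1e6, 10.0, 0.5) == pytest.approx(20.0)

    def test_group_sums_and_ratio(self):
        areas = {m: 100.0 for m in BACTERIAL_MARKERS}
        areas[FUNGAL_MARKERS[0]] = 500.0
        areas["19:0"] = 1000.0
        df = pd.DataFrame([areas], index=["p1"])
        out = plfa_group_sums(df, is_amount_nmol=10.0, soil_mass_g_om=0.5)
        assert out.loc["p1", "bacterial_plfa"] == pytest.approx(
            10 * 100 / 1000 * 10 / 0.5)
        assert out.loc["p1", "fungal_plfa"] == pytest.approx(500 / 1000 * 10 / 0.5)
        assert out.loc["p1", "fungal_bacterial_ratio"] == pytest.approx(0.5)

    def test_missing_marker_is_configuration_error(self):
        df = pd.DataFrame([{m: 1.0 for m in BACTERIAL_MARKERS[:5]}])
        with pytest.raises(KeyError):
            plfa_group_sums(df, 10.0, 0.5)


class TestRoundTrips:
    """Noiseless synthetic plates invert exactly through every reduction."""

    def test_full_experiment_round_trip(self, noiseless_experiment):
        exp = noiseless_experiment
        truth = exp.truth.activities.set_index("plot_id")
        # dissolved pools
        for _, r in exp.pools_raw.iterrows():
            p = derive_dissolved_pools(r["nh4"], r["no3"], r["tdn"], r["doc"])
            assert p.don == pytest.approx(truth.loc[r["plot_id"], "don"], rel=1e-9)
        # biomass
        for _, r in exp.biomass_raw.iterrows():
            bc, bn, _, _ = microbial_biomass(BiomassExtract(
                r["c_fumigated"], r["c_unfumigated"],
                r["n_fumigated"], r["n_unfumigated"]))
            assert bc == pytest.approx(truth.loc[r["plot_id"], "biomass_c"], rel=1e-9)
            assert bn == pytest.approx(truth.loc[r["plot_id"], "biomass_n"], rel=1e-9)
        # PLFA group sums
        out = plfa_group_sums(exp.plfa_areas, is_amount_nmol=25.0,
                              soil_mass_g_om=0.5)
        for pid in out.index:
            assert out.loc[pid, "bacterial_plfa"] == pytest.approx(
                truth.loc[pid, "bacterial_plfa"], rel=1e-9)
            ratio = truth.loc[pid, "fungal_plfa"] / truth.loc[pid, "bacterial_plfa"]
            assert out.loc[pid, "fungal_bacterial_ratio"] == pytest.approx(
                ratio, rel=1e-9)

    def test_enzyme_plates_round_trip(self, noiseless_experiment):
        exp = noiseless_experiment
        truth = exp.truth.activities.set_index("plot_id")
        plates = exp.plates
        for (pid, enzyme), sub in plates.groupby(["plot_id", "enzyme"]):
            if enzyme == "peroxidase":
                with_p = sub.loc[sub["role"] == "with_h2o2", "value"].iloc[0]
                without = sub.loc[sub["role"] == "without_h2o2", "value"].iloc[0]
                a, _ = peroxidase_activity(
                    with_p, without,
                    incubation_h=sub["incubation_h"].iloc[0],
                    soil_mass_g=sub["soil_g_per_well"].iloc[0],
                    assay_volume_ml=2.0)
            else:
                std = sub[sub["role"] == "standard"]
                plate = EnzymePlate(
                    sample_rfu=sub.loc[sub["role"] == "sample", "value"].tolist(),
                    standard_nmol=std["conc_nmol"].tolist(),
                    standard_rfu=std["value"].tolist(),
                    blank_rfu=sub.loc[sub["role"] == "blank", "value"].tolist(),
                    incubation_h=sub["incubation_h"].iloc[0],
                    soil_g_per_well=sub["soil_g_per_well"].iloc[0])
                a, _ = hydrolytic_activity(plate)
            assert a == pytest.approx(truth.loc[pid, enzyme], rel=1e-9)
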