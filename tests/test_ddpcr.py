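"""Poisson quantification, VAF routes, FPR, positivity, volumes, LOD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmrd.ddpcr import (SaturationError, VafRoute, VolumeSpec, WellCounts,
                         call_positivity, compute_vaf, copies_per_ml,
                         estimate_fpr, quantify_sample, quantify_species,
                         read_wells_csv, theoretical_lod, vaf_confint,
                         write_wells_csv)
from ctmrd.simulate import demo_panel, relapse_scenario, simulate_patient_course

from conftest import make_well


def _quant(species="T", k=100, n=20000, singles=None, ci=None, lam=None):
    """Hand-built Quantification for positivity truth-table tests."""
    from ctmrd.ddpcr import Quantification
    lam = lam if lam is not None else -math.log1p(-k / n)
    conc = lam / 8.5e-4 * 20
    return Quantification(
        species=species, k_positive=k, n_droplets=n, lambda_=lam,
        conc_per_ul=conc / 20, conc_per_20ul=conc,
        ci95=ci or (conc * 0.8, conc * 1.2),
        n_single_positive=k if singles is None else singles)


class TestQuantifySpecies:
    def test_no_positives_gives_zero_with_zero_lower_bound(self):
        q = quantify_species([make_well(0, 20000)], "T")
        assert q.lambda_ == 0 and q.conc_per_20ul == 0
        assert q.ci95[0] == 0

    def test_worked_example_against_formula_and_monte_carlo(self, rng):
        # k=1000 of N=20000: lambda = -ln(0.95), conc scaling via the
        # 0.85 nL droplet volume.
        q = quantify_species([make_well(1000, 20000)], "T")
        assert q.lambda_ == pytest.approx(-math.log(0.95), rel=1e-12)
        assert q.conc_per_ul == pytest.approx(60.345, abs=0.001)
        assert q.conc_per_20ul == pytest.approx(1206.9, abs=0.1)
        # Independent Monte-Carlo partition oracle: droplets loaded
        # Poisson(lambda), fraction positive matches k/N.
        lam = q.lambda_
        draws = rng.poisson(lam, size=(200, 20000))
        frac = (draws > 0).mean(axis=1)
        assert abs(frac.mean() - 1000 / 20000) < 4 * frac.std() / math.sqrt(200)

    def test_merging_equals_pooling(self):
        merged = quantify_species(
            [make_well(500, 10000, "a"), make_well(500, 10000, "b")], "T")
        pooled = quantify_species([make_well(1000, 20000)], "T")
        assert merged.lambda_ == pooled.lambda_
        assert merged.ci95 == pooled.ci95
        assert merged.k_positive == pooled.k_positive == 1000

    def test_saturation_raises_with_dilution_advice(self):
        with pytest.raises(SaturationError, match="dilute"):
            quantify_species([make_well(100, 100)], "T")

    def test_no_droplets_is_error(self):
        w = WellCounts("w", 0, {})
        with pytest.raises(ValueError):
            quantify_species([w], "T")

    def test_double_positives_count_for_both_species(self):
        w = make_well(10, 20000, species="T", partner="W", k_partner=50,
                      k_double=5)
        qt = quantify_species([w], "T")
        qw = quantify_species([w], "W")
        assert qt.k_positive == 15 and qw.k_positive == 55
        assert qt.n_single_positive == 10

    def test_clopper_pearson_available_and_wider(self):
        wells = [make_well(50, 20000)]
        wilson = quantify_species(wells, "T")
        exact = quantify_species(wells, "T", ci_method="beta")
        assert exact.ci95[0] <= wilson.ci95[0]
        assert exact.ci95[1] >= wilson.ci95[1]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(k=st.integers(1, 200), n=st.sampled_from([20000, 40000]))
    def test_small_lambda_linearity(self, k, n):
        # For k/N <= 0.01 the Poisson correction is below 0.6% relative.
        q = quantify_species([make_well(k, n)], "T")
        p = k / n
        assert abs(q.lambda_ - p) / q.lambda_ < 0.006

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(k=st.integers(0, 19999))
    def test_ci_brackets_point_estimate(self, k):
        q = quantify_species([make_well(k, 20000)], "T")
        assert q.ci95[0] <= q.conc_per_20ul <= q.ci95[1]


class TestVafRoutes:
    def test_wildtype_route_worked_example(self):
        vaf = compute_vaf(_fixed_conc("T", 12.0),
                          wt_q=_fixed_conc("W", 2388.0),
                          route="wildtype")
        assert vaf.value == pytest.approx(12 / 2400, rel=1e-12)  # 0.5%

    def test_partner_route_worked_example(self):
        vaf = compute_vaf(_fixed_conc("SV", 10.0),
                          partner_q=_fixed_conc("P", 50.0),
                          partner_wt_q=_fixed_conc("PW", 4950.0),
                          route="partner")
        assert vaf.value == pytest.approx(10 / 5000, rel=1e-12)  # 0.2%

    def test_cnr_route(self):
        vaf = compute_vaf(_fixed_conc("T", 30.0),
                          cnr_q=_fixed_conc("CNR", 3000.0), route="cnr")
        assert vaf.value == pytest.approx(0.01, rel=1e-12)

    def test_zero_target_gives_zero(self):
        vaf = compute_vaf(_fixed_conc("T", 0.0), wt_q=_fixed_conc("W", 100.0))
        assert vaf.value == 0.0 and vaf.defined

    def test_zero_denominator_is_undefined_sentinel(self):
        vaf = compute_vaf(_fixed_conc("T", 5.0), cnr_q=_fixed_conc("C", 0.0),
                          route="cnr")
        assert not vaf.defined and math.isnan(vaf.value)

    def test_numerator_above_denominator_clamps_with_flag(self):
        vaf = compute_vaf(_fixed_conc("T", 50.0),
                          cnr_q=_fixed_conc("C", 10.0), route="cnr")
        assert vaf.value == 1.0 and vaf.clamped

    def test_missing_route_input_raises(self):
        with pytest.raises(ValueError, match="wildtype route"):
            compute_vaf(_fixed_conc("T", 5.0), route="wildtype")


class TestFpr:
    def _normal_wells(self, k_target, n_wells=12):
        return [make_well(k_target if i == 0 else 0, 18000,
                          well_id=f"n{i}", role="normal_cfDNA",
                          partner="W", k_partner=400)
                for i in range(n_wells)]

    def test_clean_wells_give_zero(self):
        fpr = estimate_fpr(self._normal_wells(0), "T", wt="W")
        assert fpr == 0.0

    def test_fpr_equals_vaf_of_merged_counts(self):
        wells = self._normal_wells(2)
        fpr = estimate_fpr(wells, "T", wt="W")
        qt = quantify_species(wells, "T")
        qw = quantify_species(wells, "W")
        assert fpr == pytest.approx(
            compute_vaf(qt, wt_q=qw, route="wildtype").value)
        assert 0 < fpr < 1e-3

    def test_too_few_wells_warns(self):
        with pytest.warns(UserWarning, match="9-12"):
            estimate_fpr(self._normal_wells(0, n_wells=3), "T", wt="W")

    def test_no_wells_is_error(self):
        with pytest.raises(ValueError):
            estimate_fpr([], "T", wt="W")

    def test_wrong_role_is_error(self):
        wells = [make_well(0, 18000, role="patient")]
        with pytest.raises(ValueError, match="normal_cfDNA"):
            estimate_fpr(wells, "T", wt="W")


class TestPositivity:
    def test_truth_table_positive_only_when_all_criteria_hold(self):
        for vaf_ok in (True, False):
            for ci_ok in (True, False):
                for droplets_ok in (True, False):
                    patient = _quant(
                        k=5 if droplets_ok else 2,
                        singles=3 if droplets_ok else 0,
                        ci=(0.8, 2.1) if ci_ok else (0.1, 2.1))
                    normal = _quant(k=0, lam=0.0, ci=(0.0, 0.3))
                    call = call_positivity(
                        patient,
                        vaf=0.001 if vaf_ok else 0.0001,
                        fpr=0.0005, normal_q=normal)
                    expected = vaf_ok and ci_ok and droplets_ok
                    assert call.positive is expected
                    assert call.criteria == {
                        "vaf_above_fpr": vaf_ok,
                        "ci_nonoverlap": ci_ok,
                        "droplet_support": droplets_ok}

    def test_two_droplets_never_positive(self):
        patient = _quant(k=2, singles=2, ci=(5.0, 9.0))
        normal = _quant(k=0, lam=0.0, ci=(0.0, 0.1))
        assert not call_positivity(patient, vaf=0.5, fpr=0.0,
                                   normal_q=normal).positive

    def test_vaf_equal_to_fpr_is_negative(self):
        patient = _quant(k=10, singles=5, ci=(5.0, 9.0))
        normal = _quant(k=0, lam=0.0, ci=(0.0, 0.1))
        call = call_positivity(patient, vaf=0.001, fpr=0.001,
                               normal_q=normal)
        assert not call.positive and not call.criteria["vaf_above_fpr"]

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(k1=st.integers(0, 500), dk=st.integers(0, 500))
    def test_monotone_in_positive_droplets(self, k1, dk):
        normal = _quant(k=0, lam=0.0, ci=(0.0, 0.5))
        fpr = 0.0001

        def call_at(k):
            wells = [make_well(k, 20000, partner="W", k_partner=5000)]
            q = quantify_species(wells, "T")
            wt = quantify_species(wells, "W")
            vaf = compute_vaf(q, wt_q=wt, route="wildtype")
            return call_positivity(q, vaf.value, fpr, normal).positive

        assert call_at(k1 + dk) >= call_at(k1)


class TestVolumesAndLod:
    def test_copies_per_ml_worked_example(self):
        vol = VolumeSpec(elution_volume_ul=40, plasma_volume_ml=4,
                         template_volume_ul=8)
        assert copies_per_ml(100, vol) == pytest.approx(125.0, rel=1e-12)

    def test_identity_scaling(self):
        vol = VolumeSpec(elution_volume_ul=8, plasma_volume_ml=1,
                         template_volume_ul=8)
        assert copies_per_ml(42.0, vol) == pytest.approx(42.0)

    def test_doubling_plasma_halves_copies_per_ml(self):
        v1 = VolumeSpec(40, 4, 8)
        v2 = VolumeSpec(40, 8, 8)
        assert copies_per_ml(100, v2) == pytest.approx(
            copies_per_ml(100, v1) / 2)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            VolumeSpec(elution_volume_ul=0, plasma_volume_ml=4,
                       template_volume_ul=8)

    @pytest.mark.parametrize("copies,lod", [(6000, 0.0005), (300, 0.01),
                                            (3, 1.0)])
    def test_theoretical_lod(self, copies, lod):
        assert theoretical_lod(copies) == pytest.approx(lod, rel=1e-12)

    def test_lod_requires_positive_copies(self):
        with pytest.raises(ValueError):
            theoretical_lod(0)


class TestSampleComposition:
    def test_all_negative_sample(self):
        panel = demo_panel()
        patient = [make_well(0, 18000, f"p{i}", species="MYD88_L265P",
                             partner="MYD88_L265P_wt", k_partner=1500)
                   for i in range(3)]
        normal = [make_well(0, 18000, f"n{i}", role="normal_cfDNA",
                            species="MYD88_L265P",
                            partner="MYD88_L265P_wt", k_partner=400)
                  for i in range(12)]
        vol = VolumeSpec(40, 4, 24)
        sq = quantify_sample("s", patient, normal, panel, vol)
        assert not sq.mrd_positive
        assert all(r.vaf.value == 0.0 for r in sq.targets.values())
        assert all(not r.positivity.positive for r in sq.targets.values())

    def test_simulated_one_percent_sample_recovers_vaf(self):
        scen = relapse_scenario()
        scen.timepoints = [scen.timepoints[0]]
        scen.timepoints[0].true_vaf = {"MYD88_L265P": 0.01,
                                       "IGH_BCL2_bp": 0.01}
        panel = demo_panel()
        b = simulate_patient_course(scen, panel, seed=21)[0]
        sq = quantify_sample("s", b["wells"], b["normal_wells"], panel,
                             b["volumes"])
        r = sq.targets["MYD88_L265P"]
        assert r.positivity.positive
        lo, hi = r.vaf_ci95
        assert lo <= 0.01 <= hi

    def test_wells_csv_round_trip(self, tmp_path):
        wells = [make_well(10, 18000, f"w{i}", partner="W", k_partner=300,
                           k_double=2) for i in range(3)]
        path = tmp_path / "wells.csv"
        write_wells_csv(wells, path)
        back = read_wells_csv(path)
        assert len(back) == 3
        assert back[0].cluster_counts == wells[0].cluster_counts


def _fixed_conc(species, conc_20ul):
    """Quantification with an exact copies/20µl value for arithmetic tests."""
    from ctmrd.ddpcr import Quantification
    return Quantification(
        species=species, k_positive=int(conc_20ul), n_droplets=20000,
        lambda_=conc_20ul * 8.5e-4 / 20, conc_per_ul=conc_20ul / 20,
        conc_per_20ul=conc_20ul, ci95=(conc_20ul * 0.9, conc_20ul * 1.1),
        n_single_positive=int(conc_20ul))
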