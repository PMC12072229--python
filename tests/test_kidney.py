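"""Mechanistic kidney block: filtration, secretion, clearance decomposition."""

import numpy as np
import pytest

from renalpbpk.kidney import (build_kidney_block, filtration_clearance,
                              kidney_rates, renal_clearance_from_sim,
                              scale_ptc_count)
from renalpbpk.model import (DoseEvent, DosingRegimen, InhibitionSchedule,
                             build_model, simulate)
from renalpbpk.nca import pk_summary
from renalpbpk.population import (CKDStage, PopulationSpec,
                                  make_ckd_population, sample_subject,
                                  subject_rng, white_population)

from conftest import no_iiv

# clearance measurements use a 0.5-h infusion and the dense output grid:
# a true bolus has no finite concentration at t=0 for the trapezoid to see
IV_REGIMEN = DosingRegimen([DoseEvent("iv_infusion", 1.0, per_kg=True,
                                      infusion_duration_h=0.5)])


def iv_clearances(subject, drug, inhibition=None):
    spec = build_model(subject, drug, inhibition=inhibition)
    res = simulate(spec, IV_REGIMEN, 48.0)
    return pk_summary(res), res


class TestFiltration:
    def test_product_of_fu_and_gfr(self):
        assert filtration_clearance(0.96, 7.2) == pytest.approx(6.912)
        assert filtration_clearance(0.5, 0.0) == 0.0
        with pytest.raises(ValueError):
            filtration_clearance(1.2, 7.2)

    def test_filtration_only_oracle(self, adefovir, mean_subject):
        """Zero transporters and zero passive diffusion: simulated CLr equals
        fu*GFR within 2%."""
        drug = adefovir.model_copy(deep=True)
        tr = drug.transporters
        tr.clint_oat1_invitro_ul_min_1e6 = 0.0
        tr.cl_mrp4_ul_min_1e6 = 0.0
        tr.clpd_baso_ul_min_1e6 = 0.0
        tr.clpd_apical_ul_min_1e6 = 0.0
        s, res = iv_clearances(mean_subject, drug)
        fu_gfr = adefovir.physchem.fu_plasma * mean_subject.gfr_l_h
        assert s.cl_r_l_h == pytest.approx(fu_gfr, rel=0.02)
        assert abs(s.cl_sec_l_h_kg) * mean_subject.body_weight_kg < \
            0.05 * s.cl_r_l_h

    def test_anuric_subject_produces_no_urine(self, adefovir, mean_subject):
        import copy
        subj = copy.deepcopy(mean_subject)
        subj.gfr_ml_min = 0.0
        drug = adefovir.model_copy(deep=True)
        drug.transporters.clint_oat1_invitro_ul_min_1e6 = 0.0
        spec = build_model(subj, drug)
        res = simulate(spec, IV_REGIMEN, 24.0)
        assert res.urine_mg[-1] == pytest.approx(0.0, abs=1e-9)


class TestSecretion:
    def test_healthy_secretion_fraction(self, adefovir, mean_subject):
        """Calibrated adefovir: secretion ~60% and filtration ~40% of CLr."""
        s, res = iv_clearances(mean_subject, adefovir)
        frac_sec = s.cl_sec_l_h_kg / s.cl_r_l_h_kg
        assert 0.55 <= frac_sec <= 0.67
        assert 0.33 <= res.fu_gfr_l_h / s.cl_r_l_h <= 0.45

    def test_fe_near_unity_after_iv(self, adefovir, mean_subject):
        s, _ = iv_clearances(mean_subject, adefovir)
        assert 0.98 <= s.fe <= 1.005

    def test_clr_below_renal_blood_flow(self, adefovir, mean_subject):
        s, _ = iv_clearances(mean_subject, adefovir)
        assert s.cl_r_l_h < mean_subject.body.flows["kidney"]

    def test_clr_monotone_in_inhibition_and_clint(self, adefovir, mean_subject):
        clrs = []
        for factor in (1.0, 2.0, 5.0):
            sched = InhibitionSchedule(lambda t, f=factor: f)
            s, _ = iv_clearances(mean_subject, adefovir, inhibition=sched)
            clrs.append(s.cl_r_l_h)
        assert clrs[0] > clrs[1] > clrs[2]

        drug = adefovir.model_copy(deep=True)
        drug.transporters.clint_oat1_invitro_ul_min_1e6 *= 2.0
        s_hi, _ = iv_clearances(mean_subject, drug)
        assert s_hi.cl_r_l_h > clrs[0]

    def test_complete_inhibition_limit(self, adefovir, mean_subject):
        """Inhibition factor -> infinity: secretion collapses to the passive
        pathway, <= 2% of the uninhibited secretion clearance."""
        control, _ = iv_clearances(mean_subject, adefovir)
        sched = InhibitionSchedule(lambda t: 1e9)
        inhibited, _ = iv_clearances(mean_subject, adefovir, inhibition=sched)
        assert inhibited.cl_sec_l_h_kg <= 0.02 * control.cl_sec_l_h_kg
        assert inhibited.cl_r_l_h == pytest.approx(
            mean_subject.gfr_l_h * adefovir.physchem.fu_plasma, rel=0.05)


class TestKidneyRates:
    def test_rejects_inhibition_below_one(self, adefovir, mean_subject):
        block = build_kidney_block(mean_subject, adefovir)
        with pytest.raises(ValueError, match="inhibition"):
            kidney_rates(block, 1.0, 0.1, 0.0, np.zeros(3),
                         inhibition_factor=0.5)

    def test_block_fluxes_conserve_drug(self, adefovir, mean_subject):
        """Everything leaving one side of a membrane arrives on the other."""
        block = build_kidney_block(mean_subject, adefovir)
        rates = kidney_rates(block, 1.0, 0.05, 0.01,
                             np.array([0.002, 0.001, 0.0005]))
        inflow = block.renal_blood_flow_l_h * 1.0 - rates["d_arterial"]
        net = (rates["d_vascular"] + rates["d_ptc"] + rates["d_lumen"].sum()
               + rates["d_urine"] + rates["to_venous"])
        assert net == pytest.approx(inflow, rel=1e-12)


class TestClearanceDecomposition:
    def test_secretion_is_subtraction_and_may_be_negative(self):
        """CLsec = CLr - fu*GFR by definition; 0.18 - 0.099 = 0.081 L/h/kg,
        and a negative difference is reported, not clamped."""

        class StubResult:
            sampling_times_h = np.linspace(0.0, 10.0, 11)
            times_h = np.linspace(0.0, 10.0, 11)
            bioavailable_dose_mg = 10.0
            fu_gfr_l_h = 0.099

            def plasma_conc_at(self, t):
                return np.full_like(np.asarray(t, dtype=float), 1000.0)

            def urine_at(self, t):
                return 0.18 * t  # mg/h at 1 mg/L -> Ae/AUC = 0.18 L/h

        rc = renal_clearance_from_sim(StubResult(), body_weight_kg=1.0)
        assert rc.cl_r_l_h == pytest.approx(0.18, rel=1e-9)
        assert rc.cl_sec_l_h == pytest.approx(0.081, rel=1e-9)

        StubResult.fu_gfr_l_h = 0.25
        rc2 = renal_clearance_from_sim(StubResult(), body_weight_kg=1.0)
        assert rc2.cl_sec_l_h == pytest.approx(-0.07, rel=1e-9)

    def test_zero_auc_is_an_error(self):
        class EmptyResult:
            sampling_times_h = np.linspace(0.0, 10.0, 11)
            times_h = np.linspace(0.0, 10.0, 11)
            bioavailable_dose_mg = 10.0
            fu_gfr_l_h = 0.1

            def plasma_conc_at(self, t):
                return np.zeros_like(np.asarray(t, dtype=float))

            def urine_at(self, t):
                return 0.0

        with pytest.raises(ValueError, match="CLr undefined"):
            renal_clearance_from_sim(EmptyResult())


class TestPtcScaling:
    def test_identity_and_proportional(self):
        assert scale_ptc_count(60.0, 1.0) == 60.0
        assert scale_ptc_count(60.0, 25.0 / 110.0) == pytest.approx(13.636,
                                                                    abs=0.001)

    def test_warns_on_improving_function(self):
        with pytest.warns(UserWarning, match="not modeled"):
            scale_ptc_count(60.0, 1.2)

    def test_severe_stage_secretion_capacity(self, adefovir):
        """PTC loss (25/110) composes multiplicatively with the OAT1 abundance
        drop (0.50): severe capacity = healthy x 0.1136."""
        base = no_iiv(white_population())
        severe = make_ckd_population(base, CKDStage.SEVERE)
        healthy_subj = sample_subject(base, subject_rng(0, 0, 0), sex="M")
        severe_subj = sample_subject(severe, subject_rng(0, 0, 0), sex="M")
        b_h = build_kidney_block(healthy_subj, adefovir)
        b_s = build_kidney_block(severe_subj, adefovir)
        ratio = b_s.cl_uptake_oat1_l_h / b_h.cl_uptake_oat1_l_h
        assert ratio == pytest.approx(25.0 / 110.0 * 0.50, rel=1e-9)
        assert ratio == pytest.approx(0.1136, abs=0.0005)
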