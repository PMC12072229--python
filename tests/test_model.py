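"""Whole-body ODE system: conservation, closed forms, linearity, dosing."""

import numpy as np
import pytest

from renalpbpk.model import (DoseEvent, DosingRegimen, build_model, oral_input,
                             simulate)
from renalpbpk.nca import auc_trapezoid, auc_to_infinity
from renalpbpk.population import (PopulationSpec, sample_subject, subject_rng)

from conftest import make_inert_drug, no_iiv


def zero_gfr_subject():
    spec = no_iiv(PopulationSpec(name="anuric", weight_mean_kg=70.0))
    subj = sample_subject(spec, subject_rng(0, 0, 0), sex="M")
    subj.gfr_ml_min = 0.0
    return subj


def fast_mixing_subject(flow_factor: float = 2000.0):
    """Flows scaled far above physiology: the body behaves as one well-mixed
    volume, reducing the system to a one-compartment model."""
    subj = zero_gfr_subject()
    subj.body.flows = {t: q * flow_factor for t, q in subj.body.flows.items()}
    subj.body.cardiac_output_l_h *= flow_factor
    return subj


class TestConservation:
    def test_closed_system_conserves_dose(self):
        """No clearance anywhere: total drug equals the administered dose."""
        drug = make_inert_drug()
        subj = zero_gfr_subject()
        res = simulate(build_model(subj, drug),
                       DosingRegimen([DoseEvent("iv_bolus", 10.0)]), 24.0)
        total = res.amounts_mg.sum(axis=0)
        assert np.allclose(total[1:], 10.0, rtol=1e-9)

    def test_iv_bolus_no_clearance_plateaus(self):
        drug = make_inert_drug()
        subj = zero_gfr_subject()
        res = simulate(build_model(subj, drug),
                       DosingRegimen([DoseEvent("iv_bolus", 10.0)]), 48.0)
        late = res.plasma_conc_ng_ml[res.times_h > 24.0]
        assert np.ptp(late) / late.mean() < 1e-6

    @pytest.mark.parametrize("route", ["iv_bolus", "oral"])
    def test_mass_balance_with_renal_elimination(self, adefovir, mean_subject,
                                                 route):
        reg = DosingRegimen([DoseEvent(route, 10.0)])
        res = simulate(build_model(mean_subject, adefovir), reg, 48.0)
        assert res.mass_balance_error() <= 1e-6

    def test_infusion_mass_balance(self, adefovir, mean_subject):
        reg = DosingRegimen([DoseEvent("iv_infusion", 70.0,
                                       infusion_duration_h=1.0)])
        res = simulate(build_model(mean_subject, adefovir), reg, 24.0)
        assert res.mass_balance_error() <= 1e-6

    def test_states_non_negative(self, adefovir, mean_subject):
        reg = DosingRegimen.single_oral(5.45)
        res = simulate(build_model(mean_subject, adefovir), reg, 24.0)
        assert res.amounts_mg.min() >= 0.0


class TestClosedFormOral:
    def test_one_compartment_reduction(self):
        """With near-instant mixing and a single linear clearance, the plasma
        profile matches the analytic oral solution within 0.5%."""
        cl, ka, fa, dose = 5.0, 1.0, 1.0, 10.0
        drug = make_inert_drug()
        drug.elimination.cl_nonrenal_linear_l_h = cl
        drug.absorption.ka_per_h = ka
        subj = fast_mixing_subject()
        spec = build_model(subj, drug)
        # effective volume: blood + perfused-tissue volumes + renal
        # vasculature; the kidney tissue itself is the mechanistic block,
        # which an inert drug (no filtration, no transport) cannot enter
        v = (subj.body.blood_volume_l
             + sum(subj.body.volumes[t] * spec.kps[t]
                   for t in subj.body.volumes if t != "kidney")
             + spec.kidney.vascular_volume_l)
        k = cl / v
        res = simulate(spec, DosingRegimen.single_oral(dose), 24.0)
        t = np.array([0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0])
        analytic = (fa * dose * ka / (v * (ka - k))
                    * (np.exp(-k * t) - np.exp(-ka * t)) * 1000.0)
        simulated = res.plasma_conc_at(t)
        assert simulated == pytest.approx(analytic, rel=5e-3)


class TestLinearityAndSuperposition:
    def test_dose_linearity_10_to_500_mg(self, adefovir, mean_subject):
        """All adefovir processes are linear: AUC is exactly proportional to
        dose across the 10-500 mg range."""
        spec = build_model(mean_subject, adefovir)
        times = np.linspace(0.0, 48.0, 97)
        aucs = {}
        for dose in (10.0, 100.0, 500.0):
            res = simulate(spec, DosingRegimen.single_oral(dose), 48.0,
                           sampling_times_h=times)
            aucs[dose] = auc_trapezoid(times, res.plasma_conc_at(times))
        assert aucs[100.0] / aucs[10.0] == pytest.approx(10.0, rel=1e-6)
        assert aucs[500.0] / aucs[10.0] == pytest.approx(50.0, rel=1e-6)

    def test_steady_state_auc_equals_single_dose_auc_inf(self, adefovir,
                                                         mean_subject):
        spec = build_model(mean_subject, adefovir)
        times = np.linspace(0.0, 96.0, 385)
        single = simulate(spec, DosingRegimen.single_oral(5.45), 96.0,
                          sampling_times_h=times)
        auc_inf = auc_to_infinity(times, single.plasma_conc_at(times))
        multi = simulate(spec, DosingRegimen.once_daily_oral(5.45, 4), 120.0,
                         sampling_times_h=np.linspace(72.0, 96.0, 97))
        tt = np.linspace(72.0, 96.0, 97)
        auc_ss = auc_trapezoid(tt, multi.plasma_conc_at(tt))
        assert auc_ss == pytest.approx(auc_inf, rel=5e-3)

    def test_time_shift_invariance(self, adefovir, mean_subject):
        spec = build_model(mean_subject, adefovir)
        delta = 3.0
        t = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        a = simulate(spec, DosingRegimen.single_oral(5.45, start_h=0.0), 30.0,
                     sampling_times_h=t)
        b = simulate(spec, DosingRegimen.single_oral(5.45, start_h=delta),
                     30.0 + delta, sampling_times_h=t + delta)
        assert b.plasma_conc_at(t + delta) == pytest.approx(
            a.plasma_conc_at(t), rel=1e-6)


class TestAbsorption:
    def test_oral_input_rate_and_lag(self):
        assert oral_input(10.0, 0.5, 0.47, lag_h=1.0, t_since_dose_h=0.5) == 0.0
        assert oral_input(10.0, 0.5, 0.47, lag_h=1.0, t_since_dose_h=2.0) == \
            pytest.approx(0.5 * 0.47 * 10.0)
        with pytest.raises(ValueError):
            oral_input(-1.0, 0.5, 0.47)

    def test_bioavailable_fraction(self, adefovir, mean_subject):
        """Total systemic input approaches Fa of the parent-equivalent dose;
        a 5.45 mg dose at Fa 0.47 delivers 2.56 mg."""
        res = simulate(build_model(mean_subject, adefovir),
                       DosingRegimen.single_oral(5.45), 96.0)
        assert res.bioavailable_dose_mg == pytest.approx(2.56, abs=0.005)
        unabsorbed = res.amounts_mg[res.compartment_names.index("unabsorbed")]
        assert unabsorbed[-1] == pytest.approx(5.45 * 0.53, rel=1e-3)

    def test_depot_decays_with_half_life_ln2_over_ka(self, adefovir,
                                                     mean_subject):
        ka = adefovir.absorption.ka_per_h
        res = simulate(build_model(mean_subject, adefovir),
                       DosingRegimen.single_oral(5.45), 24.0)
        depot = res.amounts_mg[res.compartment_names.index("depot")]
        t_half = np.log(2.0) / ka
        assert np.interp(t_half, res.times_h, depot) == \
            pytest.approx(5.45 / 2.0, rel=1e-4)

    def test_fast_ka_approaches_iv_bolus(self, mean_subject):
        drug = make_inert_drug()
        drug.elimination.cl_nonrenal_linear_l_h = 5.0
        drug.absorption.ka_per_h = 500.0
        subj = zero_gfr_subject()
        oral = simulate(build_model(subj, drug),
                        DosingRegimen.single_oral(10.0), 24.0)
        iv = simulate(build_model(subj, drug),
                      DosingRegimen([DoseEvent("iv_bolus", 10.0)]), 24.0)
        t = np.array([1.0, 2.0, 4.0, 8.0])
        assert oral.plasma_conc_at(t) == pytest.approx(iv.plasma_conc_at(t),
                                                       rel=0.02)


class TestModelStructure:
    def test_edge_audit(self, adefovir, mean_subject):
        """Structural count: 2 lung + 2 per perfused tissue + 10 kidney-block
        edges + 1 absorption edge; renal-only drug has no elimination edge."""
        spec = build_model(mean_subject, adefovir)
        kinds = [e.kind for e in spec.edges]
        assert len(spec.edges) == 2 + 2 * 11 + 10 + 1
        assert kinds.count("elimination") == 0
        assert kinds.count("absorption") == 1
        assert kinds.count("active_uptake") == 1

    def test_perpetrator_has_elimination_edge(self, probenecid, mean_subject):
        spec = build_model(mean_subject, probenecid)
        assert sum(e.kind == "elimination" for e in spec.edges) == 1

    def test_t_end_must_cover_doses(self, adefovir, mean_subject):
        spec = build_model(mean_subject, adefovir)
        with pytest.raises(ValueError, match="t_end"):
            simulate(spec, DosingRegimen.single_oral(5.45, start_h=30.0), 24.0)

    def test_mg_per_kg_resolved_at_build(self, adefovir, mean_subject):
        reg = DosingRegimen([DoseEvent("iv_bolus", 1.0, per_kg=True)])
        res = simulate(build_model(mean_subject, adefovir), reg, 24.0)
        assert res.administered_mg == pytest.approx(
            mean_subject.body_weight_kg)
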