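"""Synthetic observed datasets and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from renalpbpk.model import DoseEvent, DosingRegimen
from renalpbpk.population import (MAEDA_SAMPLING_H, TrialDesign,
                                  japanese_population, white_population)
from renalpbpk.synthetic import (fit_absorption_rate, generate_observed_study,
                                 mean_profile)

from conftest import no_iiv


def oral_design(n_trials=1, n_subjects=6, population=None, name="oral-study"):
    return TrialDesign(
        name=name,
        population=population or japanese_population(),
        n_trials=n_trials, n_subjects=n_subjects, sex_composition="male",
        age_range=(20.0, 31.0),
        regimens={"control": DosingRegimen.single_oral(5.45)},
        sampling_times_h=list(MAEDA_SAMPLING_H), t_end_h=10.0,
    )


def maeda_design():
    d = oral_design()
    d.regimens = {
        "control": DosingRegimen.single_oral(5.45, start_h=2.0),
        "p-0.5g": DosingRegimen.single_oral(5.45, start_h=2.0),
        "p-0.75g": DosingRegimen.single_oral(5.45, start_h=2.0),
        "p-1.5g": DosingRegimen.single_oral(5.45, start_h=2.0),
    }
    d.perpetrator_regimens = {
        "p-0.5g": DosingRegimen.single_oral(500.0),
        "p-0.75g": DosingRegimen.single_oral(750.0),
        "p-1.5g": DosingRegimen.single_oral(1500.0),
    }
    d.sampling_times_h = [2.0 + t for t in MAEDA_SAMPLING_H]
    d.t_end_h = 12.0
    return d


class TestGeneration:
    def test_zero_residual_reproduces_simulation(self, adefovir):
        design = oral_design(population=no_iiv(japanese_population()))
        study = generate_observed_study(adefovir, design, seed=3,
                                        residual_cv=0.0, lloq_ng_ml=0.0)
        rep = generate_observed_study(adefovir, design, seed=99,
                                      residual_cv=0.0, lloq_ng_ml=0.0)
        # no noise and no subject variability: the seed cannot matter
        pd.testing.assert_frame_equal(study.records, rep.records)

    def test_crossover_record_count_and_reproducibility(self, adefovir,
                                                        probenecid):
        """Four-phase crossover in 6 subjects over 9 time points: 216 records,
        bit-identical across runs with the same seed."""
        a = generate_observed_study(adefovir, maeda_design(), seed=11,
                                    perpetrator=probenecid, lloq_ng_ml=0.0)
        b = generate_observed_study(adefovir, maeda_design(), seed=11,
                                    perpetrator=probenecid, lloq_ng_ml=0.0)
        assert len(a.records) == 6 * 4 * 9
        pd.testing.assert_frame_equal(a.records, b.records)
        c = generate_observed_study(adefovir, maeda_design(), seed=12,
                                    perpetrator=probenecid, lloq_ng_ml=0.0)
        assert not a.records["conc_ng_ml"].equals(c.records["conc_ng_ml"])

    def test_lloq_censoring_leaves_no_nonpositive_values(self, adefovir):
        study = generate_observed_study(adefovir, oral_design(), seed=5)
        assert (study.records["conc_ng_ml"] >= 0.5).all()

    def test_summary_derives_from_records(self, adefovir):
        study = generate_observed_study(adefovir, oral_design(), seed=7,
                                        lloq_ng_ml=0.0)
        cmax_row = study.summary[(study.summary["metric"] == "cmax_ng_ml")]
        by_subject = study.records.groupby("subject_id")["conc_ng_ml"].max()
        assert cmax_row["mean"].iloc[0] == pytest.approx(by_subject.mean())
        assert cmax_row["n"].iloc[0] == 6

    def test_geometric_mean_unbiased(self, adefovir):
        """Per-timepoint geometric mean of the noisy records tracks the
        noiseless profile within 2 standard errors for n >= 24."""
        design = oral_design(n_trials=1, n_subjects=24,
                             population=no_iiv(japanese_population()))
        noisy = generate_observed_study(adefovir, design, seed=21,
                                        residual_cv=0.15, lloq_ng_ml=0.0)
        clean = generate_observed_study(adefovir, design, seed=21,
                                        residual_cv=0.0, lloq_ng_ml=0.0)
        merged = noisy.records.merge(
            clean.records, on=["subject_id", "time_h"], suffixes=("", "_true"))
        merged = merged[merged["conc_ng_ml_true"] > 0]
        sigma = np.sqrt(np.log(1.0 + 0.15**2))
        for t, grp in merged.groupby("time_h"):
            log_ratio = np.log(grp["conc_ng_ml"] / grp["conc_ng_ml_true"])
            se = sigma / np.sqrt(len(grp))
            assert abs(log_ratio.mean()) <= 2.5 * se


class TestAbsorptionFit:
    def test_noiseless_self_consistency(self, adefovir):
        """Fitting ka to data generated by the same model recovers the
        generating value within 1%."""
        pop = no_iiv(japanese_population())
        design = oral_design(n_subjects=1, population=pop)
        study = generate_observed_study(adefovir, design, seed=1,
                                        residual_cv=0.0, lloq_ng_ml=0.0)
        truth = adefovir.absorption.ka_per_h
        start = adefovir.model_copy(deep=True)
        start.absorption.ka_per_h = 0.5
        fit = fit_absorption_rate(study.records, start, pop,
                                  DosingRegimen.single_oral(5.45),
                                  t_end_h=10.0)
        assert fit.ka_per_h == pytest.approx(truth, rel=0.01)

    def test_recovery_under_noise(self, adefovir):
        """n = 24 subjects with 15% residual error: ka estimate within 10%."""
        pop = japanese_population()
        design = oral_design(n_trials=4, n_subjects=6, population=pop)
        study = generate_observed_study(adefovir, design, seed=33,
                                        residual_cv=0.15, lloq_ng_ml=0.0)
        start = adefovir.model_copy(deep=True)
        start.absorption.ka_per_h = 0.5
        fit = fit_absorption_rate(study.records, start, pop,
                                  DosingRegimen.single_oral(5.45),
                                  t_end_h=10.0)
        truth = adefovir.absorption.ka_per_h
        assert 0.9 * truth <= fit.ka_per_h <= 1.1 * truth
        assert fit.ka_se > 0

    def test_flat_profile_raises(self, adefovir):
        records = pd.DataFrame({
            "subject_id": ["s1"] * 6, "phase": ["control"] * 6,
            "time_h": [0.5, 1.0, 2.0, 4.0, 6.0, 8.0],
            "conc_ng_ml": [10.0] * 6,
        })
        with pytest.raises(RuntimeError, match="flat"):
            fit_absorption_rate(records, adefovir, japanese_population(),
                                DosingRegimen.single_oral(5.45))

    def test_mean_profile_shape(self, adefovir):
        study = generate_observed_study(adefovir, oral_design(), seed=2,
                                        lloq_ng_ml=0.0)
        prof = mean_profile(study.records, phase="control")
        assert list(prof.columns) == ["time_h", "conc_ng_ml"]
        assert prof["time_h"].is_monotonic_increasing
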