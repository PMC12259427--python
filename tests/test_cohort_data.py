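"""Synthetic cohort generation and NONMEM-style dataset round-trips."""

import numpy as np
import pandas as pd
import pytest

from teicopk.cohort import (
    CohortConfig, Observation, generate_cohort, simulate_observations,
)
from teicopk.data import Dataset
from teicopk.model import ModelSpec, ResidualModel, final_model
from teicopk.pk import concentration


class TestAllocation:
    def test_default_study_strata(self):
        """Default config reproduces the study's exact stratum counts."""
        for seed in (0, 7, 123):
            cohort = generate_cohort(CohortConfig(seed=seed))
            assert len(cohort) == 86
            assert sum(s.covariates.sex for s in cohort) == 35
            assert sum(s.covariates.crrt for s in cohort) == 20
            assert sum(s.covariates.ecmo for s in cohort) == 4

    @pytest.mark.parametrize("n,frac,expected", [(10, 0.25, 3), (10, 0.55, 6), (3, 0.5, 2)])
    def test_round_half_up_allocation(self, n, frac, expected):
        cohort = generate_cohort(CohortConfig(n_subjects=n, fraction_female=frac, seed=1))
        assert sum(s.covariates.sex for s in cohort) == expected

    def test_degenerate_single_male(self):
        (s,) = generate_cohort(CohortConfig(
            n_subjects=1, fraction_female=0, fraction_crrt=0, fraction_ecmo=0, seed=2))
        assert s.covariates.sex == 0
        assert [d.start_time for d in s.dose_events][:4] == [0, 12, 24, 48]
        assert {d.amount for d in s.dose_events} == {400.0}

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            CohortConfig(n_subjects=0)
        with pytest.raises(ValueError):
            CohortConfig(fraction_crrt=1.2)

    def test_continuous_medians_match(self):
        """Sampled continuous covariates reproduce the configured medians."""
        cfg = CohortConfig(n_subjects=10_000, seed=3)
        cohort = generate_cohort(cfg)
        for name, (median, _, _) in cfg.continuous.items():
            vals = [getattr(s.covariates, name) for s in cohort]
            assert np.median(vals) == pytest.approx(median, rel=0.10)

    def test_ages_adult(self):
        cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=4))
        assert min(s.covariates.age for s in cohort) >= 18.0


class TestSimulateObservations:
    def test_zero_variability_equals_prediction(self, no_bsv_model):
        cohort = generate_cohort(CohortConfig(
            n_subjects=5, fraction_female=0, fraction_crrt=0, fraction_ecmo=0, seed=5))
        ds = simulate_observations(cohort, no_bsv_model, design="trough", seed=6)
        obs = ds.df[ds.df.EVID == 0]
        for s in cohort:
            row = obs[obs.ID == s.id].iloc[0]
            f = concentration(
                no_bsv_model.individual_params(s.covariates.as_dict()),
                s.dose_events, float(row.TIME))
            assert row.DV == pytest.approx(f, abs=1e-6)

    def test_trough_on_maintenance_day(self, published_model):
        cohort = generate_cohort(CohortConfig(n_subjects=40, seed=7))
        ds = simulate_observations(cohort, published_model, design="trough",
                                   tdm_day_range=(4, 7), seed=8)
        times = ds.df.loc[ds.df.EVID == 0, "TIME"]
        assert set(times) <= {96.0, 120.0, 144.0, 168.0}

    def test_determinism(self, published_model):
        cohort = generate_cohort(CohortConfig(n_subjects=10, seed=9))
        a = simulate_observations(cohort, published_model, seed=10)
        b = simulate_observations(cohort, published_model, seed=10)
        assert a.equals(b)

    def test_empty_cohort_raises(self, published_model):
        with pytest.raises(ValueError):
            simulate_observations([], published_model, seed=0)

    def test_median_trough_plausible(self, published_model):
        """Large simulated cohorts land inside the study's observed IQR."""
        cohort = generate_cohort(CohortConfig(n_subjects=2000, seed=11))
        ds = simulate_observations(cohort, published_model, design="trough", seed=12)
        med = ds.df.loc[ds.df.EVID == 0, "DV"].median()
        assert 10.48 <= med <= 19.83


class TestDatasetRoundtrip:
    def test_write_read_identity(self, tmp_path, published_model):
        cohort = generate_cohort(CohortConfig(seed=13))
        ds = simulate_observations(cohort, published_model, seed=14)
        path = tmp_path / "cohort.csv"
        ds.write_csv(path)
        assert Dataset.read_csv(path).equals(ds)

    def test_dose_rows_preserved(self, tmp_path, published_model):
        cohort = generate_cohort(CohortConfig(n_subjects=3, seed=15))
        ds = simulate_observations(cohort, published_model, seed=16)
        path = tmp_path / "d.csv"
        ds.write_csv(path)
        back = Dataset.read_csv(path).df
        doses = back[back.EVID == 1]
        assert doses.DV.isna().all()
        assert (doses.MDV == 1).all()
        assert (doses.AMT > 0).all()

    def test_observation_ordered_before_dose_at_equal_time(self):
        rows = pd.DataFrame({
            "ID": [1, 1, 1], "TIME": [0.0, 96.0, 96.0],
            "AMT": [400.0, np.nan, 400.0], "DUR": [1.0, np.nan, 1.0],
            "EVID": [1, 0, 1], "DV": [np.nan, 12.5, np.nan], "MDV": [1, 0, 1],
            "SEX": 0, "CRRT": 0, "ECMO": 0, "AGE": 60.0, "WT": 62.0,
            "HT": 165.0, "ALB": 31.6, "SCR": 109.0,
        })
        # dose listed before the observation at t=96; constructor reorders
        ds = Dataset(rows.iloc[[0, 2, 1]])
        at96 = ds.df[ds.df.TIME == 96.0]
        assert list(at96.EVID) == [0, 1]

    def test_unknown_column_rejected(self):
        bad = pd.DataFrame({"ID": [1], "BOGUS": [2]})
        with pytest.raises(ValueError):
            Dataset(bad)

    def test_non_monotone_times_rejected_on_read(self, tmp_path):
        text = (
            "ID,TIME,AMT,DUR,EVID,DV,MDV,SEX,CRRT,ECMO,AGE,WT,HT,ALB,SCR\n"
            "1,96,,,0,12.0,0,0,0,0,60,62,165,31.6,109\n"
            "1,0,400,1,1,,1,0,0,0,60,62,165,31.6,109\n"
        )
        p = tmp_path / "bad.csv"
        p.write_text(text)
        with pytest.raises(ValueError, match="non-monotone"):
            Dataset.read_csv(p)

    def test_negative_observation_rejected(self):
        with pytest.raises(ValueError):
            Observation(time=10.0, concentration=-1.0)
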