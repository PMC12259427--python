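"""FOCE-I objective, outer estimation, and residual diagnostics."""

import math

import numpy as np
import pytest

from teicopk.cohort import CohortConfig, generate_cohort, simulate_observations
from teicopk.data import Dataset
from teicopk.estimate import compute_cwres, fit, foce_ofv
from teicopk.model import ModelSpec, ResidualModel, final_model
from teicopk.pk import concentration
from teicopk.reference import marginal_ofv_agq

from conftest import start_values


def _exact_fit_dataset(model, n=1, seed=0, design="trough"):
    """Dataset whose observations equal the model's typical predictions."""
    cohort = generate_cohort(CohortConfig(
        n_subjects=n, fraction_female=0, fraction_crrt=0, fraction_ecmo=0,
        seed=seed))
    ds = simulate_observations(cohort, model, design=design, seed=seed + 1)
    df = ds.df.copy()
    for s in cohort:
        p = model.individual_params(s.covariates.as_dict())
        sel = (df.ID == s.id) & (df.EVID == 0)
        df.loc[sel, "DV"] = [
            concentration(p, s.dose_events, float(t)) for t in df.loc[sel, "TIME"]
        ]
    return Dataset(df), cohort


class TestFoceOfv:
    def test_closed_form_no_bsv(self):
        """With omega = 0 and y = f the OFV is the Gaussian constant."""
        m = ModelSpec(theta={"cl": 0.98, "v": 108.69},
                      omega2={"cl": 0.0, "v": 0.0},
                      residual=ResidualModel("additive", 0.23))
        ds, _ = _exact_fit_dataset(m)
        r = foce_ofv(ds, m)
        assert r["ofv"] == pytest.approx(math.log(2 * math.pi * 0.23**2), abs=1e-9)
        assert r["ofv"] == pytest.approx(-1.1015, abs=1e-4)

    def test_residual_term_adds_quadratic(self):
        m = ModelSpec(theta={"cl": 0.98, "v": 108.69},
                      omega2={"cl": 0.0, "v": 0.0},
                      residual=ResidualModel("additive", 0.23))
        ds, _ = _exact_fit_dataset(m)
        df = ds.df.copy()
        df.loc[df.EVID == 0, "DV"] += 0.46  # 2 sigma
        r = foce_ofv(Dataset(df), m)
        assert r["ofv"] == pytest.approx(math.log(2 * math.pi * 0.23**2) + 4.0, abs=1e-6)

    def test_subject_duplication_doubles_ofv(self, published_model, rich_dataset):
        import pandas as pd

        df = rich_dataset.df
        half_ids = df.ID.unique()[:10]
        sub = df[df.ID.isin(half_ids)]
        dup = sub.copy()
        dup["ID"] = dup["ID"] + 10_000
        single = foce_ofv(Dataset(sub), published_model)["ofv"]
        double = foce_ofv(Dataset(pd.concat([sub, dup])), published_model)["ofv"]
        assert double == pytest.approx(2 * single, abs=1e-6)

    def test_agrees_with_quadrature(self, published_model):
        """FOCE-I tracks the adaptive Gauss-Hermite marginal closely."""
        for seed in (1, 2, 3):
            cohort = generate_cohort(CohortConfig(n_subjects=6, sampling_design="rich",
                                                  seed=300 + seed))
            ds = simulate_observations(cohort, published_model, design="rich",
                                       seed=400 + seed)
            arr = ds.arrays()
            d = foce_ofv(arr, published_model)["ofv"] - marginal_ofv_agq(
                arr, published_model, n_nodes=32)
            assert abs(d) <= 0.5


class TestFit:
    def test_noise_free_recovery(self):
        """Deterministic inversion: sigma ~ 0, omega = 0, rich sampling."""
        truth = ModelSpec(theta={"cl": 0.98, "v": 108.69},
                          omega2={"cl": 0.0, "v": 0.0},
                          residual=ResidualModel("additive", 1e-6))
        ds, _ = _exact_fit_dataset(truth, n=4, seed=20, design="rich")
        init = ModelSpec(theta={"cl": 1.5, "v": 70.0},
                         omega2={"cl": 0.0, "v": 0.0},
                         residual=ResidualModel("additive", 1e-6))
        res = fit(ds, init, fixed=("sigma_add",), compute_se=False)
        assert res.estimates["tv_cl"] == pytest.approx(0.98, rel=1e-4)
        assert res.estimates["tv_v"] == pytest.approx(108.69, rel=1e-4)

    def test_underdetermined_flags(self, published_model):
        cohort = generate_cohort(CohortConfig(n_subjects=1, seed=21))
        ds = simulate_observations(cohort, published_model, design="trough", seed=22)
        res = fit(ds, start_values(), compute_se=False, max_iter=30)
        assert any("identifiability" in w or "boundary" in w for w in res.warnings)

    def test_fit_is_deterministic(self, published_model, rich_dataset):
        ids = rich_dataset.df.ID.unique()[:15]
        sub = Dataset(rich_dataset.df[rich_dataset.df.ID.isin(ids)])
        a = fit(sub, start_values(), compute_se=False)
        b = fit(sub, start_values(), compute_se=False)
        assert a.ofv == b.ofv
        assert a.estimates == b.estimates

    def test_ofv_invariant_to_subject_order(self, published_model, rich_dataset):
        df = rich_dataset.df
        shuffled = df.sort_values(["ID"], ascending=False, kind="stable")
        a = foce_ofv(Dataset(df), published_model)["ofv"]
        b = foce_ofv(Dataset(shuffled), published_model)["ofv"]
        assert a == pytest.approx(b, abs=1e-8)


class TestCwres:
    def test_reduces_to_standardized_residual(self):
        m = ModelSpec(theta={"cl": 0.98, "v": 108.69},
                      omega2={"cl": 0.0, "v": 0.0},
                      residual=ResidualModel("additive", 0.23))
        ds, cohort = _exact_fit_dataset(m, n=1, seed=30)
        df = ds.df.copy()
        df.loc[df.EVID == 0, "DV"] += 0.46
        res = fit(Dataset(df), m, fixed=("tv_cl", "tv_v", "sigma_add"),
                  compute_se=False, max_iter=0)
        tab = compute_cwres(Dataset(df), res)
        # y = f + 2 sigma, no BSV: CWRES is exactly the standardized residual
        assert tab.CWRES.iloc[0] == pytest.approx(2.0, abs=1e-6)
        assert tab.PRED.iloc[0] == pytest.approx(tab.IPRED.iloc[0])

    def test_sigma_inflation_shrinks_cwres(self):
        """Without BSV, doubling sigma halves every weighted residual."""
        m = ModelSpec(theta={"cl": 0.98, "v": 108.69},
                      omega2={"cl": 0.0, "v": 0.0},
                      residual=ResidualModel("additive", 0.23))
        ds, _ = _exact_fit_dataset(m, n=5, seed=31, design="rich")
        rng = np.random.default_rng(32)
        df = ds.df.copy()
        df.loc[df.EVID == 0, "DV"] += rng.normal(0, 0.23, (df.EVID == 0).sum())
        noisy = Dataset(df)
        from dataclasses import replace

        fixed = ("tv_cl", "tv_v", "sigma_add")
        a = compute_cwres(noisy, fit(noisy, m, fixed=fixed, compute_se=False))
        m2 = replace(m, residual=ResidualModel("additive", 0.46))
        b = compute_cwres(noisy, fit(noisy, m2, fixed=fixed, compute_se=False))
        assert np.allclose(b.CWRES.to_numpy(), a.CWRES.to_numpy() / 2.0)

    def test_calibrated_under_generating_model(self, published_model, rich_dataset):
        """CWRES from the generating model are ~N(0,1)."""
        res = fit(rich_dataset, published_model,
                  fixed=("tv_cl", "tv_v", "beta_crrt_v", "beta_sex_v",
                         "omega2_cl", "omega2_v", "sigma_add"),
                  compute_se=False, max_iter=0)
        tab = compute_cwres(rich_dataset, res)
        cw = tab.CWRES.to_numpy()
        assert abs(cw.mean()) < 0.1
        assert 0.8 < cw.var() < 1.2
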