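"""Mixed-effects estimation: OFV oracles, EB etas, fitting behavior."""

import dataclasses

import numpy as np
import pytest

import sertpk as sp
from sertpk.cohort import Individual, simulate_tdm
from sertpk.estimate import FitSpec, empirical_bayes, fit, ofv, set_params


def _additive_only_model(sigma_add=5.0, omega=0.0):
    return sp.PopulationModel(
        re=sp.RandomEffects(omega_cl=omega),
        rm=sp.ResidualModel(sigma_prop=0.0, sigma_add=sigma_add),
    )


def _cohort(n, weight=70.0, dose_per_kg=3.0, tau=24.0, zop=0):
    dose = dose_per_kg * weight * tau / 24.0
    return [
        Individual(
            sp.Subject(id=i + 1, weight_kg=weight, zop=zop),
            sp.Regimen(dose_mg=dose, tau_h=tau),
            dose_per_kg,
        )
        for i in range(n)
    ]


class TestOfv:
    def test_closed_form_gaussian_oracle(self, final_model):
        """omega=0, additive-only error: OFV is the exact least-squares
        log-likelihood sum[(B-C)^2/sigma^2 + ln(2 pi sigma^2)]."""
        model = _additive_only_model(sigma_add=5.0)
        spec = sp.CohortSpec(n_subjects=15, troughs_per_subject=2, seed=8)
        cohort = _cohort(15)
        ds = simulate_tdm(cohort, model, spec)
        # independent oracle: direct arithmetic from the event table
        preds = []
        for ind in cohort:
            c = sp.trough_at_steady_state(
                sp.typical_params(model.fe, ind.subject), ind.regimen
            )
            preds.append(c)
        y = ds.observations()["DV"].to_numpy()
        n_per = ds.observations().groupby(ds.events["ID"]).size()
        c_obs = np.repeat(preds, n_per.reindex(range(1, 16)).to_numpy())
        expected = np.sum(
            (y - c_obs) ** 2 / 5.0**2 + np.log(2 * np.pi * 5.0**2)
        )
        assert ofv(ds, model) == pytest.approx(expected, rel=1e-6)

    def test_additive_over_duplicated_subjects(self, final_model, small_dataset):
        doubled = small_dataset.subset_subjects(
            small_dataset.subject_ids * 2, relabel=True
        )
        assert ofv(doubled, final_model) == pytest.approx(
            2.0 * ofv(small_dataset, final_model), rel=1e-9
        )

    def test_scale_transformation_jacobian(self):
        """Scaling doses, observations and sigma_add by k shifts the
        additive-only OFV by exactly 2 N ln k."""
        model = _additive_only_model(sigma_add=5.0)
        spec = sp.CohortSpec(n_subjects=10, troughs_per_subject=2, seed=13)
        cohort = _cohort(10)
        ds = simulate_tdm(cohort, model, spec)
        k = 3.0
        d = ds.dialect
        scaled = ds.events.copy()
        scaled[d.dv_col] = scaled[d.dv_col] * k
        scaled[d.amt_col] = scaled[d.amt_col] * k
        ds_scaled = sp.TdmDataset(scaled, dialect=d)
        model_scaled = _additive_only_model(sigma_add=5.0 * k)
        n = ds.n_observations
        assert ofv(ds_scaled, model_scaled) == pytest.approx(
            ofv(ds, model) + 2.0 * n * np.log(k), rel=1e-9
        )

    def test_deterministic(self, final_model, small_dataset):
        assert ofv(small_dataset, final_model) == ofv(small_dataset, final_model)

    def test_laplace_close_to_foce(self, final_model, small_dataset):
        a = ofv(small_dataset, final_model, approx="foce")
        b = ofv(small_dataset, final_model, approx="laplace")
        assert a == pytest.approx(b, rel=0.01)


class TestEmpiricalBayes:
    def test_on_typical_observations(self, final_model):
        """Observations exactly at typical predictions give eta ~ 0."""
        noise_free = sp.PopulationModel(
            re=final_model.re, rm=sp.ResidualModel(sigma_prop=0.0, sigma_add=0.0)
        )
        spec = sp.CohortSpec(n_subjects=5, troughs_per_subject=3, seed=1)
        cohort = _cohort(5)
        zero_iiv = sp.PopulationModel(
            re=sp.RandomEffects(omega_cl=0.0),
            rm=sp.ResidualModel(sigma_prop=0.0, sigma_add=0.0),
        )
        ds = simulate_tdm(cohort, zero_iiv, spec)
        etas = empirical_bayes(ds, final_model)
        # the interaction term ln v(eta) shifts the joint mode slightly off
        # zero even for perfectly typical data; "small vs omega" is the claim
        assert np.all(np.abs(etas.to_numpy()) < 0.05 * final_model.re.omega_sd)

    def test_prior_domination_as_omega_vanishes(self, final_model, small_dataset):
        tiny = sp.PopulationModel(
            re=sp.RandomEffects(omega_cl=1e-4), rm=final_model.rm
        )
        etas = empirical_bayes(small_dataset, tiny)
        assert np.all(np.abs(etas.to_numpy()) < 1e-3)

    def test_matches_grid_search_oracle(self, final_model):
        """Single subject, rich sampling: EB mode vs 1-D grid search."""
        spec = sp.CohortSpec(n_subjects=1, troughs_per_subject=10, seed=21)
        cohort = _cohort(1)
        ds = simulate_tdm(cohort, final_model, spec)
        eta_hat = empirical_bayes(ds, final_model, subject=1)

        # independent oracle: dense grid over eta of the joint density
        y = ds.observations()["DV"].to_numpy()
        tp = sp.typical_params(final_model.fe, cohort[0].subject)
        omega = final_model.re.omega_sd
        grid = np.linspace(-2.0, 2.0, 40001)
        best, best_val = None, np.inf
        for eta in grid:
            p = sp.StructuralParams(cl=tp.cl * np.exp(eta), v=tp.v, ka=tp.ka)
            c = sp.trough_at_steady_state(p, cohort[0].regimen)
            var = (final_model.rm.prop_sd * c) ** 2 + final_model.rm.add_sd**2
            val = np.sum((y - c) ** 2 / var + np.log(var)) + eta**2 / omega**2
            if val < best_val:
                best, best_val = eta, val
        assert eta_hat == pytest.approx(best, abs=1e-4)


class TestFit:
    def test_noiseless_identifiability(self):
        """Zero noise, zero IIV, one free parameter: exact recovery."""
        truth = sp.PopulationModel(
            re=sp.RandomEffects(omega_cl=0.0),
            rm=sp.ResidualModel(sigma_prop=0.0, sigma_add=0.0),
        )
        spec = sp.CohortSpec(n_subjects=12, troughs_per_subject=2, seed=30)
        cohort = sp.generate_cohort(spec)
        ds = simulate_tdm(cohort, truth, spec)
        start = sp.PopulationModel(
            fe=dataclasses.replace(truth.fe, cl_pop=50.0),
            re=truth.re,
            rm=sp.ResidualModel(sigma_prop=0.0, sigma_add=0.5),
        )
        res = fit(ds, start, FitSpec(free=("cl_pop",), compute_se=False))
        assert res.estimates["cl_pop"] == pytest.approx(74.0, rel=1e-3)

    def test_ofv_never_worse_than_start(self, final_model, small_dataset):
        res = fit(small_dataset, final_model, FitSpec(compute_se=False))
        assert res.ofv <= res.ofv_start + 1e-9

    def test_nested_model_ordering(self, final_model, small_dataset):
        """Freeing an extra parameter can only lower the optimal OFV."""
        base = fit(
            small_dataset,
            final_model,
            FitSpec(free=("cl_pop", "omega_cl", "sigma_add"), compute_se=False),
        )
        wider = fit(
            small_dataset,
            base.model,
            FitSpec(
                free=("cl_pop", "omega_cl", "sigma_add", "sigma_prop"),
                compute_se=False,
            ),
        )
        assert wider.ofv <= base.ofv + 1e-6

    def test_fixing_true_covariate_effect_costs_ofv(self, final_model):
        """Data carry a real zopiclone effect; forcing theta_zop = 0 fits worse."""
        spec = sp.CohortSpec(
            n_subjects=80, troughs_per_subject=2, zop_prevalence=0.4, seed=17
        )
        ds = simulate_tdm(sp.generate_cohort(spec), final_model, spec)
        free_no_zop = ("cl_pop", "v_pop", "omega_cl", "sigma_prop", "sigma_add")
        null_model = set_params(final_model, {"theta_zop": 0.0})
        res_null = fit(ds, null_model, FitSpec(free=free_no_zop, compute_se=False))
        res_full = fit(
            ds, final_model, FitSpec(free=free_no_zop + ("theta_zop",), compute_se=False)
        )
        assert res_full.ofv < res_null.ofv - 3.84

    def test_report_table_and_json(self, final_model, small_dataset, tmp_path):
        res = fit(small_dataset, final_model, FitSpec(compute_se=False))
        table = res.report_table()
        assert set(["parameter", "estimate", "se_pct", "fixed"]) <= set(table.columns)
        assert (table[table["parameter"] == "ka"]["fixed"]).all()
        res.to_json(tmp_path / "fit.json")
        assert (tmp_path / "fit.json").exists()

    def test_standard_errors_present_when_identified(self, final_model, study_dataset):
        res = fit(study_dataset, final_model, FitSpec())
        assert res.se_pct is not None
        # clearance is the best-identified parameter on sparse troughs
        assert 0 < res.se_pct["cl_pop"] < 40.0
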