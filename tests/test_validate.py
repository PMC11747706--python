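"""Bootstrap, VPC and goodness-of-fit diagnostics."""

import numpy as np
import pandas as pd
import pytest

import sertpk as sp
from sertpk.cohort import Individual, simulate_tdm
from sertpk.estimate import FitSpec, fit, set_params
from sertpk.validate import bias_pct, bootstrap, gof, vpc

FAST = FitSpec(free=("cl_pop", "omega_cl", "sigma_prop", "sigma_add"), compute_se=False)


def _cohort(n, weight=70.0, dose_per_kg=3.0, tau=24.0):
    dose = dose_per_kg * weight * tau / 24.0
    return [
        Individual(
            sp.Subject(id=i + 1, weight_kg=weight),
            sp.Regimen(dose_mg=dose, tau_h=tau),
            dose_per_kg,
        )
        for i in range(n)
    ]


class TestBiasFormula:
    @pytest.mark.parametrize(
        "median,estimate,expected",
        [
            (886.0, 874.0, 1.37),     # volume of distribution
            (-0.550, -0.547, 0.55),   # zopiclone effect
            (74.0, 74.0, 0.0),
        ],
    )
    def test_published_bias_examples(self, median, estimate, expected):
        assert bias_pct(median, estimate) == pytest.approx(expected, abs=0.005)


class TestBootstrap:
    def test_identical_subjects_degenerate(self, final_model):
        """All subjects identical: every resample is the same dataset, so
        percentiles collapse onto the point estimate."""
        spec = sp.CohortSpec(n_subjects=1, troughs_per_subject=3, seed=5)
        one = simulate_tdm(_cohort(1), final_model, spec)
        # replicate the single subject's rows 10 times under distinct ids
        clones = one.subset_subjects([1] * 10, relabel=True)
        res = bootstrap(clones, final_model, spec=FAST, n_boot=8, seed=3)
        assert res.n_success == 8
        t = res.table.set_index("parameter")
        for p in FAST.free:
            assert t.loc[p, "ci_lo"] == pytest.approx(t.loc[p, "estimate"], rel=5e-3)
            assert t.loc[p, "ci_hi"] == pytest.approx(t.loc[p, "estimate"], rel=5e-3)
            assert abs(t.loc[p, "bias_pct"]) < 0.5

    def test_resamples_subjects_not_rows(self, small_dataset, final_model):
        res = bootstrap(small_dataset, final_model, spec=FAST, n_boot=3, seed=1)
        assert res.n_requested == 3
        assert set(res.table["parameter"]) == set(FAST.free)

    def test_invalid_n_boot(self, small_dataset, final_model):
        with pytest.raises(ValueError):
            bootstrap(small_dataset, final_model, n_boot=0)


class TestVpc:
    def test_zero_variability_bands_collapse(self):
        model = sp.PopulationModel(
            re=sp.RandomEffects(omega_cl=0.0),
            rm=sp.ResidualModel(sigma_prop=0.0, sigma_add=0.0),
        )
        spec = sp.CohortSpec(n_subjects=12, troughs_per_subject=2, seed=9)
        cohort = sp.generate_cohort(spec)
        ds = simulate_tdm(cohort, model, spec)
        res = vpc(ds, model, n_replicates=30, seed=0, bins=3)
        for _, row in res.simulated.iterrows():
            assert row["band_lo"] == pytest.approx(row["band_hi"], rel=1e-9)
        merged = res.observed.merge(
            res.simulated[res.simulated["percentile"] == 50.0], on="bin"
        )
        assert np.allclose(merged["p50"], merged["band_mid"], rtol=1e-9)

    def test_self_consistency_under_true_model(self, final_model, study_dataset):
        """Data simulated from the model: observed medians sit inside the
        simulated 95% median bands in (nearly) all bins."""
        res = vpc(study_dataset, final_model, n_replicates=300, seed=4, bins=6)
        med = res.simulated[res.simulated["percentile"] == 50.0].set_index("bin")
        inside = 0
        for _, row in res.observed.iterrows():
            b = row["bin"]
            if med.loc[b, "band_lo"] <= row["p50"] <= med.loc[b, "band_hi"]:
                inside += 1
        assert inside >= len(res.observed) - 1

    def test_misfit_detection(self, final_model, study_dataset):
        """Doubling clearance halves predictions: observed medians rise
        above the simulated median bands in most bins."""
        wrong = set_params(final_model, {"cl_pop": 148.0})
        res = vpc(study_dataset, wrong, n_replicates=200, seed=4, bins=6)
        med = res.simulated[res.simulated["percentile"] == 50.0].set_index("bin")
        above = sum(
            row["p50"] > med.loc[row["bin"], "band_hi"]
            for _, row in res.observed.iterrows()
        )
        assert above >= 4

    def test_empty_bins_reported(self, final_model, small_dataset):
        res = vpc(small_dataset, final_model, n_replicates=20, seed=1, bins=4)
        assert res.bins["n_obs"].sum() == small_dataset.n_observations

    def test_csv_export(self, final_model, small_dataset, tmp_path):
        res = vpc(small_dataset, final_model, n_replicates=20, seed=1, bins=3)
        res.to_csv(tmp_path / "vpc.csv")
        back = pd.read_csv(tmp_path / "vpc.csv")
        assert len(back) == len(res.bins)


class TestGof:
    def test_additive_only_reduction(self, final_model):
        """With sigma_prop = 0, iWRES is exactly (DV - IPRED)/sigma_add."""
        model = sp.PopulationModel(
            rm=sp.ResidualModel(sigma_prop=0.0, sigma_add=7.0)
        )
        spec = sp.CohortSpec(n_subjects=15, troughs_per_subject=2, seed=14)
        ds = simulate_tdm(sp.generate_cohort(spec), model, spec)
        res = fit(ds, model, FitSpec(free=("cl_pop", "omega_cl"), compute_se=False))
        table = gof(ds, res.model, res)
        manual = (table["dv"] - table["ipred"]) / res.model.rm.add_sd
        assert np.allclose(table["iwres"], manual)

    def test_perfect_predictions_zero_iwres(self, final_model):
        noise_free = sp.PopulationModel(
            re=sp.RandomEffects(omega_cl=0.0),
            rm=sp.ResidualModel(sigma_prop=0.0, sigma_add=0.0),
        )
        spec = sp.CohortSpec(n_subjects=8, troughs_per_subject=2, seed=2)
        cohort = sp.generate_cohort(spec)
        ds = simulate_tdm(cohort, noise_free, spec)
        res = fit(ds, final_model, FitSpec(free=("cl_pop",), compute_se=False))
        res.etas[:] = 0.0
        table = gof(ds, final_model, res)
        # typical-model predictions match the noise-free data exactly
        assert np.allclose(table["ipred"], table["dv"], rtol=1e-9)
        assert np.allclose(table["iwres"], 0.0, atol=1e-9)

    def test_iwres_standardized_under_true_model(self, final_model):
        """Rich per-subject sampling: iWRES mean ~ 0, sd ~ 1."""
        spec = sp.CohortSpec(n_subjects=30, troughs_per_subject=20, seed=3)
        ds = simulate_tdm(sp.generate_cohort(spec), final_model, spec)
        res = fit(ds, final_model, FitSpec(free=("cl_pop",), compute_se=False))
        table = gof(ds, final_model, res)
        assert np.mean(table["iwres"]) == pytest.approx(0.0, abs=0.1)
        assert np.std(table["iwres"]) == pytest.approx(1.0, abs=0.1)

    def test_zero_sd_rows_flagged(self):
        model = sp.PopulationModel(
            rm=sp.ResidualModel(sigma_prop=0.3, sigma_add=0.0)
        )
        spec = sp.CohortSpec(n_subjects=4, troughs_per_subject=1, seed=1)
        cohort = _cohort(4, dose_per_kg=0.0)  # zero dose -> zero prediction
        ds = simulate_tdm(cohort, model, spec)
        res = fit(ds, model, FitSpec(free=("cl_pop",), compute_se=False, polish=False,
                                     maxiter=3))
        table = gof(ds, model, res)
        assert table["zero_sd_flag"].all()
        assert table["iwres"].isna().all()
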