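"""Indicator coding, binomial likelihood, MLE, contrasts and bootstrap."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from frmodules import response, simulate
from frmodules.fit import (
    BootstrapEnvelope,
    ModelSpec,
    between_module_spec,
    bootstrap_fr,
    build_indicator_rows,
    contrast_table,
    fit_fr,
    nll_binomial,
    no_treatment_spec,
    predict_curve_ci,
    within_module_spec,
)
from tests.conftest import BASE_A, BASE_H, LADDER, single_cell_records


def _units(**cols):
    base = {
        "prey_species": "A_aquaticus",
        "predator_species": "G_d_celticus",
        "parasitised": False,
        "fish_present": False,
        "density": 10,
        "killed": 2,
    }
    base.update(cols)
    return pd.DataFrame([base])


class TestIndicatorRows:
    def test_base_cell_all_zero(self):
        xa, a_names, xh, h_names = build_indicator_rows(_units(), within_module_spec())
        assert xa.shape == (1, 0)  # simplified model: a is intercept-only
        assert np.all(xh == 0)
        assert len(h_names) == 7  # 3 mains + 3 two-way + 1 three-way

    def test_prey_coding_matches_convention(self):
        spec = between_module_spec()
        xa, a_names, _, _ = build_indicator_rows(
            _units(prey_species="B_rhodani"), spec
        )
        coded = dict(zip(a_names, xa[0]))
        assert coded == {
            "prey_species[Simulium]": 0.0,
            "prey_species[B_rhodani]": 1.0,
        }

    def test_interaction_indicators_are_products(self):
        spec = within_module_spec()
        rows = []
        for pred, par, fish in itertools.product(
            ("G_d_celticus", "G_pulex"), (False, True), (False, True)
        ):
            rows.append(
                _units(predator_species=pred, parasitised=par, fish_present=fish)
            )
        units = pd.concat(rows, ignore_index=True)
        _, _, xh, h_names = build_indicator_rows(units, spec)
        cols = dict(zip(h_names, xh.T))
        amph = cols["predator_species[G_pulex]"]
        par = cols["parasitised[True]"]
        fish = cols["fish_present[True]"]
        assert np.array_equal(
            cols["predator_species[G_pulex]:parasitised[True]"], amph * par
        )
        assert np.array_equal(
            cols["predator_species[G_pulex]:parasitised[True]:fish_present[True]"],
            amph * par * fish,
        )

    def test_unseen_level_named_in_error(self):
        with pytest.raises(ValueError, match="Hydra"):
            build_indicator_rows(_units(prey_species="Hydra"), between_module_spec())


class TestNLL:
    def test_single_record_half_probability(self):
        # h = 0, a = ln 2 gives kill probability exactly 1/2 at any density
        df = _units(density=2, killed=1)
        val = nll_binomial([np.log(2), 0.0], df, no_treatment_spec())
        assert val == pytest.approx(-np.log(2 * 0.25), abs=1e-12)

    def test_empty_records_zero(self):
        df = _units().iloc[:0]
        assert nll_binomial([1.0, 0.1], df, no_treatment_spec()) == 0.0

    def test_additive_over_records(self):
        r1 = _units(density=6, killed=3)
        r2 = _units(density=20, killed=5)
        both = pd.concat([r1, r2], ignore_index=True)
        theta = [0.8, 0.2]
        spec = no_treatment_spec()
        assert nll_binomial(theta, both, spec) == pytest.approx(
            nll_binomial(theta, r1, spec) + nll_binomial(theta, r2, spec)
        )

    def test_infeasible_theta_infinite(self):
        assert nll_binomial([-0.1, 0.2], _units(), no_treatment_spec()) == np.inf
        assert nll_binomial([0.5, -0.2], _units(), no_treatment_spec()) == np.inf


class TestFit:
    def test_recovery_within_three_se(self):
        df = single_cell_records(BASE_A, BASE_H, reps=40, seed=13)
        fit = fit_fr(df)
        assert fit.converged
        a_hat, h_hat = fit.theta
        assert abs(a_hat - BASE_A) < 3 * fit.se[0]
        assert abs(h_hat - BASE_H) < 3 * fit.se[1]

    def test_saturated_data_flagged(self):
        df = pd.DataFrame(
            {"density": np.repeat(LADDER, 2), "killed": np.repeat(LADDER, 2)}
        )
        fit = fit_fr(df)
        assert fit.boundary and not fit.converged

    def test_requires_two_densities(self):
        df = pd.DataFrame({"density": [10] * 8, "killed": [2] * 8})
        with pytest.raises(ValueError, match="densities"):
            fit_fr(df)

    def test_nested_model_never_beats_full(self, one_prey_scenario):
        trials, _ = simulate.simulate_dataset(one_prey_scenario)
        full = fit_fr(trials, within_module_spec(simplified_a=False))
        simplified = fit_fr(trials, within_module_spec(simplified_a=True))
        assert simplified.loglik <= full.loglik + 1e-6

    def test_base_swap_recovers_cell_values(self, one_prey_scenario):
        trials, _ = simulate.simulate_dataset(one_prey_scenario)
        spec_a = within_module_spec()
        spec_b = spec_a.with_base(predator_species="G_pulex")
        fit_a = fit_fr(trials, spec_a)
        fit_b = fit_fr(trials, spec_b)
        for pred in ("G_d_celticus", "G_pulex"):
            for fish in (False, True):
                cell = {"predator_species": pred, "fish_present": fish}
                pa = fit_a.cell_params(cell)
                pb = fit_b.cell_params(cell)
                assert pa == pytest.approx(pb, abs=1e-5)

    def test_null_effect_rarely_significant(self):
        # handling-time effect simulated at zero: |z| < 1.96 should hold at
        # roughly the nominal 95% rate
        spec = ModelSpec(h_terms=(("predator_species",),))
        n_sig = 0
        n_runs = 60
        for s in range(n_runs):
            rng = np.random.default_rng(1000 + s)
            rows = []
            for pred in ("G_d_celticus", "G_pulex"):
                for n0 in LADDER:
                    p = response.rogers_expected_eaten(BASE_A, BASE_H, n0, 1.0) / n0
                    for _ in range(8):
                        rows.append(
                            {
                                "predator_species": pred,
                                "density": n0,
                                "killed": int(rng.binomial(n0, p)),
                            }
                        )
            fit = fit_fr(pd.DataFrame(rows), spec, n_starts=2)
            if fit.se_available and abs(fit.z[2]) > 1.96:
                n_sig += 1
        # binomial(60, 0.05): > 9 false positives has probability < 1e-3
        assert n_sig <= 9

    def test_bias_shrinks_with_replication(self):
        errs = {}
        for reps in (4, 64):
            errors = []
            for s in range(20):
                df = single_cell_records(BASE_A, BASE_H, reps=reps, seed=2000 + s)
                fit = fit_fr(df, n_starts=2)
                errors.append(abs(fit.theta[0] - BASE_A) + abs(fit.theta[1] - BASE_H))
            errs[reps] = np.mean(errors)
        assert errs[64] < errs[4]


class TestContrasts:
    def test_published_intercept_arithmetic(self):
        # printed attack-rate intercept 0.992 with SE 0.155 implies z = 6.40,
        # matching the printed 6.399 to table rounding
        z = 0.992 / 0.155
        assert abs(z - 6.399) < 0.0065

    def test_z_to_p_normal_quantile(self):
        df = single_cell_records(BASE_A, BASE_H, reps=20, seed=17)
        fit = fit_fr(df)
        table = contrast_table(fit)
        for _, row in table.iterrows():
            assert row["P"] == pytest.approx(
                2 * stats.norm.sf(abs(row["z value"])), abs=1e-12
            )
        assert 2 * stats.norm.sf(1.959964) == pytest.approx(0.0500, abs=1e-4)

    def test_group_level_contrast_matches_delta_method(self, one_prey_scenario):
        trials, _ = simulate.simulate_dataset(one_prey_scenario)
        fit = fit_fr(trials, ModelSpec(h_terms=(("predator_species",),)))
        # group-level handling time for the invasive amphipod: intercept + effect
        c = np.array([0.0, 1.0, 1.0])
        [row] = contrast_table(fit, contrasts=[("h G_pulex", c)]).to_dict("records")
        assert row["Estimate"] == pytest.approx(fit.theta[1] + fit.theta[2])
        assert row["SE"] == pytest.approx(float(np.sqrt(c @ fit.cov @ c)))

    def test_weight_length_mismatch(self):
        df = single_cell_records(BASE_A, BASE_H, reps=8, seed=18)
        fit = fit_fr(df)
        with pytest.raises(ValueError, match="weights"):
            contrast_table(fit, contrasts=[("bad", [1.0])])

    def test_three_decimal_formatting(self):
        df = single_cell_records(BASE_A, BASE_H, reps=8, seed=19)
        table = contrast_table(fit_fr(df), decimals=3)
        assert (table["Estimate"] == table["Estimate"].round(3)).all()


@pytest.fixture(scope="module")
def fitted():
    df = single_cell_records(BASE_A, BASE_H, reps=4, seed=23)
    fit = fit_fr(df)
    env = bootstrap_fr(df, no_treatment_spec(), n_boot=200, seed=29, base_fit=fit)
    return df, fit, env


class TestBootstrap:
    def test_same_seed_identical_envelope(self, fitted):
        df, fit, env = fitted
        env2 = bootstrap_fr(df, no_treatment_spec(), n_boot=200, seed=29, base_fit=fit)
        assert np.array_equal(env.lower, env2.lower)
        assert np.array_equal(env.upper, env2.upper)
        assert np.array_equal(env.draws, env2.draws)

    def test_envelope_contains_point_prediction(self, fitted):
        df, fit, env = fitted
        a, h = fit.cell_params({})
        preds = np.array(
            [response.rogers_expected_eaten(a, h, n0, 1.0) for n0 in env.grid]
        )
        inside = (env.lower <= preds + 1e-9) & (preds <= env.upper + 1e-9)
        assert inside.mean() >= 0.95
        assert np.all(env.lower <= env.upper)

    def test_bookkeeping(self, fitted):
        _, _, env = fitted
        assert env.n_kept == env.n_boot - env.n_failed == len(env.draws)

    def test_width_shrinks_with_replication(self):
        widths = {}
        for reps in (4, 8):
            wins = 0
            for s in range(8):
                df = single_cell_records(BASE_A, BASE_H, reps=reps, seed=3000 + s)
                env = bootstrap_fr(df, no_treatment_spec(), n_boot=120, seed=s)
                widths.setdefault(reps, []).append(env.upper - env.lower)
        mean4 = np.mean(widths[4], axis=0)
        mean8 = np.mean(widths[8], axis=0)
        assert np.all(mean8 < mean4)

    def test_predict_curve_consistent_with_direct_calls(self, fitted):
        df, fit, env = fitted
        table = predict_curve_ci(fit, env)
        a, h = fit.cell_params({})
        for _, row in table.iterrows():
            assert row["mean"] == pytest.approx(
                response.rogers_expected_eaten(a, h, row["density"], 1.0)
            )

    def test_collapsed_band_flagged(self, fitted):
        df, fit, env = fitted
        frozen = dataclasses.replace(env, draws=np.repeat(env.draws[:1], 5, axis=0))
        table = predict_curve_ci(fit, frozen)
        assert table["collapsed"].all()

    def test_positive_grid_required(self, fitted):
        df, fit, env = fitted
        with pytest.raises(ValueError, match="positive"):
            predict_curve_ci(fit, env, grid=[0.0, 5.0])

    def test_stratification_preserves_layout(self, one_prey_scenario):
        trials, _ = simulate.simulate_dataset(one_prey_scenario)
        trials = trials[trials["density"].isin([10, 20, 30])]
        env = bootstrap_fr(trials, within_module_spec(), n_boot=12, seed=31)
        assert env.n_kept + env.n_failed == 12
        assert np.all(env.lower <= env.upper)
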