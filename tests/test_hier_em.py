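"""Hierarchical EM fitting, iBIC, and parameter hypothesis tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import riskshift as rs
from riskshift import hier_em as he


def _simulated_table(spec, alphas=None, betas=None, seed=0, n_blocks=1, **extra):
    rng = np.random.default_rng(seed)
    n = len(alphas if alphas is not None else betas)
    params = []
    for i in range(n):
        kw = dict(extra)
        if alphas is not None:
            kw["alpha"] = alphas[i]
        if betas is not None:
            kw["beta"] = betas[i]
        params.append(rs.UtilityParams(**kw))
    scheds = [
        rs.ExperimentDesign(
            2, "IPI",
            tuple(rs.generate_block(rs.build_environment("intermediate"), rng, b + 1)
                  for b in range(n_blocks)),
        )
        for _ in range(n)
    ]
    return rs.simulate_choices(spec, params, scheds, rng)


def test_excluded_parameters_are_fixed_at_one():
    spec = rs.ModelSpec("multiplicative", include_lambda=True, include_gamma=False)
    assert spec.free_parameters == ("beta", "lam")
    # gamma is ignored in the likelihood when excluded
    p1 = rs.UtilityParams(beta=1.0, lam=0.8, gamma=1.0)
    p2 = rs.UtilityParams(beta=1.0, lam=0.8, gamma=3.0)
    assert rs.utility(spec, p1, 30, 0.5) == rs.utility(spec, p2, 30, 0.5)


def test_single_participant_map_matches_grid_search_ml():
    """With a near-flat prior the MAP coincides with a brute-force ML grid fit."""
    spec = rs.ModelSpec("risk_return")
    table = _simulated_table(spec, alphas=[1.8e-2], betas=[0.5], seed=3, n_blocks=10)
    m, p, y = he.participant_trial_arrays(table)[1]
    flat = {"beta": ("gamma", 1.0, 0.01), "alpha": ("normal", 0.0, 100.0)}
    best = None
    for a in np.linspace(0.005, 0.03, 51):
        for b in np.linspace(0.1, 1.2, 56):
            ll = he.log_likelihood(spec, rs.UtilityParams(alpha=a, beta=b), m, p, y)
            if best is None or ll > best[0]:
                best = (ll, a, b)
    x0 = he._best_start(spec, flat, m, p, y)
    res = optimize.minimize(
        he._neg_map_objective, x0, args=(spec, flat, m, p, y),
        method="L-BFGS-B", bounds=[he._BOUNDS[n] for n in spec.free_parameters],
    )
    beta_hat, alpha_hat = res.x
    assert alpha_hat == pytest.approx(best[1], abs=0.0008)  # within grid resolution
    assert beta_hat == pytest.approx(best[2], abs=0.04)


def test_hierarchical_fit_recovers_population_location():
    rng = np.random.default_rng(5)
    n = 24
    alphas = rng.normal(1.8e-2, 0.3e-2, n)
    betas = rng.gamma(25.0, 0.5 / 25.0, n)
    spec = rs.ModelSpec("risk_return")
    table = _simulated_table(spec, alphas=alphas, betas=betas, seed=5, n_blocks=2)
    fit = rs.fit_hierarchical(spec, table, seed=0, n_e_samples=1500)
    assert fit.converged
    assert fit.prior_mean("alpha") == pytest.approx(alphas.mean(), abs=1.5e-3)
    assert fit.prior_mean("beta") == pytest.approx(betas.mean(), abs=0.08)
    # per-participant surface: one estimate and sd per free parameter
    assert set(fit.estimates.parameter) == set(spec.free_parameters)
    assert len(fit.estimates) == n * len(spec.free_parameters)
    assert (fit.estimates.sd > 0).all()


def test_prior_mean_invariant_to_participant_relabeling():
    rng = np.random.default_rng(6)
    spec = rs.ModelSpec("risk_return")
    alphas = rng.normal(1.8e-2, 0.3e-2, 10)
    table = _simulated_table(spec, alphas=alphas, betas=[0.5] * 10, seed=6)
    fit1 = rs.fit_hierarchical(spec, table, seed=1, n_e_samples=800)
    relabeled = table.copy()
    relabeled["participant_id"] = 11 - relabeled["participant_id"]
    fit2 = rs.fit_hierarchical(spec, relabeled, seed=1, n_e_samples=800)
    assert fit1.prior_mean("alpha") == pytest.approx(fit2.prior_mean("alpha"), rel=1e-9)


def test_ibic_penalty_formula():
    spec = rs.ModelSpec("risk_return")
    table = _simulated_table(spec, alphas=[1.5e-2] * 4, betas=[0.5] * 4, seed=7)
    fit = rs.fit_hierarchical(spec, table, seed=0, n_e_samples=500, max_iter=30)
    val = rs.ibic(fit, table, n_prior_samples=400, seed=0)
    assert val == pytest.approx(
        -2.0 * fit.log_marginal + fit.n_hyperparameters * np.log(fit.n_observations)
    )
    # two hyperparameters per free model parameter
    assert fit.n_hyperparameters == 4


def test_candidate_set_and_tie_breaking():
    specs = rs.candidate_model_specs()
    assert len(specs) == 18
    fits = [
        he.HierFit(rs.ModelSpec("risk_return"), pd.DataFrame(), {}, True, 1, 10, 0.0,
                   ibic=100.0),
        he.HierFit(rs.ModelSpec("additive"), pd.DataFrame(), {}, True, 1, 10, 0.0,
                   ibic=100.0),
    ]
    ranked = rs.compare_models(fits)
    assert ranked.iloc[0].n_hyperparameters < ranked.iloc[1].n_hyperparameters
    assert ranked.delta_ibic.iloc[0] == 0.0
    with pytest.raises(ValueError, match="ibic"):
        rs.compare_models([he.HierFit(rs.ModelSpec(), pd.DataFrame(), {}, True, 1, 10, 0.0)])


def test_parameter_hypothesis_tests():
    rng = np.random.default_rng(8)
    a = rng.normal(0.02, 0.004, 60)
    b = rng.normal(0.016, 0.004, 60)
    t, p = rs.parameter_hypothesis_tests(a, b, alternative="greater", m_tests=3)
    assert t > 0 and p < 0.05
    # Bonferroni multiplies the raw p
    _, p1 = rs.parameter_hypothesis_tests(a, b, alternative="greater", m_tests=1)
    assert p == pytest.approx(min(3 * p1, 1.0))
    # identical populations: non-significant
    c = rng.normal(0.02, 0.004, 60)
    _, p_null = rs.parameter_hypothesis_tests(a, c, alternative="greater")
    assert p_null > 0.05 or abs(a.mean() - c.mean()) > 0
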