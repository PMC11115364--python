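"""Hierarchical expectation-maximization fitting and iBIC model comparison.

Each participant's analyzed choices in one environment are fitted with a
decision model (see :mod:`riskshift.models`) under group-level prior
distributions: beta, gamma and lambda carry gamma priors, alpha a normal
prior, w_p a beta prior, and eta a beta prior affinely mapped to [-1, 1].
The E-step computes each participant's posterior moments by importance
weighting a shared set of prior draws (common random numbers across
iterations, via the prior quantile functions); the M-step moment-matches
the prior hyperparameters to the averaged posterior moments. Iteration
stops when the summed log marginal-likelihood estimate changes by less
than a relative tolerance. A final pass reports per-participant MAP
estimates (box-constrained quasi-Newton in the natural parameter space)
with diagonal-Laplace standard deviations under the fitted prior.

Model comparison uses the integrated Bayesian Information Criterion:

    iBIC = -2 * sum_i log p(data_i | fitted prior) + k_hyper * log(n_obs),

where the per-participant marginal likelihood is a Monte-Carlo average of
the data likelihood over draws from the fitted prior, and k_hyper counts
two hyperparameters per free model parameter. Lower is better; ties rank
the model with fewer hyperparameters first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp

from .models import ModelSpec, UtilityParams, choice_probability
from .task import SURE_MAGNITUDE, MAGNITUDES

_EPS = 1e-12
MAX_MAGNITUDE = max(MAGNITUDES)

# box constraints per parameter (natural space)
_BOUNDS = {
    "beta": (1e-4, 50.0),
    "alpha": (-1.0, 1.0),
    "lam": (0.02, 10.0),
    "gamma": (0.02, 10.0),
    "w_p": (1e-4, 1.0 - 1e-4),
    "eta": (-1.0 + 1e-4, 1.0 - 1e-4),
}

# broad initial hyperparameters: gamma(1, 0.1), normal(0, 10), beta(1, 1)
_INITIAL_PRIORS = {
    "beta": ("gamma", 1.0, 0.1),
    "alpha": ("normal", 0.0, 10.0),
    "lam": ("gamma", 1.0, 0.1),
    "gamma": ("gamma", 1.0, 0.1),
    "w_p": ("beta", 1.0, 1.0),
    "eta": ("beta_pm1", 1.0, 1.0),
}

# coarse initialization grids; the choice likelihood is multimodal in
# (alpha, beta), so the first E-step starts each optimization from the best
# grid point instead of a fixed guess
_START_GRID = {
    "beta": (0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 3.0),
    "alpha": (-0.05, -0.02, 0.0, 0.01, 0.02, 0.05),
    "lam": (0.3, 0.7, 1.0, 1.5),
    "gamma": (0.3, 0.7, 1.0, 1.5),
    "w_p": (0.2, 0.5, 0.8),
    "eta": (-0.5, 0.0, 0.5),
}


def _log_prior(name: str, prior: tuple, x: float | np.ndarray):
    family, h1, h2 = prior
    if family == "gamma":
        return stats.gamma.logpdf(x, a=h1, scale=1.0 / h2)
    if family == "normal":
        return stats.norm.logpdf(x, loc=h1, scale=h2)
    if family == "beta":
        return stats.beta.logpdf(x, h1, h2)
    if family == "beta_pm1":
        return stats.beta.logpdf((np.asarray(x) + 1.0) / 2.0, h1, h2) - np.log(2.0)
    raise ValueError(f"unknown prior family {family!r}")


def _sample_prior(name: str, prior: tuple, size: int, rng: np.random.Generator):
    family, h1, h2 = prior
    if family == "gamma":
        return rng.gamma(h1, 1.0 / h2, size)
    if family == "normal":
        return rng.normal(h1, h2, size)
    if family == "beta":
        return rng.beta(h1, h2, size)
    if family == "beta_pm1":
        return 2.0 * rng.beta(h1, h2, size) - 1.0
    raise ValueError(f"unknown prior family {family!r}")


def _moments_to_prior(family: str, m1: float, m2: float) -> tuple:
    """Convert (E[x], E[x^2]) into the family's hyperparameters."""
    var = max(m2 - m1**2, 1e-12)
    if family == "normal":
        return ("normal", m1, float(np.sqrt(var)))
    if family == "gamma":
        m1 = max(m1, 1e-8)
        return ("gamma", m1**2 / var, m1 / var)
    if family in ("beta", "beta_pm1"):
        if family == "beta_pm1":
            m1, var = (m1 + 1.0) / 2.0, var / 4.0
        m1 = float(np.clip(m1, 1e-4, 1.0 - 1e-4))
        nu = m1 * (1.0 - m1) / var - 1.0
        if nu <= 0:  # variance too large for a proper beta; fall back to uniform
            return (family if family == "beta" else "beta_pm1", 1.0, 1.0)
        fam = "beta" if family == "beta" else "beta_pm1"
        return (fam, m1 * nu, (1.0 - m1) * nu)
    raise ValueError(family)


def participant_trial_arrays(
    table: pd.DataFrame, environment: str | None = None
) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-participant (magnitude, probability, accept) arrays of analyzed choices."""
    sub = table[table["analyzed"] & (table["choice"] != "missing")]
    if environment is not None:
        sub = sub[sub["environment"] == environment]
    out = {}
    for pid, g in sub.groupby("participant_id", sort=True):
        out[int(pid)] = (
            g["magnitude"].to_numpy(float),
            g["probability"].to_numpy(float),
            (g["choice"] == "accept").to_numpy(float),
        )
    return out


def _params_from_vector(spec: ModelSpec, x: np.ndarray) -> UtilityParams:
    return UtilityParams(**dict(zip(spec.free_parameters, x)))


def log_likelihood(spec: ModelSpec, params: UtilityParams,
                   m: np.ndarray, p: np.ndarray, y: np.ndarray) -> float:
    pc = np.clip(choice_probability(spec, params, m=m, p=p), _EPS, 1.0 - _EPS)
    return float(np.sum(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc)))


def _neg_map_objective(x, spec, priors, m, p, y) -> float:
    try:
        params = _params_from_vector(spec, x)
    except ValueError:
        return 1e10
    ll = log_likelihood(spec, params, m, p, y)
    lp = sum(float(_log_prior(n, priors[n], v)) for n, v in zip(spec.free_parameters, x))
    if not np.isfinite(ll + lp):
        return 1e10
    return -(ll + lp)


def _hessian_diag(f, x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Diagonal of the numerical Hessian by central second differences."""
    f0 = f(x)
    d = np.empty_like(x)
    for j in range(x.size):
        e = np.zeros_like(x)
        e[j] = h[j]
        d[j] = (f(x + e) - 2.0 * f0 + f(x - e)) / h[j] ** 2
    return d


def _best_start(spec: ModelSpec, priors: dict, m, p, y) -> np.ndarray:
    """Best point of a coarse product grid under the penalized objective."""
    names = spec.free_parameters
    grids = np.meshgrid(*[_START_GRID[n] for n in names], indexing="ij")
    samples = {n: g.ravel() for n, g in zip(names, grids)}
    ll = _loglik_samples(spec, samples, m, p, y)
    lp = np.zeros_like(ll)
    for n in names:
        lp += np.asarray(_log_prior(n, priors[n], samples[n]))
    j = int(np.argmax(ll + lp))
    return np.array([samples[n][j] for n in names])


@dataclass
class HierFit:
    spec: ModelSpec
    estimates: pd.DataFrame           # participant, parameter, estimate, sd
    priors: dict[str, tuple]
    converged: bool
    n_iter: int
    n_observations: int
    objective: float                  # summed log marginal-likelihood estimate at convergence
    log_marginal: float | None = None
    ibic: float | None = None

    @property
    def n_hyperparameters(self) -> int:
        return 2 * len(self.spec.free_parameters)

    def prior_mean(self, name: str) -> float:
        family, h1, h2 = self.priors[name]
        if family == "gamma":
            return h1 / h2
        if family == "normal":
            return h1
        if family == "beta":
            return h1 / (h1 + h2)
        if family == "beta_pm1":
            return 2.0 * h1 / (h1 + h2) - 1.0
        raise ValueError(family)

    def participant_estimates(self, name: str) -> pd.Series:
        sub = self.estimates[self.estimates["parameter"] == name]
        return sub.set_index("participant_id")["estimate"]


def _quantile_samples(name: str, prior: tuple, u: np.ndarray) -> np.ndarray:
    """Prior samples via the quantile transform of fixed uniforms."""
    family, h1, h2 = prior
    if family == "gamma":
        return stats.gamma.ppf(u, a=h1, scale=1.0 / h2)
    if family == "normal":
        return stats.norm.ppf(u, loc=h1, scale=h2)
    if family == "beta":
        return stats.beta.ppf(u, h1, h2)
    if family == "beta_pm1":
        return 2.0 * stats.beta.ppf(u, h1, h2) - 1.0
    raise ValueError(family)


def fit_hierarchical(
    spec: ModelSpec,
    table: pd.DataFrame,
    environment: str | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    seed: int = 0,
    n_e_samples: int = 3_000,
) -> HierFit:
    """Fit the model to each participant's analyzed choices under EM-updated priors.

    The E-step computes each participant's posterior moments by importance
    weighting a shared set of prior draws (common random numbers across
    iterations, so the marginal-likelihood objective is smooth in the
    hyperparameters); the M-step moment-matches the group prior. The prior is
    initialized by moment-matching coarse-grid best fits per participant. A
    final pass reports per-participant MAP estimates with diagonal-Laplace
    standard deviations under the fitted prior.
    """
    data = participant_trial_arrays(table, environment)
    if len(data) < 2:
        raise ValueError("hierarchical fitting needs at least 2 participants")
    names = spec.free_parameters
    pids = sorted(data)
    bounds = [_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)
    u = rng.random((len(names), n_e_samples))
    # initial prior from coarse-grid fits (variance doubled to stay permissive)
    init_priors = {n: _INITIAL_PRIORS[n] for n in names}
    starts = np.array([_best_start(spec, init_priors, *data[pid]) for pid in pids])
    priors = {}
    for j, n in enumerate(names):
        m1 = float(starts[:, j].mean())
        var = max(float(starts[:, j].var()), 1e-10) * 2.0
        priors[n] = _moments_to_prior(_INITIAL_PRIORS[n][0], m1, m1**2 + var)
    prev_obj = -np.inf
    converged = False
    n_obs = sum(len(v[0]) for v in data.values())
    it = 0
    post_m1 = np.empty((len(pids), len(names)))
    for it in range(1, max_iter + 1):
        samples = {n: _quantile_samples(n, priors[n], u[j]) for j, n in enumerate(names)}
        smat = np.column_stack([samples[n] for n in names])
        total = 0.0
        post_m2 = np.empty_like(post_m1)
        for i, pid in enumerate(pids):
            ll = _loglik_samples(spec, samples, *data[pid])
            lse = logsumexp(ll)
            total += lse - np.log(n_e_samples)
            w = np.exp(ll - lse)
            post_m1[i] = w @ smat
            post_m2[i] = w @ smat**2
        for j, n in enumerate(names):
            priors[n] = _moments_to_prior(
                _INITIAL_PRIORS[n][0], float(post_m1[:, j].mean()), float(post_m2[:, j].mean())
            )
        if np.isfinite(prev_obj) and abs(total - prev_obj) < tol * max(abs(prev_obj), 1.0):
            converged = True
            prev_obj = total
            break
        prev_obj = total
    # final per-participant MAP + diagonal Laplace under the fitted prior
    rows = []
    for i, pid in enumerate(pids):
        m, p, y = data[pid]
        x0 = np.clip(post_m1[i], [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _neg_map_objective, x0, args=(spec, priors, m, p, y),
            method="L-BFGS-B", bounds=bounds,
        )
        h = np.maximum(1e-4 * np.maximum(np.abs(res.x), 1.0), 1e-6)
        hd = _hessian_diag(lambda v: _neg_map_objective(v, spec, priors, m, p, y), res.x, h)
        var = np.where(hd > 1e-8, 1.0 / np.maximum(hd, 1e-8), 1.0)
        for j, n in enumerate(names):
            rows.append({"participant_id": pid, "parameter": n,
                         "estimate": float(res.x[j]), "sd": float(np.sqrt(var[j]))})
    return HierFit(spec, pd.DataFrame(rows), priors, converged, it, n_obs, float(prev_obj))


def _loglik_samples(spec: ModelSpec, samples: dict[str, np.ndarray],
                    m: np.ndarray, p: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Log-likelihood of one participant's data for S prior samples (vectorized)."""
    S = len(next(iter(samples.values())))
    ones = np.ones(S)
    beta = samples.get("beta", ones)
    lam = samples.get("lam", ones)[:, None]
    gam = samples.get("gamma", ones)
    if spec.family == "risk_return":
        alpha = samples.get("alpha", np.zeros(S))[:, None]
        du = (m * p - SURE_MAGNITUDE)[None, :] - alpha * (m**2 * p * (1.0 - p))[None, :]
    else:
        # Prelec weights per (sample, trial)
        with np.errstate(divide="ignore"):
            neglogp = -np.log(np.clip(p, _EPS, 1.0))
        pi = np.exp(-np.power(neglogp[None, :], gam[:, None]))
        pi = np.where(p[None, :] >= 1.0, 1.0, pi)
        pi_sure = np.ones((S, 1))
        if spec.family == "multiplicative":
            u = np.power(m[None, :], lam) * pi
            u_sure = np.power(float(SURE_MAGNITUDE), lam) * pi_sure
        else:
            w = samples.get("w_p", 0.5 * ones)[:, None]
            v = np.power(m[None, :], lam) / np.power(MAX_MAGNITUDE, lam)
            v_sure = np.power(float(SURE_MAGNITUDE), lam) / np.power(MAX_MAGNITUDE, lam)
            u = (1.0 - w) * v + w * pi
            u_sure = (1.0 - w) * v_sure + w * pi_sure
        du = u - u_sure
    pc = 1.0 / (1.0 + np.exp(-np.clip(beta[:, None] * du, -700, 700)))
    if spec.rule == "approach_avoidance":
        eta = samples.get("eta", np.zeros(S))[:, None]
        pc = np.where(eta >= 0, (1.0 - eta) * pc + eta, (1.0 + eta) * pc)
    pc = np.clip(pc, _EPS, 1.0 - _EPS)
    return np.sum(y[None, :] * np.log(pc) + (1.0 - y[None, :]) * np.log(1.0 - pc), axis=1)


def ibic(
    fit: HierFit,
    table: pd.DataFrame,
    environment: str | None = None,
    n_prior_samples: int = 2_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo iBIC of a fitted model on its data (lower is better)."""
    rng = np.random.default_rng(seed)
    names = fit.spec.free_parameters
    samples = {n: _sample_prior(n, fit.priors[n], n_prior_samples, rng) for n in names}
    # keep sampled values inside the model's admissible box
    for n in names:
        lo, hi = _BOUNDS[n]
        samples[n] = np.clip(samples[n], lo, hi)
    data = participant_trial_arrays(table, environment)
    log_marg = 0.0
    for pid, (m, p, y) in data.items():
        ll = _loglik_samples(fit.spec, samples, m, p, y)
        log_marg += logsumexp(ll) - np.log(n_prior_samples)
    fit.log_marginal = float(log_marg)
    fit.ibic = float(-2.0 * log_marg + fit.n_hyperparameters * np.log(fit.n_observations))
    return fit.ibic


def candidate_model_specs(rules: tuple[str, ...] = ("sigmoid", "approach_avoidance")) -> list[ModelSpec]:
    """The 18 candidate models: risk-return + 4 multiplicative + 4 additive per rule."""
    specs = []
    for rule in rules:
        specs.append(ModelSpec("risk_return", rule=rule))
        for family in ("multiplicative", "additive"):
            for inc_l in (False, True):
                for inc_g in (False, True):
                    specs.append(ModelSpec(family, inc_l, inc_g, rule))
    return specs


def compare_models(fits: list[HierFit]) -> pd.DataFrame:
    """Rank fitted models by iBIC (ascending); ties favor fewer hyperparameters."""
    if any(f.ibic is None for f in fits):
        raise ValueError("compute ibic() for every fit before comparing")
    rows = [
        {"model": f.spec.label, "ibic": f.ibic,
         "n_hyperparameters": f.n_hyperparameters}
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values(
        ["ibic", "n_hyperparameters"], kind="stable"
    ).reset_index(drop=True)
    out["delta_ibic"] = out["ibic"] - out["ibic"].iloc[0]
    return out


def parameter_hypothesis_tests(
    estimates_a: np.ndarray,
    estimates_b: np.ndarray,
    alternative: str = "greater",
    m_tests: int = 1,
) -> tuple[float, float]:
    """One-tailed unpaired t-test on per-participant estimates, Bonferroni-corrected."""
    t, p = stats.ttest_ind(np.asarray(estimates_a, float),
                           np.asarray(estimates_b, float),
                           alternative=alternative)
    return float(t), float(min(p * m_tests, 1.0))
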