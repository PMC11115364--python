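"""Trial-table file format, run configuration, and the end-to-end pipeline.

The shared long-format trial CSV has one row per presented trial:

    participant_id, group, experiment, block_index, trial_index, environment,
    magnitude, probability, catch_type, analyzed, choice, outcome

with 1-based contiguous trial indices per participant, choice in
{accept, reject, missing}, and outcome empty for missing responses. Reads are
schema-validated and name the first offending row/column on failure.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .task import GROUP_ENVIRONMENTS, build_environment

COLUMNS = (
    "participant_id", "group", "experiment", "block_index", "trial_index",
    "environment", "magnitude", "probability", "catch_type", "analyzed",
    "choice", "outcome",
)
_CHOICES = {"accept", "reject", "missing"}
_CATCH = {"none", "always_reject", "always_accept"}
_ENVS = {"poor", "intermediate", "rich"}


class SchemaError(ValueError):
    """A trial table violated the file schema."""


def write_trial_table(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, list(COLUMNS)].to_csv(path, index=False)


def _check_enum(table: pd.DataFrame, col: str, allowed: set) -> None:
    bad = ~table[col].isin(allowed)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise SchemaError(
            f"column {col!r}, row {row}: invalid value {table[col].iloc[row]!r} "
            f"(allowed: {sorted(allowed)})"
        )


def read_trial_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trial CSV."""
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty trial table") from None
    if table.empty:
        raise SchemaError(f"{path}: empty trial table")
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    _check_enum(table, "choice", _CHOICES)
    _check_enum(table, "catch_type", _CATCH)
    _check_enum(table, "environment", _ENVS)
    _check_enum(table, "group", set(GROUP_ENVIRONMENTS))
    table["analyzed"] = table["analyzed"].astype(bool)
    for pid, g in table.groupby("participant_id"):
        idx = np.sort(g["trial_index"].to_numpy())
        if idx[0] != 1 or np.any(np.diff(idx) != 1):
            raise SchemaError(
                f"column 'trial_index': participant {pid} indices are not "
                "1-based and contiguous"
            )
    missing_choice = table["choice"] == "missing"
    if table.loc[missing_choice, "outcome"].notna().any():
        row = int(np.flatnonzero(missing_choice & table["outcome"].notna())[0])
        raise SchemaError(f"column 'outcome', row {row}: outcome present for a missing choice")
    return table[list(COLUMNS)]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; every stochastic stage is seeded."""

    seed: int
    groups: tuple[str, ...] = ("PR", "RP", "IPI", "IRI")
    n_per_group: int = 120
    scale: str = "smoke"                  # smoke | full
    bootstrap_B: int = 9_999
    em: dict = field(default_factory=lambda: {"max_iter": 200, "tol": 1e-4})
    pf: dict = field(default_factory=lambda: {"n_particles": 10_000, "lag": 20})

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required")
        if self.scale not in ("smoke", "full"):
            raise ValueError(f"scale must be smoke or full, got {self.scale!r}")
        unknown = set(self.groups) - set(GROUP_ENVIRONMENTS)
        if unknown:
            raise ValueError(f"unknown group(s) {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError(f"{path}: configuration lacks the required 'seed' key")
        if "groups" in raw:
            raw["groups"] = tuple(raw["groups"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["groups"] = list(self.groups)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def reproduce_all(config: RunConfig, outdir: str | Path) -> Path:
    """Run the full pipeline and write tidy outputs plus a run log.

    Stages: cohort generation, exclusions, descriptives, bootstrap tests,
    hierarchical fits, particle filter, regression, forward simulations, and
    fitness curves. Any stage failure halts with the stage name; outputs
    written before the failure persist.
    """
    from . import bootstrap, cohort, descriptive, fitness, hier_em, regression, statespace
    from .models import ModelSpec

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    smoke = config.scale == "smoke"
    n_per = min(config.n_per_group, 24) if smoke else config.n_per_group
    B = min(config.bootstrap_B, 999) if smoke else config.bootstrap_B
    log = {"seed": config.seed, "scale": config.scale, "python": platform.python_version(),
           "numpy": np.__version__, "pandas": pd.__version__, "stages": []}
    stage = "cohort"
    try:
        cfg = cohort.CohortConfig(n_per_group=n_per)
        table, truth = cohort.generate_cohort(cfg, tuple(config.groups), seed=config.seed)
        write_trial_table(table, out / "cohort.csv")
        truth.to_csv(out / "cohort_truth.csv", index=False)
        with open(out / "cohort_truth_params.json", "w") as fh:
            json.dump({k: v for k, v in truth.attrs.items()}, fh, indent=2)
        log["stages"].append(stage)

        stage = "exclusions"
        kept, report = descriptive.apply_exclusions(table)
        report.assign(reasons=report["reasons"].map(";".join)).to_csv(
            out / "exclusions.csv", index=False
        )
        write_trial_table(kept, out / "cohort_kept.csv")
        log["stages"].append(stage)

        stage = "descriptives"
        descriptive.pooled_acceptance(kept, by=["group", "block_index", "environment"]).to_csv(
            out / "acceptance_by_block.csv", index=False
        )
        descriptive.moving_average_acceptance(kept).to_csv(
            out / "acceptance_moving_average.csv", index=False
        )
        log["stages"].append(stage)

        stage = "bootstrap_tests"
        tests = []
        exp1 = [g for g in ("PR", "RP") if g in config.groups]
        if len(exp1) == 2:
            first = kept[kept["block_index"] == 1]
            res = bootstrap.one_tailed_diff_test(
                first[first["group"] == "PR"], first[first["group"] == "RP"],
                B=B, seed=config.seed,
            )
            tests.append({"contrast": "PR_vs_RP_first_block", "D": res.observed,
                          "p": res.p_value, "ci_low": res.ci_low, "ci_high": res.ci_high,
                          "B": res.B, "seed": config.seed})
        if tests:
            pd.DataFrame(tests).to_csv(out / "bootstrap_tests.csv", index=False)
        log["stages"].append(stage)

        stage = "hierarchical_fit"
        spec = ModelSpec("risk_return", rule="sigmoid")
        fits = []
        for env in sorted(kept["environment"].unique()):
            fit = hier_em.fit_hierarchical(spec, kept, environment=env,
                                           seed=config.seed, **config.em)
            hier_em.ibic(fit, kept, environment=env,
                         n_prior_samples=500 if smoke else 2000, seed=config.seed)
            fits.append((env, fit))
        pd.concat(
            [f.estimates.assign(environment=env) for env, f in fits], ignore_index=True
        ).to_csv(out / "hier_estimates.csv", index=False)
        pd.DataFrame(
            [{"environment": env, "model": f.spec.label, "ibic": f.ibic} for env, f in fits]
        ).to_csv(out / "hier_ibic.csv", index=False)
        log["stages"].append(stage)

        stage = "particle_filter"
        group = config.groups[0]
        arrays = statespace.table_to_arrays(kept, group=group)
        pf_cfg = statespace.StateSpaceConfig(
            n_particles=1_000 if smoke else config.pf["n_particles"],
            lag=config.pf["lag"], seed=config.seed,
        )
        sg = np.logspace(-5, -2, 5 if smoke else 50)
        bg = np.linspace(0.1, 1.0, 5 if smoke else 50)
        best_cfg, traj, surface = statespace.grid_search(*arrays, sg, bg, pf_cfg)
        traj.to_csv(out / f"pf_trajectory_{group}.csv", index=False)
        surface.to_csv(out / f"pf_surface_{group}.csv", index=False)
        log["pf_best"] = {"sigma": best_cfg.sigma, "beta": best_cfg.beta}
        log["stages"].append(stage)

        stage = "regression"
        exp_tables = {e: kept[kept["experiment"] == e] for e in sorted(kept["experiment"].unique())}
        for e, sub in exp_tables.items():
            matrix = regression.build_regressors(sub)
            fit = regression.fit_logistic(matrix, bootstrap_B=0)
            fit.coefficients.rename("coefficient").to_csv(out / f"regression_exp{e}.csv")
            regression.vif(matrix).rename("vif").to_csv(out / f"vif_exp{e}.csv")
            stage = "simulation"
            groups_e = tuple(g for g in config.groups
                             if {1: ("PR", "RP"), 2: ("IPI", "IRI")}[e].count(g))
            sim1 = regression.simulate_from_fit(fit, groups_e, n_per, seed=config.seed)
            write_trial_table(sim1, out / f"simulation1_exp{e}.csv")
            reduced = tuple(r for r in matrix.regressors if r not in ("dp_c", "dp_p"))
            fit2 = regression.fit_logistic(matrix, reduced)
            sim2 = regression.simulate_from_fit(fit2, groups_e, n_per, seed=config.seed)
            write_trial_table(sim2, out / f"simulation2_exp{e}.csv")
            stage = "regression"
        log["stages"].append("regression")

        stage = "fitness"
        rng = np.random.default_rng(config.seed)
        curves = []
        for env_name in ("poor", "rich"):
            env = build_environment(env_name)
            curves.append(
                fitness.fitness_curves(
                    env, fitness.default_alpha_grid(21 if smoke else 41),
                    fitness.standard_needs(), rng,
                    n_agents=2_000 if smoke else 10_000,
                )
            )
        pd.concat(curves, ignore_index=True).to_csv(out / "fitness_curves.csv", index=False)
        log["stages"].append(stage)
    except Exception as exc:
        log["failed_stage"] = stage
        with open(out / "run_log.json", "w") as fh:
            json.dump(log, fh, indent=2)
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
    return out
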