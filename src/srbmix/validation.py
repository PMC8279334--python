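"""Out-of-sample validation and parameter-recovery harnesses.

Two reusable checks of the model's predictive and inferential performance:

* ``out_of_sample``: fit on observations up to a cutoff year, then score the
  held-out later observations against the posterior predictive distribution
  (95%-interval empirical coverage, median absolute error on the SRB ratio
  scale, and the sign of the median bias);
* ``parameter_recovery``: repeatedly simulate a known-truth scenario, refit,
  and record detector classification accuracy plus 95%-CI coverage of the
  maximum imbalance, the start year, and the transition end year.

Coverage estimates carry exact (Clopper-Pearson) binomial intervals.
"""

from __future__ import annotations

import json
import math

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, short_config
from .inference import (
    PosteriorDraws,
    classify_transition,
    fit,
    inflation_probability,
    srb_draws,
)
from .projection import project
from .synthetic import ScenarioSpec, simulate_database

__all__ = ["ValidationError", "out_of_sample", "parameter_recovery"]


class ValidationError(RuntimeError):
    """Validation is impossible on the provided inputs."""


def _exact_binomial_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    res = stats.binomtest(k, n)
    ci = res.proportion_ci(confidence_level=level, method="exact")
    return (float(ci.low), float(ci.high))


def _predictive_scores(
    draws: PosteriorDraws, held_out: pd.DataFrame, seed: int
) -> dict:
    """Score held-out observations against the posterior predictive."""
    rng = np.random.default_rng(seed)
    horizon = int(np.floor(held_out["reference_year"].max()))
    last_est = int(draws.years[-1])
    proj = (
        project(draws, horizon_year=horizon, seed=int(rng.integers(2**31)))
        if horizon > last_est
        else None
    )
    stype_pos = {s: i for i, s in enumerate(draws.source_types)}

    inside = 0
    abs_err = []
    bias = []
    for row in held_out.itertuples(index=False):
        region = row.region
        year = int(math.floor(row.reference_year))
        if year <= last_est:
            traj = srb_draws(draws, region)
            mu = np.log(traj[:, np.searchsorted(draws.years, year)])
        else:
            pr = proj[region]
            mu = np.log(pr.trajectories[:, np.searchsorted(pr.years, year)])
        s_i = stype_pos.get(getattr(row, "source_type", None))
        sigma_ns = draws.flat("sigma_ns")[:, s_i] if s_i is not None else 0.0
        sd = np.sqrt(row.sampling_se**2 + np.asarray(sigma_ns) ** 2)
        y_rep = mu + sd * rng.standard_normal(mu.shape)
        lo, hi = np.percentile(y_rep, [2.5, 97.5])
        if lo <= row.log_srb <= hi:
            inside += 1
        pred = float(np.exp(np.median(mu)))
        abs_err.append(abs(pred - row.srb))
        bias.append(pred - row.srb)

    n = len(held_out)
    coverage = inside / n
    lo_ci, hi_ci = _exact_binomial_ci(inside, n)
    return {
        "n_held_out": n,
        "coverage_95": coverage,
        "coverage_ci": (lo_ci, hi_ci),
        "median_abs_error": float(np.median(abs_err)),
        "median_bias": float(np.median(bias)),
        "bias_sign": int(np.sign(np.median(bias))),
    }


def out_of_sample(
    observations: pd.DataFrame,
    cutoff_year: float,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Fit on data up to ``cutoff_year`` and score the held-out remainder.

    Reports empirical coverage of 95% posterior predictive intervals for the
    held-out observations, the median absolute error of the predictive
    median on the SRB ratio scale, and the sign of the median bias.
    Deterministic given (observations, config, seed).
    """
    before = observations[observations["reference_year"] <= cutoff_year]
    after = observations[observations["reference_year"] > cutoff_year]
    if len(after) == 0:
        raise ValidationError(f"no held-out observations after {cutoff_year}")
    if len(before) == 0:
        raise ValidationError(f"no training observations up to {cutoff_year}")
    config = config or short_config()
    draws = fit(before.reset_index(drop=True), config, seed=seed)
    report = _predictive_scores(draws, after.reset_index(drop=True), seed=seed + 1)
    report.update(
        {
            "kind": "out_of_sample",
            "metrics": "coverage of 95% prediction intervals, median absolute "
            "error (SRB scale), sign of median bias",
            "cutoff_year": float(cutoff_year),
            "n_training": int(len(before)),
            "seed": seed,
            "converged": draws.diagnostics.get("converged"),
        }
    )
    return report


def _ci_covers(samples: np.ndarray, truth: float) -> bool:
    lo, hi = np.percentile(samples, [2.5, 97.5])
    return bool(lo <= truth <= hi)


def parameter_recovery(
    spec: ScenarioSpec,
    n_replicates: int,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> dict:
    """Simulate-and-refit study of detector accuracy and CI coverage.

    For each replicate, a database is generated from ``spec`` with a fresh
    seed, preprocessed, and fitted.  Per region the study records whether the
    detector classification matches the truth and — for true transition
    regions — whether the 95% CIs of the maximum imbalance ``xi``, the start
    year ``gamma`` and the transition end year cover the truth (conditional
    on detector-on draws; a region with no detector-on draws counts as not
    covered).  Deterministic given (spec, config, seed).
    """
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    config = config or short_config()
    from .database import apply_window_rules, impute_sampling_error

    n_class = n_correct = 0
    xi_trials = xi_covered = 0
    gamma_trials = gamma_covered = 0
    end_trials = end_covered = 0
    per_replicate = []

    for rep in range(n_replicates):
        rep_seed = seed + 1000 * rep
        _, obs = simulate_database(spec, seed=rep_seed)
        obs = impute_sampling_error(apply_window_rules(obs))
        draws = fit(obs, config, seed=rep_seed + 7)
        rep_record = {"replicate": rep, "regions": {}}
        for region in spec.regions:
            truth_delta = spec.delta[region]
            prob = inflation_probability(draws, region)
            classified = classify_transition(prob, config.classification_threshold)
            correct = classified == bool(truth_delta)
            n_class += 1
            n_correct += correct
            rec = {"prob": prob, "classified": classified, "correct": bool(correct)}
            if truth_delta == 1:
                r = draws.region_index(region)
                on = draws.flat("delta")[:, r] == 1
                tp = spec.trapezoids[region]
                if on.any():
                    xi_s = draws.flat("xi")[:, r][on]
                    g_s = draws.flat("gamma")[:, r][on]
                    end_s = (
                        draws.flat("gamma")[:, r]
                        + draws.flat("lambda1")[:, r]
                        + draws.flat("lambda2")[:, r]
                        + draws.flat("lambda3")[:, r]
                    )[on]
                    cov_xi = _ci_covers(xi_s, tp.xi)
                    cov_g = _ci_covers(g_s, tp.gamma)
                    cov_e = _ci_covers(end_s, tp.end)
                else:
                    cov_xi = cov_g = cov_e = False
                xi_trials += 1
                xi_covered += cov_xi
                gamma_trials += 1
                gamma_covered += cov_g
                end_trials += 1
                end_covered += cov_e
                rec.update(
                    {"xi_covered": cov_xi, "gamma_covered": cov_g, "end_covered": cov_e}
                )
            rep_record["regions"][region] = rec
        per_replicate.append(rep_record)

    return {
        "kind": "parameter_recovery",
        "metrics": "detector classification accuracy; 95% CI coverage of xi, "
        "gamma, and the transition end year",
        "n_replicates": n_replicates,
        "seed": seed,
        "classification_accuracy": n_correct / n_class,
        "classification_trials": n_class,
        "classification_ci": _exact_binomial_ci(n_correct, n_class),
        "xi_coverage": xi_covered / max(xi_trials, 1),
        "xi_trials": xi_trials,
        "xi_coverage_ci": _exact_binomial_ci(xi_covered, xi_trials),
        "gamma_coverage": gamma_covered / max(gamma_trials, 1),
        "gamma_trials": gamma_trials,
        "gamma_coverage_ci": _exact_binomial_ci(gamma_covered, gamma_trials),
        "end_year_coverage": end_covered / max(end_trials, 1),
        "end_year_trials": end_trials,
        "end_year_coverage_ci": _exact_binomial_ci(end_covered, end_trials),
        "per_replicate": per_replicate,
    }


def report_text(report: dict) -> str:
    """Render a validation report as human-readable text."""
    lines = [f"{report['kind']} validation report", f"metrics: {report['metrics']}"]
    for key, value in report.items():
        if key in ("kind", "metrics", "per_replicate"):
            continue
        lines.append(f"  {key}: {value}")
    return "\n".join(lines)


def save_report(report: dict, path_json, path_txt=None) -> None:
    from pathlib import Path

    Path(path_json).write_text(json.dumps(report, indent=1, default=str))
    if path_txt is not None:
        Path(path_txt).write_text(report_text(report) + "\n")
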