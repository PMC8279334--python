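"""Probabilistic projection of regional SRB beyond the last data year.

Each posterior draw is extended forward: the AR(1) log-fluctuation is
simulated onward from its last estimated state with that draw's own
(rho, sigma_eps), while the trapezoid imbalance is evaluated
deterministically into its decline.  Projection uncertainty therefore
combines posterior parameter uncertainty with future AR(1) innovations,
which is why credible bands keep widening after the data period before the
trajectories settle back at the national baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import ConditioningError, PosteriorDraws, classify_transition, inflation_probability
from .model import trapezoid_profile

__all__ = ["ProjectionResult", "project", "end_year_summary"]


@dataclass
class ProjectionResult:
    """Per-region projected SRB trajectories and pointwise summaries."""

    region: str
    years: np.ndarray          # projection years (last data year + 1 .. horizon)
    trajectories: np.ndarray   # (n_draws, H) SRB paths
    median: np.ndarray
    lower95: np.ndarray
    upper95: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "year": self.years,
                "median": self.median,
                "lower95": self.lower95,
                "upper95": self.upper95,
            }
        )


def project(
    draws: PosteriorDraws, horizon_year: int = 2050, seed: int = 0
) -> dict[str, ProjectionResult]:
    """Project every region's SRB from the last estimation year to the horizon.

    For each posterior draw the phi recursion continues from its last
    estimated value (no discontinuity at the estimation/projection boundary)
    and the SRB path is ``b*exp(phi) + delta*alpha``.  Reproducible given
    ``seed``.
    """
    last_year = int(draws.years[-1])
    if horizon_year <= last_year:
        raise ValueError(
            f"horizon_year must be after the last estimation year {last_year}"
        )
    proj_years = np.arange(last_year + 1, horizon_year + 1)
    H = len(proj_years)
    rng = np.random.default_rng(seed)
    b = draws.config.baseline

    results: dict[str, ProjectionResult] = {}
    for r_i, region in enumerate(draws.regions):
        phi_last = draws.flat("phi")[:, r_i, -1]
        rho = draws.flat("rho")[:, r_i]
        sig = draws.flat("sigma_eps")[:, r_i]
        n = phi_last.shape[0]
        phi = np.empty((n, H))
        prev = phi_last
        innov = rng.standard_normal((n, H))
        for h in range(H):
            prev = rho * prev + sig * innov[:, h]
            phi[:, h] = prev
        alpha = trapezoid_profile(
            proj_years.astype(float),
            draws.flat("gamma")[:, r_i],
            draws.flat("lambda1")[:, r_i],
            draws.flat("lambda2")[:, r_i],
            draws.flat("lambda3")[:, r_i],
            draws.flat("xi")[:, r_i],
        )
        delta = draws.flat("delta")[:, r_i]
        traj = b * np.exp(phi) + delta[:, None] * alpha
        med, lo, hi = np.percentile(traj, [50.0, 2.5, 97.5], axis=0)
        results[region] = ProjectionResult(
            region=region,
            years=proj_years,
            trajectories=traj,
            median=med,
            lower95=lo,
            upper95=hi,
        )
    return results


def end_year_summary(
    draws: PosteriorDraws, region: str, threshold: float | None = None
) -> dict:
    """Posterior median and 95% CI of the transition end year for a region.

    The end year is gamma + lambda1 + lambda2 + lambda3, summarized over
    detector-on draws.  Raises ``ConditioningError`` for regions not
    classified as undergoing a transition.
    """
    threshold = (
        draws.config.classification_threshold if threshold is None else threshold
    )
    prob = inflation_probability(draws, region)
    if not classify_transition(prob, threshold):
        raise ConditioningError(
            f"region {region} is not classified as a transition region "
            f"(inflation probability {prob:.3f} < {threshold})"
        )
    r = draws.region_index(region)
    delta = draws.flat("delta")[:, r] == 1
    end = (
        draws.flat("gamma")[:, r]
        + draws.flat("lambda1")[:, r]
        + draws.flat("lambda2")[:, r]
        + draws.flat("lambda3")[:, r]
    )[delta]
    med, lo, hi = np.percentile(end, [50.0, 2.5, 97.5])
    return {
        "region": region,
        "end_year": float(med),
        "end_year_ci": (float(lo), float(hi)),
    }
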