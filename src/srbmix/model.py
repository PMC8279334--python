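"""Generative model for regional sex-ratio-at-birth (SRB) dynamics.

The SRB of region ``r`` in year ``t`` is decomposed into a normal level and a
possible imbalance from prenatal sex selection::

    SRB(r, t) = b * exp(phi[r, t]) + delta_r * alpha_r(t)

where

* ``b`` is the national baseline SRB (1.063 for Vietnam), the level expected
  in the absence of any sex selection;
* ``phi[r, t]`` is a stationary AR(1) process on the log scale capturing
  natural year-to-year fluctuation of the regional SRB around the baseline;
* ``delta_r`` is a binary detector: 1 if region ``r`` undergoes a sex ratio
  transition, 0 otherwise, with region-specific prior probability ``pi_r``;
* ``alpha_r(t)`` is a nonnegative trapezoid-shaped transition: zero until a
  start year ``gamma``, linear rise of duration ``lambda1`` up to a maximum
  imbalance ``xi``, plateau of duration ``lambda2``, and linear decline of
  duration ``lambda3`` back to zero.

Observed log-SRB values are modelled as normal around the log of the model
SRB, with variance equal to the sampling variance of the observation plus a
source-type-specific non-sampling variance.  Region-level trapezoid
parameters share truncated-normal priors with fixed national-level means and
spreads, which lets sparsely observed regions borrow strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ParameterError",
    "TruncatedNormal",
    "HalfNormal",
    "TrapezoidParams",
    "AR1Params",
    "RegionLatent",
    "Hyperparams",
    "trapezoid_alpha",
    "trapezoid_profile",
    "ar1_logpdf",
    "expected_srb",
    "observation_loglik",
    "joint_logpost",
]


class ParameterError(ValueError):
    """A model parameter violates its support or an invariant."""


# ---------------------------------------------------------------------------
# Prior building blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruncatedNormal:
    """Normal(mean, sd) truncated to [lower, upper]."""

    mean: float
    sd: float
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ParameterError(f"sd must be > 0, got {self.sd}")
        if self.lower >= self.upper:
            raise ParameterError("lower must be < upper")

    @property
    def _frozen(self):
        # cached: frozen-distribution construction dominates repeated rvs calls
        frozen = object.__getattribute__(self, "__dict__").get("_frozen_cache")
        if frozen is None:
            a = (self.lower - self.mean) / self.sd
            b = (self.upper - self.mean) / self.sd
            frozen = stats.truncnorm(a, b, loc=self.mean, scale=self.sd)
            object.__setattr__(self, "_frozen_cache", frozen)
        return frozen

    def logpdf(self, x):
        return self._frozen.logpdf(x)

    def logpdf_unnorm(self, x):
        """Log density up to the truncation constant; -inf outside support."""
        x = np.asarray(x, dtype=float)
        out = -0.5 * ((x - self.mean) / self.sd) ** 2
        return np.where((x >= self.lower) & (x <= self.upper), out, -np.inf)

    def in_support(self, x):
        x = np.asarray(x, dtype=float)
        return (x >= self.lower) & (x <= self.upper)

    def rvs(self, rng: np.random.Generator, size=None):
        return self._frozen.rvs(size=size, random_state=rng)

    def ppf(self, q):
        return self._frozen.ppf(q)

    def mean_value(self) -> float:
        return float(self._frozen.mean())


@dataclass(frozen=True)
class HalfNormal:
    """Half-normal prior on a nonnegative scale parameter."""

    scale: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ParameterError("scale must be > 0")

    def logpdf(self, x):
        return stats.halfnorm(scale=self.scale).logpdf(x)

    def logpdf_unnorm(self, x):
        x = np.asarray(x, dtype=float)
        out = -0.5 * (x / self.scale) ** 2
        return np.where(x >= 0, out, -np.inf)

    def rvs(self, rng: np.random.Generator, size=None):
        return np.abs(rng.normal(0.0, self.scale, size=size))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrapezoidParams:
    """Shape of one region's sex ratio transition.

    ``gamma`` is the start calendar year; ``lambda1``/``lambda2``/``lambda3``
    are the rise, plateau, and decline durations in years; ``xi`` is the
    maximum imbalance, additive on the SRB ratio scale.
    """

    gamma: float
    lambda1: float
    lambda2: float
    lambda3: float
    xi: float

    def __post_init__(self) -> None:
        if self.lambda1 <= 0:
            raise ParameterError(f"rise duration must be > 0, got {self.lambda1}")
        if self.lambda3 <= 0:
            raise ParameterError(f"decline duration must be > 0, got {self.lambda3}")
        if self.lambda2 < 0:
            raise ParameterError(f"plateau duration must be >= 0, got {self.lambda2}")
        if self.xi < 0:
            raise ParameterError(f"maximum imbalance must be >= 0, got {self.xi}")

    @property
    def end(self) -> float:
        """Calendar year when the imbalance returns to zero."""
        return self.gamma + self.lambda1 + self.lambda2 + self.lambda3


@dataclass(frozen=True)
class AR1Params:
    """Stationary AR(1) with autocorrelation rho and innovation sd sigma_eps."""

    rho: float
    sigma_eps: float

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ParameterError(f"rho must lie in (-1, 1), got {self.rho}")
        if self.sigma_eps <= 0:
            raise ParameterError(f"sigma_eps must be > 0, got {self.sigma_eps}")

    @property
    def stationary_var(self) -> float:
        return self.sigma_eps**2 / (1.0 - self.rho**2)

    @property
    def stationary_sd(self) -> float:
        return math.sqrt(self.stationary_var)


@dataclass
class RegionLatent:
    """Full latent state of one region over a calendar-year grid."""

    region: str
    years: np.ndarray
    phi: np.ndarray
    delta: int
    pi: float
    trapezoid: TrapezoidParams

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.years.shape != self.phi.shape:
            raise ParameterError("years and phi must have equal length")
        if self.delta not in (0, 1):
            raise ParameterError("delta must be 0 or 1")
        if not 0.0 < self.pi < 1.0:
            raise ParameterError("pi must lie in (0, 1)")

    def year_index(self, t) -> np.ndarray:
        idx = np.searchsorted(self.years, t)
        idx = np.atleast_1d(idx)
        tt = np.atleast_1d(t)
        if np.any(idx >= len(self.years)) or np.any(self.years[idx] != tt):
            raise ParameterError(f"year {t} outside latent grid "
                                 f"[{self.years[0]}, {self.years[-1]}]")
        return idx


DEFAULT_BASELINE = 1.063

DEFAULT_GAMMA_PRIOR = TruncatedNormal(2001.0, 5.0, 1980.0, 2030.0)
DEFAULT_LAMBDA1_PRIOR = TruncatedNormal(13.0, 5.0, 1.0, math.inf)
DEFAULT_LAMBDA2_PRIOR = TruncatedNormal(5.0, 4.0, 0.0, math.inf)
DEFAULT_LAMBDA3_PRIOR = TruncatedNormal(18.0, 8.0, 1.0, math.inf)
DEFAULT_XI_PRIOR = TruncatedNormal(0.07, 0.03, 0.0, math.inf)


@dataclass(frozen=True)
class Hyperparams:
    """Fixed national-level hyperparameters shared across regions.

    The trapezoid priors carry the national transition estimates (mean and
    spread for start year, durations, and maximum imbalance); the baseline is
    the national natural SRB.  ``pi_a``/``pi_b`` parameterize the Beta prior
    on each region's inflation probability; ``sigma_eps_scale`` and
    ``sigma_ns_scale`` are half-normal prior scales for the AR(1) innovation
    sd and the source-type non-sampling error sd.
    """

    b: float = DEFAULT_BASELINE
    gamma: TruncatedNormal = DEFAULT_GAMMA_PRIOR
    lambda1: TruncatedNormal = DEFAULT_LAMBDA1_PRIOR
    lambda2: TruncatedNormal = DEFAULT_LAMBDA2_PRIOR
    lambda3: TruncatedNormal = DEFAULT_LAMBDA3_PRIOR
    xi: TruncatedNormal = DEFAULT_XI_PRIOR
    pi_a: float = 1.0
    pi_b: float = 1.0
    sigma_eps_scale: float = 0.02
    sigma_ns_scale: float = 0.02

    @property
    def trapezoid_priors(self) -> dict[str, TruncatedNormal]:
        return {
            "gamma": self.gamma,
            "lambda1": self.lambda1,
            "lambda2": self.lambda2,
            "lambda3": self.lambda3,
            "xi": self.xi,
        }

    def sample_trapezoid(self, rng: np.random.Generator) -> TrapezoidParams:
        return TrapezoidParams(
            gamma=float(self.gamma.rvs(rng)),
            lambda1=float(self.lambda1.rvs(rng)),
            lambda2=float(self.lambda2.rvs(rng)),
            lambda3=float(self.lambda3.rvs(rng)),
            xi=float(self.xi.rvs(rng)),
        )


# ---------------------------------------------------------------------------
# Model functions
# ---------------------------------------------------------------------------


def trapezoid_alpha(t, p: TrapezoidParams):
    """Imbalance alpha(t): zero / linear rise / plateau at xi / linear decline.

    Accepts scalar or array ``t``; returns the matching shape.  Continuous and
    piecewise linear in ``t``, nonnegative everywhere, zero outside
    ``[gamma, gamma + lambda1 + lambda2 + lambda3]``.
    """
    out = trapezoid_profile(t, p.gamma, p.lambda1, p.lambda2, p.lambda3, p.xi)
    if np.isscalar(t):
        return float(out)
    return out


def trapezoid_profile(years, gamma, lambda1, lambda2, lambda3, xi):
    """Vectorized trapezoid: params broadcast against trailing ``years`` axis.

    ``years`` has shape (T,); parameter arrays of shape S produce output of
    shape S + (T,).  Scalars are fine throughout.
    """
    years = np.asarray(years, dtype=float)
    g = np.asarray(gamma, dtype=float)[..., None]
    l1 = np.asarray(lambda1, dtype=float)[..., None]
    l2 = np.asarray(lambda2, dtype=float)[..., None]
    l3 = np.asarray(lambda3, dtype=float)[..., None]
    x = np.asarray(xi, dtype=float)[..., None]

    rise_end = g + l1
    plat_end = rise_end + l2
    end = plat_end + l3

    t = years  # broadcasts against (..., 1)
    alpha = np.where(
        t <= g,
        0.0,
        np.where(
            t < rise_end,
            x * (t - g) / l1,
            np.where(t <= plat_end, x, np.where(t < end, x * (end - t) / l3, 0.0)),
        ),
    )
    if np.ndim(gamma) == 0:
        # Scalar params: drop the axis injected for broadcasting.
        return alpha.reshape(years.shape)
    return alpha


def ar1_logpdf(phi, params: AR1Params):
    """Exact log density of a stationary Gaussian AR(1) path.

    ``phi`` may be 1-D (one path, returns a scalar) or 2-D with independent
    paths along rows (returns one value per row).  The first point gets the
    stationary distribution N(0, sigma_eps^2 / (1 - rho^2)); subsequent points
    get N(rho * phi[t-1], sigma_eps^2).
    """
    phi = np.asarray(phi, dtype=float)
    rho, sigma = params.rho, params.sigma_eps
    sd0 = params.stationary_sd
    lp0 = stats.norm.logpdf(phi[..., 0], 0.0, sd0)
    if phi.shape[-1] > 1:
        lpt = stats.norm.logpdf(phi[..., 1:], rho * phi[..., :-1], sigma).sum(axis=-1)
    else:
        lpt = 0.0
    out = lp0 + lpt
    return float(out) if np.ndim(out) == 0 else out


def expected_srb(latent: RegionLatent, b: float, t):
    """Model SRB of a region in year(s) ``t``: b*exp(phi) + delta*alpha."""
    idx = latent.year_index(t)
    alpha = trapezoid_profile(
        np.asarray(t, dtype=float).ravel(),
        latent.trapezoid.gamma,
        latent.trapezoid.lambda1,
        latent.trapezoid.lambda2,
        latent.trapezoid.lambda3,
        latent.trapezoid.xi,
    )
    srb = b * np.exp(latent.phi[idx]) + latent.delta * alpha
    return float(srb[0]) if np.isscalar(t) else srb


def observation_loglik(log_srb, sampling_se, expected, sigma_nonsampling=0.0):
    """Normal log likelihood of an observed log-SRB given the model SRB.

    Total variance = sampling variance + squared source-type non-sampling sd.
    """
    expected = np.asarray(expected, dtype=float)
    if not np.all(np.isfinite(expected)) or np.any(expected <= 0):
        raise ParameterError("expected SRB must be finite and positive")
    se = np.asarray(sampling_se, dtype=float)
    if np.any(se <= 0):
        raise ParameterError("sampling_se must be > 0")
    sd = np.sqrt(se**2 + np.asarray(sigma_nonsampling, dtype=float) ** 2)
    out = stats.norm.logpdf(np.asarray(log_srb, dtype=float), np.log(expected), sd)
    return float(out) if np.ndim(out) == 0 else out


def joint_logpost(
    latents: dict[str, RegionLatent] | list[RegionLatent],
    hypers: Hyperparams,
    observations,
    ar1: AR1Params,
    sigma_ns: dict[str, float] | None = None,
):
    """Log posterior density (up to a constant) of the full model state.

    ``observations`` is a model-ready table (DataFrame) with columns
    ``region``, ``reference_year``, ``log_srb``, ``sampling_se`` and
    ``source_type``.  ``sigma_ns`` maps source types to non-sampling sds
    (treated as 0 when omitted).  This is the plain, term-by-term reference
    density; the sampler uses an equivalent factorized form.
    """
    if not isinstance(latents, dict):
        latents = {lat.region: lat for lat in latents}
    sigma_ns = dict(sigma_ns or {})

    lp = 0.0
    # Observation likelihood.
    for row in observations.itertuples(index=False):
        lat = latents[row.region]
        year = int(math.floor(row.reference_year))
        srb = expected_srb(lat, hypers.b, year)
        lp += observation_loglik(
            row.log_srb,
            row.sampling_se,
            srb,
            sigma_ns.get(getattr(row, "source_type", None), 0.0),
        )

    priors = hypers.trapezoid_priors
    for lat in latents.values():
        lp += ar1_logpdf(lat.phi, ar1)
        lp += lat.delta * math.log(lat.pi) + (1 - lat.delta) * math.log1p(-lat.pi)
        lp += float(stats.beta.logpdf(lat.pi, hypers.pi_a, hypers.pi_b))
        for name, prior in priors.items():
            val = getattr(lat.trapezoid, name)
            term = float(prior.logpdf(val))
            if not np.isfinite(term):
                raise ParameterError(f"{name}={val} outside prior support")
            lp += term

    # Hyper-level priors on the AR(1) and non-sampling scales.
    if not 0.0 <= ar1.rho < 1.0:
        return -math.inf
    lp += float(HalfNormal(hypers.sigma_eps_scale).logpdf(ar1.sigma_eps))
    for val in sigma_ns.values():
        lp += float(HalfNormal(hypers.sigma_ns_scale).logpdf(val))
    return float(lp)
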