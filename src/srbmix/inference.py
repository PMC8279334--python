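"""MCMC estimation of the hierarchical SRB mixture model.

The sampler is a Metropolis-within-Gibbs scheme over

* ``phi``: the AR(1) log-fluctuation field (region x year), updated with
  single-site random walks in two vectorized odd/even-year passes (sites of
  one parity are conditionally independent given the other parity);
* the trapezoid transition parameters of each region, updated with scalar
  random walks where the detector is on and refreshed exactly from their
  priors where it is off (the exact full conditional there);
* the Bernoulli detector ``delta``, drawn from its exact conditional;
* the inflation probability ``pi`` of each region (conjugate Beta update);
* the shared (or region-specific) AR(1) parameters and the source-type
  non-sampling error sds, with random walks on transformed scales.

Two detector treatments are available.  ``indicator`` conditions every
likelihood evaluation on the current ``delta``.  ``marginalize`` integrates
the detector out, targeting the mixture likelihood
``(1 - pi) L(delta=0) + pi L(delta=1)`` per region, and draws ``delta`` from
its exact conditional for reporting only.  Both target the same posterior;
their agreement is a sampler correctness check.

Random-walk step sizes adapt toward standard acceptance targets during
warmup only and are frozen afterwards, so the retained draws come from a
fixed, valid transition kernel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .config import ModelConfig
from .model import Hyperparams, trapezoid_profile

logger = logging.getLogger(__name__)

__all__ = [
    "InferenceError",
    "ConditioningError",
    "PosteriorDraws",
    "fit",
    "inflation_probability",
    "classify_transition",
    "summarize_transition",
    "annual_estimates",
    "srb_draws",
    "diagnostics",
    "compute_diagnostics",
    "mcse_probability",
]

_TRAP_NAMES = ("gamma", "lambda1", "lambda2", "lambda3", "xi")
_ADAPT_BATCH = 50
_ADAPT_TARGET = 0.44


class InferenceError(RuntimeError):
    """A problem during or after MCMC estimation."""


class ConditioningError(InferenceError):
    """A summary conditional on delta=1 was requested but no such draws exist."""


# ---------------------------------------------------------------------------
# Data preparation
# ---------------------------------------------------------------------------


@dataclass
class _Data:
    regions: tuple[str, ...]
    years: np.ndarray          # (T,) int calendar years
    r_idx: np.ndarray          # (N,) region index per observation
    t_idx: np.ndarray          # (N,) year index per observation
    y: np.ndarray              # (N,) observed log-SRB
    se: np.ndarray             # (N,) sampling SE of log-SRB
    stype_idx: np.ndarray      # (N,) source-type index
    source_types: tuple[str, ...]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_years(self) -> int:
        return len(self.years)


def _prepare(observations: pd.DataFrame, config: ModelConfig) -> _Data:
    n = len(observations)
    if n == 0:
        if config.regions is None or config.year_start is None or config.year_end is None:
            raise InferenceError(
                "a prior-only fit (no observations) needs explicit regions, "
                "year_start and year_end in the config"
            )
        regions = tuple(config.regions)
        years = np.arange(config.year_start, config.year_end + 1)
        empty = np.empty(0)
        return _Data(regions, years, empty.astype(int), empty.astype(int),
                     empty, empty, empty.astype(int), ("none",))

    obs_regions = list(pd.unique(observations["region"]))
    if config.regions is not None:
        regions = tuple(config.regions)
        unknown = set(obs_regions) - set(regions)
        if unknown:
            raise InferenceError(f"observations contain regions not in config: {unknown}")
    else:
        regions = tuple(r for r in obs_regions)
        regions = tuple(sorted(regions))
    for r in regions:
        if r not in obs_regions:
            logger.warning("region %s has no observations; it will be prior-only", r)

    se = observations["sampling_se"].to_numpy(dtype=float)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise InferenceError(
            "every observation entering the likelihood needs sampling_se > 0; "
            "run impute_sampling_error first"
        )

    # A fractional reference year is a time point inside calendar year
    # floor(reference_year); the latent grid is annual.
    obs_years = np.floor(observations["reference_year"].to_numpy(dtype=float)).astype(int)
    year_start = config.year_start if config.year_start is not None else int(obs_years.min())
    year_end = config.year_end if config.year_end is not None else int(obs_years.max())
    if obs_years.min() < year_start or obs_years.max() > year_end:
        raise InferenceError("observation years fall outside the configured year grid")
    years = np.arange(year_start, year_end + 1)

    region_pos = {r: i for i, r in enumerate(regions)}
    r_idx = observations["region"].map(region_pos).to_numpy(dtype=int)
    t_idx = obs_years - year_start
    if "source_type" in observations.columns:
        stypes = tuple(sorted(pd.unique(observations["source_type"].astype(str))))
        stype_pos = {s: i for i, s in enumerate(stypes)}
        stype_idx = observations["source_type"].astype(str).map(stype_pos).to_numpy(dtype=int)
    else:
        stypes = ("unknown",)
        stype_idx = np.zeros(n, dtype=int)

    return _Data(
        regions=regions,
        years=years,
        r_idx=r_idx,
        t_idx=t_idx,
        y=observations["log_srb"].to_numpy(dtype=float),
        se=se,
        stype_idx=stype_idx,
        source_types=stypes,
    )


# ---------------------------------------------------------------------------
# Posterior draw container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorDraws:
    """Post-warmup MCMC draws of all latent states and hyperparameters.

    Array layout: leading axes are (chain, iteration); region-indexed
    quantities add a region axis and ``phi`` adds a year axis.
    """

    regions: tuple[str, ...]
    years: np.ndarray
    source_types: tuple[str, ...]
    phi: np.ndarray        # (C, D, R, T)
    delta: np.ndarray      # (C, D, R) in {0, 1}
    pi: np.ndarray         # (C, D, R)
    gamma: np.ndarray      # (C, D, R)
    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray
    xi: np.ndarray
    rho: np.ndarray        # (C, D, R)
    sigma_eps: np.ndarray  # (C, D, R)
    sigma_ns: np.ndarray   # (C, D, S)
    config: ModelConfig
    n_warmup: int
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.phi.shape[0]

    @property
    def n_iter(self) -> int:
        return self.phi.shape[1]

    @property
    def n_draws(self) -> int:
        return self.n_chains * self.n_iter

    def region_index(self, region: str) -> int:
        try:
            return self.regions.index(region)
        except ValueError:
            raise KeyError(f"unknown region {region!r}; have {self.regions}") from None

    def flat(self, name: str) -> np.ndarray:
        """Draws of a parameter with chain/iteration axes merged."""
        arr = getattr(self, name)
        return arr.reshape(self.n_draws, *arr.shape[2:])

    # -- persistence ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (chain, iter, parameter, value) of all draws."""
        rows = []
        C, D = self.n_chains, self.n_iter
        chain = np.repeat(np.arange(C), D)
        it = np.tile(np.arange(D), C)

        def emit(name, arr):
            rows.append(
                pd.DataFrame(
                    {"chain": chain, "iter": it, "parameter": name,
                     "value": arr.reshape(C * D)}
                )
            )

        for r_i, r in enumerate(self.regions):
            for name in ("delta", "pi", *_TRAP_NAMES, "rho", "sigma_eps"):
                emit(f"{name}[{r}]", getattr(self, name)[:, :, r_i])
            for t_i, yr in enumerate(self.years):
                emit(f"phi[{r},{yr}]", self.phi[:, :, r_i, t_i])
        for s_i, s in enumerate(self.source_types):
            emit(f"sigma_ns[{s}]", self.sigma_ns[:, :, s_i])
        return pd.concat(rows, ignore_index=True)

    def save(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "draws.csv", index=False)
        meta = {
            "regions": list(self.regions),
            "years": [int(v) for v in self.years],
            "source_types": list(self.source_types),
            "n_chains": self.n_chains,
            "n_iter": self.n_iter,
            "n_warmup": self.n_warmup,
            "seed": self.seed,
            "config": self.config.to_dict(),
        }
        import json

        (d / "draws_meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory) -> "PosteriorDraws":
        import json
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "draws_meta.json").read_text())
        frame = pd.read_csv(d / "draws.csv")
        C, D = meta["n_chains"], meta["n_iter"]
        regions = tuple(meta["regions"])
        years = np.asarray(meta["years"], dtype=int)
        stypes = tuple(meta["source_types"])
        R, T, S = len(regions), len(years), len(stypes)

        wide = frame.pivot_table(
            index=["chain", "iter"], columns="parameter", values="value", sort=False
        )

        def grab(name):
            return wide[name].to_numpy().reshape(C, D)

        arrays = {}
        for name in ("delta", "pi", *_TRAP_NAMES, "rho", "sigma_eps"):
            arrays[name] = np.stack([grab(f"{name}[{r}]") for r in regions], axis=-1)
        arrays["phi"] = np.stack(
            [
                np.stack([grab(f"phi[{r},{yr}]") for yr in years], axis=-1)
                for r in regions
            ],
            axis=-2,
        )
        arrays["sigma_ns"] = np.stack([grab(f"sigma_ns[{s}]") for s in stypes], axis=-1)
        arrays["delta"] = arrays["delta"].astype(int)
        return cls(
            regions=regions,
            years=years,
            source_types=stypes,
            config=ModelConfig.from_dict(meta["config"]),
            n_warmup=meta["n_warmup"],
            seed=meta["seed"],
            **arrays,
        )


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------


def _normal_ll(y, mu, sd):
    # Log density up to the -0.5*log(2*pi) constant, which cancels in every
    # ratio and in the detector's conditional (same observation count on
    # both branches).
    return -0.5 * ((y - mu) / sd) ** 2 - np.log(sd)


class _Sampler:
    def __init__(self, data: _Data, config: ModelConfig, rng: np.random.Generator):
        self.data = data
        self.config = config
        self.hypers: Hyperparams = config.hypers
        self.rng = rng
        self.b = config.baseline
        R, T = data.n_regions, data.n_years
        self.R, self.T = R, T
        self.years_f = data.years.astype(float)
        self.marginal = config.detector_method == "marginalize"

        self.trap_priors = [(name, getattr(self.hypers, name)) for name in _TRAP_NAMES]

        # --- initial state (overdispersed via prior draws) ---
        self.phi = np.zeros((R, T))
        self.trap = np.empty((5, R))
        for r in range(R):
            tp = self.hypers.sample_trapezoid(rng)
            self.trap[:, r] = [tp.gamma, tp.lambda1, tp.lambda2, tp.lambda3, tp.xi]
        self.delta = np.ones(R, dtype=int)
        self.pi = rng.beta(self.hypers.pi_a, self.hypers.pi_b, size=R)
        self.pi = np.clip(self.pi, 1e-6, 1 - 1e-6)
        n_ar1 = R if config.region_specific_ar1 else 1
        rho0 = np.clip(0.5 * np.exp(0.1 * rng.standard_normal(n_ar1)), 0.05, 0.95)
        sig0 = 0.01 * np.exp(0.2 * rng.standard_normal(n_ar1))
        self.rho = np.resize(rho0, R).astype(float)
        self.sig = np.resize(sig0, R).astype(float)
        S = len(data.source_types)
        if config.estimate_sigma_ns:
            self.sigma_ns = np.full(S, 0.01) * np.exp(0.2 * rng.standard_normal(S))
        else:
            self.sigma_ns = np.array(
                [float(config.sigma_ns_fixed.get(s, 0.0)) for s in data.source_types]
            )
        self._refresh_sd()

        # --- observation bookkeeping ---
        self.obs_by_region = [np.flatnonzero(data.r_idx == r) for r in range(R)]
        self.obs_by_site = [
            [np.flatnonzero((data.r_idx == r) & (data.t_idx == t)) for t in range(T)]
            for r in range(R)
        ]
        self._cols = [np.arange(T)[p::2] for p in (0, 1)]
        self._parity_obs = []
        for p in (0, 1):
            o = np.flatnonzero(data.t_idx % 2 == p)
            pos = (data.t_idx[o] - p) // 2
            self._parity_obs.append({"o": o, "pos": pos})

        # --- step sizes and adaptation ---
        self.step_phi = np.full((R, T), 0.03)
        self.step_trap = np.array([[2.0], [2.0], [2.0], [3.0], [0.01]]) * np.ones((5, R))
        self.step_rho = 0.5
        self.step_sig = 0.3
        self.step_ncsig = 0.1
        self.step_ncrho = 0.3
        self.step_ns = np.full(S, 0.5)
        self.step_pi = 1.0  # logit scale, marginal scheme only
        self._acc: dict[str, np.ndarray | float] = {}
        self._trials: dict[str, np.ndarray | float] = {}

        self.alpha = self._alpha_for(np.arange(R))
        self._refresh_caches()

    # -- caches -----------------------------------------------------------

    def _refresh_sd(self):
        self.sd = np.sqrt(self.data.se**2 + self.sigma_ns[self.data.stype_idx] ** 2)

    def _alpha_for(self, r_indices):
        g, l1, l2, l3, x = self.trap[:, r_indices]
        return trapezoid_profile(self.years_f, g, l1, l2, l3, x)

    def _refresh_caches(self):
        """Recompute per-observation log likelihoods under both branches."""
        d = self.data
        srb0_obs = self.b * np.exp(self.phi[d.r_idx, d.t_idx])
        alpha_obs = self.alpha[d.r_idx, d.t_idx]
        self.mu0 = np.log(srb0_obs)
        self.mu1 = np.log(srb0_obs + alpha_obs)
        self.ll0 = _normal_ll(d.y, self.mu0, self.sd)
        self.ll1 = _normal_ll(d.y, self.mu1, self.sd)
        self.S0 = np.bincount(d.r_idx, weights=self.ll0, minlength=self.R)
        self.S1 = np.bincount(d.r_idx, weights=self.ll1, minlength=self.R)

    def _mix(self):
        return np.logaddexp(
            np.log(self.pi) + self.S1, np.log1p(-self.pi) + self.S0
        )

    def _region_loglik(self):
        """Per-region data log likelihood under the current detector scheme."""
        if self.marginal:
            return self._mix()
        return np.where(self.delta == 1, self.S1, self.S0)

    # -- adaptation helpers ----------------------------------------------

    def _track(self, key, accepted, trials=1.0):
        self._acc[key] = self._acc.get(key, 0.0) + accepted
        self._trials[key] = self._trials.get(key, 0.0) + trials

    def _adapt(self, batch_number):
        amount = min(0.5, batch_number**-0.5)

        def tune(step, key):
            acc = self._acc.get(key, 0.0)
            tri = self._trials.get(key, 1.0)
            rate = np.asarray(acc) / np.maximum(np.asarray(tri), 1e-12)
            return step * np.exp(amount * np.sign(rate - _ADAPT_TARGET))

        self.step_phi = tune(self.step_phi, "phi")
        self.step_trap = tune(self.step_trap, "trap")
        self.step_rho = float(tune(self.step_rho, "rho"))
        self.step_sig = float(tune(self.step_sig, "sig"))
        self.step_ncsig = float(np.mean(tune(self.step_ncsig, "ncsig")))
        self.step_ncrho = float(np.mean(tune(self.step_ncrho, "ncrho")))
        self.step_ns = tune(self.step_ns, "ns")
        self.step_pi = float(tune(self.step_pi, "pi"))
        self._acc.clear()
        self._trials.clear()

    # -- phi updates ------------------------------------------------------

    def _ar1_local(self, values, cols, left_mu, left_sd, right_vals, has_right):
        lp = -0.5 * ((values - left_mu) / left_sd) ** 2
        rp = -0.5 * ((right_vals - self.rho[:, None] * values) / self.sig[:, None]) ** 2
        return lp + np.where(has_right[None, :], rp, 0.0)

    def _phi_update_indicator(self, parity):
        d, R, T = self.data, self.R, self.T
        cols = self._cols[parity]
        K = len(cols)
        phi = self.phi
        cur = phi[:, cols]
        prop = cur + self.step_phi[:, cols] * self.rng.standard_normal((R, K))

        has_left = cols > 0
        left_prev = np.where(has_left, cols - 1, 0)
        sd0 = self.sig / np.sqrt(1.0 - self.rho**2)
        left_mu = np.where(has_left[None, :], self.rho[:, None] * phi[:, left_prev], 0.0)
        left_sd = np.where(has_left[None, :], self.sig[:, None], sd0[:, None])
        has_right = cols < T - 1
        right_next = np.where(has_right, cols + 1, T - 1)
        right_vals = phi[:, right_next]

        dlp = self._ar1_local(prop, cols, left_mu, left_sd, right_vals, has_right)
        dlp -= self._ar1_local(cur, cols, left_mu, left_sd, right_vals, has_right)

        po = self._parity_obs[parity]
        o, pos = po["o"], po["pos"]
        if o.size:
            r_o = d.r_idx[o]
            srb_new = self.b * np.exp(prop[r_o, pos]) + self.delta[r_o] * self.alpha[
                r_o, d.t_idx[o]
            ]
            mu_new = np.log(srb_new)
            mu_cur = np.where(self.delta[r_o] == 1, self.mu1[o], self.mu0[o])
            dll = _normal_ll(d.y[o], mu_new, self.sd[o]) - _normal_ll(
                d.y[o], mu_cur, self.sd[o]
            )
            dlp += np.bincount(r_o * K + pos, weights=dll, minlength=R * K).reshape(R, K)

        accept = np.log(self.rng.random((R, K))) < dlp
        phi[:, cols] = np.where(accept, prop, cur)
        acc = np.zeros((self.R, self.T))
        acc[:, cols] = accept
        tri = np.zeros((self.R, self.T))
        tri[:, cols] = 1.0
        self._track("phi", acc, tri)
        self._refresh_caches()

    def _phi_update_marginal(self):
        d = self.data
        rng = self.rng
        mix = self._mix()
        logpi = np.log(self.pi)
        log1mpi = np.log1p(-self.pi)
        sd0 = self.sig / np.sqrt(1.0 - self.rho**2)
        acc = np.zeros((self.R, self.T))
        for r in range(self.R):
            rho_r, sig_r = self.rho[r], self.sig[r]
            for t in range(self.T):
                v = self.phi[r, t]
                vp = v + self.step_phi[r, t] * rng.standard_normal()
                if t == 0:
                    dlp = -0.5 * (vp / sd0[r]) ** 2 + 0.5 * (v / sd0[r]) ** 2
                else:
                    pm = rho_r * self.phi[r, t - 1]
                    dlp = -0.5 * ((vp - pm) / sig_r) ** 2 + 0.5 * ((v - pm) / sig_r) ** 2
                if t < self.T - 1:
                    nxt = self.phi[r, t + 1]
                    dlp += -0.5 * ((nxt - rho_r * vp) / sig_r) ** 2
                    dlp -= -0.5 * ((nxt - rho_r * v) / sig_r) ** 2
                o = self.obs_by_site[r][t]
                if o.size:
                    srb0 = self.b * math.exp(vp)
                    mu0n = math.log(srb0)
                    mu1n = math.log(srb0 + self.alpha[r, t])
                    ll0n = _normal_ll(d.y[o], mu0n, self.sd[o])
                    ll1n = _normal_ll(d.y[o], mu1n, self.sd[o])
                    S0n = self.S0[r] + (ll0n - self.ll0[o]).sum()
                    S1n = self.S1[r] + (ll1n - self.ll1[o]).sum()
                    mix_new = np.logaddexp(logpi[r] + S1n, log1mpi[r] + S0n)
                    dlp += mix_new - mix[r]
                else:
                    S0n, S1n, mix_new = self.S0[r], self.S1[r], mix[r]
                if math.log(rng.random()) < dlp:
                    self.phi[r, t] = vp
                    acc[r, t] = 1.0
                    if o.size:
                        self.ll0[o] = ll0n
                        self.ll1[o] = ll1n
                        self.mu0[o] = mu0n
                        self.mu1[o] = mu1n
                        self.S0[r], self.S1[r] = S0n, S1n
                        mix[r] = mix_new
        self._track("phi", acc, np.ones((self.R, self.T)))

    # -- trapezoid updates ------------------------------------------------

    def _trap_update(self):
        rng = self.rng
        if self.marginal:
            active = np.arange(self.R)
        else:
            free = np.flatnonzero(self.delta == 0)
            # delta=0: the likelihood is flat in the trapezoid, so its full
            # conditional is the prior -- draw it exactly.
            for r in free:
                for k, (_, prior) in enumerate(self.trap_priors):
                    self.trap[k, r] = float(prior.rvs(rng))
            if free.size:
                self.alpha[free] = self._alpha_for(free)
                self._refresh_caches()  # branch-1 likelihoods went stale
            active = np.flatnonzero(self.delta == 1)
        if active.size == 0:
            return

        d = self.data
        if self.marginal:
            logpi = np.log(self.pi)
            log1mpi = np.log1p(-self.pi)
        for k, (_, prior) in enumerate(self.trap_priors):
            cur = self.trap[k, active].copy()
            prop = cur + self.step_trap[k, active] * rng.standard_normal(active.size)
            ok = np.asarray(prior.in_support(prop))
            trap_prop = self.trap[:, active].copy()
            trap_prop[k] = np.where(ok, prop, cur)
            alpha_new = trapezoid_profile(self.years_f, *trap_prop)
            dlp = np.where(
                ok,
                prior.logpdf_unnorm(np.where(ok, prop, cur))
                - prior.logpdf_unnorm(cur),
                -np.inf,
            )
            accepted = np.zeros(active.size, dtype=bool)
            for j, r in enumerate(active):
                if not ok[j]:
                    continue
                o = self.obs_by_region[r]
                if o.size:
                    mu1n = np.log(
                        self.b * np.exp(self.phi[r, d.t_idx[o]])
                        + alpha_new[j, d.t_idx[o]]
                    )
                    ll1n = _normal_ll(d.y[o], mu1n, self.sd[o])
                    S1n = self.S1[r] + (ll1n - self.ll1[o]).sum()
                else:
                    S1n = self.S1[r]
                if self.marginal:
                    mix_new = np.logaddexp(logpi[r] + S1n, log1mpi[r] + self.S0[r])
                    mix_cur = np.logaddexp(
                        logpi[r] + self.S1[r], log1mpi[r] + self.S0[r]
                    )
                    dlp_j = dlp[j] + mix_new - mix_cur
                else:
                    dlp_j = dlp[j] + S1n - self.S1[r]
                if math.log(rng.random()) < dlp_j:
                    accepted[j] = True
                    self.trap[k, r] = prop[j]
                    self.alpha[r] = alpha_new[j]
                    if o.size:
                        self.mu1[o] = mu1n
                        self.ll1[o] = ll1n
                        self.S1[r] = S1n
            acc = np.zeros((5, self.R))
            acc[k, active] = accepted
            tri = np.zeros((5, self.R))
            tri[k, active] = 1.0
            self._track("trap", acc, tri)

    # -- detector and inflation probability --------------------------------

    def _delta_update(self):
        logodds = (
            np.log(self.pi) - np.log1p(-self.pi) + self.S1 - self.S0
        )
        p1 = expit(logodds)
        self.delta = (self.rng.random(self.R) < p1).astype(int)

    def _pi_update(self):
        if self.marginal:
            # pi enters the mixture weight; Metropolis on the logit scale with
            # its Beta prior.
            rng = self.rng
            for r in range(self.R):
                z = logit(self.pi[r])
                zp = z + self.step_pi * rng.standard_normal()
                pp = expit(zp)
                mix_cur = np.logaddexp(
                    np.log(self.pi[r]) + self.S1[r],
                    np.log1p(-self.pi[r]) + self.S0[r],
                )
                mix_new = np.logaddexp(
                    np.log(pp) + self.S1[r], np.log1p(-pp) + self.S0[r]
                )
                a, b = self.hypers.pi_a, self.hypers.pi_b
                dlp = (
                    mix_new
                    - mix_cur
                    + a * (math.log(pp) - math.log(self.pi[r]))
                    + b * (math.log1p(-pp) - math.log1p(-self.pi[r]))
                )
                # (a-1)+1 and (b-1)+1 exponents: Beta prior plus the logit
                # Jacobian log(p(1-p)).
                if math.log(rng.random()) < dlp:
                    self.pi[r] = pp
                    self._track("pi", 1.0)
                else:
                    self._track("pi", 0.0)
        else:
            self.pi = self.rng.beta(
                self.hypers.pi_a + self.delta,
                self.hypers.pi_b + 1 - self.delta,
            )
            self.pi = np.clip(self.pi, 1e-9, 1 - 1e-9)

    # -- AR(1) and error-scale updates -------------------------------------

    def _ar1_rows_lp(self, rho, sig):
        """Log density of each region's phi row under AR(1)(rho, sig)."""
        phi = self.phi
        rho = np.broadcast_to(np.asarray(rho, dtype=float), (self.R,))
        sig = np.broadcast_to(np.asarray(sig, dtype=float), (self.R,))
        sd0 = sig / np.sqrt(1.0 - rho**2)
        lp = -0.5 * (phi[:, 0] / sd0) ** 2 - np.log(sd0)
        if self.T > 1:
            resid = phi[:, 1:] - rho[:, None] * phi[:, :-1]
            lp = lp + (-0.5 * (resid / sig[:, None]) ** 2).sum(axis=1) - (
                self.T - 1
            ) * np.log(sig)
        return lp

    def _ar1_update(self):
        rng = self.rng
        shared = not self.config.region_specific_ar1

        # rho: uniform(0,1) prior, random walk on logit(rho).
        z = logit(self.rho[:1] if shared else self.rho)
        zp = z + self.step_rho * rng.standard_normal(z.shape)
        rho_p = expit(zp)
        lp_cur = self._ar1_rows_lp(self.rho, self.sig)
        rho_new = np.broadcast_to(rho_p, (self.R,)) if shared else rho_p
        lp_new = self._ar1_rows_lp(rho_new, self.sig)
        jac = np.log(rho_p * (1 - rho_p)) - np.log(
            (self.rho[:1] if shared else self.rho)
            * (1 - (self.rho[:1] if shared else self.rho))
        )
        if shared:
            dlp = lp_new.sum() - lp_cur.sum() + float(jac[0])
            if math.log(rng.random()) < dlp:
                self.rho = np.full(self.R, float(rho_p[0]))
                self._track("rho", 1.0)
            else:
                self._track("rho", 0.0)
        else:
            accept = np.log(rng.random(self.R)) < (lp_new - lp_cur + jac)
            self.rho = np.where(accept, rho_p, self.rho)
            self._track("rho", accept.mean())

        # sigma_eps: half-normal prior, random walk on log sigma.
        w = np.log(self.sig[:1] if shared else self.sig)
        wp = w + self.step_sig * rng.standard_normal(w.shape)
        sig_p = np.exp(wp)
        lp_cur = self._ar1_rows_lp(self.rho, self.sig)
        sig_new = np.broadcast_to(sig_p, (self.R,)) if shared else sig_p
        lp_new = self._ar1_rows_lp(self.rho, sig_new)
        scale = self.hypers.sigma_eps_scale
        prior_jac = (-0.5 * (sig_p / scale) ** 2 + np.log(sig_p)) - (
            -0.5 * ((self.sig[:1] if shared else self.sig) / scale) ** 2
            + np.log(self.sig[:1] if shared else self.sig)
        )
        if shared:
            dlp = lp_new.sum() - lp_cur.sum() + float(prior_jac[0])
            if math.log(rng.random()) < dlp:
                self.sig = np.full(self.R, float(sig_p[0]))
                self._track("sig", 1.0)
            else:
                self._track("sig", 0.0)
        else:
            accept = np.log(rng.random(self.R)) < (lp_new - lp_cur + prior_jac)
            self.sig = np.where(accept, sig_p, self.sig)
            self._track("sig", accept.mean())

    def _region_target(self, S0, S1):
        """Per-region data log likelihood given branch sums."""
        if self.marginal:
            return np.logaddexp(np.log(self.pi) + S1, np.log1p(-self.pi) + S0)
        return np.where(self.delta == 1, S1, S0)

    def _compute_sums(self, phi, alpha):
        """Branch likelihood sums and caches for a candidate phi field."""
        d = self.data
        srb0_obs = self.b * np.exp(phi[d.r_idx, d.t_idx])
        mu0 = np.log(srb0_obs)
        mu1 = np.log(srb0_obs + alpha[d.r_idx, d.t_idx])
        ll0 = _normal_ll(d.y, mu0, self.sd)
        ll1 = _normal_ll(d.y, mu1, self.sd)
        S0 = np.bincount(d.r_idx, weights=ll0, minlength=self.R)
        S1 = np.bincount(d.r_idx, weights=ll1, minlength=self.R)
        return S0, S1, {"mu0": mu0, "mu1": mu1, "ll0": ll0, "ll1": ll1}

    def _adopt(self, phi, S0, S1, caches):
        self.phi = phi
        self.S0, self.S1 = S0, S1
        self.mu0, self.mu1 = caches["mu0"], caches["mu1"]
        self.ll0, self.ll1 = caches["ll0"], caches["ll1"]

    def _nc_ar1_moves(self):
        """Interweaving: joint (sigma_eps, phi) and (rho, phi) moves.

        In the non-centered parameterization the AR(1) prior factors cancel
        exactly, so these moves are accepted on the data likelihood and the
        hyperprior alone -- they break the strong coupling between the
        AR(1) scale parameters and the high-dimensional phi field that makes
        purely centered updates mix slowly.
        """
        rng = self.rng
        shared = not self.config.region_specific_ar1
        cur_target = self._region_target(self.S0, self.S1)

        # --- scale move: sigma' = c*sigma, phi' = c*phi ---
        if shared:
            w = math.log(self.sig[0])
            wp = w + self.step_ncsig * rng.standard_normal()
            c = math.exp(wp - w)
            sig_p = self.sig * c
            phi_new = self.phi * c
            S0n, S1n, caches = self._compute_sums(phi_new, self.alpha)
            scale = self.hypers.sigma_eps_scale
            dlp = (
                (self._region_target(S0n, S1n) - cur_target).sum()
                - 0.5 * (sig_p[0] / scale) ** 2
                + 0.5 * (self.sig[0] / scale) ** 2
                + (wp - w)
            )
            if math.log(rng.random()) < dlp:
                self.sig = sig_p
                self._adopt(phi_new, S0n, S1n, caches)
                cur_target = self._region_target(self.S0, self.S1)
                self._track("ncsig", 1.0)
            else:
                self._track("ncsig", 0.0)
        else:
            w = np.log(self.sig)
            wp = w + self.step_ncsig * rng.standard_normal(self.R)
            c = np.exp(wp - w)
            phi_new = self.phi * c[:, None]
            S0n, S1n, caches = self._compute_sums(phi_new, self.alpha)
            scale = self.hypers.sigma_eps_scale
            dlp = (
                self._region_target(S0n, S1n)
                - cur_target
                - 0.5 * ((self.sig * c) / scale) ** 2
                + 0.5 * (self.sig / scale) ** 2
                + (wp - w)
            )
            accept = np.log(rng.random(self.R)) < dlp
            if accept.any():
                self.sig = np.where(accept, self.sig * c, self.sig)
                self.phi = np.where(accept[:, None], phi_new, self.phi)
                self.S0, self.S1, _ = self._compute_sums(self.phi, self.alpha)
                self._refresh_caches()
                cur_target = self._region_target(self.S0, self.S1)
            self._track("ncsig", accept.mean())

        # --- rho move holding standardized innovations fixed ---
        sd0 = self.sig / np.sqrt(1.0 - self.rho**2)
        z = np.empty_like(self.phi)
        z[:, 0] = self.phi[:, 0] / sd0
        if self.T > 1:
            z[:, 1:] = (self.phi[:, 1:] - self.rho[:, None] * self.phi[:, :-1]) / self.sig[
                :, None
            ]

        if shared:
            zz = logit(self.rho[0])
            zzp = zz + self.step_ncrho * rng.standard_normal()
            rho_p = float(expit(zzp))
            rho_new = np.full(self.R, rho_p)
        else:
            zz = logit(self.rho)
            zzp = zz + self.step_ncrho * rng.standard_normal(self.R)
            rho_new = expit(zzp)

        sd0p = self.sig / np.sqrt(1.0 - rho_new**2)
        phi_new = np.empty_like(self.phi)
        phi_new[:, 0] = z[:, 0] * sd0p
        for t in range(1, self.T):
            phi_new[:, t] = rho_new * phi_new[:, t - 1] + self.sig * z[:, t]
        S0n, S1n, caches = self._compute_sums(phi_new, self.alpha)
        jac = np.log(rho_new * (1 - rho_new)) - np.log(self.rho * (1 - self.rho))
        if shared:
            dlp = (self._region_target(S0n, S1n) - cur_target).sum() + float(jac[0])
            if math.log(rng.random()) < dlp:
                self.rho = rho_new
                self._adopt(phi_new, S0n, S1n, caches)
                self._track("ncrho", 1.0)
            else:
                self._track("ncrho", 0.0)
        else:
            dlp = self._region_target(S0n, S1n) - cur_target + jac
            accept = np.log(rng.random(self.R)) < dlp
            if accept.any():
                self.rho = np.where(accept, rho_new, self.rho)
                self.phi = np.where(accept[:, None], phi_new, self.phi)
                self.S0, self.S1, _ = self._compute_sums(self.phi, self.alpha)
                self._refresh_caches()
            self._track("ncrho", accept.mean())

    def _sigma_ns_update(self):
        if not self.config.estimate_sigma_ns:
            return
        d = self.data
        rng = self.rng
        scale = self.hypers.sigma_ns_scale
        for s in range(len(d.source_types)):
            o = np.flatnonzero(d.stype_idx == s)
            w = math.log(self.sigma_ns[s]) if self.sigma_ns[s] > 0 else -10.0
            wp = w + self.step_ns[s] * rng.standard_normal()
            ns_p = math.exp(wp)
            sd_new = np.sqrt(d.se[o] ** 2 + ns_p**2)
            ll0n = _normal_ll(d.y[o], self.mu0[o], sd_new)
            ll1n = _normal_ll(d.y[o], self.mu1[o], sd_new)
            dS0 = np.bincount(d.r_idx[o], weights=ll0n - self.ll0[o], minlength=self.R)
            dS1 = np.bincount(d.r_idx[o], weights=ll1n - self.ll1[o], minlength=self.R)
            if self.marginal:
                mix_cur = self._mix().sum()
                S0n, S1n = self.S0 + dS0, self.S1 + dS1
                mix_new = np.logaddexp(
                    np.log(self.pi) + S1n, np.log1p(-self.pi) + S0n
                ).sum()
                dll = mix_new - mix_cur
            else:
                dll = np.where(self.delta == 1, dS1, dS0).sum()
            dlp = (
                dll
                - 0.5 * (ns_p / scale) ** 2
                + 0.5 * (self.sigma_ns[s] / scale) ** 2
                + (wp - w)
            )
            if math.log(rng.random()) < dlp:
                self.sigma_ns[s] = ns_p
                self.sd[o] = sd_new
                self.ll0[o] = ll0n
                self.ll1[o] = ll1n
                self.S0 += dS0
                self.S1 += dS1
                acc = 1.0
            else:
                acc = 0.0
            a = np.zeros(len(d.source_types))
            a[s] = acc
            t = np.zeros(len(d.source_types))
            t[s] = 1.0
            self._track("ns", a, t)

    # -- main loop ---------------------------------------------------------

    def sweep(self):
        if self.marginal:
            self._phi_update_marginal()
        else:
            # Two cheap vectorized passes over the phi field per sweep: the
            # field is high-dimensional and its updates are far cheaper than
            # the trapezoid block.
            for _ in range(2):
                self._phi_update_indicator(0)
                self._phi_update_indicator(1)
        self._trap_update()
        self._delta_update()
        self._pi_update()
        self._ar1_update()
        self._nc_ar1_moves()
        self._sigma_ns_update()

    def run(self, n_warmup: int, n_iter: int) -> dict[str, np.ndarray]:
        R, T = self.R, self.T
        S = len(self.data.source_types)
        out = {
            "phi": np.empty((n_iter, R, T)),
            "delta": np.empty((n_iter, R), dtype=int),
            "pi": np.empty((n_iter, R)),
            "gamma": np.empty((n_iter, R)),
            "lambda1": np.empty((n_iter, R)),
            "lambda2": np.empty((n_iter, R)),
            "lambda3": np.empty((n_iter, R)),
            "xi": np.empty((n_iter, R)),
            "rho": np.empty((n_iter, R)),
            "sigma_eps": np.empty((n_iter, R)),
            "sigma_ns": np.empty((n_iter, S)),
        }
        batch = 0
        for i in range(n_warmup):
            self.sweep()
            if (i + 1) % _ADAPT_BATCH == 0:
                batch += 1
                self._adapt(batch)
        self._acc.clear()
        self._trials.clear()
        for i in range(n_iter):
            self.sweep()
            out["phi"][i] = self.phi
            out["delta"][i] = self.delta
            out["pi"][i] = self.pi
            for k, name in enumerate(_TRAP_NAMES):
                out[name][i] = self.trap[k]
            out["rho"][i] = self.rho
            out["sigma_eps"][i] = self.sig
            out["sigma_ns"][i] = self.sigma_ns
        return out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------


def fit(observations: pd.DataFrame, config: ModelConfig | None = None, seed: int = 0) -> PosteriorDraws:
    """Run MCMC on an observation table and return posterior draws.

    Chains are run sequentially with per-chain RNGs derived deterministically
    from ``seed``; identical data, config, and seed give an identical draw
    stream.  Convergence is assessed with split R-hat on all continuous
    parameters; a run with any R-hat above 1.05 is flagged in
    ``draws.diagnostics`` (and logged), never silently ignored.
    """
    config = config or ModelConfig()
    data = _prepare(observations, config)
    seeds = np.random.SeedSequence(seed).spawn(config.n_chains)
    chains = []
    for c in range(config.n_chains):
        sampler = _Sampler(data, config, np.random.default_rng(seeds[c]))
        chains.append(sampler.run(config.n_warmup, config.n_iter))

    stacked = {k: np.stack([ch[k] for ch in chains]) for k in chains[0]}
    draws = PosteriorDraws(
        regions=data.regions,
        years=data.years,
        source_types=data.source_types,
        config=config,
        n_warmup=config.n_warmup,
        seed=seed,
        **stacked,
    )
    diag = diagnostics(draws)
    draws.diagnostics = {
        "converged": bool(diag.attrs["converged"]),
        "max_rhat": diag.attrs["max_rhat"],
        "min_ess": diag.attrs["min_ess"],
        "table": diag,
    }
    if not draws.diagnostics["converged"]:
        logger.warning(
            "MCMC not converged: max R-hat %.3f (threshold 1.05)",
            draws.diagnostics["max_rhat"],
        )
    return draws


def _monitored_samples(draws: PosteriorDraws) -> dict[str, np.ndarray]:
    """Continuous scalar samples monitored for convergence, name -> (C, D)."""
    out: dict[str, np.ndarray] = {}
    for r_i, r in enumerate(draws.regions):
        out[f"pi[{r}]"] = draws.pi[:, :, r_i]
        for name in _TRAP_NAMES:
            out[f"{name}[{r}]"] = getattr(draws, name)[:, :, r_i]
        step = max(1, len(draws.years) // 8)
        for t_i in range(0, len(draws.years), step):
            out[f"phi[{r},{draws.years[t_i]}]"] = draws.phi[:, :, r_i, t_i]
    if draws.config.region_specific_ar1:
        for r_i, r in enumerate(draws.regions):
            out[f"rho[{r}]"] = draws.rho[:, :, r_i]
            out[f"sigma_eps[{r}]"] = draws.sigma_eps[:, :, r_i]
    else:
        out["rho"] = draws.rho[:, :, 0]
        out["sigma_eps"] = draws.sigma_eps[:, :, 0]
    if draws.config.estimate_sigma_ns:
        for s_i, s in enumerate(draws.source_types):
            out[f"sigma_ns[{s}]"] = draws.sigma_ns[:, :, s_i]
    return out


def compute_diagnostics(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Split R-hat and effective sample size for (chain, draw) sample arrays.

    Returns a table with one row per parameter and sets ``converged`` in the
    frame's ``attrs``: True iff every R-hat is finite and at most 1.05.
    Undefined R-hat (constant or single-chain samples) counts as not
    converged and is reported as NaN.  With a single chain, R-hat is skipped
    (with a warning) and only ESS is reported.
    """
    import warnings

    import arviz as az

    names = list(samples)
    arrays = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    any_arr = next(iter(arrays.values()))
    single_chain = any_arr.shape[0] < 2
    if single_chain:
        logger.warning("only one chain: R-hat unavailable, reporting ESS only")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        idata = az.from_dict(posterior=arrays)
        ess = az.ess(idata)
        rhat = None if single_chain else az.rhat(idata)

    rows = []
    for name in names:
        r = float("nan") if rhat is None else float(rhat[name].values)
        e = float(ess[name].values)
        rows.append({"parameter": name, "rhat": r, "ess": e})
    df = pd.DataFrame(rows)
    finite = df["rhat"].to_numpy()
    converged = bool(np.all(np.isfinite(finite)) and np.all(finite <= 1.05))
    df.attrs["converged"] = converged
    df.attrs["max_rhat"] = float(np.nanmax(finite)) if np.any(np.isfinite(finite)) else float("nan")
    df.attrs["min_ess"] = float(np.nanmin(df["ess"].to_numpy()))
    return df


def diagnostics(draws: PosteriorDraws) -> pd.DataFrame:
    """Convergence diagnostics for a fit (continuous parameters monitored)."""
    return compute_diagnostics(_monitored_samples(draws))


def inflation_probability(draws: PosteriorDraws, region: str) -> float:
    """Posterior probability that the region has any SRB imbalance."""
    r = draws.region_index(region)
    return float(draws.delta[:, :, r].mean())


def mcse_probability(draws: PosteriorDraws, region: str) -> float:
    """Monte-Carlo standard error of ``inflation_probability`` (chain spread)."""
    r = draws.region_index(region)
    means = draws.delta[:, :, r].mean(axis=1)
    if len(means) < 2:
        p = means.mean()
        return float(math.sqrt(max(p * (1 - p), 1e-12) / draws.n_draws))
    return float(means.std(ddof=1) / math.sqrt(len(means)))


def classify_transition(prob: float, threshold: float = 0.95) -> bool:
    """True iff the inflation probability reaches the threshold (inclusive)."""
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must lie in [0, 1], got {prob}")
    return prob >= threshold


def srb_draws(
    draws: PosteriorDraws, region: str, delta_one_only: bool = False
) -> np.ndarray:
    """Per-draw SRB trajectories b*exp(phi) + delta*alpha over the year grid.

    Returns an array of shape (n_draws, n_years).  With ``delta_one_only``,
    restrict to draws where the region's detector is on (raises
    ``ConditioningError`` if there are none).
    """
    r = draws.region_index(region)
    phi = draws.flat("phi")[:, r, :]
    delta = draws.flat("delta")[:, r]
    alpha = trapezoid_profile(
        draws.years.astype(float),
        draws.flat("gamma")[:, r],
        draws.flat("lambda1")[:, r],
        draws.flat("lambda2")[:, r],
        draws.flat("lambda3")[:, r],
        draws.flat("xi")[:, r],
    )
    srb = draws.config.baseline * np.exp(phi) + delta[:, None] * alpha
    if delta_one_only:
        mask = delta == 1
        if not mask.any():
            raise ConditioningError(
                f"no delta=1 draws for region {region}; cannot condition on a transition"
            )
        srb = srb[mask]
    return srb


def annual_estimates(
    draws: PosteriorDraws,
    region: str,
    first_year: int | None = None,
    last_year: int | None = None,
) -> pd.DataFrame:
    """Pointwise posterior median and 95% credible interval of annual SRB."""
    srb = srb_draws(draws, region)
    med, lo, hi = np.percentile(srb, [50.0, 2.5, 97.5], axis=0)
    df = pd.DataFrame(
        {"region": region, "year": draws.years, "median": med, "lower95": lo, "upper95": hi}
    )
    if first_year is not None:
        df = df[df["year"] >= first_year]
    if last_year is not None:
        df = df[df["year"] <= last_year]
    return df.reset_index(drop=True)


def summarize_transition(draws: PosteriorDraws, region: str) -> dict:
    """Transition schedule summary, conditional on detector-on draws.

    Reports the posterior median and 95% CI of the start year, the SRB in the
    (median) start year, the peak year (the year maximizing the posterior
    median SRB trajectory, reported as a point value), and the SRB in that
    peak year.
    """
    r = draws.region_index(region)
    prob = inflation_probability(draws, region)
    srb1 = srb_draws(draws, region, delta_one_only=True)
    delta = draws.flat("delta")[:, r] == 1
    gamma = draws.flat("gamma")[:, r][delta]

    g_med, g_lo, g_hi = np.percentile(gamma, [50.0, 2.5, 97.5])
    start_year = int(round(g_med))
    start_idx = int(np.clip(np.searchsorted(draws.years, start_year), 0, len(draws.years) - 1))
    s_med, s_lo, s_hi = np.percentile(srb1[:, start_idx], [50.0, 2.5, 97.5])

    med_traj = np.median(srb1, axis=0)
    peak_idx = int(np.argmax(med_traj))
    p_med, p_lo, p_hi = np.percentile(srb1[:, peak_idx], [50.0, 2.5, 97.5])

    return {
        "region": region,
        "inflation_probability": prob,
        "start_year": start_year,
        "start_year_ci": (float(g_lo), float(g_hi)),
        "srb_at_start": float(s_med),
        "srb_at_start_ci": (float(s_lo), float(s_hi)),
        "peak_year": int(draws.years[peak_idx]),
        "srb_at_peak": float(p_med),
        "srb_at_peak_ci": (float(p_lo), float(p_hi)),
    }
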