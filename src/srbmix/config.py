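"""Model and sampler configuration, YAML-serializable.

Every prior default and structural switch of the model is exposed here so a
run can be reproduced from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .model import (
    DEFAULT_BASELINE,
    Hyperparams,
    TruncatedNormal,
)

__all__ = ["ModelConfig", "short_config"]


def _prior_to_dict(p: TruncatedNormal) -> dict:
    return {
        "mean": p.mean,
        "sd": p.sd,
        "lower": None if math.isinf(p.lower) else p.lower,
        "upper": None if math.isinf(p.upper) else p.upper,
    }


def _prior_from_dict(d: dict) -> TruncatedNormal:
    return TruncatedNormal(
        mean=float(d["mean"]),
        sd=float(d["sd"]),
        lower=-math.inf if d.get("lower") is None else float(d["lower"]),
        upper=math.inf if d.get("upper") is None else float(d["upper"]),
    )


@dataclass
class ModelConfig:
    """Complete configuration of a model fit.

    Attributes
    ----------
    baseline:
        National natural SRB level b (ratio scale).
    hypers:
        Fixed national hyperparameters: truncated-normal priors for the
        regional trapezoid parameters, Beta prior for the inflation
        probability, half-normal scales for the AR(1) innovation sd and
        non-sampling error sds.
    detector_method:
        "indicator" samples the Bernoulli detector explicitly inside the
        Gibbs sweep; "marginalize" integrates it out of the likelihood and
        draws it from its exact conditional for reporting.
    estimate_sigma_ns:
        Whether source-type non-sampling error sds are estimated.  When
        False, ``sigma_ns_fixed`` (per source type, default 0.0) is used,
        recovering a sampling-error-only observation model.
    region_specific_ar1:
        Estimate (rho, sigma_eps) per region instead of shared across the
        six regions (shared is the default: six short series borrow
        strength).
    regions / year_start / year_end:
        Optional overrides; by default both the region set and the
        estimation year grid are inferred from the observation table.
    """

    baseline: float = DEFAULT_BASELINE
    hypers: Hyperparams = field(default_factory=Hyperparams)
    detector_method: str = "indicator"
    estimate_sigma_ns: bool = True
    sigma_ns_fixed: dict = field(default_factory=dict)
    region_specific_ar1: bool = False
    classification_threshold: float = 0.95
    regions: tuple | None = None
    year_start: int | None = None
    year_end: int | None = None
    horizon_year: int = 2050
    n_chains: int = 4
    n_warmup: int = 2000
    n_iter: int = 2000

    def __post_init__(self) -> None:
        if self.detector_method not in ("indicator", "marginalize"):
            raise ValueError(
                f"detector_method must be 'indicator' or 'marginalize', "
                f"got {self.detector_method!r}"
            )
        if self.regions is not None:
            self.regions = tuple(self.regions)
        # Keep the baseline and the hyperparameter block consistent.
        if self.hypers.b != self.baseline:
            self.hypers = dataclasses.replace(self.hypers, b=self.baseline)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        h = self.hypers
        return {
            "baseline": self.baseline,
            "priors": {
                "gamma": _prior_to_dict(h.gamma),
                "lambda1": _prior_to_dict(h.lambda1),
                "lambda2": _prior_to_dict(h.lambda2),
                "lambda3": _prior_to_dict(h.lambda3),
                "xi": _prior_to_dict(h.xi),
                "pi_beta": [h.pi_a, h.pi_b],
                "sigma_eps_halfnormal_scale": h.sigma_eps_scale,
                "sigma_ns_halfnormal_scale": h.sigma_ns_scale,
            },
            "detector_method": self.detector_method,
            "estimate_sigma_ns": self.estimate_sigma_ns,
            "sigma_ns_fixed": dict(self.sigma_ns_fixed),
            "region_specific_ar1": self.region_specific_ar1,
            "classification_threshold": self.classification_threshold,
            "regions": list(self.regions) if self.regions else None,
            "year_start": self.year_start,
            "year_end": self.year_end,
            "horizon_year": self.horizon_year,
            "n_chains": self.n_chains,
            "n_warmup": self.n_warmup,
            "n_iter": self.n_iter,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        priors = d.pop("priors", {})
        kwargs = {}
        hyper_kwargs = {"b": float(d.get("baseline", DEFAULT_BASELINE))}
        for name in ("gamma", "lambda1", "lambda2", "lambda3", "xi"):
            if name in priors:
                hyper_kwargs[name] = _prior_from_dict(priors[name])
        if "pi_beta" in priors:
            hyper_kwargs["pi_a"], hyper_kwargs["pi_b"] = map(float, priors["pi_beta"])
        if "sigma_eps_halfnormal_scale" in priors:
            hyper_kwargs["sigma_eps_scale"] = float(priors["sigma_eps_halfnormal_scale"])
        if "sigma_ns_halfnormal_scale" in priors:
            hyper_kwargs["sigma_ns_scale"] = float(priors["sigma_ns_halfnormal_scale"])
        kwargs["hypers"] = Hyperparams(**hyper_kwargs)
        for key in (
            "baseline",
            "detector_method",
            "estimate_sigma_ns",
            "sigma_ns_fixed",
            "region_specific_ar1",
            "classification_threshold",
            "regions",
            "year_start",
            "year_end",
            "horizon_year",
            "n_chains",
            "n_warmup",
            "n_iter",
        ):
            if key in d and d[key] is not None:
                kwargs[key] = d[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Stable short hash of the configuration, for run manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def short_config(**overrides) -> ModelConfig:
    """A shortened-chain configuration for validation harnesses and tests.

    Two chains of 600 kept iterations after 600 warmup sweeps: long enough
    for stable posterior means of the detector and the trapezoid parameters
    on synthetic data of the default scenario's size, short enough to run
    many replicates.
    """
    defaults = dict(n_chains=2, n_warmup=600, n_iter=600)
    defaults.update(overrides)
    return ModelConfig(**defaults)
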