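"""Synthetic multi-source regional SRB databases with known ground truth.

The generator mirrors the statistical structure of the compiled Vietnamese
regional database: six regions observed between the mid-1970s and 2019 by a
mix of censuses (one reference year each, large birth counts), retrospective
birth-history surveys (annual observations within a 25-year recall window,
small counts), and annual surveys whose sampling design — and hence sampling
error — is unknown and must be imputed downstream.

Truth is generated from the estimation model itself: a stationary AR(1)
log-fluctuation around the national baseline plus, where the true detector
is on, a trapezoid imbalance.  Observation noise is binomial sampling of
male births among the planned total births; an optional design-effect
multiplier can inflate it to emulate complex survey designs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from .database import REGION_CODES, validate_observations
from .model import AR1Params, TrapezoidParams, trapezoid_profile

__all__ = [
    "ScenarioError",
    "SourcePlan",
    "ScenarioSpec",
    "default_vietnam_like_scenario",
    "simulate_truth",
    "simulate_observations",
    "simulate_database",
]

MIN_BIRTHS_PER_CELL = 20


class ScenarioError(ValueError):
    """Invalid synthetic-scenario specification."""


@dataclass(frozen=True)
class SourcePlan:
    """One planned data source.

    ``years`` are the integer calendar years of the births the source
    reports on; ``births_per_region_year`` is the planned total number of
    births per (region, year) cell.  ``fractional_offset`` shifts the
    recorded reference year (annual surveys and censuses report on the 12
    months before the survey date, so their reference point falls half a
    year earlier).
    """

    name: str
    source_type: str
    survey_year: int
    years: tuple[int, ...]
    births_per_region_year: int
    fractional_offset: float = 0.0
    report_sampling_se: bool = True
    design_effect: float = 1.0


@dataclass
class ScenarioSpec:
    """Ground-truth configuration for the synthetic generator."""

    regions: tuple[str, ...]
    year_start: int
    year_end: int
    trapezoids: dict[str, TrapezoidParams]
    delta: dict[str, int]
    ar1: AR1Params
    baseline: float
    sources: tuple[SourcePlan, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.regions) < 1:
            raise ScenarioError("need at least one region")
        if self.year_start >= self.year_end:
            raise ScenarioError("year_start must be before year_end")
        covered: set[str] = set()
        for sp in self.sources:
            if sp.births_per_region_year < MIN_BIRTHS_PER_CELL:
                raise ScenarioError(
                    f"source {sp.name}: births per region-year must be >= "
                    f"{MIN_BIRTHS_PER_CELL}, got {sp.births_per_region_year}"
                )
            if min(sp.years) < self.year_start or max(sp.years) > self.year_end:
                raise ScenarioError(
                    f"source {sp.name} covers years outside the scenario range"
                )
            covered.update(self.regions)
        if not self.sources:
            raise ScenarioError("need at least one source")
        for r in self.regions:
            if r not in self.trapezoids or r not in self.delta:
                raise ScenarioError(f"region {r} missing trapezoid/delta truth")
            if self.delta[r] not in (0, 1):
                raise ScenarioError(f"delta[{r}] must be 0 or 1")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    def true_peak_srb(self, region: str) -> float:
        """Maximum of the noise-free trajectory b + delta*alpha."""
        return self.baseline + self.delta[region] * self.trapezoids[region].xi

    def true_end_year(self, region: str) -> float:
        return self.trapezoids[region].end

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "regions": list(self.regions),
            "year_start": self.year_start,
            "year_end": self.year_end,
            "baseline": self.baseline,
            "ar1": {"rho": self.ar1.rho, "sigma_eps": self.ar1.sigma_eps},
            "delta": dict(self.delta),
            "trapezoids": {r: asdict(tp) for r, tp in self.trapezoids.items()},
            "sources": [asdict(sp) | {"years": list(sp.years)} for sp in self.sources],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            regions=tuple(d["regions"]),
            year_start=int(d["year_start"]),
            year_end=int(d["year_end"]),
            baseline=float(d["baseline"]),
            ar1=AR1Params(**d["ar1"]),
            delta={k: int(v) for k, v in d["delta"].items()},
            trapezoids={k: TrapezoidParams(**v) for k, v in d["trapezoids"].items()},
            sources=tuple(
                SourcePlan(**{**sp, "years": tuple(sp["years"])}) for sp in d["sources"]
            ),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        from pathlib import Path

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_vietnam_like_scenario(seed: int = 0) -> ScenarioSpec:
    """The reference scenario emulating the Vietnamese regional database.

    Six regions over 1975-2019.  Four regions carry a true sex ratio
    transition starting around 2001 with 12-15 year rises and maximum
    imbalances between 0.054 and 0.083 (the strongest region peaking at
    1.146 on the ratio scale); two southern-like regions have none.  The
    source plan has four census-like sources with large birth counts, three
    retrospective-survey-like sources with a 25-year birth-history window
    and a few hundred births per region-year, and fourteen annual-survey-like
    sources that do not report sampling errors.
    """
    regions = REGION_CODES  # NMM, RRD, NCC, CH, SE, MKD
    trapezoids = {
        "NMM": TrapezoidParams(2001.5, 15.0, 3.0, 18.0, 0.069),
        "RRD": TrapezoidParams(2001.0, 12.0, 4.0, 18.0, 0.083),
        "NCC": TrapezoidParams(2001.5, 14.0, 4.0, 17.0, 0.054),
        "CH": TrapezoidParams(2001.0, 13.0, 5.0, 18.0, 0.0),
        "SE": TrapezoidParams(2000.5, 12.0, 5.0, 17.0, 0.059),
        "MKD": TrapezoidParams(2001.0, 13.0, 5.0, 18.0, 0.0),
    }
    delta = {"NMM": 1, "RRD": 1, "NCC": 1, "CH": 0, "SE": 1, "MKD": 0}

    sources: list[SourcePlan] = []
    for year, births in ((1989, 13_000), (1999, 6_500), (2009, 44_000), (2019, 230_000)):
        sources.append(
            SourcePlan(
                name=f"{year} Census",
                source_type="census",
                survey_year=year,
                years=(year - 1,),
                births_per_region_year=births,
                fractional_offset=0.5,  # age-0 counts reflect the preceding 12 months
            )
        )
    for survey_year, first, births in ((1997, 1975, 150), (2002, 1978, 140), (2014, 1990, 500)):
        sources.append(
            SourcePlan(
                name=f"{survey_year} Retrospective Survey",
                source_type="retrospective_survey",
                survey_year=survey_year,
                years=tuple(range(first, survey_year)),
                births_per_region_year=births,
            )
        )
    for survey_year in range(2006, 2020):
        sources.append(
            SourcePlan(
                name=f"{survey_year} Annual Survey",
                source_type="annual_survey",
                survey_year=survey_year,
                years=(survey_year - 1,),
                births_per_region_year=3_500,
                fractional_offset=0.5,  # births from the previous 12 months
                report_sampling_se=False,
            )
        )

    return ScenarioSpec(
        regions=regions,
        year_start=1975,
        year_end=2019,
        trapezoids=trapezoids,
        delta=delta,
        ar1=AR1Params(rho=0.5, sigma_eps=0.006),
        baseline=1.063,
        sources=tuple(sources),
        seed=seed,
    )


def simulate_truth(spec: ScenarioSpec, seed: int | None = None) -> pd.DataFrame:
    """Simulate true per-region SRB trajectories on the scenario year grid.

    The log fluctuation phi is drawn from the stationary AR(1); the true SRB
    is ``b*exp(phi) + delta*alpha``.  Returns a table with columns region,
    year, phi, alpha, srb.  Deterministic given the seed (``spec.seed`` by
    default).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    years = spec.years
    T = len(years)
    frames = []
    for region in spec.regions:
        phi = np.empty(T)
        phi[0] = rng.normal(0.0, spec.ar1.stationary_sd)
        eps = rng.normal(0.0, spec.ar1.sigma_eps, size=T - 1)
        for t in range(1, T):
            phi[t] = spec.ar1.rho * phi[t - 1] + eps[t - 1]
        tp = spec.trapezoids[region]
        alpha = trapezoid_profile(
            years.astype(float), tp.gamma, tp.lambda1, tp.lambda2, tp.lambda3, tp.xi
        )
        srb = spec.baseline * np.exp(phi) + spec.delta[region] * alpha
        frames.append(
            pd.DataFrame(
                {"region": region, "year": years, "phi": phi, "alpha": alpha, "srb": srb}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_observations(
    truth: pd.DataFrame, spec: ScenarioSpec, seed: int | None = None
) -> pd.DataFrame:
    """Draw the observation table implied by the scenario's source plan.

    For each planned (source, region, year) cell with ``n`` births, male
    births are Binomial(n, SRB/(1+SRB)); the observed SRB, log-SRB and
    delta-method sampling SE follow from the counts.  Sources flagged as not
    reporting sampling errors emit the SRB only (no counts, no SE), which is
    what downstream imputation must handle.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    srb_lookup = {
        (r, int(y)): s
        for r, y, s in zip(truth["region"], truth["year"], truth["srb"])
    }
    rows = []
    for sp in spec.sources:
        deff = float(sp.design_effect)
        for region in spec.regions:
            for year in sp.years:
                try:
                    true_srb = srb_lookup[(region, year)]
                except KeyError:
                    raise ScenarioError(
                        f"truth does not cover ({region}, {year}) needed by {sp.name}"
                    ) from None
                n = sp.births_per_region_year
                p = true_srb / (1.0 + true_srb)
                male = int(rng.binomial(n, p))
                male = min(max(male, 1), n - 1)  # keep both counts positive
                female = n - male
                srb = male / female
                se = deff * float(np.sqrt(1.0 / male + 1.0 / female))
                row = {
                    "region": region,
                    "source": sp.name,
                    "source_type": sp.source_type,
                    "survey_year": sp.survey_year,
                    "reference_year": year + sp.fractional_offset,
                    "male_births": male if sp.report_sampling_se else np.nan,
                    "female_births": female if sp.report_sampling_se else np.nan,
                    "srb": srb,
                    "sampling_se": se if sp.report_sampling_se else np.nan,
                }
                rows.append(row)
    raw = pd.DataFrame(rows)
    return validate_observations(raw)


def simulate_database(spec: ScenarioSpec, seed: int | None = None):
    """Convenience wrapper: (truth, observations) for a scenario."""
    base = spec.seed if seed is None else seed
    truth = simulate_truth(spec, seed=base)
    obs = simulate_observations(truth, spec, seed=base + 1)
    return truth, obs
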