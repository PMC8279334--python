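"""Multi-source regional SRB observation database.

Handles reading, validation, and preprocessing of sex-ratio-at-birth
observations compiled from censuses and sample surveys of heterogeneous
design.  Each observation carries a region, a data source with its type, a
reference year (possibly fractional, for 12-month recall windows), the
observed SRB (male/female births) and a sampling standard error on the
log-SRB scale.

Preprocessing implements the database rules used for multi-source SRB
compilation:

* retrospective birth-history surveys contribute only births within 25 years
  before the survey was conducted (older recall is unreliable and sparse);
* facility-based birth surveys that recorded only the most recent birth
  contribute only the survey year itself (earlier births from such surveys
  are biased by male-favouring stopping rules);
* annual surveys of unknown sampling design get their missing sampling
  errors imputed conservatively from same-region sources of known design.
"""

from __future__ import annotations


import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REGION_NAMES",
    "REGION_CODES",
    "SOURCE_TYPES",
    "SOURCE_CATALOGUE",
    "CATALOGUE_PRINTED_TOTALS",
    "DatabaseError",
    "SchemaError",
    "RegionMappingError",
    "ImputationError",
    "SRBObservation",
    "normalize_region",
    "srb_from_counts",
    "load_database",
    "write_database",
    "validate_observations",
    "apply_window_rules",
    "impute_sampling_error",
    "catalogue_birth_total",
]


class DatabaseError(ValueError):
    """Base class for database validation problems."""


class SchemaError(DatabaseError):
    """Required column missing or malformed."""


class RegionMappingError(DatabaseError):
    """Region name cannot be mapped to one of the six region codes."""


class ImputationError(DatabaseError):
    """Sampling-error imputation impossible (e.g. empty donor pool)."""


# The six macro-regions of Vietnam, north to south.
REGION_NAMES: dict[str, str] = {
    "NMM": "Northern Midlands and Mountain Areas",
    "RRD": "Red River Delta",
    "NCC": "Northern Central and Central Coastal Areas",
    "CH": "Central Highlands",
    "SE": "South East",
    "MKD": "Mekong River Delta",
}
REGION_CODES: tuple[str, ...] = tuple(REGION_NAMES)

# Accepted spellings -> canonical code.  Deliberately a fixed lookup: unknown
# names fail loudly rather than fuzzy-match.
_NAME_TO_CODE: dict[str, str] = {}
for _code, _name in REGION_NAMES.items():
    _NAME_TO_CODE[_code.lower()] = _code
    _NAME_TO_CODE[_name.lower()] = _code
_NAME_TO_CODE.update(
    {
        "northern midlands and mountains": "NMM",
        "northern midland and mountain areas": "NMM",
        "north central and central coastal areas": "NCC",
        "northern central and central coastal area": "NCC",
        "central coastal areas": "NCC",
        "mekong delta": "MKD",
        "mekong river": "MKD",
        "southeast": "SE",
        "south-east": "SE",
    }
)

SOURCE_TYPES: tuple[str, ...] = (
    "census",
    "retrospective_survey",
    "annual_survey",
    "facility_survey",
)

#: Catalogue of the survey/census sources behind the compiled Vietnamese
#: regional SRB database: printed observation and birth (or household) counts
#: per source.  ``births`` is None where individual-level data are
#: unavailable; ``unit`` distinguishes births from household counts.
SOURCE_CATALOGUE: tuple[dict, ...] = (
    {"source": "1989 Census", "source_type": "census", "n_obs": 6, "count": 79_180, "unit": "births"},
    {"source": "1997 DHS", "source_type": "retrospective_survey", "n_obs": 39, "count": 15_202, "unit": "births"},
    {"source": "1999 Census", "source_type": "census", "n_obs": 6, "count": 39_464, "unit": "births"},
    {"source": "2002 DHS", "source_type": "retrospective_survey", "n_obs": 26, "count": 14_100, "unit": "births"},
    {"source": "2006 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": 24_499, "unit": "births"},
    {"source": "2007 Survey of Birth", "source_type": "facility_survey", "n_obs": 155, "count": 643_683, "unit": "births"},
    {"source": "2008 Survey of Birth", "source_type": "facility_survey", "n_obs": 6, "count": 7_645, "unit": "births"},
    {"source": "2008 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": 23_597, "unit": "births"},
    {"source": "2009 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2009 Census", "source_type": "census", "n_obs": 6, "count": 262_272, "unit": "births"},
    {"source": "2010 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2011 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2012 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2013 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2013-2014 MICS", "source_type": "retrospective_survey", "n_obs": 34, "count": 14_486, "unit": "births"},
    {"source": "2014 Intercensal Survey", "source_type": "retrospective_survey", "n_obs": 154, "count": 482_446, "unit": "births"},
    {"source": "2014 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2015 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": 305_600, "unit": "households"},
    {"source": "2016 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": 305_600, "unit": "households"},
    {"source": "2017 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2018 Annual PCFPS", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2019 Annual PCFPS (Preliminary)", "source_type": "annual_survey", "n_obs": 6, "count": None, "unit": None},
    {"source": "2019 Census", "source_type": "census", "n_obs": 6, "count": 1_374_615, "unit": "births"},
)

#: Totals as printed in the published source table.  The per-source
#: observation counts above sum to 516, not the printed 526; the deposited
#: database is authoritative for the record count, so neither number is
#: forced anywhere — these are reference constants only.
CATALOGUE_PRINTED_TOTALS: dict[str, int] = {"observations": 526, "births": 2_933_093}


def catalogue_birth_total() -> int:
    """Sum of catalogued birth counts over sources with known birth numbers.

    Annual-survey (PCFPS) rows are excluded because their individual-level
    data are unavailable, and household-count rows are excluded because they
    do not count births.
    """
    return int(
        sum(
            row["count"]
            for row in SOURCE_CATALOGUE
            if row["unit"] == "births" and row["source_type"] != "annual_survey"
        )
    )


def normalize_region(name: str) -> str:
    """Map a region name or code to its canonical code; unknown names raise."""
    key = str(name).strip().lower()
    try:
        return _NAME_TO_CODE[key]
    except KeyError:
        raise RegionMappingError(
            f"unknown region name {name!r}; expected one of {sorted(REGION_CODES)} "
            "or a full region name"
        ) from None


def srb_from_counts(male, female, design_effect: float = 1.0):
    """SRB, log-SRB, and delta-method sampling SE from sex-specific counts.

    The SE of log(male/female) for independent count data is
    ``sqrt(1/male + 1/female)``; an optional multiplicative design effect
    inflates it for complex survey designs.  Accepts scalars or arrays.
    """
    male = np.asarray(male, dtype=float)
    female = np.asarray(female, dtype=float)
    if np.any(~np.isfinite(male)) or np.any(~np.isfinite(female)):
        raise DatabaseError("birth counts must be finite")
    if np.any(male <= 0) or np.any(female <= 0):
        raise DatabaseError("birth counts must be > 0 to compute an SRB")
    srb = male / female
    log_srb = np.log(srb)
    se = design_effect * np.sqrt(1.0 / male + 1.0 / female)
    if np.ndim(srb) == 0:
        return float(srb), float(log_srb), float(se)
    return srb, log_srb, se


@dataclass
class SRBObservation:
    """One observed region-year SRB data point with source metadata."""

    region: str
    source: str
    source_type: str
    reference_year: float
    srb: float
    log_srb: float
    sampling_se: float
    survey_year: float | None = None
    male_births: float | None = None
    female_births: float | None = None
    se_imputed: bool = False

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems = []
        if self.region not in REGION_CODES:
            problems.append(f"region {self.region!r} is not a region code")
        if self.source_type not in SOURCE_TYPES:
            problems.append(f"source_type {self.source_type!r} unknown")
        if not (self.srb > 0):
            problems.append(f"srb must be > 0, got {self.srb}")
        elif abs(self.log_srb - math.log(self.srb)) > 1e-9:
            problems.append("log_srb inconsistent with srb")
        if self.male_births is not None and self.female_births is not None:
            if self.female_births <= 0 or self.male_births <= 0:
                problems.append("birth counts must be positive")
            elif abs(self.srb - self.male_births / self.female_births) > 1e-9 * self.srb:
                problems.append("srb inconsistent with birth counts")
        if not (self.sampling_se > 0) and not math.isnan(self.sampling_se):
            problems.append(f"sampling_se must be > 0, got {self.sampling_se}")
        if not 1950.0 <= self.reference_year <= 2020.0:
            problems.append(f"reference_year {self.reference_year} outside [1950, 2020]")
        return problems


_REQUIRED_COLUMNS = ("region", "source", "source_type", "reference_year")
_CANONICAL_COLUMNS = (
    "region",
    "source",
    "source_type",
    "survey_year",
    "reference_year",
    "male_births",
    "female_births",
    "srb",
    "log_srb",
    "sampling_se",
    "se_imputed",
)


def load_database(path, fmt: str | None = None, design_effect: float = 1.0) -> pd.DataFrame:
    """Read and validate a multi-source SRB observation table.

    ``path`` is a CSV or XLSX file (format inferred from the extension unless
    ``fmt`` is given).  Rows may provide either ``srb`` (+ ``sampling_se``)
    directly or ``male_births``/``female_births``, from which SRB, log-SRB
    and the delta-method sampling SE are computed.  Annual-survey rows may
    leave ``sampling_se`` empty (to be imputed later); all other rows must
    have a positive SE.  Any invariant violation raises ``DatabaseError``
    with one itemized message per offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    return validate_observations(raw, design_effect=design_effect)


def validate_observations(raw: pd.DataFrame, design_effect: float = 1.0) -> pd.DataFrame:
    """Normalize, complete, and validate a raw observation table."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    has_counts = "male_births" in raw.columns and "female_births" in raw.columns
    if "srb" not in raw.columns and not has_counts:
        raise SchemaError(
            "need either an 'srb' column or 'male_births'+'female_births' columns"
        )

    df = raw.copy()
    for col in ("survey_year", "male_births", "female_births", "srb", "sampling_se"):
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "se_imputed" not in df.columns:
        df["se_imputed"] = False
    df["se_imputed"] = df["se_imputed"].fillna(False).astype(bool)

    errors: list[str] = []
    regions = []
    for i, name in enumerate(df["region"]):
        try:
            regions.append(normalize_region(name))
        except RegionMappingError as exc:
            errors.append(f"row {i}: {exc}")
            regions.append("??")
    df["region"] = regions

    # Fill srb from counts where counts are present.
    m = df["male_births"].to_numpy()
    f = df["female_births"].to_numpy()
    counts_ok = np.isfinite(m) & np.isfinite(f)
    bad_counts = counts_ok & ((m <= 0) | (f <= 0))
    for i in np.flatnonzero(bad_counts):
        errors.append(
            f"row {i}: non-positive birth count (male={m[i]}, female={f[i]})"
        )
    usable = counts_ok & ~bad_counts
    if usable.any():
        srb, log_srb, se = srb_from_counts(m[usable], f[usable], design_effect)
        srb_col = df["srb"].to_numpy(dtype=float)
        se_col = df["sampling_se"].to_numpy(dtype=float)
        fill_srb = usable & ~np.isfinite(srb_col)
        srb_col[fill_srb] = (m / f)[fill_srb]
        fill_se = usable & ~np.isfinite(se_col)
        se_col[fill_se] = (design_effect * np.sqrt(1.0 / m + 1.0 / f))[fill_se]
        df["srb"] = srb_col
        df["sampling_se"] = se_col

    df["log_srb"] = np.log(df["srb"].where(df["srb"] > 0))

    for i, row in enumerate(df.itertuples(index=False)):
        if row.region == "??":
            continue  # already reported
        obs = SRBObservation(
            region=row.region,
            source=str(row.source),
            source_type=str(row.source_type),
            reference_year=float(row.reference_year),
            srb=float(row.srb) if np.isfinite(row.srb) else float("nan"),
            log_srb=float(row.log_srb) if np.isfinite(row.log_srb) else float("nan"),
            sampling_se=float(row.sampling_se),
            survey_year=float(row.survey_year) if np.isfinite(row.survey_year) else None,
            male_births=float(row.male_births) if np.isfinite(row.male_births) else None,
            female_births=float(row.female_births) if np.isfinite(row.female_births) else None,
            se_imputed=bool(row.se_imputed),
        )
        if math.isnan(obs.srb):
            errors.append(f"row {i}: no usable SRB (srb missing and counts unusable)")
            continue
        if math.isnan(obs.sampling_se) and obs.source_type != "annual_survey":
            errors.append(
                f"row {i}: sampling_se missing for source_type "
                f"{obs.source_type!r} (only annual_survey rows may omit it)"
            )
        errors.extend(f"row {i}: {p}" for p in obs.validate())

    if errors:
        raise DatabaseError(
            "observation table failed validation:\n  " + "\n  ".join(errors)
        )
    return df[list(_CANONICAL_COLUMNS)].reset_index(drop=True)


def write_database(df: pd.DataFrame, path) -> None:
    """Write a validated observation table as canonical CSV (UTF-8)."""
    df.to_csv(path, index=False)


def apply_window_rules(observations: pd.DataFrame) -> pd.DataFrame:
    """Apply source-specific reference-year restrictions.

    * ``retrospective_survey``: keep births within 25 years before the survey
      year (``reference_year >= survey_year - 25``);
    * ``facility_survey``: keep only the survey year itself (most-recent-birth
      designs are stopping-rule biased for earlier years);
    * ``census`` and ``annual_survey``: unchanged.

    Idempotent.  Retrospective or facility rows without a survey year raise.
    """
    df = observations
    retro = df["source_type"] == "retrospective_survey"
    facility = df["source_type"] == "facility_survey"
    needs_sy = retro | facility
    missing = needs_sy & ~np.isfinite(df["survey_year"].to_numpy(dtype=float))
    if missing.any():
        rows = list(df.index[missing])
        raise DatabaseError(
            f"survey_year required for retrospective/facility rows; missing at rows {rows}"
        )
    keep = np.ones(len(df), dtype=bool)
    keep[retro.to_numpy()] &= (
        df.loc[retro, "reference_year"] >= df.loc[retro, "survey_year"] - 25
    ).to_numpy()
    keep[facility.to_numpy()] &= (
        np.floor(df.loc[facility, "reference_year"]) == df.loc[facility, "survey_year"]
    ).to_numpy()
    return df.loc[keep].reset_index(drop=True)


def impute_sampling_error(
    observations: pd.DataFrame, method: str = "max"
) -> pd.DataFrame:
    """Fill missing sampling SEs of annual-survey rows from known-design donors.

    Donors are same-region observations from sources of known design (census,
    retrospective or facility surveys) with non-imputed SEs.  ``method`` is
    ``"max"`` (conservative default: the largest donor SE) or ``"mean"``.
    Rows filled here get ``se_imputed=True``.  A region needing imputation
    with an empty donor pool raises ``ImputationError``.
    """
    if method not in ("max", "mean"):
        raise ValueError(f"unknown imputation method {method!r}")
    df = observations.copy()
    se = df["sampling_se"].to_numpy(dtype=float)
    needs = ~np.isfinite(se)
    if not needs.any():
        return df
    bad = needs & (df["source_type"] != "annual_survey").to_numpy()
    if bad.any():
        raise DatabaseError(
            f"missing sampling_se outside annual_survey rows: rows {list(df.index[bad])}"
        )
    donor_mask = (
        df["source_type"].isin(["census", "retrospective_survey", "facility_survey"])
        & ~df["se_imputed"]
        & np.isfinite(se)
    )
    for region in df.loc[needs, "region"].unique():
        pool = se[donor_mask.to_numpy() & (df["region"] == region).to_numpy()]
        if pool.size == 0:
            raise ImputationError(
                f"no known-design donor observations in region {region} "
                "to impute annual-survey sampling errors from"
            )
        value = float(pool.max() if method == "max" else pool.mean())
        target = needs & (df["region"] == region).to_numpy()
        se[target] = value
        df.loc[target, "se_imputed"] = True
    df["sampling_se"] = se
    return df
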