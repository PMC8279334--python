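"""Tests for the multi-source SRB observation database."""

import math

import numpy as np
import pandas as pd
import pytest

from srbmix.database import (
    CATALOGUE_PRINTED_TOTALS,
    DatabaseError,
    ImputationError,
    RegionMappingError,
    SchemaError,
    apply_window_rules,
    catalogue_birth_total,
    impute_sampling_error,
    load_database,
    normalize_region,
    srb_from_counts,
    validate_observations,
    write_database,
)


def _csv(tmp_path, text, name="db.csv"):
    p = tmp_path / name
    p.write_text(text)
    return p


HEADER = "region,source,source_type,survey_year,reference_year,male_births,female_births,srb,sampling_se\n"


class TestLoadDatabase:
    def test_counts_rows_get_srb_and_se(self, tmp_path):
        p = _csv(
            tmp_path,
            HEADER
            + "RRD,1999 Census,census,1999,1998,500,470,,\n"
            + "Red River Delta,1999 Census,census,1999,1997,512,480,,\n"
            + "MKD,1999 Census,census,1999,1998,1060,1000,,\n",
        )
        df = load_database(p)
        assert len(df) == 3
        np.testing.assert_allclose(
            df["srb"], [500 / 470, 512 / 480, 1060 / 1000], rtol=1e-12
        )
        np.testing.assert_allclose(
            df["sampling_se"].iloc[0], math.sqrt(1 / 500 + 1 / 470), rtol=1e-12
        )
        assert list(df["region"]) == ["RRD", "RRD", "MKD"]

    def test_zero_female_births_rejected(self, tmp_path):
        p = _csv(tmp_path, HEADER + "RRD,x,census,1999,1998,500,0,,\n")
        with pytest.raises(DatabaseError, match="non-positive birth count"):
            load_database(p)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = _csv(tmp_path, "region,source,reference_year\nRRD,x,1998\n")
        with pytest.raises(SchemaError):
            load_database(p)

    def test_unknown_region_is_itemized(self, tmp_path):
        p = _csv(
            tmp_path,
            HEADER
            + "Atlantis,x,census,1999,1998,500,470,,\n"
            + "RRD,x,census,1999,1997,,,-1.0,0.02\n",
        )
        with pytest.raises(DatabaseError) as err:
            load_database(p)
        msg = str(err.value)
        assert "row 0" in msg and "Atlantis" in msg
        assert "row 1" in msg  # non-positive SRB also itemized

    def test_reference_year_bounds_enforced(self, tmp_path):
        p = _csv(tmp_path, HEADER + "RRD,x,census,1949,1948,500,470,,\n")
        with pytest.raises(DatabaseError, match="reference_year"):
            load_database(p)

    def test_missing_se_allowed_only_for_annual_surveys(self, tmp_path):
        ok = _csv(tmp_path, HEADER + "RRD,x,annual_survey,2010,2009.5,,,1.08,\n", "a.csv")
        df = load_database(ok)
        assert math.isnan(df["sampling_se"].iloc[0])
        bad = _csv(tmp_path, HEADER + "RRD,x,census,2009,2008,,,1.08,\n", "b.csv")
        with pytest.raises(DatabaseError, match="annual_survey"):
            load_database(bad)

    def test_xlsx_round_trip(self, tmp_path):
        raw = pd.DataFrame(
            {
                "region": ["RRD"],
                "source": ["2009 Census"],
                "source_type": ["census"],
                "survey_year": [2009],
                "reference_year": [2008.5],
                "male_births": [44000],
                "female_births": [41000],
            }
        )
        p = tmp_path / "db.xlsx"
        raw.to_excel(p, index=False)
        df = load_database(p)
        assert df["srb"].iloc[0] == pytest.approx(44000 / 41000)


class TestSrbFromCounts:
    def test_closed_form_example(self):
        srb, log_srb, se = srb_from_counts(1063, 1000)
        assert srb == pytest.approx(1.063)
        assert log_srb == pytest.approx(math.log(1.063), rel=1e-12)
        assert se == pytest.approx(math.sqrt(1 / 1063 + 1 / 1000), rel=1e-12)
        assert se == pytest.approx(0.04407, abs=5e-5)

    def test_direct_division(self):
        srb, _, _ = srb_from_counts(515, 485)
        assert srb == pytest.approx(515 / 485, rel=1e-14)

    def test_log_exp_round_trip(self):
        srb, log_srb, _ = srb_from_counts(10000, 9400)
        assert math.exp(log_srb) == pytest.approx(srb, rel=1e-12)

    def test_se_matches_bootstrap_oracle(self):
        # Oracle: sd of log(SRB) over bootstrap replicates of 19,400
        # Bernoulli births with male probability 10000/19400.
        m, f = 10000, 9400
        n = m + f
        rng = np.random.default_rng(12345)
        males = rng.binomial(n, m / n, size=10_000)
        log_srb = np.log(males / (n - males))
        _, _, se = srb_from_counts(m, f)
        assert se == pytest.approx(log_srb.std(ddof=1), rel=0.05)

    @pytest.mark.parametrize("m,f", [(0, 100), (100, 0), (-5, 100)])
    def test_nonpositive_counts_raise(self, m, f):
        with pytest.raises(DatabaseError):
            srb_from_counts(m, f)

    def test_design_effect_scales_se(self):
        _, _, se1 = srb_from_counts(500, 470)
        _, _, se2 = srb_from_counts(500, 470, design_effect=1.5)
        assert se2 == pytest.approx(1.5 * se1, rel=1e-12)


class TestRegionNormalization:
    @pytest.mark.parametrize(
        "name, code",
        [
            ("Red River Delta", "RRD"),
            ("red river delta", "RRD"),
            ("RRD", "RRD"),
            ("Mekong Delta", "MKD"),
            ("Northern Midlands and Mountain Areas", "NMM"),
            ("South East", "SE"),
        ],
    )
    def test_known_names(self, name, code):
        assert normalize_region(name) == code

    def test_unknown_name_fails_loudly(self):
        with pytest.raises(RegionMappingError):
            normalize_region("Northern Delta-ish")


def _obs_frame(rows):
    df = pd.DataFrame(
        rows,
        columns=[
            "region",
            "source",
            "source_type",
            "survey_year",
            "reference_year",
            "male_births",
            "female_births",
            "srb",
            "sampling_se",
        ],
    )
    return validate_observations(df)


class TestWindowRules:
    def test_retrospective_25_year_window(self):
        rows = [
            ("RRD", "1997 DHS", "retrospective_survey", 1997, y, np.nan, np.nan, 1.06, 0.03)
            for y in range(1970, 1997)
        ]
        out = apply_window_rules(_obs_frame(rows))
        assert sorted(out["reference_year"]) == list(range(1972, 1997))

    def test_facility_survey_keeps_only_survey_year(self):
        rows = [
            ("SE", "2008 Survey of Birth", "facility_survey", 2008, y, np.nan, np.nan, 1.07, 0.02)
            for y in (2005, 2006, 2007, 2008)
        ]
        out = apply_window_rules(_obs_frame(rows))
        assert list(out["reference_year"]) == [2008]

    def test_census_and_annual_rows_unchanged(self):
        rows = [
            ("CH", "1989 Census", "census", 1989, 1955.0, np.nan, np.nan, 1.05, 0.02),
            ("CH", "2010 PCFPS", "annual_survey", 2010, 2009.5, np.nan, np.nan, 1.08, np.nan),
        ]
        df = _obs_frame(rows)
        out = apply_window_rules(df)
        pd.testing.assert_frame_equal(out, df)

    def test_idempotent(self):
        rows = [
            ("RRD", "1997 DHS", "retrospective_survey", 1997, y, np.nan, np.nan, 1.06, 0.03)
            for y in range(1965, 1997)
        ]
        once = apply_window_rules(_obs_frame(rows))
        twice = apply_window_rules(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_survey_year_raises(self):
        rows = [("RRD", "DHS", "retrospective_survey", np.nan, 1990, np.nan, np.nan, 1.06, 0.03)]
        with pytest.raises(DatabaseError, match="survey_year"):
            apply_window_rules(_obs_frame(rows))


class TestImputation:
    def _frame(self):
        rows = [
            ("RRD", "c1", "census", 2009, 2008, np.nan, np.nan, 1.08, 0.012),
            ("RRD", "s1", "retrospective_survey", 1997, 1990, np.nan, np.nan, 1.05, 0.031),
            ("RRD", "s2", "retrospective_survey", 2002, 1995, np.nan, np.nan, 1.06, 0.022),
            ("RRD", "p1", "annual_survey", 2010, 2009.5, np.nan, np.nan, 1.09, np.nan),
        ]
        return _obs_frame(rows)

    def test_max_of_donor_pool(self):
        out = impute_sampling_error(self._frame())
        filled = out[out["se_imputed"]]
        assert len(filled) == 1
        assert filled["sampling_se"].iloc[0] == pytest.approx(0.031)

    def test_mean_method(self):
        out = impute_sampling_error(self._frame(), method="mean")
        filled = out[out["se_imputed"]]
        assert filled["sampling_se"].iloc[0] == pytest.approx(np.mean([0.012, 0.031, 0.022]))

    def test_no_op_when_complete(self):
        df = self._frame().iloc[:3].reset_index(drop=True)
        out = impute_sampling_error(df)
        pd.testing.assert_frame_equal(out, df)

    def test_empty_donor_pool_raises(self):
        rows = [("CH", "p1", "annual_survey", 2010, 2009.5, np.nan, np.nan, 1.09, np.nan)]
        with pytest.raises(ImputationError):
            impute_sampling_error(_obs_frame(rows))

    def test_imputed_se_is_conservative_in_synthetic_replicates(self):
        # With a conservative (max) rule and donors spanning the truth, the
        # imputed SE should be at least the true sampling SE most of the time.
        from srbmix.synthetic import default_vietnam_like_scenario, simulate_database

        spec = default_vietnam_like_scenario(seed=0)
        hits = total = 0
        for rep in range(6):
            _, obs = simulate_database(spec, seed=100 + rep)
            annual = obs["source_type"] == "annual_survey"
            n = spec.sources[-1].births_per_region_year
            true_se = math.sqrt(1 / (n * 0.515) + 1 / (n * 0.485))
            out = impute_sampling_error(apply_window_rules(obs))
            filled = out[out["se_imputed"]]
            hits += int((filled["sampling_se"] >= true_se).sum())
            total += len(filled)
        assert hits / total >= 0.5

    def test_round_trip_is_exact(self, tmp_path):
        df = impute_sampling_error(self._frame())
        path = tmp_path / "canonical.csv"
        write_database(df, path)
        back = load_database(path)
        pd.testing.assert_frame_equal(back, df)


class TestSourceCatalogue:
    def test_birth_total_matches_printed_total(self):
        assert catalogue_birth_total() == CATALOGUE_PRINTED_TOTALS["births"]
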