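"""Catalogue arithmetic against an independently typed membership oracle."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bametrics.catalogue import (
    ANALYTES,
    BileAcidProfile,
    CatalogueError,
    ProfileValidationError,
    IndexCatalogue,
    build_feature_table,
    compute_percent,
    compute_pools,
    compute_ratio,
    default_catalogue,
    evaluate_catalogue,
)
from conftest import random_profile

# A second, separately typed copy of the pool membership lists.  Any edit to
# the package's own tables that drifts from these definitions fails the
# oracle-equivalence test below.
ORACLE_POOLS = {
    "Primary": ["TCA", "TCDCA", "GCA", "GCDCA", "CDCA", "CA"],
    "Secondary": ["DCA", "GDCA", "TDCA", "LCA", "GLCA", "TLCA", "UDCA", "GUDCA", "TUDCA"],
    "TBA": ["GDCA", "TDCA", "GLCA", "TLCA", "GUDCA", "TUDCA", "TCA", "TCDCA",
            "GCA", "GCDCA", "CA", "CDCA", "DCA", "LCA", "UDCA"],
    "Conjugated": ["TCA", "TCDCA", "GCA", "GCDCA"],
    "Unconjugated": ["CA", "CDCA", "DCA", "LCA", "UDCA"],
    "G-conjugated": ["GCA", "GCDCA", "GDCA", "GLCA", "GUDCA"],
    "T-conjugated": ["TCA", "TCDCA", "TDCA", "TLCA", "TUDCA"],
    "12-OH": ["CA", "TCA", "GCA", "DCA", "TDCA", "GDCA"],
    "non-12-OH": ["CDCA", "TCDCA", "GCDCA", "LCA", "TLCA", "GLCA", "UDCA", "GUDCA", "TUDCA"],
    "CAs": ["GCA", "TCA", "CA"],
    "CDCAs": ["GCDCA", "TCDCA", "CDCA"],
    "DCAs": ["GDCA", "TDCA", "DCA"],
    "LCAs": ["GLCA", "TLCA", "LCA"],
    "UDCAs": ["GUDCA", "TUDCA", "UDCA"],
    "Neurotoxic": ["GCA", "GCDCA", "GDCA"],
    "Neuroprotective": ["GUDCA", "TUDCA", "UDCA"],
    "Conjugated-UDCAs": ["GUDCA", "TUDCA"],
}


def oracle_value(profile, name):
    """Literal re-summation evaluator: raw, pool, %x, or a/b."""
    if name.startswith("%"):
        tba = sum(profile[a] for a in ORACLE_POOLS["TBA"])
        return oracle_value(profile, name[1:]) / tba if tba else float("nan")
    if "/" in name and name not in ORACLE_POOLS and name not in ANALYTES:
        # longest-prefix split handles pool names containing "-"
        for cut in range(len(name)):
            num, _, den = name[:cut], name[cut], name[cut + 1:]
            if name[cut] != "/":
                continue
            if (num in ORACLE_POOLS or num in ANALYTES) and (den in ORACLE_POOLS or den in ANALYTES):
                den_v = oracle_value(profile, den)
                return oracle_value(profile, num) / den_v if den_v else float("nan")
        raise KeyError(name)
    if name in ORACLE_POOLS:
        return sum(profile[a] for a in ORACLE_POOLS[name])
    return profile[name]


class TestProfileValidation:
    def test_rejects_missing_and_extra_analytes(self):
        with pytest.raises(ProfileValidationError, match="missing"):
            BileAcidProfile({a: 1.0 for a in ANALYTES[:-1]})
        bad = {a: 1.0 for a in ANALYTES}
        bad["XYZ"] = 1.0
        with pytest.raises(ProfileValidationError, match="XYZ"):
            BileAcidProfile(bad)

    @pytest.mark.parametrize("value", [-0.1, float("nan"), float("inf")])
    def test_rejects_invalid_concentrations_naming_analyte(self, value):
        conc = {a: 1.0 for a in ANALYTES}
        conc["GLCA"] = value
        with pytest.raises(ProfileValidationError, match="GLCA"):
            BileAcidProfile(conc)


class TestPools:
    def test_unit_profile_pool_sizes(self, unit_profile):
        pools = compute_pools(unit_profile)
        assert pools["TBA"] == 15.0
        assert pools["Primary"] == 6.0
        assert pools["Secondary"] == 9.0
        assert pools["12-OH"] == 6.0
        assert pools["non-12-OH"] == 9.0
        assert pools["CAs"] == 3.0
        assert pools["Neurotoxic"] == 3.0

    def test_single_analyte_profile(self):
        conc = {a: 0.0 for a in ANALYTES}
        conc["CA"] = 2.0
        pools = compute_pools(BileAcidProfile(conc))
        assert pools["TBA"] == 2.0
        assert pools["Primary"] == 2.0
        assert pools["Secondary"] == 0.0
        assert pools["Unconjugated"] == 2.0
        assert pools["12-OH"] == 2.0

    def test_pools_match_oracle_on_random_profiles(self, rng):
        for _ in range(200):
            p = random_profile(rng)
            pools = compute_pools(p)
            for name in ORACLE_POOLS:
                assert pools[name] == pytest.approx(oracle_value(p, name), rel=1e-12)


class TestPercentAndRatio:
    def test_percent_examples(self, unit_profile):
        assert compute_percent(unit_profile, "Primary") == pytest.approx(0.4)
        conc = {a: 0.0 for a in ANALYTES}
        conc["CA"] = 3.5
        assert compute_percent(BileAcidProfile(conc), "CA") == pytest.approx(1.0)

    def test_percent_missing_when_tba_zero(self):
        p = BileAcidProfile({a: 0.0 for a in ANALYTES})
        assert np.isnan(compute_percent(p, "GLCA"))

    def test_ratio_examples(self, unit_profile):
        conc = {a: 0.0 for a in ANALYTES}
        conc["GLCA"], conc["TLCA"] = 2.0, 1.0
        assert compute_ratio(BileAcidProfile(conc), "GLCA", "TLCA") == pytest.approx(2.0)
        assert compute_ratio(unit_profile, "12-OH", "non-12-OH") == pytest.approx(6 / 9)

    def test_zero_denominator_is_missing_not_infinite(self):
        conc = {a: 0.0 for a in ANALYTES}
        conc["GLCA"] = 2.0
        assert np.isnan(compute_ratio(BileAcidProfile(conc), "GLCA", "TLCA"))

    def test_unknown_pool_name_raises(self, unit_profile):
        with pytest.raises(CatalogueError):
            compute_ratio(unit_profile, "GLCA", "NOPE")


class TestCatalogue:
    def test_frozen_size_and_unique_names(self):
        cat = default_catalogue()
        assert len(cat) == 71
        assert len(set(cat.names)) == 71

    def test_kind_census(self):
        cat = default_catalogue()
        kinds = pd.Series([d.kind for d in cat]).value_counts().to_dict()
        assert kinds == {"raw": 15, "pool": 17, "percent": 31, "ratio": 8}

    def test_json_roundtrip(self):
        cat = default_catalogue()
        again = IndexCatalogue.from_json(cat.to_json())
        assert again.names == cat.names
        assert [d.numerator for d in again] == [d.numerator for d in cat]

    def test_catalogue_matches_oracle_on_random_profiles(self, rng):
        cat = default_catalogue()
        for _ in range(200):
            p = random_profile(rng)
            values = evaluate_catalogue(p, cat)
            for name, v in values.items():
                assert v == pytest.approx(oracle_value(p, name), rel=1e-12)

    def test_partition_invariants(self, rng):
        for _ in range(300):
            p = random_profile(rng)
            pools = compute_pools(p)
            tba = pools["TBA"]
            assert pools["Primary"] + pools["Secondary"] == pytest.approx(tba, rel=1e-9)
            assert pools["12-OH"] + pools["non-12-OH"] == pytest.approx(tba, rel=1e-9)
            assert (pools["G-conjugated"] + pools["T-conjugated"] + pools["Unconjugated"]
                    ) == pytest.approx(tba, rel=1e-9)

    def test_raw_percent_values_sum_to_one(self, rng):
        for _ in range(50):
            p = random_profile(rng)
            vals = evaluate_catalogue(p)
            total = sum(vals[f"%{a}"] for a in ANALYTES)
            assert total == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           seed=st.integers(min_value=0, max_value=10_000))
    def test_scale_equivariance(self, scale, seed):
        """Scaling concentrations scales pools by c, leaves fractions fixed."""
        rng = np.random.default_rng(seed)
        p = random_profile(rng)
        scaled = BileAcidProfile({a: p[a] * scale for a in ANALYTES})
        v, vs = evaluate_catalogue(p), evaluate_catalogue(scaled)
        cat = default_catalogue()
        for d in cat:
            if d.kind in {"raw", "pool"}:
                assert vs[d.name] == pytest.approx(v[d.name] * scale, rel=1e-9)
            else:
                assert vs[d.name] == pytest.approx(v[d.name], rel=1e-9)


class TestFeatureTable:
    def test_shape_and_no_missing_for_positive_cohort(self, small_cohort_df):
        table = build_feature_table(small_cohort_df)
        assert table.features.shape == (10, 71)
        assert table.n_missing == 0
        assert list(table.labels.unique()) == ["NMOSD_AQP4neg", "MS"]

    def test_zero_tlca_flags_exactly_its_ratio_indices(self, small_cohort_df):
        df = small_cohort_df.copy()
        df.loc[0, "TLCA"] = 0.0
        table = build_feature_table(df)
        missing = table.features.iloc[0].isna()
        # the only catalogue entry whose denominator can vanish here is GLCA/TLCA
        assert set(missing[missing].index) == {"GLCA/TLCA"}

    def test_duplicate_subject_ids_rejected(self, small_cohort_df):
        df = small_cohort_df.copy()
        df.loc[1, "subject_id"] = df.loc[0, "subject_id"]
        with pytest.raises(ProfileValidationError, match="duplicate"):
            build_feature_table(df)

    def test_missing_analyte_column_named_in_error(self, small_cohort_df):
        df = small_cohort_df.drop(columns=["GDCA"])
        with pytest.raises(ProfileValidationError, match="GDCA"):
            build_feature_table(df)

    def test_matches_scalar_evaluator(self, small_cohort_df):
        table = build_feature_table(small_cohort_df)
        row = small_cohort_df.iloc[3]
        p = BileAcidProfile.from_series(row)
        expected = evaluate_catalogue(p)
        got = table.features.loc[row["subject_id"]]
        for name, v in expected.items():
            assert got[name] == pytest.approx(v, rel=1e-12)
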