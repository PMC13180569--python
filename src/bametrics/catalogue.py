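"""Bile-acid pools, proportions and ratios derived from a 15-analyte serum panel.

The targeted LC-MS/MS panel quantifies six primary bile acids (the hepatic
products CA and CDCA together with their glycine/taurine conjugates) and nine
secondary bile acids (the microbially transformed DCA, LCA and UDCA families).
From those raw concentrations this module derives a fixed, ordered catalogue of
71 indices:

* 15 raw analyte concentrations (μmol/L),
* 17 physiologically defined pools (sums of member analytes, μmol/L),
* 15 analyte proportions of the total bile-acid pool (fractions of TBA),
* 16 pool proportions (every pool except TBA itself),
*  8 pathway ratios (e.g. 12-OH/non-12-OH, indexing classical-pathway
   synthesis activity, and the conjugation ratios GLCA/TLCA, GDCA/TDCA).

All derived values reduce to ``sum(numerator) / sum(denominator)`` over analyte
membership lists, so the whole catalogue is evaluated vectorised through two
membership matrices.  A zero denominator yields a missing value (NaN), never an
infinity; downstream consumers handle missingness by pairwise deletion.

Percentages are stored as fractions in [0, 1]; rendering as "%" is left to the
presentation layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "PRIMARY_ANALYTES",
    "SECONDARY_ANALYTES",
    "POOL_MEMBERS",
    "RATIO_PAIRS",
    "BileAcidProfile",
    "IndexDefinition",
    "IndexCatalogue",
    "FeatureTable",
    "CatalogueError",
    "ProfileValidationError",
    "default_catalogue",
    "compute_pools",
    "compute_percent",
    "compute_ratio",
    "evaluate_catalogue",
    "build_feature_table",
]


class CatalogueError(KeyError):
    """An index, pool or analyte name not present in the catalogue."""


class ProfileValidationError(ValueError):
    """A bile-acid profile violated the non-negative/finite/complete contract."""


PRIMARY_ANALYTES: tuple[str, ...] = ("TCA", "TCDCA", "GCA", "GCDCA", "CDCA", "CA")
SECONDARY_ANALYTES: tuple[str, ...] = (
    "DCA", "GDCA", "TDCA", "LCA", "GLCA", "TLCA", "UDCA", "GUDCA", "TUDCA",
)
ANALYTES: tuple[str, ...] = PRIMARY_ANALYTES + SECONDARY_ANALYTES

# Pool membership.  "Conjugated" is deliberately the primary-conjugate sum
# (TCA + TCDCA + GCA + GCDCA): that is how the assay panel's conjugated pool is
# defined here even though chemically the term is broader; see docs/methods.md.
POOL_MEMBERS: dict[str, tuple[str, ...]] = {
    "Primary": PRIMARY_ANALYTES,
    "Secondary": SECONDARY_ANALYTES,
    "TBA": ANALYTES,
    "Conjugated": ("TCA", "TCDCA", "GCA", "GCDCA"),
    "Unconjugated": ("CA", "CDCA", "DCA", "LCA", "UDCA"),
    "G-conjugated": ("GCA", "GCDCA", "GDCA", "GLCA", "GUDCA"),
    "T-conjugated": ("TCA", "TCDCA", "TDCA", "TLCA", "TUDCA"),
    "12-OH": ("CA", "TCA", "GCA", "DCA", "TDCA", "GDCA"),
    "non-12-OH": ("CDCA", "TCDCA", "GCDCA", "LCA", "TLCA", "GLCA", "UDCA", "GUDCA", "TUDCA"),
    "CAs": ("GCA", "TCA", "CA"),
    "CDCAs": ("GCDCA", "TCDCA", "CDCA"),
    "DCAs": ("GDCA", "TDCA", "DCA"),
    "LCAs": ("GLCA", "TLCA", "LCA"),
    "UDCAs": ("GUDCA", "TUDCA", "UDCA"),
    "Neurotoxic": ("GCA", "GCDCA", "GDCA"),
    "Neuroprotective": ("GUDCA", "TUDCA", "UDCA"),
    "Conjugated-UDCAs": ("GUDCA", "TUDCA"),
}

#: Ratio indices, written "num/den"; names may be pools or single analytes.
RATIO_PAIRS: tuple[tuple[str, str], ...] = (
    ("12-OH", "non-12-OH"),
    ("GLCA", "TLCA"),
    ("GDCA", "TDCA"),
    ("Primary", "Secondary"),
    ("Conjugated", "Unconjugated"),
    ("G-conjugated", "T-conjugated"),
    ("Neurotoxic", "Neuroprotective"),
    ("CAs", "CDCAs"),
)


def _members(name: str) -> tuple[str, ...]:
    """Expand a pool or analyte name to its analyte membership tuple."""
    if name in POOL_MEMBERS:
        return POOL_MEMBERS[name]
    if name in ANALYTES:
        return (name,)
    raise CatalogueError(f"unknown pool or analyte name: {name!r}")


@dataclass(frozen=True)
class BileAcidProfile:
    """One subject's 15 serum bile-acid concentrations in μmol/L.

    The analyte set must be exactly the 15 panel analytes; every value must be
    finite and non-negative.
    """

    concentrations: Mapping[str, float]

    def __post_init__(self) -> None:
        keys = set(self.concentrations)
        missing = set(ANALYTES) - keys
        extra = keys - set(ANALYTES)
        if missing:
            raise ProfileValidationError(f"missing analytes: {sorted(missing)}")
        if extra:
            raise ProfileValidationError(f"unknown analytes: {sorted(extra)}")
        for name in ANALYTES:
            v = float(self.concentrations[name])
            if not np.isfinite(v):
                raise ProfileValidationError(f"non-finite concentration for {name}")
            if v < 0:
                raise ProfileValidationError(f"negative concentration for {name}: {v}")

    @classmethod
    def from_series(cls, row: pd.Series) -> "BileAcidProfile":
        return cls({a: float(row[a]) for a in ANALYTES})

    def as_array(self) -> np.ndarray:
        return np.array([float(self.concentrations[a]) for a in ANALYTES])

    def __getitem__(self, analyte: str) -> float:
        return float(self.concentrations[analyte])


@dataclass(frozen=True)
class IndexDefinition:
    """One catalogue entry: value = sum(numerator) / sum(denominator).

    ``kind`` is one of raw | pool | percent | ratio.  For raw and pool entries
    the denominator is empty (the value is a concentration in μmol/L); percent
    entries always have the full 15-analyte TBA membership as denominator.
    """

    name: str
    kind: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in {"raw", "pool", "percent", "ratio"}:
            raise CatalogueError(f"unknown index kind: {self.kind!r}")
        if self.kind == "percent" and tuple(sorted(self.denominator)) != tuple(sorted(ANALYTES)):
            raise CatalogueError(f"percent index {self.name!r} must have TBA denominator")
        if self.kind == "ratio" and (not self.numerator or not self.denominator):
            raise CatalogueError(f"ratio index {self.name!r} needs numerator and denominator")
        for a in self.numerator + self.denominator:
            if a not in ANALYTES:
                raise CatalogueError(f"index {self.name!r} references unknown analyte {a!r}")


@dataclass
class IndexCatalogue:
    """The fixed ordered set of derived indices (71 in the default build)."""

    definitions: list[IndexDefinition] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [d.name for d in self.definitions]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise CatalogueError(f"duplicate index names: {dupes}")

    def __len__(self) -> int:
        return len(self.definitions)

    def __iter__(self):
        return iter(self.definitions)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.definitions]

    def __getitem__(self, name: str) -> IndexDefinition:
        for d in self.definitions:
            if d.name == name:
                return d
        raise CatalogueError(f"unknown index: {name!r}")

    # -- serialization ---------------------------------------------------
    def to_json(self) -> str:
        payload = [
            {
                "name": d.name,
                "kind": d.kind,
                "numerator": list(d.numerator),
                "denominator": list(d.denominator),
            }
            for d in self.definitions
        ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "IndexCatalogue":
        payload = json.loads(text)
        defs = [
            IndexDefinition(
                name=e["name"],
                kind=e["kind"],
                numerator=tuple(e["numerator"]),
                denominator=tuple(e["denominator"]),
            )
            for e in payload
        ]
        return cls(defs)

    # -- vectorised evaluation -------------------------------------------
    def membership_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """(num, den) 0/1 matrices of shape (n_indices, 15) in analyte order."""
        idx = {a: j for j, a in enumerate(ANALYTES)}
        num = np.zeros((len(self.definitions), len(ANALYTES)))
        den = np.zeros_like(num)
        for i, d in enumerate(self.definitions):
            for a in d.numerator:
                num[i, idx[a]] += 1.0
            for a in d.denominator:
                den[i, idx[a]] += 1.0
        return num, den


def default_catalogue() -> IndexCatalogue:
    """Build the frozen 71-index catalogue.

    Ordering: raw analytes, pools, analyte percentages, pool percentages
    (every pool except TBA), ratios.
    """
    defs: list[IndexDefinition] = []
    for a in ANALYTES:
        defs.append(IndexDefinition(a, "raw", (a,)))
    for pool, members in POOL_MEMBERS.items():
        defs.append(IndexDefinition(pool, "pool", members))
    for a in ANALYTES:
        defs.append(IndexDefinition(f"%{a}", "percent", (a,), ANALYTES))
    for pool, members in POOL_MEMBERS.items():
        if pool == "TBA":
            continue
        defs.append(IndexDefinition(f"%{pool}", "percent", members, ANALYTES))
    for num, den in RATIO_PAIRS:
        defs.append(IndexDefinition(f"{num}/{den}", "ratio", _members(num), _members(den)))
    return IndexCatalogue(defs)


# ---------------------------------------------------------------------------
# scalar evaluation (single profile)
# ---------------------------------------------------------------------------

def compute_pools(profile: BileAcidProfile) -> dict[str, float]:
    """All 17 pool sums (μmol/L) for one subject."""
    return {pool: sum(profile[a] for a in members) for pool, members in POOL_MEMBERS.items()}


def compute_percent(profile: BileAcidProfile, index_name: str) -> float:
    """Proportion of an analyte or pool within TBA; NaN when TBA is zero."""
    tba = sum(profile[a] for a in ANALYTES)
    if tba == 0:
        return float("nan")
    return sum(profile[a] for a in _members(index_name)) / tba


def compute_ratio(profile: BileAcidProfile, num: str, den: str) -> float:
    """num/den over pool-or-analyte sums; NaN when the denominator is zero."""
    den_v = sum(profile[a] for a in _members(den))
    if den_v == 0:
        return float("nan")
    return sum(profile[a] for a in _members(num)) / den_v


def evaluate_catalogue(
    profile: BileAcidProfile, catalogue: IndexCatalogue | None = None
) -> dict[str, float]:
    """Every catalogue index for one subject (NaN marks missing)."""
    catalogue = catalogue or default_catalogue()
    out: dict[str, float] = {}
    for d in catalogue:
        num_v = sum(profile[a] for a in d.numerator)
        if not d.denominator:
            out[d.name] = num_v
        else:
            den_v = sum(profile[a] for a in d.denominator)
            out[d.name] = num_v / den_v if den_v != 0 else float("nan")
    return out


# ---------------------------------------------------------------------------
# cohort evaluation
# ---------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects × indices matrix with labels and clinical covariates.

    ``features`` is indexed by subject id and ordered by the catalogue;
    ``n_missing`` counts NaN cells (zero-denominator indices).
    """

    features: pd.DataFrame
    labels: pd.Series
    covariates: pd.DataFrame
    catalogue: IndexCatalogue
    n_missing: int

    def to_csv(self, path) -> None:
        out = pd.concat([self.labels.rename("group"), self.covariates, self.features], axis=1)
        out.to_csv(path, index_label="subject_id")

    def schema(self) -> dict:
        return {
            "index_columns": self.catalogue.names,
            "label_column": "group",
            "covariate_columns": list(self.covariates.columns),
            "n_missing_cells": int(self.n_missing),
        }


COVARIATE_COLUMNS = ("EDSS", "lesion_segments")


def build_feature_table(
    cohort: pd.DataFrame,
    catalogue: IndexCatalogue | None = None,
    id_column: str = "subject_id",
    label_column: str = "group",
) -> FeatureTable:
    """Evaluate the catalogue on every subject of a cohort table.

    ``cohort`` must carry one column per analyte plus a group label; a subject
    id column is used if present, otherwise the frame's index.  Covariate
    columns (EDSS, lesion_segments) are carried through unchanged.
    """
    catalogue = catalogue or default_catalogue()
    missing_cols = [a for a in ANALYTES if a not in cohort.columns]
    if missing_cols:
        raise ProfileValidationError(f"cohort is missing analyte columns: {missing_cols}")
    if label_column not in cohort.columns:
        raise ProfileValidationError(f"cohort is missing label column {label_column!r}")

    if id_column in cohort.columns:
        ids = cohort[id_column]
    else:
        ids = cohort.index.to_series()
    if ids.duplicated().any():
        dupes = sorted(ids[ids.duplicated()].unique().tolist())
        raise ProfileValidationError(f"duplicate subject ids: {dupes}")

    conc = cohort[list(ANALYTES)].to_numpy(dtype=float)
    if not np.isfinite(conc).all():
        bad = [ANALYTES[j] for j in np.where(~np.isfinite(conc).all(axis=0))[0]]
        raise ProfileValidationError(f"non-finite concentrations in columns: {bad}")
    if (conc < 0).any():
        bad = [ANALYTES[j] for j in np.where((conc < 0).any(axis=0))[0]]
        raise ProfileValidationError(f"negative concentrations in columns: {bad}")

    num_m, den_m = catalogue.membership_matrices()
    num_v = conc @ num_m.T                    # (n_subjects, n_indices)
    den_v = conc @ den_m.T
    has_den = den_m.sum(axis=1) > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(has_den, np.where(den_v != 0, num_v / np.where(den_v == 0, 1.0, den_v), np.nan), num_v)

    features = pd.DataFrame(values, index=pd.Index(ids.to_numpy(), name="subject_id"),
                            columns=catalogue.names)
    labels = pd.Series(cohort[label_column].to_numpy(), index=features.index, name="group")
    cov_cols = [c for c in COVARIATE_COLUMNS if c in cohort.columns]
    covariates = pd.DataFrame(
        {c: cohort[c].to_numpy() for c in cov_cols}, index=features.index
    )
    n_missing = int(np.isnan(values).sum())
    return FeatureTable(features, labels, covariates, catalogue, n_missing)
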