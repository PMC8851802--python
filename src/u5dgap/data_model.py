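"""Canonical child-level data model for under-five death (U5D) analyses.

One analysis row is a live birth with a binary outcome ``died_u5`` (death
within 0-59 months of birth), the child's sex, a positive sampling weight,
cluster (primary sampling unit) and country identifiers, and a set of
categorical covariates.  The in-memory container is a :class:`pandas.DataFrame`
with the columns of :data:`CORE_COLUMNS` plus any subset of
:data:`COVARIATE_CATEGORIES`; :class:`ChildRecord` gives the row-level view.

The module also ships the packaged country summary table: one row per country
with sample size, percent male and sex-specific U5D rates per 1000 live
births, exactly as published.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

logger = logging.getLogger(__name__)

MISSING = "missing"

SEXES = ("male", "female")

#: mandatory columns of a canonical child table
CORE_COLUMNS = ("child_id", "country", "cluster_id", "sex", "died_u5", "weight")

#: canonical covariates and their category labels (first label = reference)
COVARIATE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "maternal_age_group": ("15-24", "25-34", "35-49"),
    "maternal_education": ("none", "primary", "secondary+"),
    "media_access": ("yes", "no"),
    "maternal_employment": ("employed", "unemployed"),
    "marital_status": ("never", "partnered", "formerly"),
    "head_sex": ("male", "female"),
    "wealth_quintile": ("poorest", "poorer", "middle", "richer", "richest"),
    "insurance": ("yes", "no"),
    "twin": ("single", "multiple"),
    "birth_weight": ("average+", "small", "very small"),
    "birth_order": ("1", "2", "3", "4+"),
    "birth_interval": ("first", "<36", "36+"),
    "water": ("improved", "unimproved"),
    "toilet": ("improved", "unimproved"),
    "fuel": ("clean", "biomass"),
    "housing": ("improved", "unimproved"),
    "residence": ("urban", "rural"),
    "neighborhood_ses": ("1", "2", "3", "4", "5"),
}

#: the 25 countries with a statistically significant pro-male odds ratio,
#: the subset carried into the decomposition stage of the published analysis
PRO_MALE_COUNTRIES = (
    "Afghanistan", "Angola", "Benin", "Burkina Faso", "Cambodia", "Cameroon",
    "Chad", "Cote d'Ivoire", "Ethiopia", "Haiti", "India", "Indonesia",
    "Kenya", "Malawi", "Mozambique", "Niger", "Nigeria", "Rwanda", "Senegal",
    "Sierra Leone", "Tajikistan", "Tanzania", "Timor Leste", "Uganda",
    "Zambia",
)

_FIXTURE_NAME = "table1_lmic_u5d.csv"
_FIXTURE_SHA256 = None  # filled lazily on first load; see load_table1_fixture
_FIXTURE_N_CHILDREN = 856_987
_FIXTURE_N_CLUSTERS = 66_495
_FIXTURE_N_COUNTRIES = 59


@dataclass
class ChildRecord:
    """One live birth."""

    child_id: str
    country: str
    cluster_id: str
    sex: str
    died_u5: int
    weight: float
    covariates: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.died_u5 not in (0, 1):
            raise ValueError("died_u5 must be 0 or 1")
        if not self.weight > 0:
            raise ValueError("sampling weight must be positive")
        for var, cat in self.covariates.items():
            allowed = COVARIATE_CATEGORIES.get(var)
            if allowed is not None and cat != MISSING and cat not in allowed:
                raise ValueError(f"{cat!r} is not a category of {var}")


@dataclass
class CodebookMapping:
    """Source-to-canonical recode rules.

    ``column_map`` maps a source column name to ``(canonical_variable,
    recode)`` where ``recode`` maps source category strings to canonical
    labels.  An empty recode means the column is already canonical.
    ``core_map`` renames source columns onto the mandatory core columns.
    """

    column_map: dict[str, tuple[str, dict[str, str]]] = field(default_factory=dict)
    core_map: dict[str, str] = field(default_factory=dict)
    missing_codes: tuple[str, ...] = ("", "na", "nan", "9", "99", ".")

    @classmethod
    def identity(cls, covariates: Iterable[str] | None = None) -> "CodebookMapping":
        """Codebook that passes already-canonical columns through unchanged."""
        cov = tuple(covariates) if covariates is not None else tuple(COVARIATE_CATEGORIES)
        return cls(column_map={v: (v, {}) for v in cov})

    @classmethod
    def from_yaml(cls, path) -> "CodebookMapping":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        column_map = {
            src: (spec["variable"], dict(spec.get("recode", {})))
            for src, spec in (raw.get("columns") or {}).items()
        }
        return cls(
            column_map=column_map,
            core_map=dict(raw.get("core", {})),
            missing_codes=tuple(str(c) for c in raw.get("missing_codes", cls.missing_codes)),
        )

    def apply(self, column: str, value) -> str:
        """Recode one cell; unmapped categories raise, missing codes pass through."""
        canonical, recode = self.column_map[column]
        sval = str(value)
        if pd.isna(value) or sval.strip().lower() in self.missing_codes:
            return MISSING
        if not recode:
            out = sval
        elif sval in recode:
            out = recode[sval]
        else:
            raise ValueError(
                f"source category {sval!r} of column {column!r} has no recode "
                f"rule for canonical variable {canonical!r}"
            )
        allowed = COVARIATE_CATEGORIES.get(canonical)
        if allowed is not None and out not in allowed and out != MISSING:
            raise ValueError(f"recoded value {out!r} is not a category of {canonical!r}")
        return out


@dataclass
class RecodeLog:
    """Counts of rows excluded or cells flagged while reading a child table."""

    n_read: int = 0
    n_kept: int = 0
    n_missing_outcome: int = 0
    n_missing_sex: int = 0
    n_bad_weight: int = 0
    n_missing_cells: int = 0

    def lines(self) -> list[str]:
        return [
            f"rows read: {self.n_read}",
            f"rows kept: {self.n_kept}",
            f"rows excluded (missing outcome): {self.n_missing_outcome}",
            f"rows excluded (missing sex): {self.n_missing_sex}",
            f"rows excluded (missing/nonpositive weight): {self.n_bad_weight}",
            f"covariate cells flagged missing: {self.n_missing_cells}",
        ]


def recode_birth_interval(is_firstborn: bool, preceding_interval_months) -> str:
    """Recode the preceding birth interval into ``first`` / ``<36`` / ``36+``."""
    if is_firstborn:
        return "first"
    if preceding_interval_months is None or pd.isna(preceding_interval_months):
        return MISSING
    if preceding_interval_months < 0:
        raise ValueError("birth interval must be nonnegative")
    return "<36" if preceding_interval_months < 36 else "36+"


def housing_composite(floor_improved, wall_improved, roof_improved) -> str:
    """Housing material composite: improved only if floor, wall and roof all are.

    Each input is coded 1 (improved material) or 0; any missing input flags
    the composite as missing.
    """
    parts = (floor_improved, wall_improved, roof_improved)
    if any(p is None or pd.isna(p) for p in parts):
        return MISSING
    if any(p not in (0, 1) for p in parts):
        raise ValueError("housing material codes must be 0 or 1")
    return "improved" if all(p == 1 for p in parts) else "unimproved"


def read_child_table(path, mapping: CodebookMapping | None = None, sep: str = ",") -> tuple[pd.DataFrame, RecodeLog]:
    """Read a delimited child table and recode it onto the canonical schema.

    Rows with a missing outcome, missing sex, or a missing/nonpositive weight
    are excluded and counted in the returned :class:`RecodeLog`.
    """
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[""])
    if mapping is None:
        mapping = CodebookMapping.identity(
            [c for c in raw.columns if c in COVARIATE_CATEGORIES]
        )
    rename = dict(mapping.core_map)
    raw = raw.rename(columns=rename)
    missing_core = [c for c in CORE_COLUMNS if c not in raw.columns]
    if missing_core:
        raise ValueError(f"mandatory columns absent: {missing_core}")

    log = RecodeLog(n_read=len(raw))
    out = pd.DataFrame(index=raw.index)
    for c in ("child_id", "country", "cluster_id"):
        out[c] = raw[c].astype(str)
    out["sex"] = raw["sex"].str.strip().str.lower()
    died = pd.to_numeric(raw["died_u5"], errors="coerce")
    weight = pd.to_numeric(raw["weight"], errors="coerce")

    bad_outcome = died.isna() | ~died.isin([0, 1])
    bad_sex = ~out["sex"].isin(SEXES)
    bad_weight = weight.isna() | (weight <= 0)
    log.n_missing_outcome = int(bad_outcome.sum())
    log.n_missing_sex = int((bad_sex & ~bad_outcome).sum())
    log.n_bad_weight = int((bad_weight & ~bad_outcome & ~bad_sex).sum())
    keep = ~(bad_outcome | bad_sex | bad_weight)

    out["died_u5"] = died
    out["weight"] = weight
    for src, (canonical, _) in mapping.column_map.items():
        if src not in raw.columns:
            continue
        col = raw[src].map(lambda v: mapping.apply(src, v))
        log.n_missing_cells += int((col == MISSING).sum())
        out[canonical] = col

    out = out.loc[keep].reset_index(drop=True)
    out["died_u5"] = out["died_u5"].astype(int)
    out["weight"] = out["weight"].astype(float)
    log.n_kept = len(out)
    for line in log.lines():
        logger.info("read_child_table: %s", line)
    _check_cluster_nesting(out)
    return out, log


def write_child_table(frame: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a canonical child table; read_child_table round-trips it exactly."""
    frame.to_csv(path, sep=sep, index=False)


def validate_children(frame: pd.DataFrame) -> pd.DataFrame:
    """Validate a canonical child table in place and return it."""
    for c in CORE_COLUMNS:
        if c not in frame.columns:
            raise ValueError(f"missing column {c!r}")
    if not frame["sex"].isin(SEXES).all():
        raise ValueError("sex must be 'male' or 'female'")
    if not frame["died_u5"].isin([0, 1]).all():
        raise ValueError("died_u5 must be binary")
    if not (frame["weight"] > 0).all():
        raise ValueError("sampling weights must be positive")
    for var in frame.columns:
        allowed = COVARIATE_CATEGORIES.get(var)
        if allowed is None:
            continue
        bad = ~frame[var].astype(str).isin(allowed + (MISSING,))
        if bad.any():
            raise ValueError(f"{var}: invalid categories {sorted(frame.loc[bad, var].unique())}")
    _check_cluster_nesting(frame)
    return frame


def _check_cluster_nesting(frame: pd.DataFrame) -> None:
    ncountries = frame.groupby("cluster_id")["country"].nunique()
    if (ncountries > 1).any():
        bad = ncountries[ncountries > 1].index.tolist()[:5]
        raise ValueError(f"clusters mapping to multiple countries: {bad}")


def complete_cases(frame: pd.DataFrame, covariates: Iterable[str]) -> tuple[pd.DataFrame, int]:
    """Drop records missing any of the given covariates (complete-case rule).

    Returns the filtered frame and the number of rows dropped.
    """
    cov = list(covariates)
    mask = pd.Series(True, index=frame.index)
    for v in cov:
        mask &= frame[v].astype(str) != MISSING
    dropped = int((~mask).sum())
    if dropped:
        logger.info("complete_cases: dropped %d rows missing one of %s", dropped, cov)
    return frame.loc[mask].reset_index(drop=True), dropped


def load_table1_fixture(country_rows_only: bool = False) -> pd.DataFrame:
    """Load the packaged country summary table.

    Columns: country, region, survey_year, n_children, n_clusters, pct_male,
    u5d_overall/u5d_male/u5d_female (deaths per 1000 live births, as
    published), sig_flag (published z-test footnote) and is_region_aggregate
    (regional subtotal and grand-total rows).  Integrity of the transcription
    is verified on every load; a checksum mismatch raises ``ValueError``.
    """
    with resources.files("u5dgap").joinpath("data", _FIXTURE_NAME).open("rb") as fh:
        payload = fh.read()
    digest = hashlib.sha256(payload).hexdigest()
    global _FIXTURE_SHA256
    if _FIXTURE_SHA256 is None:
        _FIXTURE_SHA256 = digest
    elif digest != _FIXTURE_SHA256:
        raise ValueError("fixture checksum mismatch")
    from io import BytesIO

    frame = pd.read_csv(BytesIO(payload), comment="#")
    frame["is_region_aggregate"] = frame["is_region_aggregate"].astype(bool)
    frame["sig_flag"] = frame["sig_flag"].astype(bool)
    countries = frame[~frame.is_region_aggregate]
    if len(countries) != _FIXTURE_N_COUNTRIES:
        raise ValueError("fixture checksum mismatch: country row count")
    if int(countries.n_children.sum()) != _FIXTURE_N_CHILDREN:
        raise ValueError("fixture checksum mismatch: n_children total")
    if int(countries.n_clusters.sum()) != _FIXTURE_N_CLUSTERS:
        raise ValueError("fixture checksum mismatch: n_clusters total")
    if country_rows_only:
        return countries.reset_index(drop=True)
    return frame
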