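"""Survey data model for woman-level maternal-health microdata.

The analysis population is one record per eligible woman (last birth within
the eligibility window), carrying a relative sampling weight, a continuous
household wealth score with its quintile label, the socio-demographic
covariates used throughout the pipeline, and the raw care-utilisation fields
from which the three binary outcome indicators are derived:

* **full ANC** — four or more antenatal visits, at least one tetanus
  injection, and 100+ iron-folic-acid (IFA) tablets/days for the last birth;
* **SBA** — delivery in a medical institution, or at home attended by a
  skilled provider (doctor/nurse/LHV/ANM);
* **PNC** — a maternal check-up within 48 hours of delivery.

Wealth quintiles 1-2 are labelled *poor* and 3-5 *non-poor* for the gap
tables; the continuous score drives the ranking used by the concentration
index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("healthineq.survey")

__all__ = [
    "SchemaError",
    "DataError",
    "DomainError",
    "SurveyTable",
    "GapTable",
    "CATEGORICAL_DOMAINS",
    "ANALYSIS_COLUMNS",
    "load_survey",
    "validate_frame",
    "filter_eligible",
    "recode_full_anc",
    "recode_sba",
    "recode_pnc",
    "derive_indicators",
    "dichotomize_wealth",
    "weighted_proportion",
    "gap_table",
]


class SchemaError(ValueError):
    """A required column is missing or the file does not match the dictionary."""


class DataError(ValueError):
    """The data are structurally valid but empty or unusable."""


class DomainError(ValueError):
    """A value lies outside its documented domain."""


#: categorical covariates and their admissible levels
CATEGORICAL_DOMAINS: dict[str, tuple[str, ...]] = {
    "residence": ("urban", "rural"),
    "age_group": ("15-24", "25-34", "35-49"),
    "birth_order": ("1", "2", "3+"),
    "education": ("none", "primary", "secondary", "higher"),
    "caste": ("SC", "ST", "OBC", "Others"),
    "media_exposure": ("no", "yes"),
}

COUNT_COLUMNS = ("anc_visits", "tt_injections", "ifa_count", "months_since_last_birth")
BOOL_COLUMNS = ("institutional_delivery", "skilled_attendant_at_home", "pnc_within_48h")

#: canonical column set a loaded table must provide
REQUIRED_COLUMNS: tuple[str, ...] = (
    "woman_id",
    "state",
    "weight",
    "wealth_score",
    "wealth_quintile",
    *CATEGORICAL_DOMAINS,
    *COUNT_COLUMNS,
    *BOOL_COLUMNS,
)

#: columns subject to listwise deletion before analysis
ANALYSIS_COLUMNS: tuple[str, ...] = tuple(c for c in REQUIRED_COLUMNS if c != "woman_id")

#: derived indicator columns added by :func:`derive_indicators`
INDICATOR_COLUMNS = ("full_anc", "sba", "pnc")


@dataclass
class SurveyTable:
    """A validated woman-level table plus a provenance tag.

    ``data`` is an ordinary :class:`pandas.DataFrame` with the canonical
    columns; all operations in this package accept and return this thin
    wrapper so that provenance travels with the records.
    """

    data: pd.DataFrame
    provenance: str = ""

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.data)

    def with_data(self, data: pd.DataFrame) -> "SurveyTable":
        return SurveyTable(data=data, provenance=self.provenance)


@dataclass
class GapTable:
    """Tidy poor / non-poor utilisation table.

    One row per (stratifier, level, outcome) with weighted utilisation
    percentages among the poor and the non-poor plus unweighted cell counts.
    Structurally empty cells are reported as NaN, never 0: a genuine 0.0
    means "nobody in this cell used the service", which is a different fact
    from "this cell has no women".
    """

    data: pd.DataFrame
    provenance: str = ""


def _coerce_bool(series: pd.Series) -> pd.Series:
    """Map common boolean encodings (0/1, true/false strings) to pandas booleans."""
    if series.dtype == bool:
        return series
    mapping = {
        "true": True, "false": False, "yes": True, "no": False,
        "1": True, "0": False, 1: True, 0: False, True: True, False: False,
        1.0: True, 0.0: False,
    }

    def conv(v):
        if pd.isna(v):
            return pd.NA
        key = v.strip().lower() if isinstance(v, str) else v
        return mapping.get(key, pd.NA)

    return series.map(conv).astype("boolean")


def validate_frame(df: pd.DataFrame, provenance: str = "") -> SurveyTable:
    """Validate a raw frame against the canonical schema.

    Performs, in order: schema check (every required column present), type
    coercion, listwise deletion over the analysis columns (per-column
    missingness logged), and row-level invariant checks (positive weight,
    quintile in 1..5, categoricals within their domains, nonnegative counts)
    with offending rows rejected and logged.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.copy()
    df["weight"] = pd.to_numeric(df["weight"], errors="coerce")
    df["wealth_score"] = pd.to_numeric(df["wealth_score"], errors="coerce")
    df["wealth_quintile"] = pd.to_numeric(df["wealth_quintile"], errors="coerce")
    for col in COUNT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in BOOL_COLUMNS:
        df[col] = _coerce_bool(df[col])
    for col in CATEGORICAL_DOMAINS:
        df[col] = df[col].astype("string")

    # listwise deletion over analysis columns, with a missingness report
    na_counts = df[list(ANALYSIS_COLUMNS)].isna().sum()
    dropped_na = int(df[list(ANALYSIS_COLUMNS)].isna().any(axis=1).sum())
    if dropped_na:
        report = ", ".join(f"{c}={int(n)}" for c, n in na_counts.items() if n > 0)
        logger.warning(
            "listwise deletion removed %d row(s); per-column missing: %s",
            dropped_na, report,
        )
        df = df.dropna(subset=list(ANALYSIS_COLUMNS))

    # row-level domain invariants
    bad = pd.Series(False, index=df.index)
    reasons: dict[str, pd.Series] = {
        "weight <= 0": df["weight"] <= 0,
        "wealth_quintile not in 1..5": ~df["wealth_quintile"].isin([1, 2, 3, 4, 5]),
    }
    for col, domain in CATEGORICAL_DOMAINS.items():
        reasons[f"{col} outside domain"] = ~df[col].isin(domain)
    for col in COUNT_COLUMNS:
        reasons[f"{col} negative"] = df[col] < 0
    for why, mask in reasons.items():
        n = int(mask.sum())
        if n:
            logger.warning("rejecting %d row(s): %s (e.g. index %s)",
                           n, why, list(df.index[mask][:5]))
        bad |= mask
    df = df[~bad]

    if df.empty:
        raise DataError(f"no valid records remain after validation ({provenance or 'input'})")

    df = df.reset_index(drop=True)
    df["wealth_quintile"] = df["wealth_quintile"].astype(int)
    for col in COUNT_COLUMNS:
        df[col] = df[col].astype(int)
    for col in BOOL_COLUMNS:
        df[col] = df[col].astype(bool)
    return SurveyTable(data=df, provenance=provenance)


def load_survey(path, dictionary: dict[str, str] | None = None,
                religion: str | None = None) -> SurveyTable:
    """Load and validate woman-level microdata from a CSV file.

    Parameters
    ----------
    path
        CSV file with a header row.
    dictionary
        Optional map of *source column name → canonical name*, applied before
        validation, so arbitrarily-named source files can be used.
    religion
        Optional level of a ``religion`` column to restrict to.  The pipeline
        itself is population-agnostic; pass this only when the source file
        carries multiple analysis populations.
    """
    df = pd.read_csv(path)
    if dictionary:
        df = df.rename(columns=dictionary)
    if religion is not None:
        if "religion" not in df.columns:
            raise SchemaError("religion filter requested but no 'religion' column present")
        df = df[df["religion"].astype(str) == religion]
    return validate_frame(df, provenance=str(path))


def filter_eligible(table: SurveyTable, window_months: int = 60) -> SurveyTable:
    """Keep women whose last birth fell inside the eligibility window.

    The window is half-open: ``months_since_last_birth < window_months``
    counts as "within the five years preceding the survey" (DHS convention),
    so a birth exactly at the boundary is excluded.  Record order is
    preserved; the result may be empty (downstream operations raise).
    """
    df = table.data
    kept = df[df["months_since_last_birth"] < window_months].reset_index(drop=True)
    logger.info("eligibility filter (<%d months): %d -> %d rows",
                window_months, len(df), len(kept))
    return table.with_data(kept)


def recode_full_anc(anc_visits: int, tt_injections: int, ifa_count: int) -> int:
    """Full antenatal care: ≥4 ANC visits, ≥1 tetanus injection, ≥100 IFA."""
    if anc_visits < 0 or tt_injections < 0 or ifa_count < 0:
        raise DomainError("care counts must be nonnegative")
    return int(anc_visits >= 4 and tt_injections >= 1 and ifa_count >= 100)


def recode_sba(institutional_delivery: bool, skilled_attendant_at_home: bool) -> int:
    """Skilled attendance at birth: institutional delivery OR skilled home attendance."""
    return int(bool(institutional_delivery) or bool(skilled_attendant_at_home))


def recode_pnc(pnc_within_48h: bool) -> int:
    """Postnatal care: maternal check-up within 48 hours of delivery."""
    return int(bool(pnc_within_48h))


def derive_indicators(table: SurveyTable) -> SurveyTable:
    """Add the three binary outcome columns and the poor/non-poor label.

    Idempotent and row-wise deterministic: each indicator is a pure function
    of the raw fields of its own record.
    """
    df = table.data.copy()
    if (df[list(COUNT_COLUMNS[:3])] < 0).any().any():
        raise DomainError("care counts must be nonnegative")
    df["full_anc"] = ((df["anc_visits"] >= 4)
                      & (df["tt_injections"] >= 1)
                      & (df["ifa_count"] >= 100)).astype(int)
    df["sba"] = (df["institutional_delivery"]
                 | df["skilled_attendant_at_home"]).astype(int)
    df["pnc"] = df["pnc_within_48h"].astype(int)
    df["poor"] = df["wealth_quintile"].map(dichotomize_wealth)
    return table.with_data(df)


def dichotomize_wealth(wealth_quintile: int) -> str:
    """Collapse quintiles to the poor / non-poor dichotomy.

    Quintiles 1 (poorest) and 2 (poorer) are *poor*; 3-5 (middle, richer,
    richest) are *non-poor*.
    """
    if wealth_quintile not in (1, 2, 3, 4, 5):
        raise DomainError(f"wealth quintile must be in 1..5, got {wealth_quintile!r}")
    return "poor" if wealth_quintile in (1, 2) else "non-poor"


def weighted_proportion(indicator, weights) -> float:
    """Weighted utilisation percentage, 100 * Σ w_i y_i / Σ w_i."""
    y = np.asarray(indicator, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise DataError("cannot take a proportion of an empty vector")
    if y.shape != w.shape:
        raise DataError("indicator and weights must have equal length")
    return float(100.0 * np.sum(w * y) / np.sum(w))


def _cell_pct(df: pd.DataFrame, outcome: str) -> float:
    if df.empty:
        return float("nan")
    return weighted_proportion(df[outcome].to_numpy(), df["weight"].to_numpy())


def gap_table(table: SurveyTable,
              outcomes: tuple[str, ...] = INDICATOR_COLUMNS,
              stratifiers: tuple[str, ...] = tuple(CATEGORICAL_DOMAINS)) -> GapTable:
    """Poor vs non-poor weighted utilisation by subgroup.

    For every stratifier level and outcome, the weighted utilisation
    percentage among poor and among non-poor women, plus unweighted cell
    counts; a ``Total`` row per outcome covers the whole table.  An empty
    poor or non-poor cell yields NaN with a log entry.
    """
    df = table.data
    if not set(INDICATOR_COLUMNS) <= set(df.columns) or "poor" not in df.columns:
        df = derive_indicators(table).data
    for name in (*outcomes, *stratifiers):
        if name not in df.columns:
            raise SchemaError(f"unknown column for gap table: {name}")

    poor = df[df["poor"] == "poor"]
    nonpoor = df[df["poor"] == "non-poor"]
    rows = []

    def emit(strat: str, level: str, sub_poor: pd.DataFrame, sub_nonpoor: pd.DataFrame):
        for outcome in outcomes:
            p = _cell_pct(sub_poor, outcome)
            q = _cell_pct(sub_nonpoor, outcome)
            if np.isnan(p) or np.isnan(q):
                logger.warning("gap table cell (%s=%s, %s) has an empty poor or "
                               "non-poor stratum; reported as undefined", strat, level, outcome)
            rows.append({"stratifier": strat, "level": level, "outcome": outcome,
                         "poor_pct": p, "nonpoor_pct": q,
                         "n_poor": len(sub_poor), "n_nonpoor": len(sub_nonpoor)})

    for strat in stratifiers:
        levels = CATEGORICAL_DOMAINS.get(strat)
        if levels is None:
            levels = tuple(pd.unique(df[strat].astype(str)))
        for level in levels:
            emit(strat, str(level),
                 poor[poor[strat].astype(str) == str(level)],
                 nonpoor[nonpoor[strat].astype(str) == str(level)])
    emit("Total", "Total", poor, nonpoor)

    return GapTable(data=pd.DataFrame(rows), provenance=table.provenance)
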