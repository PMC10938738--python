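"""Open-cohort construction with lagged time-varying exposure.

Each eligible person contributes one risk interval ("slice") per calendar
year of follow-up (2006-2017 by default).  The slice's exposure is the
comorbidity score computed from the *previous* year's dispensings; its
person-time runs from January 1 (or the year the person turns 51) to the
month of first hip fracture, death, emigration, or December 31, in units of
months/12.  The convention is month-resolution: an event or censoring in
month m contributes m/12 person-years, i.e. the event month counts as time
at risk.  A fracture and a death recorded in the same month count as an
event.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import CohortDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "BAND_LABELS",
    "AGE_GROUP_LABELS",
    "band_rx_risk",
    "age_group",
    "apply_washout",
    "require_dispensing",
    "build_slices",
]

BAND_LABELS = ["<=0", "1-5", "6-10", "11-15", "16-20", "21-25", ">25", "missing"]
AGE_GROUP_LABELS = ["51-65", "66-80", ">80"]

_BAND_EDGES = [0, 5, 10, 15, 20, 25]


def band_rx_risk(values):
    """5-unit exposure bands: <=0, 1-5, ..., 21-25, >25; NA -> 'missing'.

    Accepts a scalar (int or NA) or an array-like; total on integers.
    """
    scalar = np.isscalar(values) or values is pd.NA or values is None
    arr = pd.array([values] if scalar else values, dtype="Int64")
    idx = np.searchsorted(_BAND_EDGES, arr.to_numpy(dtype=float, na_value=np.inf), side="left")
    out = np.where(
        pd.isna(arr), "missing", np.array(BAND_LABELS, dtype=object)[idx]
    )
    return out[0] if scalar else pd.Series(out, name="rx_risk_band")


def age_group(ages):
    """Attained-age groups 51-65, 66-80, >80 (closed integer bands)."""
    scalar = np.isscalar(ages)
    arr = np.asarray([ages] if scalar else ages, dtype=float)
    if (arr < 51).any():
        raise ValueError("attained age below 51 is outside the cohort")
    out = np.where(arr <= 65, "51-65", np.where(arr <= 80, "66-80", ">80"))
    return out[0] if scalar else pd.Series(out, name="age_group")


def apply_washout(persons: pd.DataFrame, fractures: pd.DataFrame) -> pd.DataFrame:
    """Drop persons with any fracture in the washout history window, so
    follow-up events are first fractures."""
    if len(fractures) == 0 or "is_history" not in fractures:
        return persons.copy()
    excluded = fractures.loc[fractures["is_history"].astype(bool), "person_id"].unique()
    out = persons[~persons["person_id"].isin(excluded)].copy()
    logger.info(
        "washout: excluded %d of %d persons with a pre-follow-up fracture",
        len(persons) - len(out),
        len(persons),
    )
    return out


def require_dispensing(persons: pd.DataFrame, dispensings: pd.DataFrame) -> pd.DataFrame:
    """Restrict to persons who filled at least one prescription during the
    dispensing window (the population-at-risk definition)."""
    ever = dispensings["person_id"].unique()
    out = persons[persons["person_id"].isin(ever)].copy()
    logger.info(
        "population at risk: %d of %d persons ever filled a prescription",
        len(out),
        len(persons),
    )
    return out


def build_slices(
    persons: pd.DataFrame,
    scores: pd.DataFrame,
    fractures: pd.DataFrame,
    definition: CohortDefinition | None = None,
) -> pd.DataFrame:
    """One risk interval per person per follow-up calendar year.

    Parameters
    ----------
    persons : frame after washout (and any population filters).
    scores : person_id, year, rx_risk (nullable) — exposure years.
    fractures : event records; history rows are ignored here (apply washout
        first), and only each person's first in-follow-up fracture is used.
    """
    definition = definition or CohortDefinition()
    definition.validate()

    p = persons.copy().reset_index(drop=True)
    fr = fractures[~fractures.get("is_history", pd.Series(False, index=fractures.index)).astype(bool)]
    fr = fr.sort_values(["person_id", "year", "month"]).drop_duplicates(
        "person_id", keep="first"
    )
    fr = fr.set_index("person_id")

    p = p.join(fr[["year", "month"]].rename(columns={"year": "frac_year", "month": "frac_month"}), on="person_id")

    entry_year = np.maximum(
        definition.start_year, p["birth_year"].to_numpy() + definition.min_age
    )
    frac_year = p["frac_year"].to_numpy(dtype=float)
    if np.any(frac_year < entry_year):
        bad = p.loc[frac_year < entry_year, "person_id"].tolist()[:5]
        raise ValueError(
            f"fracture before cohort entry for person(s) {bad}; was washout applied?"
        )

    def key(year, month):
        return year * 12 + (month - 1)

    end_key = key(definition.end_year, 12)
    exit_key = np.full(len(p), end_key, dtype=float)
    for ycol, mcol in (
        ("death_year", "death_month"),
        ("emig_year", "emig_month"),
        ("frac_year", "frac_month"),
    ):
        yv = pd.to_numeric(p[ycol], errors="coerce").to_numpy(dtype=float)
        mv = pd.to_numeric(p[mcol], errors="coerce").to_numpy(dtype=float)
        k = np.where(np.isnan(yv), np.inf, key(yv, np.nan_to_num(mv, nan=1.0)))
        exit_key = np.minimum(exit_key, k)

    frac_key = np.where(
        np.isnan(frac_year),
        np.inf,
        key(frac_year, pd.to_numeric(p["frac_month"], errors="coerce").to_numpy(dtype=float)),
    )
    # fracture takes precedence over death/emigration in the same month
    event = frac_key <= exit_key
    exit_year = (exit_key // 12).astype(int)
    exit_month = (exit_key - exit_year * 12 + 1).astype(int)

    n_years = exit_year - entry_year + 1
    keep = n_years > 0
    if not keep.all():
        logger.info("dropping %d persons who exit before entry", int((~keep).sum()))
    idx = np.repeat(np.nonzero(keep)[0], n_years[keep])
    offsets = np.concatenate([np.arange(k) for k in n_years[keep]]) if keep.any() else np.array([], dtype=int)
    year = entry_year[idx] + offsets
    is_exit_year = year == exit_year[idx]

    slices = pd.DataFrame(
        {
            "person_id": p["person_id"].to_numpy()[idx],
            "year": year,
            "sex": p["sex"].to_numpy()[idx],
            "birth_year": p["birth_year"].to_numpy()[idx],
        }
    )
    slices["attained_age"] = slices["year"] - slices["birth_year"]
    slices["age_group"] = age_group(slices["attained_age"]).to_numpy()
    slices["person_time"] = np.where(is_exit_year, exit_month[idx] / 12.0, 1.0)
    slices["event"] = (is_exit_year & event[idx]).astype(int)

    # lagged exposure: year t classified by the score computed for year t-1
    sc = scores[["person_id", "year", "rx_risk"]].copy()
    sc["year"] = sc["year"] + 1
    slices = slices.merge(sc, on=["person_id", "year"], how="left")
    slices["rx_risk"] = slices["rx_risk"].astype("Int64")
    covered = set(scores["year"].unique() + 1)
    uncovered = sorted(set(slices["year"].unique()) - covered)
    if uncovered:
        logger.warning(
            "no score input for exposure year(s) %s; exposure set to missing",
            [y - 1 for y in uncovered],
        )
    slices = slices.rename(columns={"rx_risk": "rx_risk_value"})
    slices["rx_risk_band"] = band_rx_risk(slices["rx_risk_value"]).to_numpy()
    return slices.reset_index(drop=True)
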