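"""Aggregation, directly standardized incidence rates, and descriptives.

Slices are summed into cells by sex x birth year x calendar year x exposure
band (the unit of all rate and model computation; attained age group is a
deterministic function of birth and calendar year and is carried along).
Incidence rates per 10,000 person-years are directly standardized over the
birth-year x calendar-year distribution of the whole cohort's person-time
(configurable), with normal-approximation confidence intervals built from
Poisson stratum variances.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["aggregate", "standardized_rate", "median_test", "describe"]

CELL_KEYS = ["sex", "birth_year", "year", "rx_risk_band"]


def aggregate(slices: pd.DataFrame, extra_keys: tuple = ()) -> pd.DataFrame:
    """Sum events and person-time into cells.

    Conservation is exact: cell totals equal slice totals.
    """
    keys = CELL_KEYS + [k for k in extra_keys if k not in CELL_KEYS]
    cells = (
        slices.groupby(keys, observed=True, dropna=False)
        .agg(events=("event", "sum"), person_years=("person_time", "sum"))
        .reset_index()
    )
    cells["attained_age"] = cells["year"] - cells["birth_year"]
    from .cohort import age_group

    cells["age_group"] = age_group(cells["attained_age"]).to_numpy()
    return cells


def standardized_rate(
    cells: pd.DataFrame,
    by: tuple = ("sex", "age_group", "rx_risk_band"),
    standard: pd.DataFrame | None = None,
    per: float = 10_000.0,
) -> pd.DataFrame:
    """Directly standardized incidence rates per ``per`` person-years.

    ``standard`` is a frame with columns birth_year, year, weight giving the
    standard population's person-time distribution over birth-year x
    calendar-year strata; by default the whole input's person-time
    distribution.  Within each ``by`` group, the rate is the weighted mean of
    stratum-specific rates; strata present in the standard but without
    person-time in the group are skipped (with a warning) and the remaining
    weights renormalized.  The variance treats stratum event counts as
    Poisson; the CI is a normal approximation on the rate scale, floored at
    zero.
    """
    strata = ["birth_year", "year"]
    # attained-age group is a function of birth year x calendar year, so the
    # default standard is formed within each age-group margin (pooling sexes
    # and exposure bands); a global standard would structurally miss every
    # age-stratified group.
    default_margin = ["age_group"] if "age_group" in by else []
    if standard is None:
        total = cells.groupby(default_margin + strata, as_index=False)[
            "person_years"
        ].sum()
        total["weight"] = total["person_years"]
        standard = total[default_margin + strata + ["weight"]]
    else:
        standard = standard.copy()
        standard["weight"] = standard["weight"] / standard["weight"].sum()
        default_margin = [c for c in ["age_group"] if c in standard.columns]

    rows = []
    n_skipped_total = 0
    for labels, g in cells.groupby(list(by), observed=True):
        if not isinstance(labels, tuple):
            labels = (labels,)
        label_map = dict(zip(by, labels))
        std = standard
        for col in default_margin:
            std = std[std[col] == label_map[col]]
        gs = g.groupby(strata, as_index=False)[["events", "person_years"]].sum()
        m = std.merge(gs, on=strata, how="left")
        have = m["person_years"].fillna(0) > 0
        n_skipped_total += int((~have).sum())
        m = m[have]
        if len(m) == 0:
            continue
        w = (m["weight"] / m["weight"].sum()).to_numpy()
        r = (m["events"] / m["person_years"]).to_numpy()
        var = (m["events"] / m["person_years"] ** 2).to_numpy()
        rate = float(np.sum(w * r)) * per
        sd = float(np.sqrt(np.sum(w**2 * var))) * per
        rows.append(
            dict(zip(by, labels))
            | {
                "events": int(g["events"].sum()),
                "person_years": float(g["person_years"].sum()),
                "rate": rate,
                "ci_low": max(0.0, rate - 1.96 * sd),
                "ci_high": rate + 1.96 * sd,
            }
        )
    if n_skipped_total:
        logger.warning(
            "standardization: %d standard stratum(a) without person-time in "
            "their target group were skipped (weights renormalized)",
            n_skipped_total,
        )
    return pd.DataFrame(rows)


def median_test(values_a, values_b) -> float:
    """Mood's median test (chi-square on counts above/below the pooled
    median, continuity-corrected); returns the p-value.

    Degenerate inputs where every value equals the pooled median return
    p = 1 with a warning.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("median test requires two non-empty samples")
    try:
        res = stats.median_test(a, b, ties="below", correction=True)
    except ValueError:
        warnings.warn("all values equal the pooled median; p-value set to 1")
        return 1.0
    return float(res.pvalue)


def describe(slices: pd.DataFrame, year: int) -> pd.DataFrame:
    """Descriptive summary of one follow-up year, split by fracture status.

    Per sex x attained-age group x fracture status: number of individuals,
    person-years, and median (IQR) of the lagged exposure score; per sex x
    fracture status (age_group 'all'): median (IQR) age.  Strata without
    individuals simply do not appear.
    """
    s = slices[slices["year"] == year].copy()
    if len(s) == 0:
        raise ValueError(f"no slices in year {year}")
    s["fracture"] = np.where(s["event"] == 1, "yes", "no")

    def q(x, p):
        x = x.dropna()
        return float(np.percentile(x, p)) if len(x) else np.nan

    rows = []
    for (sex, grp, frac), g in s.groupby(["sex", "age_group", "fracture"], observed=True):
        rx = g["rx_risk_value"].astype("Float64").astype(float)
        rx = pd.Series(rx).dropna()
        rows.append(
            {
                "sex": sex,
                "age_group": grp,
                "fracture": frac,
                "n_individuals": g["person_id"].nunique(),
                "person_years": float(g["person_time"].sum()),
                "rx_risk_median": float(np.median(rx)) if len(rx) else np.nan,
                "rx_risk_q1": q(pd.Series(rx), 25) if len(rx) else np.nan,
                "rx_risk_q3": q(pd.Series(rx), 75) if len(rx) else np.nan,
            }
        )
    for (sex, frac), g in s.groupby(["sex", "fracture"], observed=True):
        age = g["attained_age"].astype(float)
        rows.append(
            {
                "sex": sex,
                "age_group": "all",
                "fracture": frac,
                "n_individuals": g["person_id"].nunique(),
                "person_years": float(g["person_time"].sum()),
                "age_median": float(np.median(age)),
                "age_q1": q(age, 25),
                "age_q3": q(age, 75),
            }
        )
    return pd.DataFrame(rows)
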