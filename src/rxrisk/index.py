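"""The medication-based Rx-Risk Comorbidity Index.

Three stages:

1. **Category assignment** — every dispensed 7-character ATC code is mapped
   to at most one of 46 disease categories by longest-prefix matching, and a
   person-year's category set is the set of distinct categories filled that
   calendar year (set semantics: repeat fills are irrelevant).

2. **Severity-weight calibration** — separately for each calendar year, a
   sex- and age-adjusted logistic regression of death in the following year
   on all category indicators yields a mortality odds ratio per category,
   converted to an integer severity weight in {-1, 0, ..., 6} by a published
   step function on (OR, p-value).

3. **Scoring** — a person's yearly score is the sum of that year's weights
   over the categories they filled.  Person-years with no index fill (or
   only fills outside the index) have no score: missingness is an explicit
   state, never coerced to zero here.

The packaged default mapping is a reconstruction of the 46-category index
from the published category list; its exact ATC prefixes are illustrative,
not authoritative, and any mapping file with the same column layout can be
substituted.
"""

from __future__ import annotations

import logging
import re
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "ATC_PATTERN",
    "CategoryMapping",
    "load_mapping",
    "default_mapping",
    "assign_categories",
    "map_or_to_weight",
    "calibrate_weights",
    "calibrate_weights_range",
    "compute_scores",
]

ATC_PATTERN = re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$")

_MAPPING_COLUMNS = ["atc_prefix", "category_id", "category_name"]


class CategoryMapping:
    """ATC-prefix to disease-category lookup.

    Longest-prefix resolution lets chemical-subgroup entries (e.g. ``N05A``)
    coexist with more specific ones (``N05AN``): a full code always resolves
    to the single longest matching prefix.  The same prefix string listed
    under two categories would make codes ambiguous and is rejected.
    """

    def __init__(self, entries: pd.DataFrame):
        missing = [c for c in _MAPPING_COLUMNS if c not in entries.columns]
        if missing:
            raise ValueError(f"mapping is missing columns: {missing}")
        entries = entries[_MAPPING_COLUMNS].astype(str)
        if len(entries) == 0:
            raise ValueError("mapping file contains no entries")
        dup = entries["atc_prefix"][entries["atc_prefix"].duplicated()]
        if not dup.empty:
            raise ValueError(
                "ambiguous mapping: prefix(es) assigned more than once: "
                + ", ".join(sorted(dup.unique()))
            )
        bad = entries["atc_prefix"][~entries["atc_prefix"].str.match(r"^[A-Z][0-9A-Z]{0,6}$")]
        if not bad.empty:
            raise ValueError(f"malformed ATC prefixes: {sorted(bad.unique())}")
        self.entries = entries.reset_index(drop=True)
        self._by_prefix = dict(
            zip(entries["atc_prefix"], entries["category_id"])
        )
        self._lengths = sorted({len(p) for p in self._by_prefix}, reverse=True)

    @property
    def category_ids(self) -> list[str]:
        return sorted(self.entries["category_id"].unique())

    @property
    def n_categories(self) -> int:
        return self.entries["category_id"].nunique()

    def resolve_code(self, code: str) -> str | None:
        """Category for one full ATC code, or None if outside the index."""
        for length in self._lengths:
            cat = self._by_prefix.get(code[:length])
            if cat is not None:
                return cat
        return None

    def resolve(self, codes: pd.Series) -> pd.Series:
        """Vectorized :meth:`resolve_code`; unmatched codes map to NA."""
        uniq = pd.Series(codes.unique())
        table = {c: self.resolve_code(c) for c in uniq}
        return codes.map(table)


def load_mapping(path) -> CategoryMapping:
    """Load and validate a delimited mapping file (atc_prefix, category_id,
    category_name)."""
    frame = pd.read_csv(path)
    return CategoryMapping(frame)


def default_mapping() -> CategoryMapping:
    """The packaged 46-category mapping (reconstruction; see module docs)."""
    with resources.as_file(
        resources.files("rxrisk").joinpath("data/atc_categories.csv")
    ) as path:
        return load_mapping(Path(path))


def assign_categories(
    dispensings: pd.DataFrame, mapping: CategoryMapping
) -> pd.DataFrame:
    """Distinct disease categories per person per calendar year.

    Returns one row per (person_id, year, category_id).  Person-years whose
    fills all fall outside the index keep a single row with category_id NA:
    the person-year was observed (they filled *something*) but contributes
    no index category — downstream that is the 'missing score' state.
    Malformed ATC codes are skipped with a logged count.
    """
    if len(dispensings) == 0:
        return pd.DataFrame(columns=["person_id", "year", "category_id"])
    d = dispensings[["person_id", "year", "atc"]].copy()
    ok = d["atc"].astype(str).str.match(ATC_PATTERN)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning(
            "skipping %d dispensing(s) with malformed ATC codes", n_bad
        )
        d = d[ok]
    d["category_id"] = mapping.resolve(d["atc"])
    observed = d[["person_id", "year"]].drop_duplicates()
    hits = (
        d.dropna(subset=["category_id"])[["person_id", "year", "category_id"]]
        .drop_duplicates()
    )
    only_nonindex = observed.merge(
        hits[["person_id", "year"]].drop_duplicates(),
        how="left",
        indicator=True,
    )
    only_nonindex = only_nonindex[only_nonindex["_merge"] == "left_only"][
        ["person_id", "year"]
    ]
    only_nonindex["category_id"] = pd.NA
    out = pd.concat([hits, only_nonindex], ignore_index=True)
    return out.sort_values(["person_id", "year", "category_id"]).reset_index(
        drop=True
    )


def map_or_to_weight(odds_ratio: float, p_value: float) -> int:
    """Severity weight from a category's 1-year mortality OR and p-value.

    Any OR with p-value > 0.10 gets weight 0.  For p <= 0.10: weight -1 for
    OR < 1, then 1 for OR in [1.00, 1.20), 2 for [1.20, 1.40), 3 for
    [1.40, 1.60), 4 for [1.60, 1.80), 5 for [1.80, 2.00), and 6 for
    OR >= 2.00.  Half-open bands close the printed gaps (1.19 -> 1.20 etc.)
    without overlap, so the function is total on (0, inf) x [0, 1].
    """
    if not odds_ratio > 0:
        raise ValueError(f"odds ratio must be positive, got {odds_ratio}")
    if not 0.0 <= p_value <= 1.0:
        raise ValueError(f"p-value out of [0,1]: {p_value}")
    if p_value > 0.10:
        return 0
    if odds_ratio < 1.0:
        return -1
    # explicit ladder: (OR - 1)/0.2 arithmetic misbands edge values like 1.2
    for upper, weight in ((1.2, 1), (1.4, 2), (1.6, 3), (1.8, 4), (2.0, 5)):
        if odds_ratio < upper:
            return weight
    return 6


def _weights_vector(odds_ratios, p_values) -> np.ndarray:
    return np.array(
        [map_or_to_weight(o, p) for o, p in zip(odds_ratios, p_values)],
        dtype=int,
    )


def calibrate_weights(
    category_sets: pd.DataFrame,
    persons: pd.DataFrame,
    year: int,
    categories: list[str] | None = None,
    min_age: int = 50,
) -> pd.DataFrame:
    """Calendar-year severity-weight calibration.

    Fits one logistic regression: outcome = death in ``year + 1``; exposures
    = indicators of all disease categories filled in ``year``; adjusted for
    sex and (continuous) age.  The calibration population is person-years
    aged >= ``min_age`` observed in the dispensing data that year (index or
    non-index fills), alive through the end of ``year``, and with vital
    status for ``year + 1`` known (not emigrated by then).

    Categories with no users, or with a zero cell in the exposure-by-death
    2x2 table (which would separate the likelihood), are dropped from the
    model and reported with weight 0 and a logged warning, keeping the
    weight table total over ``categories``.

    Returns a frame with columns year, category_id, odds_ratio, p_value,
    weight, n_exposed, n_exposed_deaths.
    """
    sets_y = category_sets[category_sets["year"] == year]
    if categories is None:
        categories = sorted(
            sets_y["category_id"].dropna().unique().tolist()
        )
    pop = sets_y[["person_id"]].drop_duplicates()
    p = persons.set_index("person_id")
    pop = pop.join(
        p[["sex", "birth_year", "death_year", "emig_year"]], on="person_id"
    )
    pop["age"] = year - pop["birth_year"]
    dead_before = pop["death_year"].notna() & (pop["death_year"] <= year)
    emigrated = pop["emig_year"].notna() & (pop["emig_year"] <= year + 1)
    pop = pop[(pop["age"] >= min_age) & ~dead_before & ~emigrated]
    if len(pop) == 0:
        raise ValueError(f"empty calibration population for year {year}")
    y = (pop["death_year"] == year + 1).fillna(False).to_numpy(dtype=float)

    fills = sets_y.dropna(subset=["category_id"])
    ind = (
        fills.assign(one=1.0)
        .pivot_table(index="person_id", columns="category_id", values="one", fill_value=0.0)
        .reindex(pop["person_id"], fill_value=0.0)
        .reindex(columns=categories, fill_value=0.0)
    )
    X = ind.to_numpy(dtype=float)

    rows = []
    usable = []
    for j, cat in enumerate(categories):
        exposed = X[:, j] > 0
        n_exp = int(exposed.sum())
        n_exp_dead = int(y[exposed].sum())
        cells = (
            n_exp_dead,
            n_exp - n_exp_dead,
            int(y[~exposed].sum()),
            int((~exposed).sum() - y[~exposed].sum()),
        )
        degenerate = min(cells) == 0
        if degenerate:
            logger.warning(
                "category %r degenerate in %d (2x2 cells %s); weight set to 0",
                cat,
                year,
                cells,
            )
        rows.append(
            {
                "category_id": cat,
                "n_exposed": n_exp,
                "n_exposed_deaths": n_exp_dead,
                "degenerate": degenerate,
            }
        )
        if not degenerate:
            usable.append(j)

    design = [X[:, usable]]
    names = [categories[j] for j in usable]
    female = (pop["sex"] == "female").to_numpy(dtype=float)
    age = pop["age"].to_numpy(dtype=float)
    for arr, nm in ((female, "female"), (age, "age")):
        if np.ptp(arr) > 0:  # constant adjusters carry no information
            design.append(arr[:, None])
            names.append(nm)
    design.append(np.ones((len(pop), 1)))
    names.append("const")
    Xd = np.hstack(design)

    try:
        res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError("logistic calibration did not converge")
    except Exception:
        logger.warning(
            "Newton fit failed for year %d; retrying with BFGS", year
        )
        res = sm.Logit(y, Xd).fit(disp=0, method="bfgs", maxiter=500)

    coef = dict(zip(names, res.params))
    pval = dict(zip(names, res.pvalues))

    out = []
    for row in rows:
        cat = row["category_id"]
        if row["degenerate"] or cat not in coef:
            o, pv, w = np.nan, np.nan, 0
        else:
            o = float(np.exp(coef[cat]))
            pv = float(pval[cat])
            w = map_or_to_weight(o, pv)
        out.append(
            {
                "year": year,
                "category_id": cat,
                "odds_ratio": o,
                "p_value": pv,
                "weight": w,
                "n_exposed": row["n_exposed"],
                "n_exposed_deaths": row["n_exposed_deaths"],
            }
        )
    return pd.DataFrame(out)


def calibrate_weights_range(
    category_sets: pd.DataFrame,
    persons: pd.DataFrame,
    years,
    categories: list[str] | None = None,
    min_age: int = 50,
) -> pd.DataFrame:
    """Stack :func:`calibrate_weights` over calendar years."""
    return pd.concat(
        [
            calibrate_weights(category_sets, persons, y, categories, min_age)
            for y in years
        ],
        ignore_index=True,
    )


def compute_scores(
    category_sets: pd.DataFrame, weight_table: pd.DataFrame
) -> pd.DataFrame:
    """Yearly total score per person: sum of the year's severity weights over
    the distinct categories filled.

    Person-years present in ``category_sets`` with no index category (only
    non-index fills) get a missing score (NA).  A category present in the
    data but absent from the weight table for that year is an error.

    Returns columns person_id, year, rx_risk (nullable Int64).
    """
    observed = category_sets[["person_id", "year"]].drop_duplicates()
    fills = category_sets.dropna(subset=["category_id"])
    merged = fills.merge(
        weight_table[["year", "category_id", "weight"]],
        on=["year", "category_id"],
        how="left",
    )
    if merged["weight"].isna().any():
        bad = (
            merged[merged["weight"].isna()][["year", "category_id"]]
            .drop_duplicates()
            .itertuples(index=False)
        )
        raise KeyError(
            "weight table does not cover: "
            + ", ".join(f"{c}@{y}" for y, c in bad)
        )
    totals = (
        merged.groupby(["person_id", "year"], as_index=False)["weight"]
        .sum()
        .rename(columns={"weight": "rx_risk"})
    )
    out = observed.merge(totals, on=["person_id", "year"], how="left")
    out["rx_risk"] = out["rx_risk"].astype("Int64")
    return out.sort_values(["person_id", "year"]).reset_index(drop=True)
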