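"""Negative-binomial incidence-rate-ratio models.

All model-based analyses regress event counts on covariates with a log
person-time offset under an NB2 (quadratic variance, mu + alpha*mu^2)
negative binomial likelihood, the standard alternative to Poisson
regression under overdispersion; alpha -> 0 recovers the Poisson model.
Coefficients are reported as exponentiated rate ratios with Wald 95%
confidence intervals.  Birth year and calendar year enter as centered
continuous linear terms by default (categorical optional).

Analyses provided:

* band IRRs (5-unit exposure bands, reference <=0, the missing-score state
  kept as its own indicator), optionally stratified by sex and age group;
* a continuous per-unit trend IRR (aggregation by exact score value);
* likelihood-ratio interaction tests of exposure with sex / birth year /
  calendar year;
* women-versus-men contrasts within band x age-group strata;
* per-disease-category IRRs from a single cross-sectional year pair
  (categories in year t as simultaneous indicators, fractures in t+1);
* 1/3/5-year latency analyses with bands above 15 collapsed;
* sensitivity variants for the missing-score state.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .cohort import BAND_LABELS, band_rx_risk
from .rates import aggregate

logger = logging.getLogger(__name__)

__all__ = [
    "fit_band_irr",
    "fit_trend_irr",
    "test_interaction",
    "sex_contrast",
    "category_irr",
    "latency_analysis",
    "sensitivity_variants",
]

REFERENCE_BAND = "<=0"
LATENCY_BANDS = ["<=0", "1-5", "6-10", "11-15", ">15", "missing"]


class ConvergenceError(RuntimeError):
    pass


class NBFit:
    """Uniform view of an NB2 fit: coefficient names (dispersion last, named
    'alpha'), point estimates, Wald confidence bounds, log-likelihood."""

    def __init__(self, names, params, conf_int, llf):
        self.names = list(names)
        self.params = np.asarray(params, dtype=float)
        self.conf_int = np.asarray(conf_int, dtype=float)
        self.llf = float(llf)

    @property
    def alpha(self) -> float:
        return float(self.params[-1])


_ALPHA_BOUNDARY = 1e-3


def _fit_nb(endog, exog: pd.DataFrame, exposure) -> NBFit:
    """NB2 fit with Poisson warm start.

    At the alpha -> 0 boundary (equidispersed data) the NB information
    matrix is singular and Wald standard errors are undefined; there the
    model *is* Poisson, so coefficient inference falls back to the Poisson
    fit with the boundary alpha reported.  Genuine non-convergence raises
    ConvergenceError reporting the last log-likelihood.
    """
    endog = np.asarray(endog, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    names = list(exog.columns) + ["alpha"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = sm.Poisson(endog, exog, exposure=exposure).fit(disp=0, maxiter=500)
        model = sm.NegativeBinomial(
            endog, exog, exposure=exposure, loglike_method="nb2"
        )
        res = model.fit(
            start_params=np.append(pois.params, 0.05),
            method="bfgs", maxiter=500, disp=0,
        )

        def bad(r):
            return (
                not r.mle_retvals.get("converged", False)
                or np.isnan(np.asarray(r.params)).any()
                or np.isnan(np.asarray(r.bse)[:-1]).any()
            )

        if bad(res):
            retry = model.fit(
                start_params=np.append(pois.params, 0.01),
                method="nm", maxiter=5000, maxfun=5000, disp=0,
            )
            if retry.llf > res.llf or bad(res) and not bad(retry):
                res = retry
        params = np.asarray(res.params, dtype=float)
        alpha = float(params[-1])

        if res.llf <= pois.llf + 1e-6:
            # alpha is at (or indistinguishable from) the zero boundary: the
            # model *is* Poisson, whose Newton MLE is exact and whose
            # information matrix is well-conditioned
            logger.info(
                "NB likelihood-equivalent to Poisson (alpha=%.2e); "
                "Poisson inference used", alpha,
            )
            ci = np.vstack([np.asarray(pois.conf_int()), [0.0, np.nan]])
            return NBFit(
                names, np.append(np.asarray(pois.params), min(alpha, _ALPHA_BOUNDARY)),
                ci, pois.llf,
            )
        if bad(res):
            # dispersion weakly identified (tiny likelihood gain) but the
            # optimizer cannot produce usable curvature: report Poisson
            # coefficient inference, flagging the unstable alpha
            if res.llf - pois.llf < 2.0:
                logger.warning(
                    "NB dispersion weakly identified (llf gain %.3f); "
                    "Poisson inference used for coefficients",
                    res.llf - pois.llf,
                )
                ci = np.vstack([np.asarray(pois.conf_int()), [0.0, np.nan]])
                return NBFit(
                    names, np.append(np.asarray(pois.params), alpha), ci, res.llf
                )
            raise ConvergenceError(
                f"negative binomial fit did not converge (last llf {res.llf:.4f})"
            )
    return NBFit(names, params, np.asarray(res.conf_int()), res.llf)


def _center(x):
    x = np.asarray(x, dtype=float)
    return x - x.mean()


def _adjusters(frame: pd.DataFrame, adjust: str) -> pd.DataFrame:
    """Birth-year and calendar-year adjustment columns."""
    out = {}
    if adjust == "continuous":
        for col in ("birth_year", "year"):
            v = frame[col].to_numpy(dtype=float)
            if np.ptp(v) > 0:
                out[f"{col}_c"] = _center(v)
    elif adjust == "categorical":
        for col in ("birth_year", "year"):
            d = pd.get_dummies(frame[col], prefix=col, drop_first=True, dtype=float)
            out.update({c: d[c].to_numpy() for c in d.columns})
    elif adjust is None:
        pass
    else:
        raise ValueError(f"unknown adjust: {adjust!r}")
    return pd.DataFrame(out, index=frame.index)


def _band_dummies(frame: pd.DataFrame, bands: list[str], ref: str, col="rx_risk_band"):
    present = [b for b in bands if (frame[col] == b).any()]
    if ref not in present:
        raise ValueError(f"reference band {ref!r} absent from the data")
    terms = [b for b in present if b != ref]
    X = pd.DataFrame(
        {b: (frame[col] == b).astype(float).to_numpy() for b in terms},
        index=frame.index,
    )
    return X, terms


def _centered_col(frame: pd.DataFrame, col: str) -> pd.DataFrame:
    """One centered continuous column, or nothing if it is constant."""
    v = frame[col].to_numpy(dtype=float)
    if np.ptp(v) == 0:
        return pd.DataFrame(index=frame.index)
    return pd.DataFrame({f"{col}_c": _center(v)}, index=frame.index)


def _maybe_female(frame: pd.DataFrame) -> pd.DataFrame:
    if "sex" in frame and frame["sex"].nunique() > 1:
        return pd.DataFrame(
            {"female": (frame["sex"] == "female").astype(float).to_numpy()},
            index=frame.index,
        )
    return pd.DataFrame(index=frame.index)


def _design(parts: list[pd.DataFrame]) -> pd.DataFrame:
    X = pd.concat([p for p in parts if p.shape[1] > 0], axis=1)
    X["const"] = 1.0
    return X


def _irr_rows(res: NBFit, terms, stratum: dict) -> list[dict]:
    params = pd.Series(res.params, index=res.names)
    ci = pd.DataFrame(res.conf_int, index=res.names, columns=["low", "high"])
    rows = []
    for t in terms:
        rows.append(
            stratum
            | {
                "term": t,
                "irr": float(np.exp(params[t])),
                "ci_low": float(np.exp(ci.loc[t, "low"])),
                "ci_high": float(np.exp(ci.loc[t, "high"])),
            }
        )
    return rows


def _alpha_row(res: NBFit, stratum: dict) -> dict:
    return stratum | {
        "alpha": res.alpha,
        "ci_low": float(max(0.0, res.conf_int[-1, 0])),
        "ci_high": float(res.conf_int[-1, 1]),
    }


def _drop_empty_bands(
    frame: pd.DataFrame, ref: str, events_col: str, pt_col: str, col="rx_risk_band"
) -> pd.DataFrame:
    """Bands with no person-time or no events cannot support a finite rate
    ratio (the MLE diverges); drop them, keeping the reference."""
    g = frame.groupby(col, observed=True)[[events_col, pt_col]].sum()
    dead = g[(g[events_col] <= 0) | (g[pt_col] <= 0)].index.tolist()
    dead = [b for b in dead if b != ref]
    if dead:
        logger.warning("dropping band(s) with no events or person-time: %s", dead)
        frame = frame[~frame[col].isin(dead)]
    return frame


def _strata(frame: pd.DataFrame, stratify):
    stratify = list(stratify or [])
    if not stratify:
        yield {}, frame
        return
    for labels, g in frame.groupby(stratify, observed=True):
        if not isinstance(labels, tuple):
            labels = (labels,)
        yield dict(zip(stratify, labels)), g


def fit_band_irr(
    slices_or_cells: pd.DataFrame,
    stratify=("sex",),
    adjust: str | None = "continuous",
    bands: list[str] = BAND_LABELS,
    ref: str = REFERENCE_BAND,
):
    """Band IRRs with the <=0 band as reference.

    Accepts slices (aggregated internally) or pre-aggregated cells.  Returns
    ``(irr, dispersion)``: one IRR row per stratum x band (reference rows
    carry irr exactly 1), and one NB dispersion (alpha) row per stratum.
    """
    cells = _as_cells(slices_or_cells, extra=("age_group",))
    irr_rows, disp_rows = [], []
    for stratum, sub in _strata(cells, stratify):
        sub = _drop_empty_bands(sub, ref, "events", "person_years")
        ref_events = sub.loc[sub["rx_risk_band"] == ref, "events"].sum()
        if ref_events <= 0:
            raise ValueError(
                f"reference band {ref!r} has no events in stratum {stratum}"
            )
        Xb, terms = _band_dummies(sub, bands, ref)
        X = _design([
            Xb,
            _maybe_female(sub) if "sex" not in (stratify or []) else pd.DataFrame(index=sub.index),
            _adjusters(sub, adjust),
        ])
        res = _fit_nb(sub["events"], X, sub["person_years"])
        per_band = sub.groupby("rx_risk_band", observed=True).agg(
            n_events=("events", "sum"), person_years=("person_years", "sum")
        )
        rows = _irr_rows(res, terms, stratum)
        rows.append(
            stratum
            | {"term": ref, "irr": 1.0, "ci_low": 1.0, "ci_high": 1.0}
        )
        for r in rows:
            r["reference"] = ref
            r["n_events"] = int(per_band.loc[r["term"], "n_events"])
            r["person_years"] = float(per_band.loc[r["term"], "person_years"])
        order = {b: i for i, b in enumerate(bands)}
        rows.sort(key=lambda r: order.get(r["term"], 99))
        irr_rows.extend(rows)
        disp_rows.append(_alpha_row(res, stratum))
    return pd.DataFrame(irr_rows), pd.DataFrame(disp_rows)


def _as_cells(frame: pd.DataFrame, extra=()) -> pd.DataFrame:
    if "person_time" in frame.columns:  # slices
        return aggregate(frame, extra_keys=extra)
    return frame


def fit_trend_irr(
    slices: pd.DataFrame,
    stratify=("sex",),
    adjust: str | None = "continuous",
) -> pd.DataFrame:
    """IRR per one-unit increase of the (lagged) score as a continuous
    exposure; person-years with a missing score are excluded."""
    s = slices[slices["rx_risk_value"].notna()].copy()
    s["score"] = s["rx_risk_value"].astype(float)
    rows = []
    for stratum, sub in _strata(s, stratify):
        if sub["score"].nunique() < 2:
            raise ValueError(
                f"continuous trend needs >= 2 distinct score values in {stratum}"
            )
        cells = (
            sub.groupby(
                list(stratify or []) + ["score", "birth_year", "year"]
                + (["sex"] if "sex" in sub and "sex" not in (stratify or []) else []),
                observed=True,
            )
            .agg(events=("event", "sum"), person_years=("person_time", "sum"))
            .reset_index()
        )
        X = _design([
            pd.DataFrame({"per_unit": cells["score"].to_numpy(dtype=float)}),
            _maybe_female(cells) if "sex" not in (stratify or []) else pd.DataFrame(index=cells.index),
            _adjusters(cells, adjust),
        ])
        res = _fit_nb(cells["events"], X, cells["person_years"])
        row = _irr_rows(res, ["per_unit"], stratum)[0]
        row["n_events"] = int(cells["events"].sum())
        row["person_years"] = float(cells["person_years"].sum())
        row["alpha"] = res.alpha
        rows.append(row)
    return pd.DataFrame(rows)


def test_interaction(slices: pd.DataFrame, modifier: str) -> float:
    """Likelihood-ratio test of exposure-band x modifier product terms.

    ``modifier`` is one of 'sex', 'birth_year', 'calendar_year'.
    """
    cells = _as_cells(slices)
    cells = _drop_empty_bands(cells, REFERENCE_BAND, "events", "person_years")
    Xb, terms = _band_dummies(cells, BAND_LABELS, REFERENCE_BAND)
    if modifier == "sex":
        if cells["sex"].nunique() < 2:
            raise ValueError("sex has a single level; interaction untestable")
        mod = (cells["sex"] == "female").astype(float).to_numpy()
    elif modifier in ("birth_year", "calendar_year"):
        col = "year" if modifier == "calendar_year" else "birth_year"
        v = cells[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"{modifier} has a single level; interaction untestable")
        mod = _center(v)
    else:
        raise ValueError(f"unknown modifier {modifier!r}")
    base_parts = [Xb, _maybe_female(cells), _adjusters(cells, "continuous")]
    X0 = _design(base_parts)
    inter = pd.DataFrame(
        {f"{t}:x": Xb[t].to_numpy() * mod for t in terms}, index=cells.index
    )
    X1 = _design(base_parts + [inter])
    r0 = _fit_nb(cells["events"], X0, cells["person_years"])
    r1 = _fit_nb(cells["events"], X1, cells["person_years"])
    lr = 2.0 * (r1.llf - r0.llf)
    if lr < -1e-6:
        raise ConvergenceError("interaction model fits are not nested/converged")
    return float(stats.chi2.sf(max(lr, 0.0), df=len(terms)))


def sex_contrast(
    slices: pd.DataFrame, adjust: str | None = "continuous"
) -> pd.DataFrame:
    """Women-versus-men IRRs within each exposure band x age group."""
    cells = _as_cells(slices, extra=("age_group",))
    rows = []
    for (band, grp), sub in cells.groupby(["rx_risk_band", "age_group"], observed=True):
        if sub["sex"].nunique() < 2:
            logger.warning("skipping single-sex stratum band=%s age=%s", band, grp)
            continue
        per_sex = sub.groupby("sex", observed=True)["events"].sum()
        if (per_sex <= 0).any():
            logger.warning(
                "skipping stratum band=%s age=%s: a sex has no events", band, grp
            )
            continue
        X = _design([
            pd.DataFrame({"female": (sub["sex"] == "female").astype(float).to_numpy()}, index=sub.index),
            _adjusters(sub, adjust),
        ])
        res = _fit_nb(sub["events"], X, sub["person_years"])
        row = _irr_rows(res, ["female"], {"rx_risk_band": band, "age_group": grp})[0]
        row["term"] = "women_vs_men"
        row["n_events"] = int(sub["events"].sum())
        row["person_years"] = float(sub["person_years"].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def category_irr(
    category_sets: pd.DataFrame,
    slices: pd.DataFrame,
    exposure_year: int,
    categories: list[str] | None = None,
    stratify_sex: bool = True,
) -> pd.DataFrame:
    """Per-disease-category IRRs from one exposure/outcome year pair.

    Persons at risk in ``exposure_year + 1`` enter one person-level NB model
    with all category indicators (from ``exposure_year`` fills)
    simultaneously, offset by that year's person-time and adjusted for birth
    year.  Persons in no category form the reference group of every
    category.  Empty categories are dropped with a warning.
    """
    outcome_year = exposure_year + 1
    risk = slices[slices["year"] == outcome_year]
    if len(risk) == 0:
        raise ValueError(f"no follow-up slices in outcome year {outcome_year}")
    risk = risk[["person_id", "sex", "birth_year", "person_time", "event"]].copy()
    fills = category_sets[
        (category_sets["year"] == exposure_year)
        & category_sets["category_id"].notna()
    ]
    if categories is None:
        categories = sorted(fills["category_id"].unique().tolist())
    ind = (
        fills.assign(one=1.0)
        .pivot_table(index="person_id", columns="category_id", values="one", fill_value=0.0)
        .reindex(risk["person_id"], fill_value=0.0)
        .reindex(columns=categories, fill_value=0.0)
        .reset_index(drop=True)
    )
    risk = risk.reset_index(drop=True)
    rows = []
    for stratum, sub in _strata(risk, ("sex",) if stratify_sex else ()):
        sub_ind = ind.loc[sub.index]
        # a category with no exposed persons (or none of its exposed having
        # an event) separates the likelihood; drop it
        exposed_events = {
            c: float(sub.loc[sub_ind[c] > 0, "event"].sum()) for c in categories
        }
        used = [
            c
            for c in categories
            if sub_ind[c].sum() > 0 and exposed_events[c] > 0
        ]
        dropped = sorted(set(categories) - set(used))
        if dropped:
            logger.warning("empty categories dropped in %s: %s", stratum, dropped)
        X = _design([
            sub_ind[used].astype(float),
            _maybe_female(sub) if not stratify_sex else pd.DataFrame(index=sub.index),
            _centered_col(sub, "birth_year"),
        ])
        res = _fit_nb(sub["event"], X, sub["person_time"])
        got = _irr_rows(res, used, stratum)
        for r in got:
            r["category_id"] = r.pop("term")
            r["n_exposed"] = int(sub_ind[r["category_id"]].sum())
        rows.extend(got)
    return pd.DataFrame(rows)


def _latency_band(values) -> pd.Series:
    base = band_rx_risk(values)
    return pd.Series(
        np.where(
            np.isin(base, ["16-20", "21-25", ">25"]), ">15", base
        ),
        name="rx_risk_band",
    )


def latency_analysis(
    slices: pd.DataFrame,
    scores: pd.DataFrame,
    exposure_year: int = 2007,
    lags=(1, 3, 5),
) -> pd.DataFrame:
    """Band IRRs with exposure frozen at ``exposure_year`` and outcomes 1, 3
    and 5 years later; bands above 15 are collapsed (sparse top bands).

    The lag-L risk set is the persons still under follow-up and
    fracture-free at the start of the outcome year (those fracturing or
    exiting in between contribute nothing to that lag).
    """
    max_year = int(slices["year"].max())
    rows = []
    for lag in lags:
        outcome_year = exposure_year + lag
        if outcome_year > max_year:
            raise ValueError(
                f"outcome year {outcome_year} is outside follow-up (<= {max_year})"
            )
        risk = slices[slices["year"] == outcome_year][
            ["person_id", "sex", "birth_year", "person_time", "event"]
        ].copy()
        exp = scores[scores["year"] == exposure_year][["person_id", "rx_risk"]]
        risk = risk.merge(exp, on="person_id", how="left")
        risk["rx_risk_band"] = _latency_band(risk["rx_risk"]).to_numpy()
        risk = _drop_empty_bands(risk, REFERENCE_BAND, "event", "person_time")
        Xb, terms = _band_dummies(risk, LATENCY_BANDS, REFERENCE_BAND)
        X = _design([
            Xb,
            _maybe_female(risk),
            _centered_col(risk, "birth_year"),
        ])
        res = _fit_nb(risk["event"], X, risk["person_time"])
        got = _irr_rows(res, terms, {"lag": lag})
        got.append({"lag": lag, "term": REFERENCE_BAND, "irr": 1.0, "ci_low": 1.0, "ci_high": 1.0})
        per_band = risk.groupby("rx_risk_band", observed=True).agg(
            n_events=("event", "sum"), person_years=("person_time", "sum")
        )
        for r in got:
            r["reference"] = REFERENCE_BAND
            r["n_events"] = int(per_band.loc[r["term"], "n_events"])
            r["person_years"] = float(per_band.loc[r["term"], "person_years"])
        order = {b: i for i, b in enumerate(LATENCY_BANDS)}
        got.sort(key=lambda r: order.get(r["term"], 99))
        rows.extend(got)
    return pd.DataFrame(rows)


SENSITIVITY_VARIANTS = ("reassign_young_missing", "drop_missing")


def sensitivity_variants(
    slices: pd.DataFrame, variant: str, **fit_kwargs
):
    """Missing-score sensitivity analyses.

    'reassign_young_missing': missing-score slices of persons younger than
    70 move to the reference band (presumed healthy non-users); 'drop_missing'
    excludes missing-score slices entirely.  Either way the band model is
    refitted unchanged.
    """
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {SENSITIVITY_VARIANTS}"
        )
    s = slices.copy()
    if variant == "reassign_young_missing":
        mask = (s["rx_risk_band"] == "missing") & (s["attained_age"] < 70)
        s.loc[mask, "rx_risk_band"] = REFERENCE_BAND
    else:
        s = s[s["rx_risk_band"] != "missing"]
    return fit_band_irr(s, **fit_kwargs)
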