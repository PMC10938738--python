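"""Negative-binomial IRR analyses: closed-form checks, Poisson limit,
recovery of generating parameters, and the derived analyses."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import rxrisk as rx
from rxrisk.models import (
    category_irr,
    fit_band_irr,
    fit_trend_irr,
    latency_analysis,
    sensitivity_variants,
    sex_contrast,
    test_interaction as interaction_test,
)


def _cells(events, person_years, bands, sex="female", by=1940, year=2010):
    n = len(events)
    return pd.DataFrame(
        {
            "sex": [sex] * n,
            "birth_year": [by] * n,
            "year": [year] * n,
            "rx_risk_band": bands,
            "age_group": ["66-80"] * n,
            "events": events,
            "person_years": person_years,
        }
    )


def test_two_cell_crude_irr_is_four():
    cells = _cells([10, 40], [100.0, 100.0], ["<=0", "1-5"])
    irr, _ = fit_band_irr(cells, stratify=(), adjust=None)
    row = irr[irr["term"] == "1-5"].iloc[0]
    assert row["irr"] == pytest.approx(4.0, rel=1e-6)


def test_reference_band_irr_is_exactly_one():
    cells = _cells([10, 40], [100.0, 100.0], ["<=0", "1-5"])
    irr, _ = fit_band_irr(cells, stratify=(), adjust=None)
    ref = irr[irr["term"] == "<=0"].iloc[0]
    assert ref["irr"] == 1.0
    assert ref["ci_low"] == 1.0 and ref["ci_high"] == 1.0


def test_scale_invariance():
    a = _cells([10, 40], [100.0, 100.0], ["<=0", "1-5"])
    b = _cells([20, 80], [200.0, 200.0], ["<=0", "1-5"])
    ia, _ = fit_band_irr(a, stratify=(), adjust=None)
    ib, _ = fit_band_irr(b, stratify=(), adjust=None)
    va = ia.loc[ia["term"] == "1-5", "irr"].iloc[0]
    vb = ib.loc[ib["term"] == "1-5", "irr"].iloc[0]
    assert va == pytest.approx(vb, rel=1e-6)


def _poisson_cells(seed=0, n=400):
    """Cells simulated from an exactly Poisson band model, with counts large
    enough that the dispersion parameter is sharply identified."""
    rng = np.random.default_rng(seed)
    bands = rng.choice(["<=0", "1-5", "6-10"], size=n, p=[0.5, 0.3, 0.2])
    log_irr = {"<=0": 0.0, "1-5": 0.35, "6-10": 0.8}
    py = rng.uniform(2000, 20_000, size=n)
    mu = py * 0.004 * np.exp([log_irr[b] for b in bands])
    events = rng.poisson(mu)
    return _cells(events, py, bands), log_irr


def test_poisson_limit_alpha_near_zero_and_irr_match():
    """On equidispersed cells the NB alpha estimate is ~0 and NB IRRs agree
    with an independent Poisson fit to within 0.1% relative."""
    cells, _ = _poisson_cells()
    irr, disp = fit_band_irr(cells, stratify=(), adjust=None)
    assert disp.iloc[0]["alpha"] < 5e-3

    X = pd.DataFrame(
        {
            "1-5": (cells["rx_risk_band"] == "1-5").astype(float),
            "6-10": (cells["rx_risk_band"] == "6-10").astype(float),
            "const": 1.0,
        }
    )
    pois = sm.Poisson(
        cells["events"].to_numpy(float), X, exposure=cells["person_years"].to_numpy()
    ).fit(disp=0)
    for term in ("1-5", "6-10"):
        nb_irr = irr.loc[irr["term"] == term, "irr"].iloc[0]
        po_irr = float(np.exp(pois.params[term]))
        assert nb_irr == pytest.approx(po_irr, rel=1e-3)


def test_band_model_aggregation_invariance(slices):
    """Fitting on slices and on pre-aggregated cells gives identical
    estimates (offset-model equivalence)."""
    irr_s, _ = fit_band_irr(slices, stratify=("sex",))
    irr_c, _ = fit_band_irr(rx.aggregate(slices), stratify=("sex",))
    m = irr_s.merge(irr_c, on=["sex", "term"], suffixes=("_s", "_c"))
    assert len(m) == len(irr_s)
    assert np.allclose(m["irr_s"], m["irr_c"], rtol=1e-5)


def test_trend_requires_two_scores():
    s = pd.DataFrame(
        {
            "person_id": [1, 2],
            "year": [2010, 2010],
            "sex": ["female", "female"],
            "birth_year": [1940, 1940],
            "attained_age": [70, 70],
            "age_group": ["66-80", "66-80"],
            "rx_risk_value": pd.array([3, 3], dtype="Int64"),
            "rx_risk_band": ["1-5", "1-5"],
            "person_time": [1.0, 1.0],
            "event": [0, 1],
        }
    )
    with pytest.raises(ValueError, match="distinct score"):
        fit_trend_irr(s, stratify=())


def test_trend_scale_invariance(medium_slices_bundle):
    slices = medium_slices_bundle["slices"]
    doubled = slices.copy()
    doubled["person_time"] *= 2
    # doubling person-time at fixed events halves rates uniformly: the
    # per-unit IRR is unchanged
    a = fit_trend_irr(slices, stratify=())
    b = fit_trend_irr(doubled, stratify=())
    assert a.iloc[0]["irr"] == pytest.approx(b.iloc[0]["irr"], rel=1e-4)


def test_trend_recovers_generating_rate_ratio(medium_slices_bundle):
    cfg = medium_slices_bundle["config"]
    truth = float(np.exp(cfg.fracture_model.log_rr_per_unit))
    res = fit_trend_irr(medium_slices_bundle["slices"], stratify=())
    row = res.iloc[0]
    assert row["ci_low"] <= truth <= row["ci_high"]


def test_band_irrs_monotone_at_scale(medium_slices_bundle):
    """The generator's hazard is log-linear in the score, so estimated band
    IRRs (pooled sexes) increase across ordered bands."""
    irr, _ = fit_band_irr(medium_slices_bundle["slices"], stratify=())
    ordered = ["<=0", "1-5", "6-10", "11-15"]
    vals = [irr.loc[irr["term"] == b, "irr"].iloc[0] for b in ordered]
    assert vals == sorted(vals)


def test_interaction_single_level_errors(slices):
    s = slices[slices["sex"] == "female"]
    with pytest.raises(ValueError, match="single level"):
        interaction_test(s, "sex")


def test_interaction_unknown_modifier(slices):
    with pytest.raises(ValueError, match="modifier"):
        interaction_test(slices, "shoe_size")


def test_interaction_detects_sex_specific_effect():
    """Band effect doubled in men: the sex interaction p-value is tiny."""
    rng = np.random.default_rng(4)
    rows = []
    for sex, extra in (("female", 1.0), ("male", 2.0)):
        for band, log_rr in (("<=0", 0.0), ("1-5", 0.4), ("6-10", 0.9)):
            for by in range(1930, 1950, 2):
                py = 4000.0
                mu = py * 0.005 * np.exp(extra * log_rr)
                rows.append(
                    {
                        "sex": sex,
                        "birth_year": by,
                        "year": 2010,
                        "rx_risk_band": band,
                        "age_group": "66-80",
                        "events": rng.poisson(mu),
                        "person_years": py,
                    }
                )
    p = interaction_test(pd.DataFrame(rows), "sex")
    assert p < 0.001


def test_sex_contrast_recovers_female_rate_ratio(medium_slices_bundle):
    cfg = medium_slices_bundle["config"]
    truth = float(np.exp(cfg.fracture_model.female_log_rr))
    out = sex_contrast(medium_slices_bundle["slices"])
    # pool evidence over the well-populated strata
    big = out[out["n_events"] >= 50]
    assert len(big) > 0
    log_est = np.average(np.log(big["irr"]))
    assert log_est == pytest.approx(np.log(truth), abs=0.35)
    covered = (big["ci_low"] <= truth) & (truth <= big["ci_high"])
    assert covered.mean() >= 0.5


def test_sex_contrast_skips_single_sex_stratum(caplog):
    cells = _cells([10, 40], [100.0, 100.0], ["<=0", "<=0"], sex="female")
    with caplog.at_level("WARNING", logger="rxrisk.models"):
        out = sex_contrast(cells)
    assert len(out) == 0


def test_category_irr_reference_membership(medium_slices_bundle):
    """Every person at risk missing a category contributes to that
    category's reference group: exposed counts + reference counts = risk
    set, for every category."""
    sets = medium_slices_bundle["category_sets"]
    slices = medium_slices_bundle["slices"]
    out = category_irr(sets, slices, exposure_year=2011, stratify_sex=False)
    n_risk = (slices["year"] == 2012).sum()
    assert (out["n_exposed"] < n_risk).all()
    assert (out["irr"] > 0).all()
    assert (out["ci_low"] <= out["irr"]).all()
    assert (out["irr"] <= out["ci_high"]).all()


def test_category_irr_detects_raised_hazard():
    """One category with a true fracture rate ratio, others null: its IRR
    estimate is elevated and most null CIs cover 1."""
    rng = np.random.default_rng(9)
    n = 40_000
    pid = np.arange(n)
    exposed = {c: rng.random(n) < 0.2 for c in ("a", "b", "c")}
    log_rr = {"a": np.log(1.5), "b": 0.0, "c": 0.0}
    mu = 0.01 * np.exp(sum(log_rr[c] * exposed[c] for c in exposed))
    event = rng.random(n) < mu
    sets = pd.concat(
        [
            pd.DataFrame(
                {"person_id": pid[exposed[c]], "year": 2011, "category_id": c}
            )
            for c in exposed
        ]
    )
    slices = pd.DataFrame(
        {
            "person_id": pid,
            "year": 2012,
            "sex": "female",
            "birth_year": 1940,
            "attained_age": 72,
            "age_group": "66-80",
            "rx_risk_value": pd.array([0] * n, dtype="Int64"),
            "rx_risk_band": "<=0",
            "person_time": 1.0,
            "event": event.astype(int),
        }
    )
    out = category_irr(sets, slices, exposure_year=2011, stratify_sex=False)
    a = out[out["category_id"] == "a"].iloc[0]
    assert a["ci_low"] <= 1.5 <= a["ci_high"]
    assert a["irr"] > 1.2
    for c in ("b", "c"):
        row = out[out["category_id"] == c].iloc[0]
        assert row["ci_low"] <= 1.0 <= row["ci_high"]


def test_latency_band_collapses_above_15():
    from rxrisk.models import _latency_band

    vals = pd.array([16, 20, 26, 15, 0, pd.NA], dtype="Int64")
    got = list(_latency_band(vals))
    assert got == [">15", ">15", ">15", "11-15", "<=0", "missing"]


def test_latency_outcome_outside_follow_up(slices, scores):
    with pytest.raises(ValueError, match="outside follow-up"):
        latency_analysis(slices, scores, exposure_year=2016, lags=(5,))


def test_sensitivity_variant_identities(medium_slices_bundle):
    """With no missing-score slices both variants equal the main fit
    exactly; variant B person-years equal main minus missing."""
    slices = medium_slices_bundle["slices"]
    no_missing = slices[slices["rx_risk_band"] != "missing"]
    main, _ = fit_band_irr(no_missing, stratify=("sex",))
    va, _ = sensitivity_variants(no_missing, "reassign_young_missing", stratify=("sex",))
    vb, _ = sensitivity_variants(no_missing, "drop_missing", stratify=("sex",))
    pd.testing.assert_frame_equal(main, va)
    pd.testing.assert_frame_equal(main, vb)

    # subtraction identity on the fitted tables: variant B loses exactly the
    # missing person-years (bands dropped as empty are the same either way)
    main_full, _ = fit_band_irr(slices, stratify=("sex",))
    vb_full, _ = sensitivity_variants(slices, "drop_missing", stratify=("sex",))
    main_nonmissing_py = main_full.loc[
        main_full["term"] != "missing", "person_years"
    ].sum()
    assert vb_full["person_years"].sum() == pytest.approx(
        main_nonmissing_py, rel=1e-9
    )
    # and the missing rows in the main fit carry exactly the slices' missing
    # person-time
    missing_py = slices.loc[slices["rx_risk_band"] == "missing", "person_time"].sum()
    assert main_full.loc[
        main_full["term"] == "missing", "person_years"
    ].sum() == pytest.approx(missing_py, rel=1e-9)


def test_sensitivity_reassignment_age_boundary():
    """A 69-year-old missing-score slice moves to the reference band under
    variant A; a 70-year-old stays missing — visible in the fitted model's
    per-band person-years."""
    rng = np.random.default_rng(2)
    rows = []
    pid = 0
    for band, value, age in [("<=0", 0, 72)] * 120 + [("1-5", 3, 72)] * 120:
        pid += 1
        rows.append(
            {
                "person_id": pid,
                "year": 2010,
                "sex": "female",
                "birth_year": 2010 - age,
                "attained_age": age,
                "age_group": rx.age_group(age),
                "rx_risk_value": value,
                "rx_risk_band": band,
                "person_time": 1.0,
                "event": int(rng.random() < (0.10 if band == "<=0" else 0.25)),
            }
        )
    for age in (69, 70):
        pid += 1
        rows.append(
            {
                "person_id": pid,
                "year": 2010,
                "sex": "female",
                "birth_year": 2010 - age,
                "attained_age": age,
                "age_group": rx.age_group(age),
                "rx_risk_value": pd.NA,
                "rx_risk_band": "missing",
                "person_time": 1.0,
                "event": 1,  # missing band keeps events so it stays estimable
            }
        )
    s = pd.DataFrame(rows)
    s["rx_risk_value"] = s["rx_risk_value"].astype("Int64")
    irr, _ = sensitivity_variants(
        s, "reassign_young_missing", stratify=(), adjust=None
    )
    ref_py = irr.loc[irr["term"] == "<=0", "person_years"].iloc[0]
    missing_py = irr.loc[irr["term"] == "missing", "person_years"].iloc[0]
    assert ref_py == pytest.approx(121.0)  # the 69-year-old joined <=0
    assert missing_py == pytest.approx(1.0)  # the 70-year-old stayed


def test_sensitivity_unknown_variant(slices):
    with pytest.raises(ValueError, match="variant"):
        sensitivity_variants(slices, "bogus")


def test_reference_band_must_be_present():
    cells = _cells([10, 40], [100.0, 100.0], ["1-5", "6-10"])
    with pytest.raises(ValueError, match="reference band"):
        fit_band_irr(cells, stratify=(), adjust=None)


def test_reference_band_needs_events():
    cells = _cells([0, 40], [100.0, 100.0], ["<=0", "1-5"])
    with pytest.raises(ValueError, match="no events"):
        fit_band_irr(cells, stratify=(), adjust=None)
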