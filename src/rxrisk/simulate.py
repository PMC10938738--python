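"""Synthetic prescription/fracture registry generator.

Generates three linked tables (persons, dispensings, fractures) with the
statistical structure the downstream analysis assumes:

* a per-person latent frailty inducing within-person correlation of
  disease-category fills across calendar years;
* yearly category fills that are logit-linear in frailty and age, with a
  Markov persistence term so a person's medication profile drifts slowly;
* death in year t+1 Bernoulli with logit-linear dependence on the year-t
  category indicators (the configured true mortality odds ratios), sex and
  age — so a yearly logistic calibration can recover the generating ORs;
* a first-fracture process with piecewise-constant yearly hazard,
  log-linear in the *previous* year's true severity score, attained age and
  sex — so the lagged-exposure cohort analysis can recover the generating
  rate ratios;
* month-resolution death/emigration/fracture dates, a 1994-2005 fracture
  history for washout testing, and a configurable share of person-years with
  no index fill (default 14%).

Everything is drawn from a single seeded generator: identical config and
seed give identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .index import map_or_to_weight

__all__ = ["simulate_population", "true_weights", "NONINDEX_ATC"]

# a syntactically valid ATC code outside the packaged index mapping
NONINDEX_ATC = "V06DX01"


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def true_weights(config: SimulationConfig) -> pd.Series:
    """Severity weights implied by the configured true mortality ORs.

    The true OR is passed through the published OR-to-weight step function
    with p-value 0 (1 for a null OR of exactly 1, which carries no signal).
    """
    out = {}
    for spec in config.category_specs:
        p = 1.0 if spec.mortality_or == 1.0 else 0.0
        out[spec.category_id] = map_or_to_weight(spec.mortality_or, p)
    return pd.Series(out, name="true_weight")


def simulate_population(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate linked persons / dispensings / fractures tables.

    Returns
    -------
    persons : DataFrame
        person_id, sex ('female'/'male'), birth_year, death_year,
        death_month, emig_year, emig_month (nullable integers).
    dispensings : DataFrame
        person_id, atc, year, month.
    fractures : DataFrame
        person_id, year, month, is_history.  At most one non-history
        (follow-up) fracture per person; history fractures fall in the
        washout window.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_persons
    specs = config.category_specs
    K = len(specs)
    fm = config.fracture_model

    female = rng.random(n) < config.female_fraction
    age0 = rng.integers(config.age_range[0], config.age_range[1] + 1, size=n)
    birth_year = config.start_year - age0
    frailty = rng.normal(0.0, config.frailty_sd, size=n)

    base_logit = np.array([_logit(s.base_fill_prob) for s in specs])
    loading = np.array([s.frailty_loading for s in specs])
    log_or = np.array([np.log(s.mortality_or) for s in specs])
    w_true = true_weights(config).to_numpy(dtype=float)
    atc_codes = np.array([s.atc_code for s in specs])

    mort_base = _logit(config.baseline_mortality)

    death_year = np.full(n, -1)
    death_month = np.zeros(n, dtype=int)
    emig_year = np.full(n, -1)
    emig_month = np.zeros(n, dtype=int)
    fractured = np.zeros(n, dtype=bool)
    institution = np.zeros(n, dtype=bool)
    latent_fill = np.zeros((n, K), dtype=bool)
    seen_fill_year = False
    prev_score = np.zeros(n)

    pid = np.arange(1, n + 1)
    disp_chunks: list[pd.DataFrame] = []
    frac_chunks: list[pd.DataFrame] = []

    # washout-window fracture history
    hist = rng.random(n) < config.washout_history_rate
    if hist.any():
        frac_chunks.append(
            pd.DataFrame(
                {
                    "person_id": pid[hist],
                    "year": rng.integers(1994, 2006, size=int(hist.sum())),
                    "month": rng.integers(1, 13, size=int(hist.sum())),
                    "is_history": True,
                }
            )
        )

    for year in range(config.start_year, config.fracture_end_year + 1):
        age = year - birth_year
        in_play = ((death_year == -1) | (death_year >= year)) & (
            (emig_year == -1) | (emig_year >= year)
        )
        exit_month = np.full(n, 12)
        exit_month = np.where(death_year == year, death_month, exit_month)
        exit_month = np.where(
            emig_year == year, np.minimum(exit_month, emig_month), exit_month
        )
        exit_month = np.maximum(exit_month, 1)

        fill = np.zeros((n, K), dtype=bool)
        if year <= config.end_year:
            nonfiller = rng.random(n) < config.nonfiller_rate
            fresh_logit = (
                base_logit[None, :]
                + loading[None, :] * frailty[:, None]
                + config.fill_age_slope * (age[:, None] - 70.0)
            )
            fresh = rng.random((n, K)) < _sigmoid(fresh_logit)
            if seen_fill_year:
                keep = rng.random((n, K)) < config.fill_persistence
                fill = np.where(keep, latent_fill, fresh)
            else:
                fill = fresh
            filler = in_play & ~nonfiller
            fill &= filler[:, None]
            # a filler person-year has >= 1 index fill by definition: empty
            # draws get one category, sampled by the person's fill odds, so
            # the no-index-fill share equals nonfiller_rate exactly
            empty = filler & ~fill.any(axis=1)
            if empty.any():
                probs = _sigmoid(fresh_logit[empty])
                probs = probs / probs.sum(axis=1, keepdims=True)
                cum = np.cumsum(probs, axis=1)
                draw = rng.random(int(empty.sum()))[:, None]
                chosen = (draw > cum).sum(axis=1)
                fill[np.nonzero(empty)[0], chosen] = True
            latent_fill = np.where(filler[:, None], fill, latent_fill)
            seen_fill_year = True

            # institutionalization: fills continue latently but are not
            # recorded (absorbing state, default off)
            if config.institutionalization_rate > 0:
                newly = in_play & ~institution & (
                    rng.random(n) < config.institutionalization_rate
                )
                institution |= newly

            recordable = fill & ~institution[:, None]
            ppos, cpos = np.nonzero(recordable)
            if ppos.size:
                counts = 1 + rng.poisson(0.8, size=ppos.size)
                rep_p = np.repeat(ppos, counts)
                rep_c = np.repeat(cpos, counts)
                months = 1 + (
                    rng.random(rep_p.size) * exit_month[rep_p]
                ).astype(int)
                disp_chunks.append(
                    pd.DataFrame(
                        {
                            "person_id": pid[rep_p],
                            "atc": atc_codes[rep_c],
                            "year": year,
                            "month": np.minimum(months, exit_month[rep_p]),
                        }
                    )
                )

            # non-index fills: half of the no-index-fill person-years, plus a
            # share of ordinary years, fill something outside the index
            noise = in_play & ~institution & (
                (nonfiller & (rng.random(n) < 0.5))
                | (~nonfiller & (rng.random(n) < config.nonindex_fill_rate))
            )
            if noise.any():
                npos = np.nonzero(noise)[0]
                disp_chunks.append(
                    pd.DataFrame(
                        {
                            "person_id": pid[npos],
                            "atc": NONINDEX_ATC,
                            "year": year,
                            "month": 1
                            + (rng.random(npos.size) * exit_month[npos]).astype(int),
                        }
                    )
                )

        # first-fracture process, lagged true score as the hazard covariate
        if year > config.start_year:
            at_risk = in_play & ~fractured
            with np.errstate(over="ignore"):
                log_rate = (
                    fm.base_log_rate
                    + fm.log_rr_per_unit * prev_score
                    + fm.log_rr_per_year_age * (age - fm.age_ref)
                    + fm.female_log_rr * female
                )
                rate = np.exp(log_rate)
            p_frac = 1.0 - np.exp(-rate * exit_month / 12.0)
            hit = at_risk & (rng.random(n) < p_frac)
            if hit.any():
                hpos = np.nonzero(hit)[0]
                frac_chunks.append(
                    pd.DataFrame(
                        {
                            "person_id": pid[hpos],
                            "year": year,
                            "month": 1
                            + (rng.random(hpos.size) * exit_month[hpos]).astype(int),
                            "is_history": False,
                        }
                    )
                )
                fractured |= hit

        if year <= config.end_year:
            # deaths and emigrations for year+1, driven by this year's fills
            eligible = (death_year == -1) & (emig_year == -1)
            mort_logit = (
                mort_base
                + config.mortality_age_slope * (age + 1 - 70.0)
                + config.mortality_female_log_or * female
                + fill.astype(float) @ log_or
            )
            dies = eligible & (rng.random(n) < _sigmoid(mort_logit))
            if dies.any():
                death_year[dies] = year + 1
                death_month[dies] = rng.integers(1, 13, size=int(dies.sum()))
            emigrates = eligible & ~dies & (rng.random(n) < config.emigration_rate)
            if emigrates.any():
                emig_year[emigrates] = year + 1
                emig_month[emigrates] = rng.integers(1, 13, size=int(emigrates.sum()))

            prev_score = fill.astype(float) @ w_true

    persons = pd.DataFrame(
        {
            "person_id": pid,
            "sex": np.where(female, "female", "male"),
            "birth_year": birth_year,
            "death_year": pd.array(
                np.where(death_year == -1, pd.NA, death_year), dtype="Int64"
            ),
            "death_month": pd.array(
                np.where(death_year == -1, pd.NA, death_month), dtype="Int64"
            ),
            "emig_year": pd.array(
                np.where(emig_year == -1, pd.NA, emig_year), dtype="Int64"
            ),
            "emig_month": pd.array(
                np.where(emig_year == -1, pd.NA, emig_month), dtype="Int64"
            ),
        }
    )
    if disp_chunks:
        dispensings = pd.concat(disp_chunks, ignore_index=True)
    else:
        dispensings = pd.DataFrame(
            columns=["person_id", "atc", "year", "month"]
        ).astype({"person_id": int, "atc": str, "year": int, "month": int})
    if frac_chunks:
        fractures = pd.concat(frac_chunks, ignore_index=True)
    else:
        fractures = pd.DataFrame(
            columns=["person_id", "year", "month", "is_history"]
        ).astype({"person_id": int, "year": int, "month": int, "is_history": bool})
    return persons, dispensings, fractures
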