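"""Summary statistics and regression models for bout counts and durations.

The study design is a three-period crossover (each subject receives every
treatment), analysed over three hourly time bins after injection.  Bout
counts per subject x treatment x state x hour are modelled with a log-link
negative binomial regression (treatment and hour as unordered categorical
fixed effects, subject as a fixed blocking effect); exponentiated treatment
coefficients are the multiplicative bout-frequency ratios versus vehicle.
Bout durations are heavily right-skewed and are modelled on the log scale
with a treatment x hour interaction, compared to the additive model by a
residual-sum-of-squares F test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices

from .bouts import OUTSIDE, REMS_CUTOFF_EPOCHS, reclassify_rems, segment_bouts
from .hypnogram import RAW_STATES, SPLIT_STATES, Hypnogram


def percent_time(
    h: Hypnogram,
    window_epochs: int = 2700,
    rems_split: bool = False,
) -> dict[str, float]:
    """Percent of the analysis window spent in each vigilance state.

    The window is ``[treatment_epoch, treatment_epoch + window_epochs)``.
    With ``rems_split`` the REM epochs are attributed to REMS_S/REMS_L
    according to the duration class of the bout they belong to.  The
    returned percentages cover every state label (zeros included) and sum
    to 100.
    """
    start = h.treatment_epoch
    stop = start + window_epochs
    if window_epochs <= 0:
        raise ValueError("window_epochs must be positive")
    if stop > h.n_epochs:
        raise ValueError(
            f"window [{start}, {stop}) exceeds recording of {h.n_epochs} epochs"
        )
    if rems_split and "REMS" in set(h.states):
        labels: list[str] = []
        for b in reclassify_rems(segment_bouts(h)):
            labels.extend([b.state] * b.n_epochs)
        window = labels[start:stop]
        keys = SPLIT_STATES
    else:
        window = list(h.states[start:stop])
        present = set(h.states)
        keys = SPLIT_STATES if present & {"REMS_S", "REMS_L"} else RAW_STATES
    counts = pd.Series(window).value_counts()
    return {s: 100.0 * counts.get(s, 0) / window_epochs for s in keys}


def count_bouts(
    table: pd.DataFrame,
    states: Sequence[str] = SPLIT_STATES,
    n_bins: int = 3,
) -> pd.DataFrame:
    """Zero-filled bout counts by subject x treatment x state x bin.

    ``table`` is a long bout table (see :func:`sleepbouts.bouts.bout_table`);
    bouts whose onset falls outside the analysis window are dropped.  Every
    (subject, treatment) pair present in the table gets a row for every
    state x bin combination, with count 0 where no bout occurred.
    """
    inside = table[table["bin"] != OUTSIDE].copy()
    inside["bin"] = inside["bin"].astype(int)
    pairs = table[["subject_id", "treatment"]].drop_duplicates()
    full = (
        pairs.merge(pd.DataFrame({"state": list(states)}), how="cross")
        .merge(pd.DataFrame({"bin": range(n_bins)}), how="cross")
    )
    counts = (
        inside.groupby(["subject_id", "treatment", "state", "bin"])
        .size()
        .rename("count")
        .reset_index()
    )
    out = full.merge(
        counts, on=["subject_id", "treatment", "state", "bin"], how="left"
    )
    out["count"] = out["count"].fillna(0).astype(int)
    return out


@dataclass(frozen=True)
class FrequencyRatioEstimate:
    """Multiplicative bout-frequency ratio of one dose versus vehicle."""

    state: str
    dose: str
    ratio: float
    ci_low: float
    ci_high: float
    n_obs: int
    estimable: bool = True
    model: str = "negative binomial"


def _dose_term(dose: str, reference: str) -> str:
    return f"C(treatment, Treatment(reference='{reference}'))[T.{dose}]"


def estimate_frequency_ratios(
    table: pd.DataFrame,
    state: str,
    reference: str = "VEH",
    alpha: float = 0.05,
) -> list[FrequencyRatioEstimate]:
    """Fit the count model for one state and return per-dose ratios vs vehicle.

    The model is a log-link negative binomial regression of bout counts on
    treatment, time bin (both unordered categorical) and subject (fixed
    blocking effect), with the NB dispersion estimated by maximum
    likelihood.  When the dispersion estimate pins at zero the fit falls
    back to Poisson with a warning.  A dose whose counts are all zero sits
    on the boundary of the parameter space and is flagged not estimable
    instead of fitted.
    """
    sub = table[table["state"] == state].copy()
    if sub.empty:
        raise ValueError(f"no rows for state {state!r}")
    treatments = list(dict.fromkeys(sub["treatment"]))
    if reference not in treatments:
        raise ValueError(f"reference level {reference!r} not in table")
    if len(treatments) < 2:
        raise ValueError("need at least two treatment levels")
    if sub["count"].sum() == 0:
        raise ValueError(f"all counts are zero for state {state!r}")

    totals = sub.groupby("treatment")["count"].sum()
    doses = [t for t in treatments if t != reference]
    dead = {d for d in doses if totals.get(d, 0) == 0}
    if totals.get(reference, 0) == 0:
        # ratios vs an all-zero vehicle are on the boundary for every dose
        dead = set(doses)

    results: list[FrequencyRatioEstimate] = []
    fit_doses = [d for d in doses if d not in dead]
    if fit_doses:
        data = sub[~sub["treatment"].isin(dead)]
        formula = (
            f"count ~ C(treatment, Treatment(reference='{reference}'))"
            " + C(bin) + C(subject_id)"
        )
        res, model_name = _fit_count_model(formula, data)
        ci = res.conf_int(alpha=alpha)
        for dose in fit_doses:
            term = _dose_term(dose, reference)
            results.append(
                FrequencyRatioEstimate(
                    state=state,
                    dose=dose,
                    ratio=float(np.exp(res.params[term])),
                    ci_low=float(np.exp(ci.loc[term, 0])),
                    ci_high=float(np.exp(ci.loc[term, 1])),
                    n_obs=int(len(data)),
                    estimable=True,
                    model=model_name,
                )
            )
    for dose in doses:
        if dose in dead:
            results.append(
                FrequencyRatioEstimate(
                    state=state, dose=dose, ratio=float("nan"),
                    ci_low=float("nan"), ci_high=float("nan"),
                    n_obs=int((sub["treatment"] == dose).sum()),
                    estimable=False, model="none",
                )
            )
    results.sort(key=lambda r: doses.index(r.dose))
    return results


def _fit_count_model(formula: str, data: pd.DataFrame):
    """NB2 fit with ML dispersion; BFGS retry; Poisson fallback at alpha ~ 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = smf.negativebinomial(formula, data).fit(disp=0, maxiter=200)
            converged = res.mle_retvals.get("converged", False)
        except Exception:
            res, converged = None, False
        if res is None or not converged or not np.isfinite(res.params).all():
            try:
                res = smf.negativebinomial(formula, data).fit(
                    disp=0, method="bfgs", maxiter=500
                )
                converged = res.mle_retvals.get("converged", False)
            except Exception:
                res, converged = None, False
    if (
        res is not None
        and converged
        and np.isfinite(res.params).all()
        and res.params.get("alpha", 1.0) > 1e-6
        and np.isfinite(res.bse.drop(labels=["alpha"], errors="ignore")).all()
    ):
        return res, "negative binomial"
    warnings.warn(
        "negative binomial dispersion pinned at zero or fit failed; "
        "falling back to Poisson",
        RuntimeWarning,
        stacklevel=3,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = smf.poisson(formula, data).fit(disp=0, maxiter=200)
    return res, "poisson"


@dataclass(frozen=True)
class DurationModelFit:
    """Log-duration linear model for one state: cell means and interaction test.

    ``cells`` has one row per (treatment, bin) with the model-predicted mean
    log duration, its 95% CI (back-transform with ``exp`` for seconds) and
    the number of observed bouts; cells with no bouts are absent.  The
    interaction F statistic compares the treatment x bin model against the
    additive one by residual mean squares.
    """

    state: str
    cells: pd.DataFrame
    f_stat: float
    df_num: int
    df_den: int
    p_value: float


def fit_duration_model(
    table: pd.DataFrame,
    state: str,
    alpha: float = 0.05,
) -> DurationModelFit:
    """Fit log(duration) ~ treatment * bin + subject for one state.

    ``table`` is a long bout table; bouts outside the analysis window are
    dropped.  Predicted cell means average the subject blocking effect over
    the subjects in the study so that cells are comparable across
    treatments.
    """
    sub = table[(table["state"] == state) & (table["bin"] != OUTSIDE)].copy()
    if sub.empty:
        raise ValueError(f"no in-window bouts for state {state!r}")
    sub["bin"] = sub["bin"].astype(int)
    sub["log_duration"] = np.log(sub["duration_s"].astype(float))

    full_f = "log_duration ~ C(treatment) * C(bin) + C(subject_id)"
    red_f = "log_duration ~ C(treatment) + C(bin) + C(subject_id)"
    full = smf.ols(full_f, sub).fit()
    reduced = smf.ols(red_f, sub).fit()

    df_num = int(reduced.df_resid - full.df_resid)
    df_den = int(full.df_resid)
    rss_f, rss_r = float(full.ssr), float(reduced.ssr)
    if df_num <= 0 or df_den <= 0:
        f_stat, p_value = float("nan"), float("nan")
    elif rss_f <= 1e-12 and (rss_r - rss_f) <= 1e-12:
        # degenerate constant data: no residual variance anywhere
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
        p_value = float(scipy.stats.f.sf(f_stat, df_num, df_den))

    design_info = full.model.data.design_info
    subjects = sorted(sub["subject_id"].unique())
    tcrit = scipy.stats.t.ppf(1 - alpha / 2, df_den) if df_den > 0 else np.nan
    cov = np.asarray(full.cov_params())
    params = np.asarray(full.params)
    rows = []
    for (treatment, b), grp in sub.groupby(["treatment", "bin"]):
        frame = pd.DataFrame(
            {"treatment": treatment, "bin": b, "subject_id": subjects}
        )
        (X,) = build_design_matrices([design_info], frame)
        c = np.asarray(X).mean(axis=0)
        mean = float(c @ params)
        se = float(np.sqrt(c @ cov @ c))
        rows.append(
            {
                "treatment": treatment,
                "bin": int(b),
                "mean_log": mean,
                "ci_low": mean - tcrit * se,
                "ci_high": mean + tcrit * se,
                "n_obs": int(len(grp)),
            }
        )
    cells = pd.DataFrame(rows).sort_values(["treatment", "bin"]).reset_index(
        drop=True
    )
    return DurationModelFit(
        state=state, cells=cells, f_stat=float(f_stat),
        df_num=df_num, df_den=df_den, p_value=float(p_value),
    )


def pk_decline_percent(half_life_h: float, duration_h: float) -> float:
    """Percent decline of drug concentration over ``duration_h`` hours.

    One-compartment first-order elimination: the fraction remaining after
    time t with half-life T is 2**(-t/T), so the relative difference between
    the initial maximum and the minimum at the end of the observation
    period is 100 * (1 - 2**(-t/T)).
    """
    if half_life_h <= 0 or duration_h < 0:
        raise ValueError("half_life_h must be > 0 and duration_h >= 0")
    return 100.0 * (1.0 - 2.0 ** (-duration_h / half_life_h))
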