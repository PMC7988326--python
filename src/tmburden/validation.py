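"""Carrier units against immune-checkpoint-inhibitor outcomes.

Progression-free survival is modeled with a Cox proportional-hazards fit of
carrier status (Efron tie handling); hazard ratio < 1 means carriers
progress later. RECIST response (PD < SD < PR < CR) is modeled with a
proportional-odds ordinal logistic fit; odds > 1 means carriers are shifted
toward better response. Both report single-predictor fits by default, with a
covariate hook. Survival p-values are reported both as the Cox Wald p and
the log-rank p.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .records import OutcomeRecord, Recist, outcomes_to_frame

logger = logging.getLogger(__name__)


@dataclass
class SurvivalResult:
    label: str
    hazard_ratio: float
    p: float  # Cox Wald p (accompanies the HR)
    p_logrank: float
    n_carriers: int
    n_total: int


@dataclass
class ResponseResult:
    label: str
    odds: float
    p: float  # likelihood-ratio p
    separation: bool = False


def _outcome_frame(outcomes) -> pd.DataFrame:
    if isinstance(outcomes, pd.DataFrame):
        return outcomes.reset_index(drop=True)
    return outcomes_to_frame(list(outcomes))


def pfs_test(outcomes, carrier, covariates: pd.DataFrame | None = None,
             label: str = "") -> SurvivalResult:
    """Cox proportional-hazards test of progression-free survival on carrier status."""
    df = _outcome_frame(outcomes)
    carrier = np.asarray(carrier, dtype=bool)
    if len(carrier) != len(df):
        raise ValueError("carrier vector length does not match outcomes")
    if carrier.all() or not carrier.any():
        raise ValueError("carrier vector is constant")
    events = df["pfs_event"].astype(bool).to_numpy()
    if events.sum() == 0:
        raise ValueError("no progression events observed")
    if events[carrier].sum() == 0 or events[~carrier].sum() == 0:
        raise ValueError("each carrier group needs at least one event")
    data = pd.DataFrame({
        "pfs_time": df["pfs_time"].astype(float),
        "pfs_event": events.astype(int),
        "carrier": carrier.astype(int),
    })
    if covariates is not None:
        data = pd.concat([data, covariates.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(data, duration_col="pfs_time", event_col="pfs_event")
    hr = float(np.exp(cph.params_["carrier"]))
    p_wald = float(cph.summary.loc["carrier", "p"])
    lr = logrank_test(df.loc[carrier, "pfs_time"], df.loc[~carrier, "pfs_time"],
                      event_observed_A=events[carrier], event_observed_B=events[~carrier])
    return SurvivalResult(label=label, hazard_ratio=hr, p=p_wald,
                          p_logrank=float(lr.p_value),
                          n_carriers=int(carrier.sum()), n_total=len(carrier))


def km_tables(outcomes, carrier) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier survival tables per carrier group, for plotting."""
    df = _outcome_frame(outcomes)
    carrier = np.asarray(carrier, dtype=bool)
    out = {}
    for name, mask in (("carrier", carrier), ("non_carrier", ~carrier)):
        km = KaplanMeierFitter()
        km.fit(df.loc[mask, "pfs_time"], df.loc[mask, "pfs_event"].astype(bool))
        tab = km.survival_function_.reset_index()
        tab.columns = ["time", "survival"]
        out[name] = tab
    return out


def recist_test(outcomes, carrier, covariates: pd.DataFrame | None = None,
                label: str = "") -> ResponseResult:
    """Proportional-odds test of RECIST category on carrier status.

    Categories are ordered PD < SD < PR < CR; records with missing RECIST are
    dropped. odds = exp(carrier coefficient), oriented so odds > 1 means
    carriers favor better response; p is the likelihood-ratio p against the
    intercepts-only model.
    """
    df = _outcome_frame(outcomes)
    carrier = np.asarray(carrier, dtype=bool)
    if len(carrier) != len(df):
        raise ValueError("carrier vector length does not match outcomes")
    keep = df["recist"].notna().to_numpy()
    df, carrier = df.loc[keep].reset_index(drop=True), carrier[keep]
    if carrier.all() or not carrier.any():
        raise ValueError("carrier vector is constant among patients with RECIST")
    codes = df["recist"].map(lambda r: Recist[r].value if isinstance(r, str) else int(r))
    y = pd.Categorical(codes, categories=[0, 1, 2, 3], ordered=True)
    observed = len(set(codes))
    if observed < 2:
        raise ValueError("at least two distinct RECIST categories required")
    X = pd.DataFrame({"carrier": carrier.astype(float)})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True).loc[:, :]], axis=1)
        X = X.reset_index(drop=True)
    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(y, X, distr="logit")
        try:
            fit = model.fit(method="bfgs", disp=0, maxiter=500)
            if not np.isfinite(np.asarray(fit.bse)[0]) or abs(np.asarray(fit.params)[0]) > 20:
                raise ValueError("separation")
        except Exception:
            separation = True
            fit = model.fit_regularized(method="l1", alpha=0.1, disp=0)
        if X.shape[1] > 1:
            null = OrderedModel(y, X.drop(columns=["carrier"]), distr="logit")
            null_llf = null.fit(method="bfgs", disp=0, maxiter=500).llf
        else:
            # intercepts-only proportional-odds MLE fits empirical frequencies
            counts = pd.Series(codes).value_counts()
            null_llf = float(sum(n * np.log(n / len(codes)) for n in counts))
    lr_stat = 2 * (fit.llf - null_llf)
    p = float(stats.chi2.sf(max(lr_stat, 0.0), df=1))
    odds = float(np.exp(np.asarray(fit.params)[0]))
    return ResponseResult(label=label, odds=odds, p=p, separation=separation)


def powered_units(matrix, outcomes, min_carriers_validation: int = 10,
                  min_events_validation: int = 10) -> list[str]:
    """Units with enough carriers and carrier-group events to be testable."""
    df = _outcome_frame(outcomes)
    events = df["pfs_event"].astype(bool).to_numpy()
    pid_to_idx = {p: i for i, p in enumerate(df["patient_id"])}
    units = []
    for unit in matrix.unit_names:
        col = matrix.column(unit)
        idx = [pid_to_idx[p] for p, c in zip(matrix.patient_ids, col)
               if c and p in pid_to_idx]
        n_car = len(idx)
        n_events = int(events[idx].sum()) if idx else 0
        if n_car >= min_carriers_validation and n_events >= min_events_validation:
            units.append(unit)
    return units


def tmb_by_carrier_summary(tmb_table: pd.DataFrame, carrier) -> pd.DataFrame:
    """Median mutation counts by carrier group with Mann-Whitney p per metric."""
    carrier = np.asarray(carrier, dtype=bool)
    rows = []
    for metric in ("overall_count", "nonsyn_count", "clonal_nonsyn_count"):
        vals = tmb_table[metric].to_numpy(dtype=float)
        a, b = vals[carrier], vals[~carrier]
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue) \
            if len(a) and len(b) else np.nan
        rows.append({
            "metric": metric,
            "median_carrier": float(np.median(a)) if len(a) else np.nan,
            "median_non_carrier": float(np.median(b)) if len(b) else np.nan,
            "p_mannwhitney": p,
        })
    return pd.DataFrame(rows)
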