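"""Somatic convergence and expression-shift tests for carrier units.

Convergence asks whether carriers of a germline unit preferentially acquire
somatic mutations in the same gene or unit *beyond* what their elevated
overall burden predicts: a logistic model of somatic-hit status on carrier
status controls for TMB (and cancer type / demographics), so a unit that
merely raises genome-wide burden yields a null carrier coefficient. Perfect
separation triggers a Firth-penalized refit rather than a failure.

Expression shifts are scored as the mean of within-cohort z-scores over a
gene set (e.g. E2F targets), compared carrier vs non-carrier by Welch's
t-test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .association import _design_matrix, _drop_collinear, bh_adjust
from .records import GeneSet

logger = logging.getLogger(__name__)


@dataclass
class ConvergenceResult:
    unit: str
    target: str
    beta: float  # carrier log-odds coefficient
    p_raw: float
    p_adjusted: float = np.nan
    separation: bool = False


@dataclass
class ExpressionScoreResult:
    unit: str
    gene_set_scored: str
    direction: str  # "up" or "down"
    p: float


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                    tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth-penalized logistic regression (Jeffreys-prior score correction).

    Returns (beta, standard errors). Used as the fallback under separation,
    where the unpenalized MLE diverges.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        XW = X * W[:, None]
        info = X.T @ XW
        cov = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, cov, X)  # hat diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1 - mu)
    cov = np.linalg.pinv(X.T @ (X * W[:, None]))
    return beta, np.sqrt(np.diag(cov))


def somatic_convergence_test(somatic_status, carrier, tmb, covariates=None,
                             unit: str = "", target: str = "") -> ConvergenceResult:
    """Logistic test of somatic-hit status on carrier status, TMB-controlled.

    beta is the carrier log-odds coefficient with a two-sided Wald p. Perfect
    separation is flagged and handled with a Firth-penalized refit.
    """
    y = np.asarray(somatic_status, dtype=float)
    carrier = np.asarray(carrier, dtype=float)
    if y.min() == y.max():
        raise ValueError("somatic status is constant; both classes required")
    if carrier.min() == carrier.max():
        raise ValueError("carrier vector is constant")
    X = _design_matrix(covariates, len(y))
    X.insert(0, "tmb", np.asarray(tmb, dtype=float))
    X.insert(0, "const", 1.0)
    X["carrier"] = carrier  # last, so covariates win collinearity conflicts
    X = _drop_collinear(X)
    if "carrier" not in X.columns:
        raise ValueError("carrier vector is collinear with the covariates")
    Xv = X.to_numpy(dtype=float)
    idx = list(X.columns).index("carrier")
    separation = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xv).fit(disp=0, maxiter=200)
        bse = fit.bse[idx]
        if not np.isfinite(bse) or bse > 50:
            raise ValueError("quasi-separation")
        beta, p = float(fit.params[idx]), float(fit.pvalues[idx])
    except Exception:
        separation = True
        b, se = _firth_logistic(Xv, y)
        z = b[idx] / se[idx]
        beta, p = float(b[idx]), float(2 * stats.norm.sf(abs(z)))
        logger.warning("separation in convergence test %r -> %r; Firth refit used",
                       unit, target)
    return ConvergenceResult(unit=unit, target=target, beta=beta, p_raw=p,
                             separation=separation)


def adjust_convergence_family(results: list[ConvergenceResult]) -> list[ConvergenceResult]:
    """BH-adjust all unit-target pairs tested in one invocation as one family."""
    if not results:
        return results
    adj = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def somatic_hit_status(maf: pd.DataFrame, patients: list[str], genes: set[str],
                       variant_classes: tuple[str, ...] = ("nonsynonymous",)) -> np.ndarray:
    """Binary vector: patient has >=1 somatic mutation (of the given classes) in genes."""
    hit = maf[
        maf["gene_symbol"].isin(genes)
        & maf["variant_classification"].isin(variant_classes)
    ]
    carriers = set(hit["patient_id"])
    return np.array([p in carriers for p in patients], dtype=bool)


def expression_set_score(expression: pd.DataFrame, carrier, scored_set: GeneSet,
                         unit: str = "") -> ExpressionScoreResult:
    """Carrier shift in the mean within-cohort z-score of a gene set.

    ``expression`` is genes x patients. Each member gene is z-scored across
    the cohort, scores averaged per patient, and carriers compared to
    non-carriers with a two-sided Welch t-test; direction is the sign of the
    carrier mean difference.
    """
    carrier = np.asarray(carrier, dtype=bool)
    members = [g for g in scored_set.genes if g in expression.index]
    if not members:
        raise ValueError(f"gene set {scored_set.name!r} shares no genes with the matrix")
    sub = expression.loc[members].to_numpy(dtype=float)
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (sub - mean) / sd
    score = z.mean(axis=0)
    if carrier.all() or not carrier.any():
        raise ValueError("both carrier groups must be non-empty")
    s_car, s_non = score[carrier], score[~carrier]
    t = stats.ttest_ind(s_car, s_non, equal_var=False)
    direction = "up" if s_car.mean() >= s_non.mean() else "down"
    return ExpressionScoreResult(unit=unit, gene_set_scored=scored_set.name,
                                 direction=direction, p=float(t.pvalue))
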