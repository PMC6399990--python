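"""Case/control discrimination: Mann-Whitney AUC, DeLong intervals,
in-sample logistic predictors, and extreme-tail counts."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from ._glm import irls_logistic

logger = logging.getLogger(__name__)

DEFAULT_TAIL_THRESHOLDS = (1.5, 2.0)


@dataclass
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    n_cases: int
    n_controls: int
    method: str = "delong"

    def as_dict(self) -> dict:
        return {"auc": self.auc, "ci_low": self.ci_low, "ci_high": self.ci_high,
                "n_cases": self.n_cases, "n_controls": self.n_controls,
                "method": self.method}


def auc_mann_whitney(scores_cases: np.ndarray, scores_controls: np.ndarray) -> float:
    """Fraction of (case, control) pairs with case score above control score;
    ties count one half."""
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both score vectors must be non-empty")
    ranks = rankdata(np.concatenate([x, y]))
    r_cases = ranks[: len(x)].sum()
    u = r_cases - len(x) * (len(x) + 1) / 2.0
    return float(u / (len(x) * len(y)))


def delong_ci(scores_cases: np.ndarray, scores_controls: np.ndarray,
              level: float = 0.95) -> AUCResult:
    """AUC with a DeLong structural-components confidence interval.

    Degenerate variance (e.g. perfect separation) collapses the interval to
    the point estimate with a warning.
    """
    x = np.asarray(scores_cases, dtype=float)
    y = np.asarray(scores_controls, dtype=float)
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise ValueError("need >= 2 samples in each class")
    tz = rankdata(np.concatenate([x, y]))
    tx = rankdata(x)
    ty = rankdata(y)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = float(v10.mean())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0:
        logger.warning("delong_ci: degenerate variance; interval collapsed to point")
        return AUCResult(auc, auc, auc, m, n)
    se = float(np.sqrt(var))
    z = norm.ppf(0.5 + level / 2.0)
    return AUCResult(auc,
                     float(np.clip(auc - z * se, 0.0, 1.0)),
                     float(np.clip(auc + z * se, 0.0, 1.0)),
                     m, n)


def apoe_dummies(apoe_genotypes: pd.Series) -> pd.DataFrame:
    """E2 and E4 allele counts from genotype labels, as two covariates."""
    g = apoe_genotypes.fillna("")
    return pd.DataFrame({
        "e2_count": g.str.count("E2"),
        "e4_count": g.str.count("E4"),
    })


def fit_logistic_predictor(status: np.ndarray, predictors: pd.DataFrame
                           ) -> tuple[np.ndarray, bool]:
    """In-sample predicted case probabilities from a logistic fit.

    On separation/non-convergence the raw first predictor is returned as the
    ranking score with a warning (AUC is rank-based, so this is a usable
    fallback).  Returns (scores, converged).
    """
    y = np.asarray(status, dtype=float)
    if y.min() == y.max():
        raise ValueError("both phenotype classes must be present")
    P = np.asarray(predictors, dtype=float)
    X = np.column_stack([np.ones(len(y)), P])
    beta, cov, converged = irls_logistic(X, y)
    if not converged:
        logger.warning("fit_logistic_predictor: separation/non-convergence; "
                       "falling back to the raw first predictor")
        return P[:, 0].copy(), False
    from scipy.special import expit
    return expit(X @ beta), True


def tail_counts(z_scores: np.ndarray, status: np.ndarray,
                thresholds=DEFAULT_TAIL_THRESHOLDS) -> dict:
    """Cases/controls in the strict extreme tails of a standardized score.

    Returns {t: {"lower": {"cases": ., "controls": .},
                 "upper": {"cases": ., "controls": .}}} with score < -t and
    score > +t respectively.
    """
    z = np.asarray(z_scores, dtype=float)
    is_case = np.asarray(status) == "case" if np.asarray(status).dtype.kind in "OUS" \
        else np.asarray(status, dtype=bool)
    out = {}
    for t in thresholds:
        lo = z < -t
        hi = z > t
        out[float(t)] = {
            "lower": {"cases": int((lo & is_case).sum()),
                      "controls": int((lo & ~is_case).sum())},
            "upper": {"cases": int((hi & is_case).sum()),
                      "controls": int((hi & ~is_case).sum())},
        }
    return out
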