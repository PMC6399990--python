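"""Per-SNP logistic association with covariates, and PCA covariates."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._glm import irls_logistic
from .genio import HardCallMatrix

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    snp_id: str
    beta: float
    se: float
    pvalue: float
    n_used: int
    converged: bool = True


def compute_pcs(matrix: HardCallMatrix, n_components: int = 2) -> np.ndarray:
    """Principal components of the column-standardized dosage matrix.

    Missing calls are imputed with the column mean; all-missing or
    zero-variance columns are excluded with a warning.  Components are
    ordered by decreasing variance explained and signed so the
    largest-magnitude loading is positive.  Returns (n_samples, n_components).
    """
    X = matrix.dosage.astype(float).copy()
    n, m = X.shape
    if n < n_components + 1:
        raise ValueError("need at least n_components+1 samples")
    if m < 2:
        raise ValueError("need at least 2 SNPs")
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_mean = np.nanmean(X, axis=0)
    all_missing = np.isnan(col_mean)
    if all_missing.any():
        logger.warning("compute_pcs: %d all-missing SNP columns excluded",
                       int(all_missing.sum()))
    X = X[:, ~all_missing]
    col_mean = col_mean[~all_missing]
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X = X - X.mean(axis=0)
    sd = X.std(axis=0)
    nonconst = sd > 0
    if (~nonconst).any():
        logger.warning("compute_pcs: %d zero-variance SNP columns excluded",
                       int((~nonconst).sum()))
    X = X[:, nonconst] / sd[nonconst]
    if X.shape[1] == 0:
        logger.warning("compute_pcs: no variable SNPs; returning zero PCs")
        return np.zeros((n, n_components))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n_components, len(S))
    scores = U[:, :k] * S[:k]
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            scores[:, c] = -scores[:, c]
    if k < n_components:
        scores = np.column_stack([scores, np.zeros((n, n_components - k))])
    return scores


def logistic_gwas(matrix: HardCallMatrix, samples: pd.DataFrame,
                  covariates: np.ndarray | None = None,
                  include_sex: bool = True) -> list[AssociationResult]:
    """Fit status ~ intercept + dosage + sex + covariates per SNP.

    Missing genotypes drop that sample for that SNP only.  Non-converged or
    separated fits are flagged (``converged=False``, NaN statistics) and the
    flagged count is logged.
    """
    y_all = (samples["status"].to_numpy() == "case").astype(float)
    if y_all.min() == y_all.max():
        raise ValueError("both phenotype classes must be present")
    sex_col = None
    if include_sex:
        sex_col = (samples["sex"].to_numpy() == "female").astype(float)
    cov = None
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(samples):
            cov = cov.T
    results = []
    n_flagged = 0
    snp_ids = matrix.snp_meta["snp_id"].tolist()
    for j, snp_id in enumerate(snp_ids):
        g = matrix.dosage[:, j]
        keep = np.isfinite(g)
        cols = [np.ones(int(keep.sum())), g[keep]]
        if sex_col is not None:
            cols.append(sex_col[keep])
        if cov is not None:
            cols.extend(cov[keep].T)
        X = np.column_stack(cols)
        y = y_all[keep]
        ok = len(y) >= X.shape[1] and y.min() != y.max() and g[keep].std() > 0
        if ok:
            beta, covm, converged = irls_logistic(X, y)
            ok = converged and covm is not None and covm[1, 1] > 0
        if not ok:
            n_flagged += 1
            results.append(AssociationResult(snp_id, np.nan, np.nan, np.nan,
                                             int(keep.sum()), converged=False))
            continue
        se = float(np.sqrt(covm[1, 1]))
        z = abs(beta[1]) / se
        p = float(np.clip(2.0 * norm.sf(z), 1e-300, 1.0))
        results.append(AssociationResult(snp_id, float(beta[1]), se, p,
                                         int(keep.sum())))
    if n_flagged:
        logger.info("logistic_gwas: %d SNPs flagged non-converged/untestable",
                    n_flagged)
    return results


def association_table(results: list[AssociationResult],
                      snp_meta: pd.DataFrame) -> pd.DataFrame:
    """Arrange association results in the summary-statistics schema."""
    meta = snp_meta.set_index("snp_id")
    rows = []
    for r in results:
        m = meta.loc[r.snp_id]
        rows.append((r.snp_id, m["chrom"], m["pos"], m["alleleB"], m["alleleA"],
                     r.beta, r.se, r.pvalue, r.converged))
    return pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "A1", "A2",
                                       "BETA", "SE", "P", "ok"])
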