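"""Per-person risk/alternative allele counts and the 2x2 stratum comparison.

The contingency comparison builds a 2x2 table of risk vs alternative allele
counts for two strata and applies a Pearson chi-square without continuity
correction.  Cells may hold mean counts per person (as printed in the source
tables) or total counts; the odds ratio is identical either way, the
chi-square statistic is not — means are conservative by construction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, fisher_exact

from .genio import HardCallMatrix
from .prs import aligned_design

logger = logging.getLogger(__name__)


@dataclass
class BurdenRow:
    threshold: float
    mean_risk_a: float
    mean_alt_a: float
    mean_risk_b: float
    mean_alt_b: float
    odds_ratio: float
    pvalue: float
    flagged: bool = False


def count_alleles_per_person(matrix: HardCallMatrix, sumstats: pd.DataFrame,
                             snp_set: list[str]) -> pd.DataFrame:
    """Risk and alternative allele counts per sample over a SNP set.

    The risk allele of each SNP is the allele with positive aligned beta
    (the other allele when beta < 0).  Missing calls contribute to neither
    count, so risk + alt = 2 x non-missing SNPs for each person.
    """
    if not snp_set:
        raise ValueError("snp_set must be non-empty")
    D, betas, _ses, kept = aligned_design(matrix, sumstats, snp_set)
    if D.shape[1] == 0:
        raise ValueError("no alignable SNPs in snp_set")
    risk_dosage = np.where(betas[None, :] >= 0, D, 2.0 - D)
    missing = np.isnan(risk_dosage)
    risk = np.where(missing, 0.0, risk_dosage).sum(axis=1)
    nonmiss = (~missing).sum(axis=1)
    alt = 2.0 * nonmiss - risk
    return pd.DataFrame({"sample_id": matrix.sample_ids,
                         "risk_count": risk, "alt_count": alt,
                         "n_snps": nonmiss})


def burden_contingency(stratum_a: pd.DataFrame, stratum_b: pd.DataFrame,
                       threshold: float = np.nan,
                       cells: str = "means") -> BurdenRow:
    """Compare risk/alternative allele burden between two strata.

    ``stratum_a``/``stratum_b`` are outputs of count_alleles_per_person
    (possibly subset).  ``cells`` selects whether the chi-square table holds
    mean counts per person (default) or stratum totals.
    """
    if cells not in ("means", "totals"):
        raise ValueError("cells must be 'means' or 'totals'")
    if len(stratum_a) == 0 or len(stratum_b) == 0:
        raise ValueError("both strata must be non-empty")
    mra = float(stratum_a["risk_count"].mean())
    maa = float(stratum_a["alt_count"].mean())
    mrb = float(stratum_b["risk_count"].mean())
    mab = float(stratum_b["alt_count"].mean())
    if cells == "means":
        table = np.array([[mra, maa], [mrb, mab]])
    else:
        table = np.array([
            [stratum_a["risk_count"].sum(), stratum_a["alt_count"].sum()],
            [stratum_b["risk_count"].sum(), stratum_b["alt_count"].sum()],
        ], dtype=float)
    flagged = False
    if (table == 0).any():
        flagged = True
        logger.warning("burden_contingency: zero cell; OR flagged, exact p used")
        odds = np.inf if (maa * mrb) == 0 and (mra * mab) > 0 else np.nan
        _or, p = fisher_exact(np.round(table).astype(int))
        if np.isfinite(_or) and _or > 0:
            odds = float(_or)
        return BurdenRow(threshold, mra, maa, mrb, mab, odds, float(p), flagged)
    odds = (mra * mab) / (maa * mrb)
    _stat, p, _dof, _exp = chi2_contingency(table, correction=False)
    return BurdenRow(threshold, mra, maa, mrb, mab, float(odds),
                     float(min(max(p, 1e-300), 1.0)), flagged)


def burden_table(matrix: HardCallMatrix, sumstats: pd.DataFrame,
                 snp_sets_by_threshold: dict[float, list[str]],
                 mask_a: np.ndarray, mask_b: np.ndarray,
                 cells: str = "means") -> pd.DataFrame:
    """One BurdenRow per threshold comparing stratum A vs B sample masks."""
    rows = []
    for thr in sorted(snp_sets_by_threshold):
        counts = count_alleles_per_person(matrix, sumstats,
                                          snp_sets_by_threshold[thr])
        row = burden_contingency(counts.loc[mask_a], counts.loc[mask_b],
                                 threshold=thr, cells=cells)
        rows.append(row)
    return pd.DataFrame([r.__dict__ for r in rows])
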