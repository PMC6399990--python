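"""Polygenic score construction: allele alignment, threshold selection,
region exclusion, standardization and PC adjustment."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import HardCallMatrix

logger = logging.getLogger(__name__)

THRESHOLD_GRID = (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
DEFAULT_APOE_REGION = ("19", 44_400_000, 46_500_000)
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


@dataclass
class ScoreSpec:
    p_threshold: float = 0.5
    exclude_region: tuple[str, int, int] | None = None
    missing_policy: str = "mean_dosage"

    def __post_init__(self):
        if not (0.0 < self.p_threshold <= 1.0):
            raise ValueError("p_threshold must be in (0,1]")
        if self.missing_policy not in ("mean_dosage", "omit"):
            raise ValueError("missing_policy must be mean_dosage or omit")
        if self.exclude_region is not None:
            chrom, start, end = self.exclude_region
            if start > end:
                raise ValueError("exclude_region start_bp must be <= end_bp")


def align_alleles(effect_allele: str, other_allele: str,
                  alleleA: str, alleleB: str) -> tuple[int, bool, str]:
    """Harmonize a summary-stat record against genotype SNP alleles.

    Returns (sign, usable, reason).  sign +1 means the effect allele is
    alleleB (dosage counts it directly); -1 means it is alleleA (dosage is
    counted as 2 - dosage).  Strand-ambiguous pairs (A/T, C/G) and allele-set
    mismatches are unusable.
    """
    pair = {effect_allele, other_allele}
    if pair in _AMBIGUOUS:
        return 0, False, "strand-ambiguous allele pair"
    if (effect_allele, other_allele) == (alleleB, alleleA):
        return 1, True, ""
    if (effect_allele, other_allele) == (alleleA, alleleB):
        return -1, True, ""
    return 0, False, "allele set mismatch"


def exclude_region(snp_meta: pd.DataFrame,
                   region: tuple[str, int, int]) -> list[str]:
    """SNP ids falling inside [start_bp, end_bp] on the given chromosome."""
    chrom, start, end = region
    if start > end:
        raise ValueError("start_bp must be <= end_bp")
    hit = (snp_meta["chrom"].astype(str) == str(chrom)) & \
          (snp_meta["pos"] >= start) & (snp_meta["pos"] <= end)
    return snp_meta.loc[hit, "snp_id"].tolist()


def aligned_design(matrix: HardCallMatrix, sumstats: pd.DataFrame,
                   snp_ids: list[str]):
    """Aligned dosage columns and betas for a SNP set.

    Returns ``(D, betas, ses, kept_ids)`` where D is (n_samples, n_kept) of
    effect-allele dosages with NaN for missing calls.  Unusable alignments
    are dropped with a logged count.
    """
    meta = matrix.snp_meta.set_index("snp_id")
    col_of = {sid: j for j, sid in enumerate(matrix.snp_meta["snp_id"])}
    ss = sumstats.set_index("SNP")
    cols, betas, ses, kept = [], [], [], []
    n_unusable = 0
    for sid in snp_ids:
        if sid not in col_of or sid not in ss.index:
            n_unusable += 1
            continue
        row = ss.loc[sid]
        m = meta.loc[sid]
        sign, usable, _reason = align_alleles(str(row["A1"]), str(row["A2"]),
                                              str(m["alleleA"]), str(m["alleleB"]))
        if not usable:
            n_unusable += 1
            continue
        g = matrix.dosage[:, col_of[sid]]
        cols.append(g if sign == 1 else 2.0 - g)
        betas.append(float(row["BETA"]))
        ses.append(float(row["SE"]))
        kept.append(sid)
    if n_unusable:
        logger.info("aligned_design: %d SNPs unusable (missing or unalignable)",
                    n_unusable)
    D = np.column_stack(cols) if cols else np.empty((matrix.n_samples, 0))
    return D, np.array(betas), np.array(ses), kept


def select_snps(sumstats: pd.DataFrame, retained: list[str], spec: ScoreSpec,
                snp_meta: pd.DataFrame) -> list[str]:
    """Retained SNPs passing the p-value threshold and region exclusion."""
    ss = sumstats.set_index("SNP")
    chosen = [sid for sid in retained
              if sid in ss.index and ss.loc[sid, "P"] <= spec.p_threshold]
    if spec.exclude_region is not None:
        removed = set(exclude_region(snp_meta, spec.exclude_region))
        chosen = [sid for sid in chosen if sid not in removed]
    return chosen


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        logger.warning("standardize: zero score variance; returning zeros")
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def residualize(z: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    """Residual of z on [1, pcs], re-standardized."""
    X = np.column_stack([np.ones(len(z)), np.asarray(pcs, dtype=float)])
    coef, *_ = np.linalg.lstsq(X, z, rcond=None)
    return _standardize(z - X @ coef)


def compute_prs(matrix: HardCallMatrix, sumstats: pd.DataFrame,
                retained: list[str], spec: ScoreSpec | None = None,
                pcs: np.ndarray | None = None) -> pd.DataFrame:
    """Score every sample over the threshold-selected retained SNP set.

    Returns a DataFrame with columns sample_id, raw_score, n_snps_used,
    z_score and adjusted_z (equal to z_score when no PCs are supplied).
    Missing hard calls contribute the SNP's mean aligned dosage under the
    default policy, or nothing under ``omit``.
    """
    spec = spec or ScoreSpec()
    chosen = select_snps(sumstats, retained, spec, matrix.snp_meta)
    if not chosen:
        region = spec.exclude_region
        raise ValueError(
            f"no SNPs selected at p<={spec.p_threshold}"
            + (f" with region {region} excluded" if region else "")
        )
    D, betas, _ses, kept = aligned_design(matrix, sumstats, chosen)
    if D.shape[1] == 0:
        raise ValueError("no alignable SNPs in the selected set")
    missing = np.isnan(D)
    if spec.missing_policy == "mean_dosage":
        col_mean = np.nanmean(D, axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        Df = np.where(missing, col_mean[None, :], D)
        n_used = np.full(D.shape[0], D.shape[1], dtype=int)
    else:
        Df = np.where(missing, 0.0, D)
        n_used = (~missing).sum(axis=1)
    raw = Df @ betas
    z = _standardize(raw)
    adj = residualize(z, pcs) if pcs is not None else z
    return pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "raw_score": raw,
        "n_snps_used": n_used,
        "z_score": z,
        "adjusted_z": adj,
    })
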