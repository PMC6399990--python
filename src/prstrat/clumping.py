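"""P-value-ordered greedy LD pruning against the test cohort's hard calls."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import HardCallMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClumpSpec:
    r2_max: float = 0.1
    window_bp: int = 500_000

    def __post_init__(self):
        if not (0.0 <= self.r2_max <= 1.0):
            raise ValueError("r2_max must be in [0,1]")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


def pairwise_r2(matrix: HardCallMatrix, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation of dosages over jointly non-missing samples."""
    gi = matrix.dosage[:, snp_i]
    gj = matrix.dosage[:, snp_j]
    keep = np.isfinite(gi) & np.isfinite(gj)
    if keep.sum() < 2:
        raise ValueError("need >= 2 jointly non-missing samples")
    return _r2(gi[keep], gj[keep])


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        logger.warning("pairwise_r2: zero dosage variance; r2 defined as 0")
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _r2_against_many(g: np.ndarray, ok: np.ndarray, G: np.ndarray,
                     OK: np.ndarray) -> np.ndarray:
    """r^2 of dosage vector g against each column of G over jointly
    non-missing samples (pairwise-complete); zero-variance pairs give 0."""
    M = ok[:, None] & OK
    n = M.sum(axis=0).astype(float)
    gz = np.where(ok, g, 0.0)[:, None] * M
    Gz = np.where(OK, G, 0.0) * M
    sx = gz.sum(axis=0)
    sy = Gz.sum(axis=0)
    sxx = (gz * gz).sum(axis=0)
    syy = (Gz * Gz).sum(axis=0)
    sxy = (gz * Gz).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = np.where((vx > 0) & (vy > 0) & (n >= 2),
                      (cov * cov) / np.where(vx * vy > 0, vx * vy, 1.0), 0.0)
    return r2


def _chrom_key(chrom: str):
    s = str(chrom)
    return (0, int(s)) if s.isdigit() else (1, s)


def greedy_prune(sumstats: pd.DataFrame, matrix: HardCallMatrix,
                 spec: ClumpSpec | None = None) -> list[str]:
    """Greedy LD pruning, most significant SNP first.

    SNPs are visited in ascending discovery p-value (ties broken by
    chromosome, position, then SNP id) and retained iff their r^2 with every
    already-retained SNP on the same chromosome within ``window_bp`` base
    pairs (inclusive) is <= ``r2_max``.  SNPs absent from the genotype matrix
    are dropped first with a logged count.
    """
    spec = spec or ClumpSpec()
    idx = pd.Index(matrix.snp_meta["snp_id"])
    pos_of = dict(zip(matrix.snp_meta["snp_id"], matrix.snp_meta["pos"]))
    chrom_of = dict(zip(matrix.snp_meta["snp_id"], matrix.snp_meta["chrom"].astype(str)))
    col_of = {sid: j for j, sid in enumerate(idx)}

    present = sumstats["SNP"].isin(idx)
    n_dropped = int((~present).sum())
    if n_dropped:
        logger.info("greedy_prune: %d summary-stat SNPs absent from genotypes dropped",
                    n_dropped)
    cand = sumstats.loc[present].copy()
    if "ok" in cand.columns:
        cand = cand.loc[cand["ok"].astype(bool)]
    if cand.empty:
        raise ValueError("no overlap between summary statistics and genotype matrix")

    order = sorted(
        cand.itertuples(index=False),
        key=lambda r: (r.P, _chrom_key(r.CHR), int(r.BP), r.SNP),
    )
    retained: list[str] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    dosage = matrix.dosage
    finite = np.isfinite(dosage)
    for rec in order:
        sid = rec.SNP
        chrom = chrom_of[sid]
        pos = pos_of[sid]
        j = col_of[sid]
        near = [rj for (rpos, rj) in by_chrom.get(chrom, ())
                if abs(pos - rpos) <= spec.window_bp]
        ok = True
        if near:
            r2 = _r2_against_many(dosage[:, j], finite[:, j],
                                  dosage[:, near], finite[:, near])
            ok = bool((r2 <= spec.r2_max).all())
        if ok:
            retained.append(sid)
            by_chrom.setdefault(chrom, []).append((int(pos), j))
    logger.info("greedy_prune: retained %d of %d candidate SNPs",
                len(retained), len(cand))
    return retained
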