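"""Genotype and summary-statistic IO, hard-calling and QC filters.

File dialects
-------------
GEN     one line per SNP: ``chrom id pos alleleA alleleB`` followed by one
        probability triple ``p(AA) p(AB) p(BB)`` per sample, space delimited.
SAMPLE  Oxford two-header-row convention: ``ID_1 ID_2 missing sex phenotype
        [apoe]`` then a type row, then one line per sample.
Summary statistics: tab-delimited with header ``SNP CHR BP A1 A2 BETA SE P``
where A1 is the effect allele.

Info scores are not part of the GEN dialect; an optional sidecar TSV
(``snp_id<TAB>info``) carries them across round-trips.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SNP_META_COLUMNS = ["snp_id", "chrom", "pos", "alleleA", "alleleB", "info_score"]
SUMSTAT_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P"]

SEX_CODES = {"male": "1", "female": "2", "unknown": "0"}
SEX_LABELS = {v: k for k, v in SEX_CODES.items()}
APOE_GENOTYPES = ("E2E2", "E2E3", "E2E4", "E3E3", "E3E4", "E4E4")


@dataclass
class GenotypeProbabilityMatrix:
    """Imputed genotype probabilities for samples x SNPs.

    probs has shape (n_samples, n_snps, 3) holding (pAA, pAB, pBB); snp_meta
    is a DataFrame with columns SNP_META_COLUMNS (extra columns tolerated).
    """
    probs: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3 or self.probs.shape[2] != 3:
            raise ValueError("probs must have shape (n_samples, n_snps, 3)")
        if self.probs.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match probs")
        if self.probs.shape[1] != len(self.snp_meta):
            raise ValueError("snp_meta length does not match probs")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative genotype probability")
        sums = self.probs.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("probability triple does not sum to 1 within 1e-6")
        info = self.snp_meta["info_score"].to_numpy(dtype=float)
        if np.any((info < 0) | (info > 1.05)):
            raise ValueError("info_score outside [0, 1.05]")

    @property
    def n_samples(self) -> int:
        return self.probs.shape[0]

    @property
    def n_snps(self) -> int:
        return self.probs.shape[1]

    def expected_dosage(self) -> np.ndarray:
        """Expected alleleB dosage, shape (n_samples, n_snps)."""
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]


@dataclass
class HardCallMatrix:
    """Hard-called alleleB dosages; NaN marks a missing call."""
    dosage: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        ok = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("hard-call dosages must be in {0,1,2} or missing")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.dosage[:, j]

    def snp_index(self) -> pd.Index:
        return pd.Index(self.snp_meta["snp_id"])


@dataclass
class SampleRecord:
    sample_id: str
    sex: str = "unknown"
    status: str = "control"
    apoe_genotype: str | None = None

    def __post_init__(self):
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case/control, got {self.status!r}")
        if self.sex not in SEX_CODES:
            raise ValueError(f"sex must be male/female/unknown, got {self.sex!r}")
        if self.apoe_genotype is not None and self.apoe_genotype not in APOE_GENOTYPES:
            raise ValueError(f"unknown APOE genotype {self.apoe_genotype!r}")


def make_sample_table(records: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "sex": [r.sex for r in records],
            "status": [r.status for r in records],
            "apoe_genotype": [r.apoe_genotype for r in records],
        }
    )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline().split()
        fh.readline()  # type row
        rows = [line.split() for line in fh if line.strip()]
    has_apoe = "apoe" in header
    recs = []
    for toks in rows:
        apoe = None
        if has_apoe:
            val = toks[header.index("apoe")]
            apoe = None if val in ("NA", "-9") else val
        pheno = toks[header.index("phenotype")]
        recs.append(
            SampleRecord(
                sample_id=toks[0],
                sex=SEX_LABELS.get(toks[header.index("sex")], "unknown"),
                status="case" if pheno == "1" else "control",
                apoe_genotype=apoe,
            )
        )
    return make_sample_table(recs)


def write_sample(samples: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("ID_1 ID_2 missing sex phenotype apoe\n")
        fh.write("0 0 0 D B D\n")
        for row in samples.itertuples(index=False):
            apoe = row.apoe_genotype if row.apoe_genotype else "NA"
            fh.write(
                f"{row.sample_id} {row.sample_id} 0 "
                f"{SEX_CODES[row.sex]} {'1' if row.status == 'case' else '0'} {apoe}\n"
            )


def read_gen(path, sample_path, info_path=None) -> GenotypeProbabilityMatrix:
    """Parse a GEN/SAMPLE pair into a GenotypeProbabilityMatrix.

    Probability triples whose sum falls outside 1 +/- 1e-3 are renormalized
    with a logged warning; triples inside the band are kept verbatim.
    """
    samples = read_sample(sample_path)
    n_samples = len(samples)
    meta_rows = []
    probs_rows = []
    n_renorm = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 5 + 3 * n_samples:
                raise ValueError(
                    f"{path}: line {lineno}: expected {5 + 3 * n_samples} tokens "
                    f"for {n_samples} samples, got {len(toks)}"
                )
            chrom, snp_id, pos, a, b = toks[:5]
            try:
                triples = np.array(toks[5:], dtype=float).reshape(n_samples, 3)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad probability token") from exc
            sums = triples.sum(axis=1)
            off = np.abs(sums - 1.0) > 1e-3
            if off.any():
                n_renorm += int(off.sum())
                triples[off] = triples[off] / sums[off, None]
            meta_rows.append((snp_id, chrom, int(pos), a, b, 1.0))
            probs_rows.append(triples)
    if n_renorm:
        logger.warning("read_gen: renormalized %d probability triples", n_renorm)
    meta = pd.DataFrame(meta_rows, columns=SNP_META_COLUMNS)
    if info_path is not None:
        info = pd.read_csv(info_path, sep="\t")
        meta = meta.drop(columns=["info_score"]).merge(
            info.rename(columns={"snp_id": "snp_id", "info": "info_score"}),
            on="snp_id", how="left",
        )
        meta["info_score"] = meta["info_score"].fillna(1.0)
    probs = (
        np.stack(probs_rows, axis=1)
        if probs_rows
        else np.empty((n_samples, 0, 3))
    )
    return GenotypeProbabilityMatrix(probs=probs, snp_meta=meta,
                                     sample_ids=list(samples["sample_id"]))


def write_gen(matrix: GenotypeProbabilityMatrix, path, info_path=None) -> None:
    with open(path, "w") as fh:
        for j, row in enumerate(matrix.snp_meta.itertuples(index=False)):
            triples = matrix.probs[:, j, :].ravel()
            fh.write(
                f"{row.chrom} {row.snp_id} {int(row.pos)} {row.alleleA} {row.alleleB} "
                + " ".join(f"{p:.7f}" for p in triples)
                + "\n"
            )
    if info_path is not None:
        matrix.snp_meta[["snp_id", "info_score"]].rename(
            columns={"info_score": "info"}
        ).to_csv(info_path, sep="\t", index=False, float_format="%.6g")


def read_sumstats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str, "A1": str, "A2": str})
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary-statistic columns {missing}")
    bad_se = df["SE"] <= 0
    bad_p = (df["P"] <= 0) | (df["P"] > 1)
    if bad_se.any() or bad_p.any():
        raise ValueError(f"{path}: {int(bad_se.sum())} rows with SE<=0, "
                         f"{int(bad_p.sum())} rows with P outside (0,1]")
    if (df["A1"] == df["A2"]).any():
        raise ValueError(f"{path}: effect allele equals other allele")
    return df[SUMSTAT_COLUMNS + [c for c in df.columns if c not in SUMSTAT_COLUMNS]]


def write_sumstats(sumstats: pd.DataFrame, path) -> None:
    sumstats[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# hard-calling and QC
# ---------------------------------------------------------------------------

def hard_call(matrix: GenotypeProbabilityMatrix, threshold: float = 0.9) -> HardCallMatrix:
    """Convert probabilities to most-probable genotypes.

    A call is emitted only when the maximal probability strictly exceeds
    ``threshold``; otherwise the entry is missing.
    """
    if not (1.0 / 3.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (1/3, 1]")
    best = matrix.probs.argmax(axis=2).astype(float)
    pmax = matrix.probs.max(axis=2)
    best[pmax <= threshold] = np.nan
    return HardCallMatrix(dosage=best, snp_meta=matrix.snp_meta.copy(),
                         sample_ids=list(matrix.sample_ids))


def compute_maf(matrix: GenotypeProbabilityMatrix, snp_index: int) -> float:
    """Minor allele frequency from expected dosage, folded to [0, 0.5]."""
    if matrix.n_samples == 0:
        raise ValueError("cannot compute MAF with zero samples")
    freq = float(matrix.expected_dosage()[:, snp_index].mean() / 2.0)
    return min(freq, 1.0 - freq)


def compute_maf_all(matrix: GenotypeProbabilityMatrix) -> np.ndarray:
    if matrix.n_samples == 0:
        raise ValueError("cannot compute MAF with zero samples")
    freq = matrix.expected_dosage().mean(axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def qc_filter(matrix: GenotypeProbabilityMatrix, info_min: float = 0.8,
              maf_min: float = 0.01) -> GenotypeProbabilityMatrix:
    """Drop SNPs failing Info or MAF thresholds (boundary values retained)."""
    if not (0 <= info_min <= 1 and 0 <= maf_min <= 1):
        raise ValueError("thresholds must be in [0,1]")
    info = matrix.snp_meta["info_score"].to_numpy(dtype=float)
    maf = compute_maf_all(matrix)
    keep = (info >= info_min) & (maf >= maf_min)
    n_info = int((info < info_min).sum())
    n_maf = int(((info >= info_min) & (maf < maf_min)).sum())
    logger.info("qc_filter: excluded %d SNPs on Info<%g, %d further on MAF<%g; "
                "%d of %d retained", n_info, info_min, n_maf, maf_min,
                int(keep.sum()), matrix.n_snps)
    if not keep.any():
        logger.warning("qc_filter: no SNPs passed QC")
    return GenotypeProbabilityMatrix(
        probs=matrix.probs[:, keep, :],
        snp_meta=matrix.snp_meta.loc[keep].reset_index(drop=True),
        sample_ids=list(matrix.sample_ids),
    )
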