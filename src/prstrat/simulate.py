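"""Synthetic cohort and discovery summary-statistic generator.

The generator produces, from one seeded configuration:

* a test cohort of imputed-genotype-style probability triples with block LD
  (Gaussian-copula haplotypes, AR(1) latent correlation within blocks),
  per-SNP Info scores inside a configurable range, an APOE locus carried both
  as a per-sample genotype label and as two biallelic SNPs inside the APOE
  region, and case/control status drawn from a logistic liability model;
* a discovery summary-statistic table obtained by running a per-SNP logistic
  association on an independently drawn (optionally overlapping) discovery
  sample.

Everything is reproducible bit-for-bit from the seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .genio import (GenotypeProbabilityMatrix, HardCallMatrix, SampleRecord,
                    SNP_META_COLUMNS, SUMSTAT_COLUMNS, make_sample_table)
from ._glm import batch_snp_logistic

logger = logging.getLogger(__name__)

APOE_SNP_429358 = "rs429358"   # C allele tags E4
APOE_SNP_7412 = "rs7412"       # T allele tags E2
APOE_CHROM = "19"
APOE_POS_429358 = 44908684
APOE_POS_7412 = 44908822

_ALLELE_PAIRS = (("A", "C"), ("A", "G"), ("C", "T"), ("G", "T"))


@dataclass
class SimulationConfig:
    n_cases: int = 500
    n_controls: int = 500
    n_snps: int = 200
    n_causal: int = 20
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_rho: float = 0.5
    effect_sd: float = 0.15
    apoe_freqs: tuple[float, float, float] = (0.08, 0.77, 0.15)  # E2, E3, E4
    apoe_betas: tuple[float, float] = (-0.5, 1.1)                # per E2, per E4 allele
    info_range: tuple[float, float] = (0.9, 1.0)
    intercept: float = 0.0
    discovery_n: int = 2000
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cases", "n_controls", "n_snps", "n_causal",
                     "ld_block_size", "discovery_n"):
            if getattr(self, name) < (0 if name == "n_causal" else 1):
                raise ValueError(f"{name} must be >= 1")
        if self.n_snps < 3:
            raise ValueError("n_snps must be >= 3 (two slots hold the APOE SNPs)")
        lo, hi = self.maf_range
        if not (0.01 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if abs(sum(self.apoe_freqs) - 1.0) > 1e-9:
            raise ValueError("apoe_freqs must sum to 1")
        ilo, ihi = self.info_range
        if not (0.0 < ilo <= ihi <= 1.0):
            raise ValueError("info_range must lie within (0, 1]")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must be in [0, 1]")
        n_test = self.n_cases + self.n_controls
        if self.overlap_fraction * n_test > self.discovery_n + 1e-9:
            raise ValueError("overlap_fraction * (n_cases+n_controls) exceeds discovery_n")
        if self.n_causal > self.n_snps - 2:
            raise ValueError("n_causal exceeds number of background SNPs")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("maf_range", "apoe_freqs", "apoe_betas", "info_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


APOE_LABELS = ("E2E2", "E2E3", "E2E4", "E3E3", "E3E4", "E4E4")


@dataclass
class TrueModel:
    """Ground truth behind one simulated dataset."""
    snp_betas: np.ndarray                 # length n_snps; 0 for non-causal and APOE slots
    apoe_effect_by_genotype: dict[str, float]
    intercept: float
    snp_meta: pd.DataFrame                # includes allele_freq_B column
    config: SimulationConfig

    def __post_init__(self):
        self.snp_betas = np.asarray(self.snp_betas, dtype=float)
        if len(self.snp_betas) != self.config.n_snps:
            raise ValueError("snp_betas length must equal n_snps")
        missing = set(APOE_LABELS) - set(self.apoe_effect_by_genotype)
        if missing:
            raise ValueError(f"apoe_effect_by_genotype missing {sorted(missing)}")


def theoretical_auc(score_mean_case: float, score_mean_control: float,
                    score_sd: float) -> float:
    """Closed-form AUC for equal-variance normal case/control scores."""
    if score_sd <= 0:
        raise ValueError("score_sd must be positive")
    d = (score_mean_case - score_mean_control) / (score_sd * np.sqrt(2.0))
    return float(norm.cdf(d))


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _build_model(config: SimulationConfig, rng: np.random.Generator):
    n_bg = config.n_snps - 2
    lo, hi = config.maf_range
    freqs_bg = rng.uniform(lo, hi, size=n_bg)
    pairs = [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), size=n_bg)]
    meta = pd.DataFrame({
        "snp_id": [f"snp{i + 1:06d}" for i in range(n_bg)],
        "chrom": ["1"] * n_bg,
        "pos": [10_000 * (i + 1) for i in range(n_bg)],
        "alleleA": [p[0] for p in pairs],
        "alleleB": [p[1] for p in pairs],
        "info_score": 1.0,
        "allele_freq_B": freqs_bg,
    })
    f2, f3, f4 = config.apoe_freqs
    apoe_meta = pd.DataFrame({
        "snp_id": [APOE_SNP_429358, APOE_SNP_7412],
        "chrom": [APOE_CHROM, APOE_CHROM],
        "pos": [APOE_POS_429358, APOE_POS_7412],
        "alleleA": ["T", "C"],
        "alleleB": ["C", "T"],
        "info_score": [1.0, 1.0],
        "allele_freq_B": [f4, f2],
    })
    meta = pd.concat([meta, apoe_meta], ignore_index=True)

    betas = np.zeros(config.n_snps)
    if config.n_causal > 0:
        causal = rng.choice(n_bg, size=config.n_causal, replace=False)
        betas[causal] = rng.normal(0.0, config.effect_sd, size=config.n_causal)

    b2, b4 = config.apoe_betas
    apoe_effect = {
        "E2E2": 2 * b2, "E2E3": b2, "E2E4": b2 + b4,
        "E3E3": 0.0, "E3E4": b4, "E4E4": 2 * b4,
    }
    model = TrueModel(snp_betas=betas, apoe_effect_by_genotype=apoe_effect,
                      intercept=config.intercept, snp_meta=meta, config=config)
    return model


def _draw_background_genotypes(rng: np.random.Generator, freqs: np.ndarray,
                               block_size: int, rho: float, n: int) -> np.ndarray:
    """True genotypes under block-AR(1) Gaussian-copula haplotypes."""
    m = len(freqs)
    thresh = norm.ppf(freqs)
    geno = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = rng.standard_normal((n, m))
        if rho > 0:
            scale = np.sqrt(1.0 - rho * rho)
            for j in range(1, m):
                if j % block_size != 0:  # block starts restart the chain
                    z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
        geno += (z < thresh[None, :]).astype(np.int8)
    return geno


def _draw_apoe(rng: np.random.Generator, freqs, n: int):
    """Returns (labels, e2_count, e4_count) for n samples."""
    alleles = rng.choice(3, size=(n, 2), p=list(freqs))  # 0=E2, 1=E3, 2=E4
    e2 = (alleles == 0).sum(axis=1)
    e4 = (alleles == 2).sum(axis=1)
    e3 = 2 - e2 - e4
    labels = np.empty(n, dtype=object)
    for lab, (c2, c3, c4) in {
        "E2E2": (2, 0, 0), "E2E3": (1, 1, 0), "E2E4": (1, 0, 1),
        "E3E3": (0, 2, 0), "E3E4": (0, 1, 1), "E4E4": (0, 0, 2),
    }.items():
        labels[(e2 == c2) & (e3 == c3) & (e4 == c4)] = lab
    return labels, e2, e4


def _liability_eta(model: TrueModel, g_bg: np.ndarray, labels: np.ndarray) -> np.ndarray:
    offsets = np.array([model.apoe_effect_by_genotype[l] for l in labels])
    return model.intercept + g_bg @ model.snp_betas[:-2] + offsets


def _draw_population(rng, model: TrueModel, n: int):
    cfg = model.config
    freqs = model.snp_meta["allele_freq_B"].to_numpy()
    g_bg = _draw_background_genotypes(rng, freqs[:-2], cfg.ld_block_size,
                                      cfg.ld_rho, n)
    labels, e2, e4 = _draw_apoe(rng, cfg.apoe_freqs, n)
    geno = np.column_stack([g_bg, e4, e2]).astype(np.int8)
    eta = _liability_eta(model, g_bg, labels)
    is_case = rng.random(n) < expit(eta)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    return geno, labels, is_case, sex


def _blur_to_probs(geno: np.ndarray, freqs: np.ndarray, info_targets: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Emit probability triples whose Info score tracks info_targets.

    Each sample/SNP entry is, with probability 1 - target, replaced by the
    Hardy-Weinberg prior triple (zero dosage information); otherwise the exact
    genotype indicator is kept.  The resulting ratio of observed to expected
    dosage variance is approximately the target.
    """
    n, m = geno.shape
    onehot = np.zeros((n, m, 3))
    ii, jj = np.meshgrid(np.arange(n), np.arange(m), indexing="ij")
    onehot[ii, jj, geno] = 1.0
    q = 1.0 - freqs
    hwe = np.stack([q * q, 2 * freqs * q, freqs * freqs], axis=1)  # (m, 3)
    blur = rng.random((n, m)) < (1.0 - info_targets)[None, :]
    return np.where(blur[:, :, None], hwe[None, :, :], onehot)


def _realized_info(probs: np.ndarray) -> np.ndarray:
    e = probs[:, :, 1] + 2.0 * probs[:, :, 2]
    p = e.mean(axis=0) / 2.0
    denom = 2.0 * p * (1.0 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        info = np.where(denom > 0, e.var(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(info, 0.0, 1.05)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

MAX_DRAW_FACTOR = 200


def simulate_cohort(config: SimulationConfig):
    """Simulate a case/control cohort.

    Returns ``(GenotypeProbabilityMatrix, SampleTable, TrueModel)``.  Case and
    control quotas are filled by rejection sampling from the population model;
    if the quotas cannot be met within ``MAX_DRAW_FACTOR * (n_cases +
    n_controls)`` population draws a RuntimeError names that bound.
    """
    rng = np.random.default_rng(config.seed)
    model = _build_model(config, rng)
    n_target = config.n_cases + config.n_controls
    max_draws = max(50_000, MAX_DRAW_FACTOR * n_target)

    need_cases, need_controls = config.n_cases, config.n_controls
    kept_geno, kept_rows = [], []
    drawn = 0
    while need_cases > 0 or need_controls > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"simulate_cohort: could not reach n_cases={config.n_cases}, "
                f"n_controls={config.n_controls} within {max_draws} population draws"
            )
        batch = int(min(4096, max_draws - drawn))
        geno, labels, is_case, sex = _draw_population(rng, model, batch)
        drawn += batch
        for i in range(batch):
            if is_case[i] and need_cases > 0:
                need_cases -= 1
            elif (not is_case[i]) and need_controls > 0:
                need_controls -= 1
            else:
                continue
            kept_geno.append(geno[i])
            kept_rows.append((labels[i], bool(is_case[i]), sex[i]))
        # fast exit once both quotas filled mid-batch is handled by the loop guard

    geno = np.vstack(kept_geno)
    records = [
        SampleRecord(
            sample_id=f"S{i + 1:06d}",
            sex=row[2],
            status="case" if row[1] else "control",
            apoe_genotype=row[0],
        )
        for i, row in enumerate(kept_rows)
    ]
    samples = make_sample_table(records)

    freqs = model.snp_meta["allele_freq_B"].to_numpy()
    info_targets = rng.uniform(config.info_range[0], config.info_range[1],
                               size=config.n_snps)
    probs = _blur_to_probs(geno, freqs, info_targets, rng)
    meta = model.snp_meta.copy()
    meta["info_score"] = _realized_info(probs)
    matrix = GenotypeProbabilityMatrix(probs=probs, snp_meta=meta[SNP_META_COLUMNS
                                                                 + ["allele_freq_B"]],
                                       sample_ids=list(samples["sample_id"]))
    logger.info("simulate_cohort: %d cases, %d controls, %d SNPs (%d population draws)",
                config.n_cases, config.n_controls, config.n_snps, drawn)
    return matrix, samples, model


def simulate_discovery_sumstats(config: SimulationConfig, model: TrueModel,
                                test_cohort: tuple[pd.DataFrame, HardCallMatrix] | None = None,
                                ) -> pd.DataFrame:
    """Simulate a discovery GWAS and return its summary-statistic table.

    When ``test_cohort`` (SampleTable, HardCallMatrix) is supplied and
    ``config.overlap_fraction > 0``, that fraction of test samples is re-used
    verbatim in the discovery sample; the remainder are fresh population
    draws.  Per-SNP logistic regression (intercept + dosage) yields BETA, SE
    and Wald P for the alleleB effect.  Monomorphic or non-converged SNPs are
    flagged ``ok=False`` with NaN SE (excluded downstream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    g_parts, y_parts = [], []
    n_overlap = 0
    if test_cohort is not None and config.overlap_fraction > 0:
        samples, hard = test_cohort
        n_test = len(samples)
        n_overlap = int(round(config.overlap_fraction * n_test))
        if n_overlap > config.discovery_n:
            raise ValueError("overlap exceeds discovery_n")
        idx = np.sort(rng.choice(n_test, size=n_overlap, replace=False))
        g_parts.append(hard.dosage[idx])
        y_parts.append((samples["status"].to_numpy() == "case")[idx].astype(float))
    n_fresh = config.discovery_n - n_overlap
    if n_fresh > 0:
        geno, labels, is_case, _sex = _draw_population(rng, model, n_fresh)
        g_parts.append(geno.astype(float))
        y_parts.append(is_case.astype(float))
    G = np.vstack(g_parts)
    y = np.concatenate(y_parts)
    if y.min() == y.max():
        raise RuntimeError("discovery sample contains a single phenotype class")

    fit = batch_snp_logistic(G, y)
    meta = model.snp_meta
    out = pd.DataFrame({
        "SNP": meta["snp_id"],
        "CHR": meta["chrom"],
        "BP": meta["pos"],
        "A1": meta["alleleB"],
        "A2": meta["alleleA"],
        "BETA": fit["beta"],
        "SE": fit["se"],
        "P": fit["pvalue"],
        "ok": fit["converged"],
    })
    n_bad = int((~out["ok"]).sum())
    if n_bad:
        logger.info("simulate_discovery_sumstats: %d untestable SNPs flagged", n_bad)
    return out
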