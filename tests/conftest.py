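import numpy as np
import pandas as pd
import pytest

from prstrat.genio import (GenotypeProbabilityMatrix, HardCallMatrix,
                           SNP_META_COLUMNS, hard_call)
from prstrat.simulate import SimulationConfig, simulate_cohort


def make_meta(n, chrom="1", start=10_000, spacing=10_000, info=1.0):
    return pd.DataFrame({
        "snp_id": [f"rs{i + 1}" for i in range(n)],
        "chrom": [chrom] * n,
        "pos": [start + spacing * i for i in range(n)],
        "alleleA": ["A"] * n,
        "alleleB": ["G"] * n,
        "info_score": [info] * n,
    })


def probs_from_dosage(dosage):
    """Exact probability triples from an integer dosage matrix (NaN allowed)."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    probs = np.full((n, m, 3), 1.0 / 3.0)
    for i in range(n):
        for j in range(m):
            if np.isfinite(dosage[i, j]):
                probs[i, j] = 0.0
                probs[i, j, int(dosage[i, j])] = 1.0
    return probs


def hardcalls_from_dosage(dosage, meta=None, sample_ids=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    meta = meta if meta is not None else make_meta(m)
    ids = sample_ids if sample_ids is not None else [f"S{i + 1}" for i in range(n)]
    return HardCallMatrix(dosage=dosage, snp_meta=meta, sample_ids=ids)


def gpm_from_probs(probs, meta=None, sample_ids=None):
    probs = np.asarray(probs, dtype=float)
    n, m = probs.shape[:2]
    meta = meta if meta is not None else make_meta(m)
    ids = sample_ids if sample_ids is not None else [f"S{i + 1}" for i in range(n)]
    return GenotypeProbabilityMatrix(probs=probs, snp_meta=meta, sample_ids=ids)


def sumstats_frame(snp_ids, betas, pvals, meta=None, ses=None):
    n = len(snp_ids)
    meta = meta if meta is not None else make_meta(n)
    meta = meta.set_index("snp_id").loc[list(snp_ids)].reset_index()
    return pd.DataFrame({
        "SNP": snp_ids,
        "CHR": meta["chrom"],
        "BP": meta["pos"],
        "A1": meta["alleleB"],
        "A2": meta["alleleA"],
        "BETA": betas,
        "SE": ses if ses is not None else [0.1] * n,
        "P": pvals,
        "ok": True,
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A modest causal cohort shared across read-only tests."""
    cfg = SimulationConfig(n_cases=400, n_controls=400, n_snps=250, n_causal=40,
                           effect_sd=0.15, ld_rho=0.4, seed=42)
    matrix, samples, model = simulate_cohort(cfg)
    return cfg, matrix, samples, model


@pytest.fixture(scope="session")
def small_hardcalls(small_cohort):
    _, matrix, _, _ = small_cohort
    return hard_call(matrix)
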