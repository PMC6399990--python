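"""APOE genotype classification and cohort stratification.

Genotypes are classified from unphased dosages of the two APOE-defining
SNPs.  Haplotype key: (rs429358, rs7412) = (T,T) -> E2, (T,C) -> E3,
(C,C) -> E4; the (C,T) haplotype is rare and any dosage combination
requiring it — notably the double heterozygote — is reported indeterminate.
"""
from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

INDETERMINATE = "indeterminate"
STRATA = ("all", "non_E4", "E3E3", "E4_carriers", "E4orE2_carriers")

def classify_apoe(rs429358_dosage: int, rs7412_dosage: int) -> str:
    """APOE genotype from C-allele dosage at rs429358 and T-allele dosage at
    rs7412; returns one of the six labels or ``indeterminate``."""
    d1, d2 = int(rs429358_dosage), int(rs7412_dosage)
    if d1 not in (0, 1, 2) or d2 not in (0, 1, 2):
        raise ValueError("dosages must be in {0,1,2}")
    if d1 == 1 and d2 == 1:
        return INDETERMINATE  # E2E4 vs E1/E3 phase ambiguity
    e4, e2 = d1, d2
    e3 = 2 - e4 - e2
    if e3 < 0:
        return INDETERMINATE  # would require a C,T (E1/rare) haplotype
    counts = {"E2": e2, "E3": e3, "E4": e4}
    alleles = sorted(a for a, c in counts.items() for _ in range(c))
    return alleles[0] + alleles[1]


def _has(genotype: str, allele: str) -> bool:
    return allele in (genotype[:2], genotype[2:])


def subset_stratum(samples: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Subset a sample table to one APOE stratum.

    Samples with missing or indeterminate genotype are excluded from every
    stratum except ``all``, with a logged count.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    if stratum == "all":
        return samples.copy()
    geno = samples["apoe_genotype"]
    known = geno.notna() & (geno != INDETERMINATE)
    n_excluded = int((~known).sum())
    if n_excluded:
        logger.info("subset_stratum(%s): %d samples without determinate APOE excluded",
                    stratum, n_excluded)
    g = geno.where(known, "")
    if stratum == "non_E4":
        keep = known & ~g.str.contains("E4")
    elif stratum == "E3E3":
        keep = known & (g == "E3E3")
    elif stratum == "E4_carriers":
        keep = known & g.str.contains("E4")
    else:  # E4orE2_carriers
        keep = known & (g.str.contains("E4") | g.str.contains("E2"))
    out = samples.loc[keep].copy()
    n_case = int((out["status"] == "case").sum())
    logger.info("subset_stratum(%s): %d cases, %d controls",
                stratum, n_case, len(out) - n_case)
    return out
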