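"""Quality-control filters for SNP panels.

Defaults follow common genotyping practice for candidate-gene panels:
minor allele frequency >= 1%, Hardy-Weinberg equilibrium in controls at
p >= 0.05, and pairwise LD pruning at r^2 <= 0.1 (the later SNP of an
offending pair is dropped, keeping panel order deterministic).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import hwe_test
from .datamodel import (
    CONTROL,
    MISSING,
    DegenerateInputError,
    GenotypeDataset,
    marginal_counts,
)


def minor_allele_frequency(ds: GenotypeDataset, snp: str) -> float:
    """Frequency of the rarer allele over all complete calls of ``snp``."""
    g = ds.genotypes[snp].to_numpy()
    g = g[g != MISSING]
    if g.size == 0:
        raise DegenerateInputError(f"{snp}: no complete genotype calls")
    p_variant = g.sum() / (2.0 * g.size)
    return float(min(p_variant, 1.0 - p_variant))


def ld_r2(ds: GenotypeDataset, snpA: str, snpB: str) -> float:
    """Composite LD: squared Pearson correlation of 0/1/2 dosage codes."""
    mask = ds.complete_cases([snpA, snpB])
    if mask.sum() < 2:
        raise DegenerateInputError(f"fewer than 2 complete pairs for {snpA}/{snpB}")
    a = ds.genotypes[snpA].to_numpy()[mask].astype(float)
    b = ds.genotypes[snpB].to_numpy()[mask].astype(float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError(
            f"LD undefined: monomorphic SNP among {snpA}/{snpB}"
        )
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def qc_filter(
    ds: GenotypeDataset,
    maf_min: float = 0.01,
    hwe_alpha: float = 0.05,
    ld_r2_max: float = 0.1,
    hwe_method: str = "chi2",
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Drop SNPs failing MAF, control-HWE or LD thresholds.

    HWE is tested in controls only (deviation there flags genotyping error;
    cases may deviate through true association). LD pruning walks pairs in
    panel order and drops the later SNP of any pair with r^2 above the
    threshold. Returns the filtered dataset and a per-SNP report
    (snp, maf, hwe_p, max_r2, kept, reason).
    """
    rows = []
    kept: list[str] = []
    for snp in ds.snps:
        maf = minor_allele_frequency(ds, snp)
        t = marginal_counts(ds, snp)
        n0, n1, n2 = (int(x) for x in t.counts[CONTROL])
        _, hwe_p = hwe_test(n0, n1, n2, method=hwe_method)
        reason = ""
        if maf < maf_min:
            reason = "MAF"
        elif hwe_p < hwe_alpha:
            reason = "HWE"
        max_r2 = float("nan")
        if not reason:
            for prev in kept:
                try:
                    r2 = ld_r2(ds, prev, snp)
                except DegenerateInputError:
                    continue
                if np.isnan(max_r2) or r2 > max_r2:
                    max_r2 = r2
                if r2 > ld_r2_max:
                    reason = f"LD({prev})"
                    break
        if not reason:
            kept.append(snp)
        rows.append(
            {
                "snp": snp,
                "maf": maf,
                "hwe_p": hwe_p,
                "max_r2": max_r2,
                "kept": not reason,
                "reason": reason,
            }
        )
    report = pd.DataFrame(rows)
    return ds.subset(snps=kept), report
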