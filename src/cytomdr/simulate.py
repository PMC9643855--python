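"""Synthetic case-control cohort generation with known genetic architecture.

Two complementary generators:

* :func:`resample_from_marginals` — rebuilds subject-level data whose
  per-SNP, per-class genotype counts equal a published count table exactly
  (SNPs independent conditional on class; the true joint distribution is
  not recoverable from marginals).
* :func:`simulate_cohort` — samples individuals genotype-first under
  Hardy-Weinberg equilibrium and a k-locus penetrance table, ascertaining
  by rejection until the case and control quotas fill. Penetrance tables
  (e.g. :func:`xor_penetrance`) give full control of marginal and epistatic
  effect sizes.

Clinical covariates are attached per class: normal variables from mean/SD,
right-skewed laboratory values from a log-normal matched by least squares to
the published median and quartiles, sex as Bernoulli.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    CASE,
    CONTROL,
    GenotypeCountTable,
    GenotypeDataset,
    SNPDescriptor,
    ValidationError,
)

_Z75 = stats.norm.ppf(0.75)  # 0.67449


@dataclass(frozen=True)
class PenetranceModel:
    """Disease probability for every k-locus genotype combination.

    ``table`` has shape (3,)*k, indexed by dosage codes, entries in [0, 1].
    """

    snps: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        if table.shape != (3,) * len(self.snps):
            raise ValidationError(
                f"penetrance table shape {table.shape} != {(3,) * len(self.snps)}"
            )
        if (table < 0).any() or (table > 1).any():
            raise ValidationError("penetrance entries must lie in [0, 1]")
        object.__setattr__(self, "table", table)
        object.__setattr__(self, "snps", tuple(self.snps))

    def prevalence(self, mafs: Sequence[float]) -> float:
        """Population disease prevalence under HWE at the given MAFs."""
        prob = 1.0
        weights = [
            np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2]) for m in mafs
        ]
        total = 0.0
        for combo in itertools.product(range(3), repeat=len(self.snps)):
            w = 1.0
            for g, wv in zip(combo, weights):
                w *= wv[g]
            total += w * self.table[combo]
        return total


@dataclass
class CohortSpec:
    """Design of a simulated case-control cohort.

    ``mafs`` maps every panel SNP to its minor-allele frequency in (0, 0.5];
    ``covariate_params`` follows :func:`cytomdr.panel.reference_covariate_params`
    (may be empty for genotype-only cohorts).
    """

    n_cases: int
    n_controls: int
    mafs: Mapping[str, float]
    covariate_params: Mapping[str, dict] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls == 0:
            raise ValidationError("class quotas must be non-negative and not both zero")
        for rsid, m in self.mafs.items():
            if not 0 <= m <= 0.5:
                raise ValidationError(f"{rsid}: MAF {m} outside [0, 0.5]")


def sample_genotypes_hwe(maf: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. dosage draws under HWE: P(0,1,2) = ((1-q)^2, 2q(1-q), q^2)."""
    if not 0 <= maf <= 0.5:
        raise ValidationError(f"MAF {maf} outside [0, 0.5]")
    # sum of two Bernoulli(maf) allele draws
    return rng.binomial(2, maf, size=n).astype(np.int8)


def uniform_penetrance(snps: Sequence[str], p: float = 0.5) -> PenetranceModel:
    """Null model: every genotype combination has disease probability ``p``."""
    snps = tuple(snps)
    return PenetranceModel(snps, np.full((3,) * len(snps), p))


def xor_penetrance(
    snpA: str, snpB: str, p_high: float, p_low: float
) -> PenetranceModel:
    """Canonical pure-epistasis model on two loci.

    Disease probability is ``p_high`` when exactly one locus is heterozygous
    and ``p_low`` otherwise. At MAF 0.5 on both loci every single-locus
    genotype has the same marginal penetrance, so neither SNP shows a
    marginal effect while the pair is strongly predictive.
    """
    if not 0 <= p_low <= p_high <= 1:
        raise ValidationError("need 0 <= p_low <= p_high <= 1")
    table = np.full((3, 3), p_low)
    for ga in range(3):
        for gb in range(3):
            if (ga == 1) != (gb == 1):
                table[ga, gb] = p_high
    return PenetranceModel((snpA, snpB), table)


def simulate_cohort(
    spec: CohortSpec,
    model: PenetranceModel | None = None,
    background_snps: int = 0,
    background_maf: float = 0.3,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000_000,
) -> GenotypeDataset:
    """Rejection-sample a case-control cohort under HWE and a penetrance model.

    Individuals are drawn genotype-first (independent SNPs), disease status
    via the penetrance table, and kept while their class quota is open.
    SNPs outside the model (and any appended ``background_snps``) have no
    effect on status. Covariates, if specified, are attached per class
    afterwards. Raises after ``max_attempts`` draws if a quota cannot fill
    (e.g. penetrance identically 0 with a nonzero case quota).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    snp_names = list(spec.mafs.keys()) + [
        f"null{i + 1}" for i in range(background_snps)
    ]
    mafs = list(spec.mafs.values()) + [background_maf] * background_snps
    if model is None:
        model = uniform_penetrance(snp_names[:1] or ["null1"], 0.5)
    model_idx = []
    for s in model.snps:
        if s not in snp_names:
            raise ValidationError(f"penetrance model SNP {s!r} not in cohort spec")
        model_idx.append(snp_names.index(s))

    need = {CASE: spec.n_cases, CONTROL: spec.n_controls}
    kept_geno: list[np.ndarray] = []
    kept_status: list[np.ndarray] = []
    drawn = 0
    while need[CASE] > 0 or need[CONTROL] > 0:
        if drawn >= max_attempts:
            raise RuntimeError(
                f"ascertainment failed: {need} still open after {drawn} draws"
            )
        batch = int(min(max(1024, 4 * (need[CASE] + need[CONTROL])), max_attempts - drawn))
        drawn += batch
        geno = np.column_stack(
            [sample_genotypes_hwe(m, batch, rng) for m in mafs]
        )
        risk = model.table[tuple(geno[:, j] for j in model_idx)]
        disease = (rng.random(batch) < risk).astype(np.int8)
        for cls in (CONTROL, CASE):
            if need[cls] <= 0:
                continue
            take = np.flatnonzero(disease == cls)[: need[cls]]
            kept_geno.append(geno[take])
            kept_status.append(np.full(len(take), cls, dtype=np.int8))
            need[cls] -= len(take)

    geno = np.concatenate(kept_geno) if kept_geno else np.empty((0, len(snp_names)), np.int8)
    status = np.concatenate(kept_status) if kept_status else np.empty(0, np.int8)
    order = np.argsort(status, kind="stable")  # controls first, stable within class
    geno, status = geno[order], status[order]
    subjects = [f"sub{i:05d}" for i in range(len(status))]
    gdf = pd.DataFrame(geno, index=subjects, columns=snp_names)
    covariates = None
    if spec.covariate_params:
        covariates = simulate_covariates(spec, status, rng)
        covariates.index = subjects
    return GenotypeDataset(gdf, status, covariates=covariates)


def resample_from_marginals(
    tables: Sequence[GenotypeCountTable], rng: np.random.Generator | None = None
) -> GenotypeDataset:
    """Subject-level dataset whose per-class marginal counts are exact.

    For each class and SNP independently, the genotype column is a random
    permutation of the exact multiset given by the counts, so
    ``marginal_counts`` recovers every input integer for any seed. Across
    SNPs the joint distribution is independent conditional on class.
    """
    rng = np.random.default_rng() if rng is None else rng
    sizes = {(t.n_controls, t.n_cases) for t in tables}
    if len(sizes) != 1:
        raise ValidationError(f"inconsistent class sizes across tables: {sizes}")
    n_controls, n_cases = sizes.pop()
    columns: dict[str, np.ndarray] = {}
    for t in tables:
        parts = []
        for cls, size in ((CONTROL, n_controls), (CASE, n_cases)):
            n0, n1, n2 = (int(x) for x in t.counts[cls])
            col = np.repeat(np.array([0, 1, 2], dtype=np.int8), [n0, n1, n2])
            parts.append(rng.permutation(col))
        columns[t.snp.rsid] = np.concatenate(parts)
    subjects = [f"ctrl{i:04d}" for i in range(n_controls)] + [
        f"case{i:04d}" for i in range(n_cases)
    ]
    status = np.array([CONTROL] * n_controls + [CASE] * n_cases, dtype=np.int8)
    gdf = pd.DataFrame(columns, index=subjects)
    return GenotypeDataset(gdf, status, panel=[t.snp for t in tables])


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def lognormal_from_quartiles(
    median: float, q1: float, q3: float
) -> tuple[float, float]:
    """(mu, sigma) of a log-normal fitted by least squares to three quartiles.

    The three log-quantiles are regressed on the standard-normal quantiles
    (-z75, 0, z75); with symmetric design points mu is the mean log-quantile
    and sigma = log(q3/q1) / (2 z75). Matching all three approximately keeps
    every implied quartile close to the printed one, which an exact
    two-point fit cannot guarantee.
    """
    if not (q1 < median < q3):
        raise ValidationError(f"quartiles must satisfy q1 < median < q3, got {(q1, median, q3)}")
    logs = np.log([q1, median, q3])
    mu = float(logs.mean())
    sigma = float((logs[2] - logs[0]) / (2 * _Z75))
    return mu, sigma


def simulate_covariates(
    spec: CohortSpec, status: Sequence[int], rng: np.random.Generator
) -> pd.DataFrame:
    """Draw the covariate table for the given status vector, class by class."""
    status = np.asarray(status)
    n = len(status)
    out: dict[str, np.ndarray] = {}
    for name, params in spec.covariate_params.items():
        kind = params["kind"]
        col = np.empty(n, dtype=float)
        for cls, key in ((CONTROL, "control"), (CASE, "case")):
            mask = status == cls
            m = int(mask.sum())
            if m == 0:
                continue
            if key not in params:
                raise ValidationError(f"covariate {name!r}: no parameters for {key}")
            p = params[key]
            if kind == "normal":
                mean, sd = p
                if sd < 0:
                    raise ValidationError(f"covariate {name!r}: negative SD")
                col[mask] = rng.normal(mean, sd, size=m) if sd > 0 else mean
            elif kind == "lognormal":
                mu, sigma = lognormal_from_quartiles(*p)
                col[mask] = rng.lognormal(mu, sigma, size=m)
            elif kind == "binary":
                col[mask] = (rng.random(m) < p).astype(float)
            else:
                raise ValidationError(f"covariate {name!r}: unknown kind {kind!r}")
        out[name] = col
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# clinical helpers
# ---------------------------------------------------------------------------

def ldl_friedewald(
    total_chol: float, hdl: float, trig: float, variant: str = "friedewald"
) -> float:
    """Estimated LDL cholesterol (mg/dL) from the standard lipid panel.

    ``friedewald``: LDL = TC - HDL - TG/5. ``delong``: LDL = TC - HDL -
    0.16*TG. The Friedewald estimate is unreliable above 400 mg/dL
    triglycerides (a warning is emitted).
    """
    if min(total_chol, hdl, trig) < 0:
        raise ValueError("lipid inputs must be non-negative")
    if variant == "friedewald":
        if trig >= 400:
            import warnings

            warnings.warn(
                "Friedewald LDL is unreliable at triglycerides >= 400 mg/dL",
                stacklevel=2,
            )
        return total_chol - hdl - trig / 5.0
    if variant == "delong":
        return total_chol - hdl - 0.16 * trig
    raise ValueError(f"unknown LDL formula variant {variant!r}")


def bmi_class(bmi: float) -> str:
    """BMI category: <25 normal, [25, 30) overweight, >=30 obese."""
    if bmi <= 0:
        raise ValueError("BMI must be positive")
    if bmi < 25:
        return "normal"
    if bmi < 30:
        return "overweight"
    return "obese"
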