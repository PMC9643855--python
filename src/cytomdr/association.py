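"""Single-SNP case-control association under inheritance models.

For each SNP the 2x3 genotype count table is collapsed into 2x2 tables under
five inheritance models and scored by odds ratio with a Wald 95% CI and a
two-sided Fisher exact p. The exposure group is fixed per model:

==================  ================================================
codominant_het      heterozygote vs common homozygote
codominant_hom      variant homozygote vs common homozygote
dominant            common homozygote vs carrier of the variant
recessive           variant homozygote vs the rest
overdominant        heterozygote vs both homozygotes
additive            variant allele vs common allele (alleles as units)
==================  ================================================

A single orientation per model keeps results reproducible; a published OR
computed the other way round is simply the reciprocal. Covariate-adjusted
odds ratios come from logistic regression (:func:`adjusted_model_or`) and
are flagged as such; the crude scan is the primary reproduction path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .datamodel import (
    CASE,
    CONTROL,
    MISSING,
    DegenerateInputError,
    GenotypeCountTable,
    GenotypeDataset,
)

Z95 = stats.norm.ppf(0.975)

CRUDE_MODELS = (
    "codominant_het",
    "codominant_hom",
    "dominant",
    "recessive",
    "overdominant",
    "additive",
)

#: Model families for AIC selection (codominant is a single 2-df fit).
AIC_MODEL_ORDER = ("codominant", "dominant", "recessive", "overdominant", "additive")


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 count table: a/b = exposed/unexposed cases, c/d = controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")

    def swapped(self) -> "TwoByTwo":
        return TwoByTwo(self.b, self.a, self.d, self.c)


@dataclass
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied


@dataclass
class AssociationResult:
    snp: str
    model: str
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    aic: float | None = None
    adjusted: bool = False
    covariates: tuple[str, ...] = ()
    n_used: int | None = None
    separation: bool = False


# ---------------------------------------------------------------------------
# allele frequencies and HWE
# ---------------------------------------------------------------------------

def allele_frequencies(t: GenotypeCountTable) -> pd.DataFrame:
    """Per-class allele counts and percentages.

    Common allele count = 2*n0 + n1, variant = 2*n2 + n1; percentages are of
    twice the class size. Raises on an empty class.
    """
    rows = []
    for cls, name in ((CONTROL, "control"), (CASE, "case")):
        n0, n1, n2 = (int(x) for x in t.counts[cls])
        total = 2 * (n0 + n1 + n2)
        if total == 0:
            raise DegenerateInputError(f"{t.snp.rsid}: empty {name} class")
        common = 2 * n0 + n1
        variant = 2 * n2 + n1
        rows.append((name, t.snp.ref_allele, common, 100.0 * common / total))
        rows.append((name, t.snp.alt_allele, variant, 100.0 * variant / total))
    return pd.DataFrame(rows, columns=["class", "allele", "count", "pct"])


def hwe_test(n0: int, n1: int, n2: int, method: str = "chi2") -> tuple[float | None, float]:
    """Test genotype counts against Hardy-Weinberg proportions.

    ``chi2``: 1-df Pearson statistic against the expected counts implied by
    the observed allele frequency. ``exact``: conditional exact test that
    enumerates all heterozygote counts compatible with the observed allele
    counts (two-sided by summing tables no more probable than the observed
    one; no mid-p). A monomorphic SNP returns p = 1 by convention.
    """
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("empty genotype table")
    p = (2 * n0 + n1) / (2.0 * n)
    if p in (0.0, 1.0):
        return (0.0, 1.0) if method == "chi2" else (None, 1.0)
    if method == "chi2":
        q = 1.0 - p
        expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
        observed = np.array([n0, n1, n2], dtype=float)
        stat = float(((observed - expected) ** 2 / expected).sum())
        return stat, float(stats.chi2.sf(stat, df=1))
    if method == "exact":
        return None, _hwe_exact_p(n0, n1, n2)
    raise ValueError(f"unknown method {method!r}")


def _hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Exact HWE p by enumerating heterozygote counts given allele counts."""
    n = n0 + n1 + n2
    rare = min(2 * n0 + n1, 2 * n2 + n1)
    hets = np.arange(rare % 2, rare + 1, 2)
    # log P(n_het = h | n, rare) via the conditional multinomial formula
    n_rare_hom = (rare - hets) // 2
    n_common_hom = n - hets - n_rare_hom
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(n_rare_hom + 1)
        - gammaln(n_common_hom + 1)
    )
    logp -= np.logaddexp.reduce(logp)
    probs = np.exp(logp)
    obs = probs[hets == n1][0]
    return float(min(1.0, probs[probs <= obs * (1 + 1e-9)].sum()))


# ---------------------------------------------------------------------------
# odds ratios
# ---------------------------------------------------------------------------

def odds_ratio_2x2(t: TwoByTwo, haldane: bool = True) -> OddsRatioResult:
    """Odds ratio, Wald 95% CI and two-sided Fisher p for a 2x2 table.

    With a zero cell and ``haldane``, 0.5 is added to every cell before the
    OR and CI (Haldane-Anscombe); the Fisher p is always computed on the
    uncorrected counts.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a * d == 0 and b * c == 0:
        raise DegenerateInputError("odds ratio undefined: both diagonals contain zero")
    corrected = False
    if 0 in (a, b, c, d):
        if not haldane:
            raise DegenerateInputError("zero cell and Haldane correction disabled")
        a, b, c, d = (x + 0.5 for x in (t.a, t.b, t.c, t.d))
        corrected = True
    or_value = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci_low = or_value * np.exp(-Z95 * se)
    ci_high = or_value * np.exp(Z95 * se)
    _, p = stats.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return OddsRatioResult(float(or_value), float(ci_low), float(ci_high), float(p), corrected)


def inheritance_tables(
    t: GenotypeCountTable, model: str
) -> list[tuple[str, TwoByTwo]]:
    """Collapse a 2x3 genotype table into the model's 2x2 table(s).

    Returns ``[(label, table), ...]`` — two tables for ``codominant``, one
    otherwise. The exposure group is the first-named class of each model's
    definition (see module docstring).
    """
    c0, c1, c2 = (int(x) for x in t.counts[CONTROL])
    k0, k1, k2 = (int(x) for x in t.counts[CASE])
    if model == "codominant":
        return [
            ("codominant_het", TwoByTwo(k1, k0, c1, c0)),
            ("codominant_hom", TwoByTwo(k2, k0, c2, c0)),
        ]
    if model == "codominant_het":
        return [("codominant_het", TwoByTwo(k1, k0, c1, c0))]
    if model == "codominant_hom":
        return [("codominant_hom", TwoByTwo(k2, k0, c2, c0))]
    if model == "dominant":
        return [("dominant", TwoByTwo(k0, k1 + k2, c0, c1 + c2))]
    if model == "recessive":
        return [("recessive", TwoByTwo(k2, k0 + k1, c2, c0 + c1))]
    if model == "overdominant":
        return [("overdominant", TwoByTwo(k1, k0 + k2, c1, c0 + c2))]
    if model == "additive":
        return [
            (
                "additive",
                TwoByTwo(2 * k2 + k1, 2 * k0 + k1, 2 * c2 + c1, 2 * c0 + c1),
            )
        ]
    raise ValueError(f"unknown inheritance model {model!r}")


def crude_model_scan(t: GenotypeCountTable, haldane: bool = True) -> list[AssociationResult]:
    """Odds ratios under every inheritance model for one SNP (unadjusted)."""
    out = []
    n_used = t.n_cases + t.n_controls
    for model in ("codominant", "dominant", "recessive", "overdominant", "additive"):
        for label, table in inheritance_tables(t, model):
            res = odds_ratio_2x2(table, haldane=haldane)
            out.append(
                AssociationResult(
                    snp=t.snp.rsid,
                    model=label,
                    or_value=res.or_value,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    p=res.p,
                    n_used=n_used,
                )
            )
    return out


# ---------------------------------------------------------------------------
# adjusted (logistic) models
# ---------------------------------------------------------------------------

def _model_design(g: np.ndarray, model: str) -> tuple[np.ndarray, list[str], int]:
    """Design columns for the genotype term(s); returns (X, names, report_idx)."""
    if model == "codominant":
        X = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        return X, ["het", "hom"], 0
    if model == "codominant_het":
        X = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        return X, ["het", "hom"], 0
    if model == "codominant_hom":
        X = np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])
        return X, ["het", "hom"], 1
    if model == "dominant":
        return (g == 0).astype(float)[:, None], ["common_hom"], 0
    if model == "recessive":
        return (g == 2).astype(float)[:, None], ["variant_hom"], 0
    if model == "overdominant":
        return (g == 1).astype(float)[:, None], ["het"], 0
    if model == "additive":
        return g.astype(float)[:, None], ["dose"], 0
    raise ValueError(f"unknown inheritance model {model!r}")


def _fit_logistic(
    ds: GenotypeDataset, snp: str, model: str, covariates: Sequence[str]
):
    import statsmodels.api as sm

    mask = ds.complete_cases([snp])
    g = ds.genotypes[snp].to_numpy()[mask]
    y = ds.status.to_numpy()[mask].astype(float)
    X, names, report_idx = _model_design(g, model)
    cols = [X]
    for cov in covariates:
        if ds.covariates is None or cov not in ds.covariates.columns:
            raise ValueError(f"covariate {cov!r} not in dataset")
        v = pd.to_numeric(ds.covariates[cov]).to_numpy()[mask]
        cols.append(v[:, None].astype(float))
        names = names + [cov]
    design = np.column_stack(cols)
    keep = ~np.isnan(design).any(axis=1)
    design, y = design[keep], y[keep]
    geno_cols = design[:, : X.shape[1]]
    if np.ptp(geno_cols[:, report_idx]) == 0:
        raise DegenerateInputError(f"{snp}: genotype term constant under model {model!r}")
    design = sm.add_constant(design, has_constant="add")
    n_params = design.shape[1]
    if len(y) < 10 * n_params:
        warnings.warn(
            f"{snp}/{model}: only {len(y)} complete cases for {n_params} parameters",
            stacklevel=3,
        )
    fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    return fit, names, report_idx, int(len(y))


def adjusted_model_or(
    ds: GenotypeDataset,
    snp: str,
    model: str,
    covariates: Sequence[str] = (),
) -> AssociationResult:
    """Covariate-adjusted odds ratio via logistic regression.

    Fits status ~ genotype-term(s) + covariates; the reported OR is
    exp(coefficient) of the model's genotype term, with Wald CI and p, and
    the fit's AIC. Quasi-separation yields a flagged result with undefined
    CI rather than a silent fallback.
    """
    import statsmodels.tools.sm_exceptions as sme

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sme.PerfectSeparationWarning)
            fit, names, idx, n_used = _fit_logistic(ds, snp, model, covariates)
        beta_chk = fit.params[idx + 1]
        se_chk = fit.bse[idx + 1]
        separated = (
            not fit.mle_retvals.get("converged", True)
            or not np.isfinite(se_chk)
            or abs(beta_chk) > 15
            or se_chk > 100
        )
    except (sme.PerfectSeparationError, sme.PerfectSeparationWarning):
        return AssociationResult(
            snp=snp, model=model, or_value=float("nan"), ci_low=float("nan"),
            ci_high=float("nan"), p=float("nan"), adjusted=True,
            covariates=tuple(covariates), separation=True,
        )
    coef_idx = idx + 1  # constant first
    beta = fit.params[coef_idx]
    se = fit.bse[coef_idx]
    if separated:
        return AssociationResult(
            snp=snp, model=model, or_value=float(np.exp(beta)), ci_low=float("nan"),
            ci_high=float("nan"), p=float("nan"), aic=float(fit.aic), adjusted=True,
            covariates=tuple(covariates), n_used=n_used, separation=True,
        )
    return AssociationResult(
        snp=snp,
        model=model,
        or_value=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p=float(fit.pvalues[coef_idx]),
        aic=float(fit.aic),
        adjusted=True,
        covariates=tuple(covariates),
        n_used=n_used,
    )


def select_best_model_aic(
    ds: GenotypeDataset, snp: str, covariates: Sequence[str] = ()
) -> str:
    """Best-fitting inheritance model by minimum AIC of the logistic fit.

    The codominant family is one 2-df fit. Ties break by the fixed order
    codominant, dominant, recessive, overdominant, additive.
    """
    aics: dict[str, float] = {}
    for model in AIC_MODEL_ORDER:
        try:
            res = adjusted_model_or(ds, snp, model, covariates)
        except DegenerateInputError:
            continue
        if res.aic is not None and not res.separation:
            aics[model] = res.aic
    if len(aics) < 2:
        raise DegenerateInputError(f"{snp}: fewer than two inheritance models converged")
    best = min(AIC_MODEL_ORDER, key=lambda m: (aics.get(m, np.inf)))
    return best


# ---------------------------------------------------------------------------
# exact 2x3 test, multiple testing
# ---------------------------------------------------------------------------

def fisher_genotype_test(t: GenotypeCountTable) -> float:
    """Two-sided Fisher exact test of the 2x3 genotype table.

    Enumerates all tables with the observed margins; p is the total
    probability of tables no more probable than the observed one.
    """
    return _fisher_exact_2x3(t.counts)


def _fisher_exact_2x3(counts: np.ndarray) -> float:
    counts = np.asarray(counts, dtype=np.int64)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    n = counts.sum()
    if n == 0 or row.min() == 0:
        return 1.0

    def log_table_prob(x0: np.ndarray, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        # P(table) = prod_j C(col_j, x_j) / C(n, row_0)
        res = (
            gammaln(col[0] + 1) - gammaln(x0 + 1) - gammaln(col[0] - x0 + 1)
            + gammaln(col[1] + 1) - gammaln(x1 + 1) - gammaln(col[1] - x1 + 1)
            + gammaln(col[2] + 1) - gammaln(x2 + 1) - gammaln(col[2] - x2 + 1)
            - (gammaln(n + 1) - gammaln(row[0] + 1) - gammaln(n - row[0] + 1))
        )
        return res

    obs = log_table_prob(*(np.asarray([v]) for v in counts[0]))[0]
    x0 = np.arange(0, min(col[0], row[0]) + 1)
    total = 0.0
    for v0 in x0:
        x1 = np.arange(0, min(col[1], row[0] - v0) + 1)
        x2 = row[0] - v0 - x1
        valid = (x2 >= 0) & (x2 <= col[2])
        if not valid.any():
            continue
        lp = log_table_prob(np.full(valid.sum(), v0), x1[valid], x2[valid])
        total += float(np.exp(lp[lp <= obs + 1e-9]).sum())
    return float(min(1.0, total))


def bonferroni(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m)."""
    p = np.asarray(pvals, dtype=float)
    return np.minimum(1.0, p * p.size)


def association_report(
    tables: Sequence[GenotypeCountTable], haldane: bool = True
) -> pd.DataFrame:
    """Crude scan of every SNP, with Bonferroni-adjusted genotype-test p."""
    rows = []
    fisher_ps = [fisher_genotype_test(t) for t in tables]
    fisher_adj = bonferroni(fisher_ps)
    for t, fp, fadj in zip(tables, fisher_ps, fisher_adj):
        for res in crude_model_scan(t, haldane=haldane):
            rows.append(
                {
                    "snp": res.snp,
                    "gene": t.snp.gene,
                    "model": res.model,
                    "or": res.or_value,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "fisher_genotype_p": fp,
                    "fisher_genotype_p_bonferroni": fadj,
                    "n_used": res.n_used,
                }
            )
    return pd.DataFrame(rows)
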