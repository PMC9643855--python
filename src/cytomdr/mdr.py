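"""Multifactor dimensionality reduction (MDR) for case-control epistasis.

MDR pools the cells of a k-locus genotype table into a binary high/low-risk
attribute: a cell is high risk when its case:control ratio, each count
normalised by its class total, exceeds a threshold T (default 1.05; the
classic variant uses T = 1). The pooled attribute is scored by balanced
accuracy under stratified 10-fold cross-validation; the best combination
per fold is the one with minimal training classification error, and
cross-validation consistency counts how many folds agree on the modal
winner.

Covariates are never used: the engine sees genotype attributes and class
labels only. Significance comes from a label-permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .association import OddsRatioResult, TwoByTwo, odds_ratio_2x2
from .datamodel import (
    CASE,
    CONTROL,
    DegenerateInputError,
    GenotypeDataset,
    ValidationError,
)

HIGH, LOW, EMPTY = "high", "low", "empty"

DEFAULT_THRESHOLD = 1.05


@dataclass
class MDRCell:
    genotype_combo: tuple[int, ...]
    n_cases: int
    n_controls: int
    risk_label: str  # high / low / empty

    @property
    def ratio(self) -> float:
        """Normalised case:control ratio R (inf when controls empty)."""
        return self._ratio

    _ratio: float = field(default=float("nan"), repr=False)


@dataclass
class MDRModel:
    """A fitted k-locus MDR model (cells labelled on the full data)."""

    snps: tuple[str, ...]
    threshold: float
    cells: list[MDRCell]
    train_balanced_accuracy: float
    test_balanced_accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    cv_consistency: int | None = None
    n_folds: int | None = None
    classifier_odds: OddsRatioResult | None = None
    p_perm: float | None = None

    @property
    def cell_labels(self) -> np.ndarray:
        labels = np.zeros(3 ** len(self.snps), dtype=bool)
        for cell in self.cells:
            if cell.risk_label == HIGH:
                labels[_combo_index(cell.genotype_combo)] = True
        return labels


def _combo_index(combo: Sequence[int]) -> int:
    idx = 0
    for g in combo:
        idx = idx * 3 + int(g)
    return idx


def _cell_indices(geno: np.ndarray) -> np.ndarray:
    """Mixed-radix cell index for an (n, k) dosage matrix."""
    idx = np.zeros(len(geno), dtype=np.int64)
    for j in range(geno.shape[1]):
        idx = idx * 3 + geno[:, j]
    return idx


def _cell_counts(
    idx: np.ndarray, status: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    size = 3**k
    cases = np.bincount(idx[status == CASE], minlength=size)
    controls = np.bincount(idx[status == CONTROL], minlength=size)
    return cases, controls


def _high_mask(
    cases: np.ndarray, controls: np.ndarray, total_cases: int, total_controls: int, T: float
) -> np.ndarray:
    """High-risk labelling: R > T, with case-only cells high."""
    with np.errstate(divide="ignore", invalid="ignore"):
        num = cases / total_cases
        den = controls / total_controls
        ratio = num / den
    high = np.zeros(len(cases), dtype=bool)
    nonzero_ctrl = controls > 0
    high[nonzero_ctrl] = ratio[nonzero_ctrl] > T
    high[(controls == 0) & (cases > 0)] = True
    return high


def _balanced_accuracy(
    cases: np.ndarray, controls: np.ndarray, high: np.ndarray
) -> tuple[float, float, float]:
    total_cases = cases.sum()
    total_controls = controls.sum()
    if total_cases == 0 or total_controls == 0:
        raise DegenerateInputError("both classes required to score a classifier")
    sens = cases[high].sum() / total_cases
    spec = controls[~high].sum() / total_controls
    return (sens + spec) / 2.0, float(sens), float(spec)


def label_cells(
    ds: GenotypeDataset,
    snps: Sequence[str],
    T: float = DEFAULT_THRESHOLD,
) -> list[MDRCell]:
    """Label every k-locus genotype cell high/low/empty on the dataset.

    R = (cell cases / total cases) / (cell controls / total controls);
    high iff R > T; case-only cells are high; empty cells (no subject)
    stay ``empty``. Subjects missing any model SNP are excluded.
    """
    if T < 0:
        raise ValidationError("threshold must be non-negative")
    snps = list(snps)
    mask = ds.complete_cases(snps)
    geno = ds.genotypes[snps].to_numpy()[mask]
    status = ds.status.to_numpy()[mask]
    total_cases = int((status == CASE).sum())
    total_controls = int((status == CONTROL).sum())
    if total_cases == 0 or total_controls == 0:
        raise DegenerateInputError("both classes must be present")
    idx = _cell_indices(geno)
    cases, controls = _cell_counts(idx, status, len(snps))
    high = _high_mask(cases, controls, total_cases, total_controls, T)
    cells = []
    for i in range(3 ** len(snps)):
        combo = tuple(int(d) for d in np.base_repr(i, base=3).zfill(len(snps)))
        if cases[i] == 0 and controls[i] == 0:
            label, ratio = EMPTY, float("nan")
        else:
            label = HIGH if high[i] else LOW
            if controls[i] > 0:
                ratio = (cases[i] / total_cases) / (controls[i] / total_controls)
            else:
                ratio = float("inf")
        cells.append(
            MDRCell(
                genotype_combo=combo,
                n_cases=int(cases[i]),
                n_controls=int(controls[i]),
                risk_label=label,
                _ratio=ratio,
            )
        )
    return cells


def fit_mdr(
    ds: GenotypeDataset, snps: Sequence[str], T: float = DEFAULT_THRESHOLD
) -> MDRModel:
    """Fit an MDR model on the full dataset (no cross-validation)."""
    snps = tuple(snps)
    cells = label_cells(ds, snps, T)
    mask = ds.complete_cases(snps)
    geno = ds.genotypes[list(snps)].to_numpy()[mask]
    status = ds.status.to_numpy()[mask]
    idx = _cell_indices(geno)
    cases, controls = _cell_counts(idx, status, len(snps))
    high = np.array([c.risk_label == HIGH for c in cells])
    ba, sens, spec = _balanced_accuracy(cases, controls, high)
    return MDRModel(
        snps=snps,
        threshold=T,
        cells=cells,
        train_balanced_accuracy=float(ba),
        sensitivity=sens,
        specificity=spec,
    )


def classify(model: MDRModel, genotypes: np.ndarray) -> np.ndarray:
    """High(True)/low(False) labels for an (n, k) dosage matrix.

    Cells never seen in training (empty) classify as low risk — the
    conservative convention.
    """
    geno = np.atleast_2d(np.asarray(genotypes))
    if geno.shape[1] != len(model.snps):
        raise ValidationError(
            f"expected {len(model.snps)} genotype columns, got {geno.shape[1]}"
        )
    return model.cell_labels[_cell_indices(geno)]


def confusion_metrics(
    model: MDRModel, ds: GenotypeDataset
) -> tuple[float, float, float]:
    """(balanced accuracy, sensitivity, specificity) of the model on ``ds``."""
    mask = ds.complete_cases(list(model.snps))
    geno = ds.genotypes[list(model.snps)].to_numpy()[mask]
    status = ds.status.to_numpy()[mask]
    idx = _cell_indices(geno)
    cases, controls = _cell_counts(idx, status, len(model.snps))
    return _balanced_accuracy(cases, controls, model.cell_labels)


def classifier_or(model: MDRModel, ds: GenotypeDataset) -> OddsRatioResult:
    """Odds ratio of the pooled high/low attribute against case status."""
    mask = ds.complete_cases(list(model.snps))
    geno = ds.genotypes[list(model.snps)].to_numpy()[mask]
    status = ds.status.to_numpy()[mask]
    labels = classify(model, geno)
    a = int(((status == CASE) & labels).sum())
    b = int(((status == CASE) & ~labels).sum())
    c = int(((status == CONTROL) & labels).sum())
    d = int(((status == CONTROL) & ~labels).sum())
    return odds_ratio_2x2(TwoByTwo(a, b, c, d))


# ---------------------------------------------------------------------------
# cross-validation and search
# ---------------------------------------------------------------------------

def stratified_folds(
    status: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold index per subject: seeded shuffle within class, position mod folds."""
    status = np.asarray(status)
    folds = np.empty(len(status), dtype=np.int64)
    for cls in (CONTROL, CASE):
        pos = np.flatnonzero(status == cls)
        if len(pos) < n_folds:
            raise ValidationError(
                f"class {cls} has {len(pos)} subjects; cannot stratify into {n_folds} folds"
            )
        perm = rng.permutation(pos)
        folds[perm] = np.arange(len(perm)) % n_folds
    return folds


@dataclass
class CVResult:
    snps: tuple[str, ...]
    mean_test_ba: float
    mean_sens: float
    mean_spec: float
    fold_test_ba: list[float]


def _fold_eval(
    idx: np.ndarray,
    status: np.ndarray,
    folds: np.ndarray,
    fold: int,
    k: int,
    T: float,
) -> tuple[float, float, float, float]:
    """(train error, test BA, test sens, test spec) for one fold."""
    train = folds != fold
    ca_tr, co_tr = _cell_counts(idx[train], status[train], k)
    high = _high_mask(ca_tr, co_tr, ca_tr.sum(), co_tr.sum(), T)
    train_ba, _, _ = _balanced_accuracy(ca_tr, co_tr, high)
    ca_te, co_te = _cell_counts(idx[~train], status[~train], k)
    test_ba, sens, spec = _balanced_accuracy(ca_te, co_te, high)
    return 1.0 - train_ba, test_ba, sens, spec


def cross_validate(
    ds: GenotypeDataset,
    snps: Sequence[str],
    T: float = DEFAULT_THRESHOLD,
    n_folds: int = 10,
    rng: np.random.Generator | None = None,
    folds: np.ndarray | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation of one SNP combination.

    Per fold, cells are labelled on the training 9/10 and scored on the
    held-out 1/10; returns fold-averaged test balanced accuracy,
    sensitivity and specificity. Deterministic given the seed (or an
    explicit fold assignment).
    """
    snps = tuple(snps)
    mask = ds.complete_cases(list(snps))
    geno = ds.genotypes[list(snps)].to_numpy()[mask]
    status = ds.status.to_numpy()[mask]
    if folds is None:
        if rng is None:
            rng = np.random.default_rng()
        folds = stratified_folds(status, n_folds, rng)
    idx = _cell_indices(geno)
    bas, senss, specs = [], [], []
    for f in range(n_folds):
        _, ba, sens, spec = _fold_eval(idx, status, folds, f, len(snps), T)
        bas.append(ba)
        senss.append(sens)
        specs.append(spec)
    return CVResult(
        snps=snps,
        mean_test_ba=float(np.mean(bas)),
        mean_sens=float(np.mean(senss)),
        mean_spec=float(np.mean(specs)),
        fold_test_ba=[float(b) for b in bas],
    )


@dataclass
class SearchResult:
    models: dict[int, MDRModel]  # best model per k
    best: MDRModel
    n_combinations: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.models):
            m = self.models[k]
            odds = m.classifier_odds
            rows.append(
                {
                    "k": k,
                    "snps": ",".join(m.snps),
                    "test_balanced_accuracy": m.test_balanced_accuracy,
                    "train_balanced_accuracy": m.train_balanced_accuracy,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "cv_consistency": f"{m.cv_consistency}/{m.n_folds}",
                    "or": odds.or_value if odds else float("nan"),
                    "or_ci_low": odds.ci_low if odds else float("nan"),
                    "or_ci_high": odds.ci_high if odds else float("nan"),
                    "p_perm": m.p_perm,
                }
            )
        return pd.DataFrame(rows)


def search_best_models(
    ds: GenotypeDataset,
    k_min: int = 1,
    k_max: int | None = None,
    T: float = DEFAULT_THRESHOLD,
    n_folds: int = 10,
    rng: np.random.Generator | None = None,
    folds: np.ndarray | None = None,
) -> SearchResult:
    """Exhaustive MDR search over all C(m, k) combinations for each k.

    Per fold the winner is the combination with minimal training
    classification error (ties: first in lexicographic combination order);
    the reported model per k is the modal fold winner, refit on all data,
    with test metrics averaged over folds and cv_consistency = number of
    folds choosing it. The overall best model maximises mean test balanced
    accuracy, ties broken by higher consistency then smaller k.
    """
    all_snps = ds.snps
    if k_max is None:
        k_max = len(all_snps)
    if k_max > len(all_snps):
        raise ValidationError(f"k_max={k_max} exceeds panel size {len(all_snps)}")
    mask = ds.complete_cases()
    geno_all = ds.genotypes.to_numpy()[mask]
    status = ds.status.to_numpy()[mask]
    if folds is None:
        if rng is None:
            rng = np.random.default_rng()
        folds = stratified_folds(status, n_folds, rng)
    ds_complete = ds.subset(mask=mask)

    models: dict[int, MDRModel] = {}
    n_comb = 0
    for k in range(k_min, k_max + 1):
        combos = list(combinations(range(len(all_snps)), k))
        n_comb += len(combos)
        idx_cache = {c: _cell_indices(geno_all[:, list(c)]) for c in combos}
        # per-fold winner by minimum training error
        fold_stats: dict[tuple[int, ...], dict[int, tuple[float, float, float]]] = {
            c: {} for c in combos
        }
        winners: list[tuple[int, ...]] = []
        for f in range(n_folds):
            best_combo, best_err = None, np.inf
            for c in combos:
                err, ba, sens, spec = _fold_eval(
                    idx_cache[c], status, folds, f, k, T
                )
                fold_stats[c][f] = (ba, sens, spec)
                if err < best_err - 1e-15:
                    best_combo, best_err = c, err
            winners.append(best_combo)
        # modal winner; ties by frequency then combination order
        counts: dict[tuple[int, ...], int] = {}
        for w in winners:
            counts[w] = counts.get(w, 0) + 1
        modal = min(counts, key=lambda c: (-counts[c], c))
        stats_f = [fold_stats[modal][f] for f in range(n_folds)]
        model = fit_mdr(ds_complete.subset(snps=[all_snps[i] for i in modal]), [all_snps[i] for i in modal], T)
        model.test_balanced_accuracy = float(np.mean([s[0] for s in stats_f]))
        model.sensitivity = float(np.mean([s[1] for s in stats_f]))
        model.specificity = float(np.mean([s[2] for s in stats_f]))
        model.cv_consistency = counts[modal]
        model.n_folds = n_folds
        try:
            model.classifier_odds = classifier_or(model, ds_complete)
        except DegenerateInputError:
            model.classifier_odds = None
        models[k] = model

    best = max(
        models.values(),
        key=lambda m: (m.test_balanced_accuracy, m.cv_consistency, -len(m.snps)),
    )
    return SearchResult(models=models, best=best, n_combinations=n_comb)


def permutation_test(
    ds: GenotypeDataset,
    snps: Sequence[str],
    T: float = DEFAULT_THRESHOLD,
    n_folds: int = 10,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Label-permutation p-value for one combination's mean test BA.

    p = (r + 1) / (n_perm + 1) with r = permutations whose cross-validated
    mean test balanced accuracy reaches the observed one; never exactly 0.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    snps = list(snps)
    mask = ds.complete_cases(snps)
    geno = ds.genotypes[snps].to_numpy()[mask]
    status = ds.status.to_numpy()[mask]
    idx = _cell_indices(geno)
    k = len(snps)

    def mean_test_ba(st: np.ndarray) -> float:
        folds = stratified_folds(st, n_folds, rng)
        return float(
            np.mean([_fold_eval(idx, st, folds, f, k, T)[1] for f in range(n_folds)])
        )

    observed = mean_test_ba(status)
    r = 0
    for _ in range(n_perm):
        perm = rng.permutation(status)
        if mean_test_ba(perm) >= observed - 1e-12:
            r += 1
    return (r + 1) / (n_perm + 1)


def list_risk_combinations(model: MDRModel) -> tuple[pd.DataFrame, int]:
    """Non-empty cells sorted by risk ratio R (descending), plus empty count.

    Per-cell case/control counts give the bar data of the classic MDR
    high/low-risk plot in machine-readable form.
    """
    rows = []
    n_empty = 0
    for cell in model.cells:
        if cell.risk_label == EMPTY:
            n_empty += 1
            continue
        rows.append(
            {
                "combo": "/".join(str(g) for g in cell.genotype_combo),
                **{s: g for s, g in zip(model.snps, cell.genotype_combo)},
                "n_cases": cell.n_cases,
                "n_controls": cell.n_controls,
                "ratio": cell.ratio,
                "risk_label": cell.risk_label,
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        "ratio", ascending=False, kind="stable"
    ).reset_index(drop=True)
    return frame, n_empty
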