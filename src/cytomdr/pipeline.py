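"""End-to-end orchestration: simulate/load -> QC -> association -> MDR ->
interaction network, with TSV/JSON/Newick report assembly and a manifest.

Every stochastic stage draws from one seeded generator, so a config plus
seed reproduces every output file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .association import association_report
from .datamodel import (
    CASE,
    CONTROL,
    GenotypeDataset,
    ValidationError,
    marginal_counts,
)
from .entropy import build_network, interaction_dendrogram
from .io import read_genotype_table, write_qc_report, write_tabular
from .mdr import permutation_test, search_best_models, list_risk_combinations
from .panel import SKEWED_COVARIATES, reference_genotype_counts
from .qc import qc_filter
from .simulate import CohortSpec, resample_from_marginals, simulate_cohort

logger = logging.getLogger("cytomdr")

STAGES = ("simulate", "qc", "assoc", "mdr", "network")


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``input_path`` (a genotype file) or a simulate stage must supply
    the cohort. ``simulate_mode`` is ``resample`` (rebuild subject-level
    data from the packaged reference marginal counts) or ``cohort`` (HWE +
    penetrance simulation from ``cohort_spec``).
    """

    stages: tuple[str, ...] = STAGES
    input_path: str | None = None
    input_dialect: str = "tabular"
    simulate_mode: str = "resample"
    cohort_spec: CohortSpec | None = None
    k_min: int = 1
    k_max: int | None = None
    threshold: float = 1.05
    n_folds: int = 10
    n_perm: int = 0
    seed: int | None = None
    out_dir: str = "cytomdr_out"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        stochastic = {"simulate", "mdr"} & set(self.stages)
        if stochastic and self.seed is None:
            raise ValidationError(
                f"seed is mandatory when stochastic stages {sorted(stochastic)} run"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "cohort_spec" in raw and raw["cohort_spec"] is not None:
            raw["cohort_spec"] = CohortSpec(**raw["cohort_spec"])
        return cls(**raw)


def descriptive_table(ds: GenotypeDataset) -> pd.DataFrame:
    """Per-covariate case/control comparison.

    Continuous variables are summarised mean +/- SD with a two-sample
    t-test; the conventionally right-skewed laboratory values (glucose,
    LDL, triglycerides) as median (IQR) with a Mann-Whitney rank-sum test;
    binary variables as n (%) with a chi-squared test. Constant-in-both-
    groups covariates get p = 1 and a flag.
    """
    if ds.covariates is None or ds.covariates.empty:
        raise ValidationError("dataset has no covariates")
    status = ds.status.to_numpy()
    rows = []
    for name in ds.covariates.columns:
        col = pd.to_numeric(ds.covariates[name], errors="coerce").to_numpy()
        ctrl = col[(status == CONTROL) & ~np.isnan(col)]
        case = col[(status == CASE) & ~np.isnan(col)]
        if len(ctrl) == 0 and len(case) == 0:
            raise ValidationError(f"covariate {name!r} is all-missing")
        flagged = ""
        values = np.concatenate([ctrl, case])
        is_binary = np.isin(np.unique(values), [0.0, 1.0]).all()
        if np.ptp(values) == 0:
            p, test = 1.0, "constant"
            flagged = "constant"
            summary = (f"{ctrl[0]:.4g}", f"{case[0]:.4g}") if len(ctrl) and len(case) else ("", "")
        elif is_binary:
            table = np.array(
                [
                    [(ctrl == 1).sum(), (ctrl == 0).sum()],
                    [(case == 1).sum(), (case == 0).sum()],
                ]
            )
            _, p, _, _ = stats.chi2_contingency(table)
            test = "chi2"
            summary = (
                f"{int(table[0, 0])} ({100 * table[0, 0] / len(ctrl):.1f})",
                f"{int(table[1, 0])} ({100 * table[1, 0] / len(case):.1f})",
            )
        elif name in SKEWED_COVARIATES:
            _, p = stats.mannwhitneyu(ctrl, case, alternative="two-sided")
            test = "rank-sum"
            summary = tuple(
                f"{np.median(v):.1f} ({np.percentile(v, 25):.1f}-{np.percentile(v, 75):.1f})"
                for v in (ctrl, case)
            )
        else:
            _, p = stats.ttest_ind(ctrl, case, equal_var=True)
            test = "t-test"
            summary = tuple(
                f"{v.mean():.1f} +/- {v.std(ddof=1):.1f}" for v in (ctrl, case)
            )
        rows.append(
            {
                "variable": name,
                "control": summary[0],
                "case": summary[1],
                "p": float(p),
                "test": test,
                "flag": flagged,
            }
        )
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the configured stages in order; returns the written outputs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    rng = np.random.default_rng(config.seed) if config.seed is not None else None
    ds: GenotypeDataset | None = None

    if "simulate" in config.stages:
        logger.info("stage simulate: mode=%s", config.simulate_mode)
        try:
            if config.simulate_mode == "resample":
                ds = resample_from_marginals(reference_genotype_counts(), rng=rng)
            elif config.simulate_mode == "cohort":
                if config.cohort_spec is None:
                    raise ValidationError("simulate_mode 'cohort' needs cohort_spec")
                ds = simulate_cohort(config.cohort_spec, rng=rng)
            else:
                raise ValidationError(
                    f"unknown simulate_mode {config.simulate_mode!r}"
                )
        except ValidationError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StageError("simulate", str(exc)) from exc
        path = out_dir / "cohort.tsv"
        write_tabular(ds, path)
        outputs["cohort"] = path
    elif config.input_path is not None:
        logger.info("loading %s (%s)", config.input_path, config.input_dialect)
        ds = read_genotype_table(config.input_path, dialect=config.input_dialect)

    if ds is None:
        raise ValidationError("no input: provide input_path or a simulate stage")

    if "qc" in config.stages:
        logger.info("stage qc")
        try:
            ds, report = qc_filter(ds)
        except Exception as exc:
            raise StageError("qc", str(exc)) from exc
        path = out_dir / "qc_report.tsv"
        write_qc_report(report, path)
        outputs["qc_report"] = path

    if "assoc" in config.stages:
        logger.info("stage assoc: %d SNPs", len(ds.snps))
        try:
            tables = [marginal_counts(ds, s) for s in ds.snps]
            report = association_report(tables)
        except Exception as exc:
            raise StageError("assoc", str(exc)) from exc
        path = out_dir / "association.tsv"
        report.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs["association"] = path
        if ds.covariates is not None and not ds.covariates.empty:
            desc = descriptive_table(ds)
            path = out_dir / "descriptives.tsv"
            desc.to_csv(path, sep="\t", index=False, float_format="%.6g")
            outputs["descriptives"] = path

    if "mdr" in config.stages:
        logger.info(
            "stage mdr: k=%d..%s T=%s folds=%d",
            config.k_min, config.k_max, config.threshold, config.n_folds,
        )
        try:
            result = search_best_models(
                ds,
                k_min=config.k_min,
                k_max=config.k_max,
                T=config.threshold,
                n_folds=config.n_folds,
                rng=rng,
            )
            if config.n_perm > 0:
                result.best.p_perm = permutation_test(
                    ds,
                    result.best.snps,
                    T=config.threshold,
                    n_folds=config.n_folds,
                    n_perm=config.n_perm,
                    rng=rng,
                )
        except Exception as exc:
            raise StageError("mdr", str(exc)) from exc
        path = out_dir / "mdr_summary.tsv"
        result.summary().to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs["mdr_summary"] = path
        risk, n_empty = list_risk_combinations(result.best)
        path = out_dir / "risk_combinations.tsv"
        risk.to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs["risk_combinations"] = path
        best = result.best
        model_json = {
            "snps": list(best.snps),
            "threshold": best.threshold,
            "train_balanced_accuracy": best.train_balanced_accuracy,
            "test_balanced_accuracy": best.test_balanced_accuracy,
            "sensitivity": best.sensitivity,
            "specificity": best.specificity,
            "cv_consistency": best.cv_consistency,
            "n_folds": best.n_folds,
            "p_perm": best.p_perm,
            "n_empty_cells": n_empty,
            "high_risk_cells": [
                list(c.genotype_combo)
                for c in best.cells
                if c.risk_label == "high"
            ],
        }
        path = out_dir / "mdr_model.json"
        path.write_text(json.dumps(model_json, indent=2, sort_keys=True) + "\n")
        outputs["mdr_model"] = path

    if "network" in config.stages:
        logger.info("stage network")
        try:
            net = build_network(ds)
            newick = interaction_dendrogram(net)
        except Exception as exc:
            raise StageError("network", str(exc)) from exc
        path = out_dir / "network_nodes.tsv"
        net.node_table().to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs["network_nodes"] = path
        path = out_dir / "network_edges.tsv"
        net.edge_table().to_csv(path, sep="\t", index=False, float_format="%.6g")
        outputs["network_edges"] = path
        path = out_dir / "dendrogram.nwk"
        path.write_text(newick + "\n")
        outputs["dendrogram"] = path

    manifest = {
        "package": "cytomdr",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "parameters": {
            "simulate_mode": config.simulate_mode,
            "k_min": config.k_min,
            "k_max": config.k_max,
            "threshold": config.threshold,
            "n_folds": config.n_folds,
            "n_perm": config.n_perm,
            "input_path": config.input_path,
        },
        "outputs": {
            name: {"path": p.name, "sha256": _sha256(p)}
            for name, p in sorted(outputs.items())
        },
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = manifest_path
    return outputs
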