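"""Core containers for case-control SNP data.

Genotypes are coded as minor-allele dosage: 0 = homozygous common allele,
1 = heterozygous, 2 = homozygous variant allele; -1 marks a missing call.
Disease status is 0 = control, 1 = case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING: int = -1
VALID_CODES = frozenset({-1, 0, 1, 2})

CONTROL, CASE = 0, 1


class ValidationError(ValueError):
    """Input data violate a structural contract (bad codes, mismatched lengths)."""


class ParseError(ValueError):
    """A genotype file could not be interpreted; message names the offending line."""


class DegenerateInputError(ValueError):
    """A statistic is undefined on this input (zero variance, empty margin, ...)."""


@dataclass(frozen=True)
class SNPDescriptor:
    """Metadata for one biallelic SNP.

    ``ref_allele`` is the common allele of the study population (the dosage-0
    homozygote), ``alt_allele`` the variant allele whose copies are counted.
    ``genomic_location`` is kept verbatim as a ``chrom:pos`` label; no
    genome-build arithmetic is ever performed on it.
    """

    rsid: str
    gene: str
    ref_allele: str
    alt_allele: str
    genomic_location: str = ""
    annotation: str = ""

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValidationError(
                f"{self.rsid}: reference and variant allele must differ"
            )


@dataclass(frozen=True)
class GenotypeCountTable:
    """Per-SNP genotype counts: 2 classes (rows control, case) x 3 genotypes."""

    snp: SNPDescriptor
    counts: np.ndarray  # shape (2, 3), int

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (2, 3):
            raise ValidationError("counts must be a 2x3 array (control/case rows)")
        if (counts < 0).any():
            raise ValidationError("genotype counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def controls(self) -> np.ndarray:
        return self.counts[CONTROL]

    @property
    def cases(self) -> np.ndarray:
        return self.counts[CASE]

    @property
    def n_controls(self) -> int:
        return int(self.counts[CONTROL].sum())

    @property
    def n_cases(self) -> int:
        return int(self.counts[CASE].sum())


class GenotypeDataset:
    """Subjects x SNPs genotype matrix with case/control labels and covariates.

    Parameters
    ----------
    genotypes
        DataFrame of dosage codes (0/1/2, -1 for missing), one row per
        subject, one column per SNP (column name = rsid).
    status
        Per-subject class, aligned with ``genotypes``; accepts 0/1 or the
        strings ``control``/``case``.
    covariates
        Optional DataFrame of named covariate columns aligned with subjects.
    panel
        Optional SNP descriptors; when given, must cover every genotype column.
    """

    def __init__(
        self,
        genotypes: pd.DataFrame,
        status: Sequence,
        covariates: pd.DataFrame | None = None,
        panel: Sequence[SNPDescriptor] | None = None,
    ) -> None:
        genotypes = pd.DataFrame(genotypes).astype(np.int8, copy=True)
        bad = set(np.unique(genotypes.to_numpy())) - VALID_CODES
        if bad:
            raise ValidationError(f"invalid genotype codes: {sorted(bad)}")
        status_arr = _coerce_status(status, n=len(genotypes))
        if covariates is not None:
            covariates = pd.DataFrame(covariates).copy()
            if len(covariates) != len(genotypes):
                raise ValidationError("covariates not aligned with subjects")
            covariates.index = genotypes.index
        if panel is not None:
            panel = list(panel)
            known = {d.rsid for d in panel}
            missing = [c for c in genotypes.columns if c not in known]
            if missing:
                raise ValidationError(f"panel lacks descriptors for {missing}")
        self.genotypes = genotypes
        self.status = pd.Series(status_arr, index=genotypes.index, name="status")
        self.covariates = covariates
        self.panel = panel

    # -- basic accessors ---------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(self.genotypes.index)

    @property
    def snps(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.genotypes)

    @property
    def n_cases(self) -> int:
        return int((self.status == CASE).sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == CONTROL).sum())

    def descriptor(self, rsid: str) -> SNPDescriptor:
        if self.panel is not None:
            for d in self.panel:
                if d.rsid == rsid:
                    return d
        return SNPDescriptor(rsid=rsid, gene="", ref_allele="R", alt_allele="V")

    # -- subsetting --------------------------------------------------------
    def complete_cases(self, snps: Iterable[str] | None = None) -> np.ndarray:
        """Boolean mask of subjects with no missing call among ``snps``."""
        cols = list(snps) if snps is not None else self.snps
        sub = self.genotypes[cols].to_numpy()
        return (sub != MISSING).all(axis=1)

    def subset(
        self, mask: np.ndarray | None = None, snps: Sequence[str] | None = None
    ) -> "GenotypeDataset":
        g = self.genotypes if snps is None else self.genotypes[list(snps)]
        if mask is not None:
            g = g.loc[np.asarray(mask, dtype=bool)]
        st = self.status.loc[g.index]
        cov = self.covariates.loc[g.index] if self.covariates is not None else None
        return GenotypeDataset(g, st, covariates=cov, panel=self.panel)


def _coerce_status(status: Sequence, n: int) -> np.ndarray:
    vals = list(status)
    if len(vals) != n:
        raise ValidationError("status not aligned with subjects")
    mapping = {0: 0, 1: 1, "0": 0, "1": 1, "control": 0, "case": 1}
    out = np.empty(n, dtype=np.int8)
    for i, v in enumerate(vals):
        key = v.strip().lower() if isinstance(v, str) else int(v)
        if key not in mapping:
            raise ValidationError(f"status must be binary (0/1 or control/case), got {v!r}")
        out[i] = mapping[key]
    return out


def marginal_counts(ds: GenotypeDataset, snp: str) -> GenotypeCountTable:
    """Per-class genotype counts for one SNP; missing calls are excluded."""
    if snp not in ds.genotypes.columns:
        raise ValidationError(f"SNP {snp!r} not in dataset")
    g = ds.genotypes[snp].to_numpy()
    st = ds.status.to_numpy()
    counts = np.zeros((2, 3), dtype=np.int64)
    for cls in (CONTROL, CASE):
        sub = g[(st == cls) & (g != MISSING)]
        counts[cls] = np.bincount(sub, minlength=3)[:3]
    return GenotypeCountTable(snp=ds.descriptor(snp), counts=counts)


def dataset_from_counts_order(
    tables: Sequence[GenotypeCountTable],
    genotype_columns: dict[str, np.ndarray],
    n_controls: int,
    n_cases: int,
) -> GenotypeDataset:
    """Assemble a dataset from per-class genotype columns (controls first)."""
    subjects = [f"ctrl{i:04d}" for i in range(n_controls)] + [
        f"case{i:04d}" for i in range(n_cases)
    ]
    status = [CONTROL] * n_controls + [CASE] * n_cases
    geno = pd.DataFrame(genotype_columns, index=subjects)
    return GenotypeDataset(geno, status, panel=[t.snp for t in tables])
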