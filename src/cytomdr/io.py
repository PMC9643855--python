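"""Readers and writers for case-control genotype files.

Three dialects are supported:

``tabular``
    UTF-8, tab- or comma-delimited, header required. One row per subject:
    a subject-id column, a ``status`` column ({0,1} or {control,case}),
    SNP columns (rs-prefixed names or given explicitly) holding dosage codes
    0/1/2, and any further columns treated as covariates.
``ped_map``
    PLINK text PED/MAP pair, read-only. Allele pairs are recoded to dosage
    against the panel's declared common allele (heterozygotes are 1
    regardless of allele order).
``mdr_flat``
    The tab-delimited format of the classic MDR software: attribute columns
    followed by a final ``Class`` column of 0/1; no covariates.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    MISSING,
    GenotypeDataset,
    ParseError,
    SNPDescriptor,
    ValidationError,
)

MISSING_TOKENS = {"", "na", "nan", ".", "-1"}
_CODE_TOKENS = {"0": 0, "1": 1, "2": 2}


def read_genotype_table(
    path: str | Path,
    dialect: str = "tabular",
    snp_columns: Sequence[str] | None = None,
    panel: Sequence[SNPDescriptor] | None = None,
) -> GenotypeDataset:
    """Read a genotype file into a :class:`GenotypeDataset`.

    ``snp_columns`` (tabular dialect) names the genotype columns explicitly;
    by default every ``rs``-prefixed column is taken as a SNP and remaining
    non-id, non-status columns as covariates. Unrecognised genotype tokens
    are an error; only the conventional missing tokens (NA, ., empty) map to
    a missing call.
    """
    path = Path(path)
    if dialect == "tabular":
        return _read_tabular(path, snp_columns, panel)
    if dialect == "ped_map":
        return _read_ped_map(path, panel)
    if dialect == "mdr_flat":
        return _read_mdr_flat(path, panel)
    raise ValueError(f"unknown dialect {dialect!r}")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _parse_code(token: str, path: Path, lineno: int, col: str) -> int:
    t = token.strip()
    if t.lower() in MISSING_TOKENS:
        return MISSING
    if t in _CODE_TOKENS:
        return _CODE_TOKENS[t]
    raise ParseError(
        f"{path}:{lineno}: uninterpretable genotype {token!r} in column {col!r}"
    )


def _read_tabular(
    path: Path,
    snp_columns: Sequence[str] | None,
    panel: Sequence[SNPDescriptor] | None,
) -> GenotypeDataset:
    with open(path, newline="", encoding="utf-8") as fh:
        first = fh.readline()
        if not first.strip():
            raise ParseError(f"{path}:1: empty file")
        delim = _sniff_delimiter(first)
        header = [h.strip() for h in first.rstrip("\n").split(delim)]
        rows = list(csv.reader(fh, delimiter=delim))
    lower = [h.lower() for h in header]
    if "status" not in lower:
        raise ParseError(f"{path}:1: header lacks a 'status' column")
    status_col = lower.index("status")
    id_col = 0 if status_col != 0 else None
    if snp_columns is None:
        snp_cols = [h for h in header if h.lower().startswith("rs")]
    else:
        snp_cols = list(snp_columns)
        missing_cols = [c for c in snp_cols if c not in header]
        if missing_cols:
            raise ParseError(f"{path}:1: SNP columns {missing_cols} not in header")
    snp_idx = [header.index(c) for c in snp_cols]
    skip = {status_col, *snp_idx}
    if id_col is not None:
        skip.add(id_col)
    cov_cols = [(i, h) for i, h in enumerate(header) if i not in skip]

    subjects, status, geno_rows, cov_rows = [], [], [], []
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) != len(header):
            raise ParseError(
                f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
            )
        subjects.append(row[id_col].strip() if id_col is not None else f"s{lineno - 2}")
        status.append(row[status_col].strip())
        geno_rows.append(
            [_parse_code(row[i], path, lineno, header[i]) for i in snp_idx]
        )
        cov_rows.append([row[i].strip() for i, _ in cov_cols])

    geno = pd.DataFrame(geno_rows, columns=snp_cols, index=subjects, dtype=np.int8)
    covariates = None
    if cov_cols:
        covariates = pd.DataFrame(
            cov_rows, columns=[h for _, h in cov_cols], index=subjects
        )
        def _maybe_numeric(col: pd.Series) -> pd.Series:
            try:
                return pd.to_numeric(col)
            except (ValueError, TypeError):
                return col

        covariates = covariates.apply(_maybe_numeric)
    return GenotypeDataset(geno, status, covariates=covariates, panel=panel)


def _read_ped_map(path: Path, panel: Sequence[SNPDescriptor] | None) -> GenotypeDataset:
    """Read a PLINK text PED (+ sibling MAP) pair."""
    ped = path if path.suffix == ".ped" else path.with_suffix(".ped")
    map_path = ped.with_suffix(".map")
    if not map_path.exists():
        raise ParseError(f"{map_path}: MAP file not found")
    snp_names = []
    with open(map_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 4:
                raise ParseError(f"{map_path}:{lineno}: expected 4 MAP fields")
            snp_names.append(fields[1])

    common = {}
    if panel is not None:
        common = {d.rsid: d.ref_allele for d in panel}

    subjects, status, allele_rows = [], [], []
    with open(ped, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(snp_names):
                raise ParseError(
                    f"{ped}:{lineno}: expected {6 + 2 * len(snp_names)} fields, "
                    f"got {len(fields)}"
                )
            subjects.append(fields[1])
            pheno = fields[5]
            if pheno not in {"1", "2"}:
                raise ValidationError(
                    f"{ped}:{lineno}: phenotype must be 1 (control) or 2 (case), got {pheno!r}"
                )
            status.append(0 if pheno == "1" else 1)
            allele_rows.append(fields[6:])

    geno = np.full((len(subjects), len(snp_names)), MISSING, dtype=np.int8)
    for j, rsid in enumerate(snp_names):
        pairs = [(row[2 * j], row[2 * j + 1]) for row in allele_rows]
        ref = common.get(rsid)
        if ref is None:
            # fall back to file-observed majority allele; alphabetical tie-break
            tally: dict[str, int] = {}
            for a, b in pairs:
                for al in (a, b):
                    if al != "0":
                        tally[al] = tally.get(al, 0) + 1
            if not tally:
                continue
            ref = max(sorted(tally), key=lambda al: tally[al])
        for i, (a, b) in enumerate(pairs):
            if a == "0" or b == "0":
                continue
            dosage = int(a != ref) + int(b != ref)
            geno[i, j] = dosage
    gdf = pd.DataFrame(geno, columns=snp_names, index=subjects)
    return GenotypeDataset(gdf, status, panel=panel)


def _read_mdr_flat(path: Path, panel: Sequence[SNPDescriptor] | None) -> GenotypeDataset:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[-1].lower() != "class":
            raise ParseError(f"{path}:1: MDR flat file must end with a 'Class' column")
        snp_cols = header[:-1]
        geno_rows, status = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            if fields[-1] not in {"0", "1"}:
                raise ValidationError(f"{path}:{lineno}: Class must be 0/1")
            status.append(int(fields[-1]))
            geno_rows.append(
                [_parse_code(t, path, lineno, c) for t, c in zip(fields, snp_cols)]
            )
    geno = pd.DataFrame(geno_rows, columns=snp_cols, dtype=np.int8)
    geno.index = [f"s{i}" for i in range(len(geno))]
    return GenotypeDataset(geno, status, panel=panel)


def write_tabular(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the tab-delimited tabular dialect (id, status, SNPs, covariates)."""
    path = Path(path)
    cols: dict[str, Sequence] = {"subject": ds.subjects, "status": ds.status.to_numpy()}
    for snp in ds.snps:
        cols[snp] = [
            "NA" if g == MISSING else str(int(g)) for g in ds.genotypes[snp]
        ]
    frame = pd.DataFrame(cols)
    if ds.covariates is not None:
        for c in ds.covariates.columns:
            frame[c] = ds.covariates[c].to_numpy()
    frame.to_csv(path, sep="\t", index=False)


def write_mdr_flatfile(ds: GenotypeDataset, path: str | Path) -> None:
    """Write the MDR software flat format: attributes then a final Class column.

    Covariates are excluded (the format carries only attributes and class);
    status must be defined for every subject. Missing calls are written as NA.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join([*ds.snps, "Class"]) + "\n")
        geno = ds.genotypes.to_numpy()
        st = ds.status.to_numpy()
        for i in range(ds.n_subjects):
            row = ["NA" if g == MISSING else str(int(g)) for g in geno[i]]
            fh.write("\t".join([*row, str(int(st[i]))]) + "\n")


def write_qc_report(report: pd.DataFrame, path: str | Path) -> None:
    """Write the QC report (snp, maf, hwe_p, max_r2, kept, reason) as TSV."""
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")
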