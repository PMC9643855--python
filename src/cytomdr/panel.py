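"""Packaged reference panel: five cytokine-gene SNPs from a dementia
case-control study of 221 cases and 710 controls.

The per-SNP marginal genotype counts and the clinical covariate summaries
(age, sex, BMI, lipids, glucose) are the published study-level figures; the
individual-level joint genotype distribution was never released, so any
subject-level data built from these marginals (see
:func:`cytomdr.simulate.resample_from_marginals`) is an emulation, exact in
its margins only.
"""

from __future__ import annotations

import numpy as np

from .datamodel import GenotypeCountTable, SNPDescriptor

#: Study class sizes.
N_CONTROLS = 710
N_CASES = 221


def reference_panel() -> list[SNPDescriptor]:
    """SNP descriptors of the five-locus cytokine panel.

    ``ref_allele`` is the common allele (dosage-0 homozygote) in the study
    population, matching the first-listed genotype of the published counts.
    """
    return [
        SNPDescriptor("rs1800587", "IL1A", "G", "A", "2:112785383",
                      "upstream transcript variant"),
        SNPDescriptor("rs1800796", "IL6", "G", "C", "7:22726627",
                      "intron / non-coding transcript variant"),
        SNPDescriptor("rs361525", "TNFA", "G", "A", "6:31575324",
                      "upstream transcript variant"),
        SNPDescriptor("rs1800629", "TNFA", "G", "A", "6:31575254",
                      "upstream transcript variant"),
        SNPDescriptor("rs2069705", "IFNG", "G", "A", "12:68161231",
                      "upstream transcript variant"),
    ]


# Genotype counts per SNP: (control (0,1,2), case (0,1,2)).
_COUNTS: dict[str, tuple[tuple[int, int, int], tuple[int, int, int]]] = {
    "rs1800587": ((486, 201, 23), (127, 78, 16)),
    "rs1800796": ((195, 353, 162), (97, 98, 26)),
    "rs361525": ((642, 63, 5), (164, 17, 40)),
    "rs1800629": ((634, 72, 4), (154, 21, 46)),
    "rs2069705": ((224, 349, 137), (86, 81, 54)),
}


def reference_genotype_counts() -> list[GenotypeCountTable]:
    """Per-SNP 2x3 genotype count tables of the study (controls row 0)."""
    out = []
    for desc in reference_panel():
        ctrl, case = _COUNTS[desc.rsid]
        out.append(GenotypeCountTable(snp=desc, counts=np.array([ctrl, case])))
    return out


def reference_covariate_params() -> dict:
    """Clinical covariate distribution parameters per class.

    Normal-style variables carry (mean, sd); right-skewed laboratory values
    (glucose, LDL, triglycerides) carry (median, q1, q3) and are simulated
    log-normally; ``sex`` is the male fraction. Units: years, kg/m^2, mg/dL.
    """
    return {
        "age": {"kind": "normal", "control": (71.5, 7.8), "case": (76.9, 7.9)},
        "education": {"kind": "normal", "control": (6.9, 5.2), "case": (5.7, 5.5)},
        "bmi": {"kind": "normal", "control": (27.4, 5.0), "case": (26.4, 5.4)},
        "cholesterol": {"kind": "normal", "control": (202.6, 41.2), "case": (247.0, 31.6)},
        "hdl": {"kind": "normal", "control": (52.8, 14.0), "case": (48.0, 9.8)},
        "glucose": {"kind": "lognormal", "control": (98.0, 90.0, 109.0), "case": (110.0, 95.0, 148.0)},
        "ldl": {"kind": "lognormal", "control": (117.0, 95.0, 140.0), "case": (121.0, 101.0, 150.5)},
        "triglycerides": {"kind": "lognormal", "control": (146.0, 111.0, 196.0), "case": (167.0, 132.0, 240.0)},
        "sex": {"kind": "binary", "control": 270 / 710, "case": 76 / 221},
    }


#: Covariates the study reports as median (IQR); everything else numeric is
#: summarised mean +/- SD.
SKEWED_COVARIATES = ("glucose", "ldl", "triglycerides")
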