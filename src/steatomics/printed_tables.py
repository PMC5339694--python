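"""Published cohort-characteristic counts for the 577-patient bariatric cohort.

These are the printed discovery-vs-validation counts of the study population
(discovery n = 443, validation n = 134), entered as integer matrices; each
categorical row is a 2×c table with rows (discovery, validation).  They are
the inputs from which the table-one statistics are recomputed.

The race and fibrosis rows were analysed with a Fisher exact variant that the
published table does not pin down; they are kept here for completeness but the
Freeman–Halton p-values computed from them are not expected to match the
printed ones (see docs/methods.md).
"""

from __future__ import annotations

import numpy as np

from .tableone import ContingencyTable

# genotype counts (CC, CG, GG), per cohort — 48 patients have unknown genotype
PNPLA3_DISCOVERY = (219, 163, 23)
PNPLA3_VALIDATION = (71, 43, 10)

CATEGORICAL_TABLES: dict[str, ContingencyTable] = {
    "sex": ContingencyTable(
        np.array([[363, 80], [112, 22]]),
        row_labels=["discovery", "validation"],
        col_labels=["female", "male"],
    ),
    "diabetes": ContingencyTable(
        np.array([[180, 263], [55, 79]]),
        row_labels=["discovery", "validation"],
        col_labels=["yes", "no"],
    ),
    "hypertension": ContingencyTable(
        np.array([[209, 234], [59, 75]]),
        row_labels=["discovery", "validation"],
        col_labels=["yes", "no"],
    ),
    "dyslipidemia": ContingencyTable(
        np.array([[163, 280], [57, 77]]),
        row_labels=["discovery", "validation"],
        col_labels=["yes", "no"],
    ),
    "steatosis_grade": ContingencyTable(
        np.array([[131, 89, 117, 106], [43, 32, 32, 27]]),
        row_labels=["discovery", "validation"],
        col_labels=["<5%", "5-33%", "33-66%", ">66%"],
    ),
    # the ">4 foci" category is unobserved in both cohorts (all-zero column,
    # dropped before testing)
    "lobular_inflammation": ContingencyTable(
        np.array([[242, 162, 39, 0], [83, 45, 6, 0]]),
        row_labels=["discovery", "validation"],
        col_labels=["no foci", "<2 foci", "2-4 foci", ">4 foci"],
    ),
    "pnpla3_genotype": ContingencyTable(
        np.array([PNPLA3_DISCOVERY, PNPLA3_VALIDATION]),
        row_labels=["discovery", "validation"],
        col_labels=["CC", "CG", "GG"],
    ),
    # Fisher rows (variant ambiguous in the published table):
    "race": ContingencyTable(
        np.array([[439, 2, 2], [133, 1, 0]]),
        row_labels=["discovery", "validation"],
        col_labels=["white", "black", "other"],
    ),
    "fibrosis_stage": ContingencyTable(
        np.array([[262, 111, 39, 20, 11], [86, 37, 10, 1, 0]]),
        row_labels=["discovery", "validation"],
        col_labels=["none", "1", "2", "3", "4"],
    ),
}

# published p-values for the nine chi-square-family rows, to 3 d.p.
PRINTED_P_VALUES = {
    "hwe_discovery": 0.304,
    "hwe_validation": 0.344,
    "pnpla3_genotype": 0.407,
    "sex": 0.663,
    "diabetes": 0.932,
    "hypertension": 0.522,
    "dyslipidemia": 0.230,
    "steatosis_grade": 0.612,
    "lobular_inflammation": 0.157,
}
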