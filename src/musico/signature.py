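"""The packaged AID/APOBEC multigene signature and clinical covariate codings.

The signature bundles the eleven cytidine-deaminase family members (AID/AICDA
and the APOBECs) with B-cell identity markers, transcriptional regulators of
AID, estrogen receptors, pluripotency genes and downstream DNA-repair
co-factors -- 24 genes in total.  Three of them (APOBEC1, APOBEC2, DPPA3) are
typically not expressed, or sit at the detection limit, in serous ovarian
carcinoma tissue and are dropped by the detection filter, leaving the 21
modelled genes.
"""

from __future__ import annotations

#: Full 24-gene panel as profiled by qPCR.
SIGNATURE_GENES: tuple[str, ...] = (
    "AICDA",
    "APOBEC1",
    "APOBEC2",
    "APOBEC3A",
    "APOBEC3B",
    "APOBEC3C",
    "APOBEC3D",
    "APOBEC3F",
    "APOBEC3G",
    "APOBEC3H",
    "APOBEC4",
    "PTPRC",
    "PAX5",
    "FCER2",
    "NUGGC",
    "PRDM1",
    "ID2",
    "ID3",
    "ESR1",
    "ESR2",
    "DPPA3",
    "NANOG",
    "XRCC5",
    "XRCC6",
)

#: Panel members typically below the qPCR detection limit in ovarian tumour
#: tissue; excluded by the detection filter in real cohorts.
LOW_EXPRESSION_GENES: tuple[str, ...] = ("APOBEC1", "APOBEC2", "DPPA3")

#: The 21 genes that survive detection filtering and enter the survival models.
MODELED_GENES: tuple[str, ...] = tuple(
    g for g in SIGNATURE_GENES if g not in LOW_EXPRESSION_GENES
)

#: Housekeeping genes used for qPCR normalisation of tissue specimens.
TISSUE_HKGS: tuple[str, ...] = ("ACTB", "TOP1", "UBC", "YWHAZ")

#: Housekeeping genes used for cell-line specimens.
CELL_LINE_HKGS: tuple[str, ...] = ("EEF1A1", "UBC")

#: Clinical covariates, in the column order used by the model matrices.
#: Codings: age in years (untransformed); FIGO stage ordinal 0/1/2 for
#: stages II/III/IV; grading 0 = G1-G2, 1 = G3; histology 0 = serous,
#: 1 = non-serous; residual disease 0 = none, 1 = present; peritoneal
#: carcinomatosis 0 = no, 1 = yes.
CLINICAL_VARIABLES: tuple[str, ...] = (
    "age",
    "figo",
    "grading",
    "histology",
    "residual",
    "peritoneal",
)

#: Default target genes for the co-expression / network stage: the top-ranked
#: signature genes by standardised coefficient that are measurable on
#: microarray platforms.
DEFAULT_TARGET_GENES: tuple[str, ...] = ("APOBEC3G", "ESR1", "ID2", "ID3", "PTPRC")

#: Cut-point on |standardised coefficient| used to nominate target genes.
STDBETA_CUTPOINT: float = 0.15
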