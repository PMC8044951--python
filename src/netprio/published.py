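"""Published reference inputs from the pancreatic-cancer IFITM1 study.

These are the printed outputs of the original analysis — the eight hub
genes passing the topology filter, the six MCL modules with their average
internal correlations, and the 90-patient tissue-microarray contingency
tables relating IFITM1 immunohistochemistry expression (dichotomized at the
median H-score into Low/High) to clinicopathological features. They serve
as fixed inputs for the clinical-validation statistics and the
hub-by-module candidate intersection, which are fully recomputable from
these counts and lists.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "HUB_GENES",
    "MODULES",
    "MODULE_AVG_CORR",
    "CLINICAL_TABLES",
    "COHORT_SIZE",
    "HIGH_EXPRESSION_COUNT",
]

# Hub genes: neighborhood connectivity >= 20 and per-node average shortest
# path length >= 3.5 in the DEG functional-interaction subnetwork.
HUB_GENES: tuple[str, ...] = (
    "EDIL3", "RSAD2", "AHR", "GBP2", "IFITM1", "AOX1", "KIF11", "CEP170",
)

# The six MCL modules (inflation 5.0) with mean internal |Pearson r|.
MODULES: dict[int, tuple[str, ...]] = {
    0: ("ADAM28", "ADAM9", "CHAD", "COL10A1", "COL11A1", "COL5A2", "COL6A3",
        "COL8A1", "FERMT1", "ITGA11", "ITGA2", "ITGA3", "ITGB1", "ITGB4",
        "LAMA4", "LUM", "PLAU", "SERPINH1", "THBS2"),
    1: ("AHR", "AOX1", "FCGR3A", "GBP2", "IFITM1", "OAS1", "OAS2", "PRLR",
        "RASAL2", "RSAD2", "STAT1", "TAP1"),
    2: ("ADAM12", "AP2B1", "CTTN", "EGF", "IL22RA1", "LIFR", "NRG4", "SGIP1",
        "SPRY4"),
    3: ("ABLIM3", "ARHGAP1", "CORO1C", "DAPP1", "ECT2", "PAK3", "RAC1",
        "RALB", "SEMA3A"),
    4: ("ANXA1", "ANXA2", "PLAT", "S100A10", "S100A4", "S100A6", "TNIK"),
    5: ("CXCL5", "FHL2", "SEL1L", "TFAP2A", "TIMP1", "TIMP2", "ZNFX1"),
}

MODULE_AVG_CORR: dict[int, float] = {
    0: 0.9927, 1: 1.0000, 2: 0.9615, 3: 0.8365, 4: 0.9739, 5: 0.7790,
}

# Contingency tables: rows = feature categories, columns = (Low, High)
# IFITM1 expression counts among the 90 TMA patients. Only the internally
# consistent tables are included (some printed rows of the original
# association table do not sum to the stated cohort).
CLINICAL_TABLES: dict[str, dict] = {
    "gender": {
        "categories": ("male", "female"),
        "counts": np.array([[14, 44], [7, 25]]),
    },
    "tumor_size": {
        "categories": ("<=4.5cm", ">4.5cm"),
        "counts": np.array([[13, 41], [8, 28]]),
    },
    "histologic_differentiation": {
        "categories": ("well", "moderate", "poor"),
        "counts": np.array([[4, 5], [14, 34], [3, 30]]),
    },
    "tnm_stage": {
        "categories": ("I", "II", "III", "IV"),
        "counts": np.array([[1, 2], [6, 31], [11, 31], [3, 5]]),
    },
}

COHORT_SIZE: int = 90
# 69/90 tumors showed upregulated marker expression (the High column total
# of the gender table: 44 + 25).
HIGH_EXPRESSION_COUNT: int = 69
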