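"""Published group-level pathway mutation-burden scores.

Reference table from a published stage II microsatellite-stable colon-cancer
cohort (21 good- / 21 poor-prognosis tumors): per gene set, the good- and
poor-group burden scores, their printed difference (poor minus good) and the
permutation p-value. Used to validate the score-difference arithmetic against
printed values at their rounding precision.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # (function, source, score_good, score_poor, dif_score, p_val)
    ("APOPTOSIS", "KEGG", 0.903, 0.432, -0.472, 0.001),
    ("SMALL CELL LUNG CANCER", "KEGG", 0.828, 0.452, -0.376, 0.012),
    ("DILATED CARDIOMYOPATHY", "KEGG", 0.837, 0.540, -0.297, 0.039),
    ("VEGF SIGNALING PATHWAY", "KEGG", 0.817, 0.538, -0.279, 0.037),
    ("CELL CYCLE", "KEGG", 0.621, 0.365, -0.256, 0.020),
    ("LIPID KINASE ACTIVITY", "GO", 1.863, 0.487, -1.376, 0.002),
    ("INOSITOL OR PHOSPHATIDYLINOSITOL KINASE ACTIVITY", "GO", 1.242, 0.325, -0.917, 0.002),
    ("NUCLEOTIDE EXCISION REPAIR", "KEGG", 0.113, 0.398, 0.285, 0.050),
    ("TIGHT JUNCTION", "KEGG", 0.389, 0.654, 0.265, 0.019),
    ("DNA POLYMERASE ACTIVITY", "GO", 0.000, 0.812, 0.812, 0.008),
    ("DNA DIRECTED DNA POLYMERASE ACTIVITY", "GO", 0.000, 0.626, 0.626, 0.008),
]


def pathway_score_table() -> pd.DataFrame:
    """The published per-set group scores as a DataFrame."""
    return pd.DataFrame(
        _ROWS,
        columns=["function", "source", "score_good", "score_poor", "dif_score", "p_val"],
    )
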