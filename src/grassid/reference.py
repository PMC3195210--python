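"""Bundled reference statistics from a published greenhouse study.

These tables come from a greenhouse experiment that imaged wheat, annual
ryegrass and brome grass seedlings at the 1–4 leaf stage and fitted a
Varimax-rotated three-component model on six selected features (n = 229
training images). The original images are not publicly deposited, so the
numbers serve two purposes here: worked-example oracles for the package's
arithmetic, and a ready-made scoring profile (``reference-2011``) usable on
pre-standardized feature vectors without refitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES

#: Features retained by the |r| >= 0.7 redundancy filter in the reference study.
REFERENCE_SELECTED = ["r_i", "RBI", "EBI", "W", "WDR", "U_t"]

# Pearson correlations among all 11 features in the reference training set,
# printed to one decimal (lower triangle mirrored).
_CORR_LOWER = [
    [1.0],
    [-0.7, 1.0],
    [-0.3, -0.5, 1.0],
    [0.4, -0.9, 0.6, 1.0],
    [-0.7, 1.0, -0.4, -0.9, 1.0],
    [0.4, 0.4, -1.0, -0.5, 0.3, 1.0],
    [0.5, 0.3, -1.0, -0.5, 0.2, 1.0, 1.0],
    [-0.6, 0.6, 0.0, -0.4, 0.6, -0.1, -0.2, 1.0],
    [0.4, -0.3, -0.1, 0.3, -0.3, 0.2, 0.2, -0.3, 1.0],
    [0.3, -0.2, -0.1, 0.2, -0.2, 0.1, 0.1, -0.2, 0.5, 1.0],
    [-0.4, 0.2, 0.2, -0.2, 0.3, -0.2, -0.2, 0.3, -0.5, -0.9, 1.0],
]


def reference_correlation_matrix() -> pd.DataFrame:
    """The study's printed 11×11 feature correlation matrix (symmetrized)."""
    n = len(FEATURE_NAMES)
    m = np.zeros((n, n))
    for i, row in enumerate(_CORR_LOWER):
        m[i, : len(row)] = row
    m = m + m.T - np.diag(np.diag(m))
    return pd.DataFrame(m, index=FEATURE_NAMES, columns=FEATURE_NAMES)


#: Eigenvalues of the three retained components (correlation-matrix PCA of the
#: six selected features) and the percentage of total variance each explains.
REFERENCE_EIGENVALUES = [2.50, 1.51, 1.00]
REFERENCE_EXPLAINED_PCT = [41.74, 25.21, 16.66]

#: Component score coefficient matrix (regression method) of the reference
#: model: multiplying a standardized six-feature row vector by this matrix
#: yields the three component scores.
REFERENCE_SCORE_COEFFICIENTS = pd.DataFrame(
    [
        [0.482, 0.127, -0.081],
        [0.251, -0.515, -0.022],
        [0.183, 0.602, -0.018],
        [-0.470, 0.055, 0.114],
        [-0.088, -0.020, 0.574],
        [-0.180, 0.011, 0.651],
    ],
    index=REFERENCE_SELECTED,
    columns=["PC1", "PC2", "PC3"],
)

#: One-way ANOVA sums of squares / degrees of freedom on the training-set
#: component scores (groups: the three species; total df = 228 at n = 229).
REFERENCE_ANOVA_SUMS = {
    "PC1": {"ss_between": 47.208, "df_between": 2, "ss_within": 180.792, "df_within": 226},
    "PC2": {"ss_between": 22.985, "df_between": 2, "ss_within": 205.015, "df_within": 226},
    "PC3": {"ss_between": 30.213, "df_between": 2, "ss_within": 197.787, "df_within": 226},
}

#: Per-species descriptive statistics of the training-set scores
#: (n, mean, sd and the printed 95% CI bounds).
REFERENCE_DESCRIPTIVES = pd.DataFrame(
    [
        ("PC1", "wheat", 87, -0.21, 0.76, -0.37, -0.05),
        ("PC1", "brome", 104, -0.19, 1.01, -0.39, 0.00),
        ("PC1", "ryegrass", 38, 1.02, 0.82, 0.75, 1.29),
        ("PC2", "wheat", 87, -0.26, 1.07, -0.49, -0.03),
        ("PC2", "brome", 104, 0.35, 0.88, 0.17, 0.52),
        ("PC2", "ryegrass", 38, -0.35, 0.86, -0.64, -0.07),
        ("PC3", "wheat", 87, 0.24, 0.92, 0.05, 0.44),
        ("PC3", "brome", 104, 0.09, 0.90, -0.09, 0.26),
        ("PC3", "ryegrass", 38, -0.80, 1.06, -1.15, -0.45),
    ],
    columns=["component", "species", "n", "mean", "sd", "ci_low", "ci_high"],
)
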