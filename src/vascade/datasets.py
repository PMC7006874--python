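"""Bundled reference data.

``load_study_correlations`` returns the published pairwise correlation
matrix of the 46-subject aging cohort (age, pulse elasticity, lesion and
thickness measures, the two segregation indices, and the six cognitive
constructs). It is the input for the printed-matrix ("closed-form") mode
of the cascade analysis, where composite correlations are derived
algebraically instead of from subject rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Number of subjects behind the bundled correlation matrix.
STUDY_N = 46


def load_study_correlations() -> pd.DataFrame:
    """Labeled, symmetric 12-variable correlation matrix (unit diagonal)."""
    with resources.files("vascade.data").joinpath("study_correlations.csv").open() as f:
        R = pd.read_csv(f, index_col=0)
    R.columns.name = None
    return R
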