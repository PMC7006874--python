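"""Cognitive construct composites and adjusted white-matter lesion volume.

Raw neuropsychological test scores are standardized across the sample
(raw scores, never age-normed ones, so age effects stay in the data) and
averaged within a-priori constructs. Trail Making A times are
sign-inverted after standardization, since longer times mean slower
performance. White-matter signal abnormality (WMSA) volume is
log-transformed (its raw distribution is strongly right-skewed) and
residualized on intracranial volume and sex.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Tests whose raw score is a completion time (larger = worse).
TIMED_TESTS = ("trail_a", "trail_b")

#: Construct -> member standardized-score columns. ``trail_a_inv`` is the
#: sign-inverted Trail A z-score; ``trail_a_minus_b`` is computed on raw
#: seconds (A - B) and then standardized.
DEFAULT_CONSTRUCTS: dict[str, list[str]] = {
    "episodic_memory": [
        "logical_memory_immediate", "logical_memory_delayed",
        "verbal_pairing_immediate", "verbal_pairing_delayed",
    ],
    "processing_speed": ["trail_a_inv"],
    "verbal_fluency": ["cfl"],
    "working_memory": ["trail_a_minus_b", "ospan"],
    "reasoning": ["raven", "kbit_nonverbal"],
    "verbal_ability": ["shipley_vocab", "kbit_verbal"],
}

#: Raw score columns the default construct set expects.
RAW_TEST_COLUMNS = (
    "logical_memory_immediate", "logical_memory_delayed",
    "verbal_pairing_immediate", "verbal_pairing_delayed",
    "trail_a", "trail_b", "cfl", "ospan", "raven",
    "kbit_nonverbal", "shipley_vocab", "kbit_verbal",
)


def zscore(x: pd.Series | np.ndarray) -> np.ndarray:
    """Sample z-score with the usual divide-by-(n-1) SD convention, so
    three scores {10, 20, 30} map to {-1, 0, +1}."""
    x = np.asarray(x, dtype=float)
    mu = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero-variance column cannot be standardized")
    return (x - mu) / sd


def zscore_tests(raw: pd.DataFrame) -> pd.DataFrame:
    """Standardize every raw test column; add derived columns.

    Adds ``trail_a_inv`` (inverted Trail A z, so faster = higher) and
    ``trail_a_minus_b`` (raw A - B seconds, standardized). Missing values
    propagate as NaN.
    """
    if len(raw) < 3:
        raise ValueError("need at least 3 subjects to standardize")
    for col in TIMED_TESTS:
        if col in raw and (raw[col] <= 0).any():
            raise ValueError(f"non-positive completion time in {col!r}")
    z = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        if not np.issubdtype(raw[col].dtype, np.number):
            continue
        z[col] = zscore(raw[col])
    if "trail_a" in z:
        z["trail_a_inv"] = -z["trail_a"]
    if {"trail_a", "trail_b"}.issubset(raw.columns):
        z["trail_a_minus_b"] = zscore(raw["trail_a"] - raw["trail_b"])
    return z


def build_constructs(z: pd.DataFrame,
                     spec: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Construct score = mean of member standardized scores."""
    spec = DEFAULT_CONSTRUCTS if spec is None else spec
    out = pd.DataFrame(index=z.index)
    for name, members in spec.items():
        missing = [m for m in members if m not in z.columns]
        if missing:
            raise ValueError(f"construct {name!r} missing member tests {missing}")
        out[name] = z[members].mean(axis=1)
    return out


def adjust_wmsa(raw_wmsa: np.ndarray, icv: np.ndarray,
                sex: np.ndarray) -> np.ndarray:
    """Log-transform WMSA volume and residualize on ICV and sex.

    Returns the least-squares residuals of log(WMSA) on an intercept,
    intracranial volume and a binary sex code, in log-mm^3 units.
    """
    raw_wmsa = np.asarray(raw_wmsa, dtype=float)
    icv = np.asarray(icv, dtype=float)
    if np.any(raw_wmsa <= 0) or np.any(icv <= 0):
        raise ValueError("volumes must be positive")
    y = np.log(raw_wmsa)
    x = np.column_stack([np.ones_like(y), icv, np.asarray(sex, dtype=float)])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def constructs_from_raw(raw: pd.DataFrame,
                        spec: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Convenience: raw scores straight to construct composites."""
    return build_constructs(zscore_tests(raw), spec)
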