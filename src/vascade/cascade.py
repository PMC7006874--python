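"""Statistics for the hierarchical vascular-structure-function-cognition
cascade.

The cascade hypothesis orders subject-level variables into four tiers —
cerebral arterial elasticity, brain structure, network segregation, and
cognition — and predicts that correlations between tier composites decay
with the number of intervening tiers. This module provides the pairwise
one-tailed and partial correlations used for the per-variable analyses,
the tier ("level") composites and their 4x4 correlation matrix, a
closed-form twin that computes the same composite correlations directly
from a printed correlation matrix, and the bootstrap ordering test on
the 1-, 2- and 3-off-diagonal means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: (variable, sign) lists for the four cascade levels, innermost first.
#: Signs align each variable with "healthier = larger" within its level
#: (lesion volume enters negatively).
DEFAULT_LEVEL_SPEC: list[list[tuple[str, int]]] = [
    [("prefx", +1)],
    [("cortical_thickness", +1), ("wmsa", -1)],
    [("assoc_segregation", +1), ("sm_segregation", +1)],
    [("episodic_memory", +1), ("reasoning", +1)],
]

LEVEL_NAMES = ("vascular", "structure", "function", "cognition")

# index pairs (0-based) at each off-diagonal distance of the 4x4 matrix
_OFFDIAG = {
    1: [(0, 1), (1, 2), (2, 3)],
    2: [(0, 2), (1, 3)],
    3: [(0, 3)],
}


@dataclass
class CascadeResult:
    """Level correlation matrix, off-diagonal means, bootstrap p-values."""

    level_names: tuple[str, ...]
    matrix: np.ndarray  # signed 4x4 composite correlations
    m_raw: tuple[float, float, float]  # raw means of |r| at distance 1,2,3
    m_fisher: tuple[float, float, float]  # Fisher-mean (tanh of mean atanh|r|)
    n: int | None = None
    bootstrap_p: dict[str, float] = field(default_factory=dict)
    n_boot: int = 0
    seed: int | None = None
    n_degenerate_redrawn: int = 0

    @property
    def abs_matrix(self) -> np.ndarray:
        out = np.abs(self.matrix)
        np.fill_diagonal(out, 1.0)
        return out


def pearson_one_tailed(x, y, direction: str = "positive") -> tuple[float, float]:
    """Pearson r with a one-tailed p in the hypothesized direction.

    p is computed from t = r*sqrt((n-2)/(1-r^2)) on n-2 df; pairs with a
    missing value in either variable are dropped (pairwise-complete).
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    denom = 1.0 - r**2
    t = np.inf * np.sign(r) if denom <= 0 else r * np.sqrt((n - 2) / denom)
    if direction == "positive":
        p = float(stats.t.sf(t, df=n - 2))
    else:
        p = float(stats.t.cdf(t, df=n - 2))
    return r, p


def partial_correlation(x, y, covariates) -> float:
    """Correlation of x and y after removing linear effects of covariates.

    Both variables are residualized by OLS (with intercept) on the
    covariate block; the Pearson correlation of the residuals is the
    partial correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariates, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n, k = z.shape
    if n <= k + 3:
        raise ValueError("too few observations for the covariate count")
    design = np.column_stack([np.ones(n), z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    return float(np.corrcoef(rx, ry)[0, 1])


def partial_correlation_closed_form(rxy: float, rxz: float, ryz: float) -> float:
    """Single-covariate partial correlation from the three pairwise r's."""
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise ValueError("covariate perfectly correlated with x or y")
    return (rxy - rxz * ryz) / denom


def paired_t_segregation(assoc, sensorimotor) -> tuple[float, float]:
    """Paired two-sample t-test between the two segregation indices."""
    assoc = np.asarray(assoc, dtype=float)
    sensorimotor = np.asarray(sensorimotor, dtype=float)
    if assoc.shape != sensorimotor.shape or assoc.size < 3:
        raise ValueError("need equal-length paired vectors, n >= 3")
    d = assoc - sensorimotor
    if d.std(ddof=1) == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = stats.ttest_rel(assoc, sensorimotor)
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(alpha: float = 0.05, m: int = 6) -> float:
    """Bonferroni-adjusted per-test alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def build_level_composites(table: pd.DataFrame,
                           spec=None) -> pd.DataFrame:
    """Per-subject level scores: z-score, sign-align, average per level."""
    spec = DEFAULT_LEVEL_SPEC if spec is None else spec
    out = {}
    for name, level in zip(LEVEL_NAMES, spec):
        cols = []
        for var, sign in level:
            if var not in table.columns:
                raise ValueError(f"variable {var!r} missing from subject table")
            v = table[var].to_numpy(dtype=float)
            sd = np.nanstd(v)
            if sd == 0:
                raise ValueError(f"zero-variance variable {var!r}")
            cols.append(sign * (v - np.nanmean(v)) / sd)
        out[name] = np.mean(cols, axis=0)
    return pd.DataFrame(out, index=table.index)


def closed_form_composite_corr(R: pd.DataFrame, level_a, level_b) -> float:
    """Correlation of two equally weighted standardized composites, from a
    correlation matrix alone.

    With signed standardized components, the composite correlation is

        sum_{i in A, j in B} s_i s_j r_ij /
        sqrt[(k_A + 2 sum_{i<i'} s_i s_i' r_ii')(k_B + 2 sum_{j<j'} ...)]

    which is exact whenever ``R`` is the sample correlation matrix of the
    same subjects the composites would be built from.
    """
    def signed_cross(la, lb):
        return sum(si * sj * R.loc[vi, vj] for vi, si in la for vj, sj in lb)

    def implied_var(level):
        k = len(level)
        s = sum(si * sj * R.loc[vi, vj]
                for a, (vi, si) in enumerate(level)
                for vj, sj in level[a + 1:])
        return k + 2 * s

    va, vb = implied_var(level_a), implied_var(level_b)
    if va <= 0 or vb <= 0:
        raise ValueError("non-positive implied composite variance")
    return float(signed_cross(level_a, level_b) / np.sqrt(va * vb))


def level_matrix_from_R(R: pd.DataFrame, spec=None) -> np.ndarray:
    """4x4 level correlation matrix in closed form from component r's."""
    spec = DEFAULT_LEVEL_SPEC if spec is None else spec
    k = len(spec)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = closed_form_composite_corr(R, spec[i], spec[j])
    return out


def offdiag_means(matrix: np.ndarray,
                  fisher: bool = False) -> tuple[float, float, float]:
    """Means of |r| at off-diagonal distances 1, 2, 3 of the 4x4 matrix.

    With ``fisher=True`` the mean is taken on the atanh scale and mapped
    back through tanh (the convention used for the bootstrap contrasts).
    """
    vals = []
    for d in (1, 2, 3):
        entries = np.array([abs(matrix[i, j]) for i, j in _OFFDIAG[d]])
        if fisher:
            vals.append(float(np.tanh(np.arctanh(entries).mean())))
        else:
            vals.append(float(entries.mean()))
    return tuple(vals)


def cascade_analysis(table: pd.DataFrame, spec=None) -> CascadeResult:
    """Level composites, their correlation matrix and off-diagonal means."""
    comp = build_level_composites(table, spec)
    mat = np.corrcoef(comp.to_numpy(dtype=float), rowvar=False)
    return CascadeResult(
        level_names=LEVEL_NAMES,
        matrix=mat,
        m_raw=offdiag_means(mat, fisher=False),
        m_fisher=offdiag_means(mat, fisher=True),
        n=len(table),
    )


def cascade_from_matrix(R: pd.DataFrame, spec=None,
                        n: int | None = None) -> CascadeResult:
    """Same summary, computed in closed form from a printed correlation
    matrix instead of subject rows."""
    mat = level_matrix_from_R(R, spec)
    return CascadeResult(
        level_names=LEVEL_NAMES,
        matrix=mat,
        m_raw=offdiag_means(mat, fisher=False),
        m_fisher=offdiag_means(mat, fisher=True),
        n=n,
    )


def _composite_design(table: pd.DataFrame, spec) -> tuple[np.ndarray, list, list]:
    """Variable matrix plus per-level column indices and signs."""
    cols, index_sets, sign_sets = [], [], []
    for level in spec:
        idx, sgn = [], []
        for var, sign in level:
            if var not in table.columns:
                raise ValueError(f"variable {var!r} missing from subject table")
            idx.append(len(cols))
            sgn.append(float(sign))
            cols.append(table[var].to_numpy(dtype=float))
        index_sets.append(np.array(idx))
        sign_sets.append(np.array(sgn))
    return np.column_stack(cols), index_sets, sign_sets


def _batched_level_corr(xb: np.ndarray, index_sets, sign_sets) -> np.ndarray:
    """(B, n, p) resampled variables -> (B, 4, 4) composite correlations.

    Variables are re-standardized within each resample, as the composite
    definition requires.
    """
    mu = xb.mean(axis=1, keepdims=True)
    sd = xb.std(axis=1, keepdims=True)
    zb = (xb - mu) / sd
    comps = np.stack(
        [(zb[:, :, idx] * sgn).mean(axis=2)
         for idx, sgn in zip(index_sets, sign_sets)],
        axis=2,
    )  # (B, n, 4)
    comps = comps - comps.mean(axis=1, keepdims=True)
    cov = np.einsum("bni,bnj->bij", comps, comps)
    d = np.sqrt(np.einsum("bii->bi", cov))
    return cov / (d[:, :, None] * d[:, None, :])


def _fisher_offdiag(mats: np.ndarray, signed: bool = False) -> np.ndarray:
    """(B, 4, 4) matrices -> (B, 3) atanh-scale off-diagonal means.

    With ``signed=True`` the correlations keep their signs (the level
    spec's sign alignment makes them positive in expectation); otherwise
    absolute values are used, matching the reporting convention.
    """
    out = np.empty((mats.shape[0], 3))
    for col, d in enumerate((1, 2, 3)):
        ij = _OFFDIAG[d]
        vals = np.stack([mats[:, i, j] for i, j in ij], axis=1)
        if not signed:
            vals = np.abs(vals)
        out[:, col] = np.arctanh(np.clip(vals, -1 + 1e-12, 1 - 1e-12)).mean(axis=1)
    return out


def bootstrap_cascade(table: pd.DataFrame, spec=None, n_boot: int = 10_000,
                      seed: int | None = None,
                      max_redraws: int = 100) -> CascadeResult:
    """Bootstrap ordering test on the off-diagonal means.

    Subjects are resampled with replacement (same n); for each resample
    the level composites are rebuilt, the 4x4 matrix recomputed, and the
    Fisher-transformed off-diagonal means m1, m2, m3 extracted. The
    p-value for a contrast (m1 - m3, m2 - m3, m1 - m2) is the fraction of
    resamples in which the contrast is <= 0, i.e. in which the observed
    ordering fails to hold. Resamples with a zero-variance variable are
    redrawn and counted.

    The bootstrap means keep the correlations' signs (the level spec's
    sign-coherence step makes them positive in expectation); folding to
    absolute values would bias the means of near-zero correlations
    upward and make the test conservative on null data. The reported
    ``m_raw``/``m_fisher`` summaries remain on the absolute scale.
    """
    spec = DEFAULT_LEVEL_SPEC if spec is None else spec
    if len(table) < 10:
        raise ValueError("need at least 10 subjects to bootstrap")
    if n_boot < 100:
        raise ValueError("need at least 100 resamples")
    rng = np.random.default_rng(seed)
    table = table.sort_index()  # row-order invariance under a fixed seed
    x, index_sets, sign_sets = _composite_design(table, spec)
    n = x.shape[0]

    base = cascade_analysis(table, spec)

    idx = rng.integers(0, n, size=(n_boot, n))
    xb = x[idx]
    n_redrawn = 0
    for _ in range(max_redraws):
        bad = np.flatnonzero((xb.std(axis=1) == 0).any(axis=1))
        if bad.size == 0:
            break
        n_redrawn += bad.size
        idx[bad] = rng.integers(0, n, size=(bad.size, n))
        xb = x[idx]
    else:
        raise RuntimeError("degenerate resamples persisted after redraws")

    mats = _batched_level_corr(xb, index_sets, sign_sets)
    m = _fisher_offdiag(mats, signed=True)  # (B, 3) on atanh scale
    contrasts = {
        "m1_minus_m3": (0, 2),
        "m2_minus_m3": (1, 2),
        "m1_minus_m2": (0, 1),
    }
    pvals = {}
    for name, (a, b) in contrasts.items():
        diff = m[:, a] - m[:, b]
        pvals[name] = float(np.mean(diff <= 0))
    return CascadeResult(
        level_names=LEVEL_NAMES,
        matrix=base.matrix,
        m_raw=base.m_raw,
        m_fisher=base.m_fisher,
        n=n,
        bootstrap_p=pvals,
        n_boot=n_boot,
        seed=seed,
        n_degenerate_redrawn=n_redrawn,
    )
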