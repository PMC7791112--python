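"""Permutation-based differential-expression caller.

Per gene, two observed statistics are computed between the test (knockout)
and reference groups on quantile-normalized log2 expression:

* the classic pooled-variance Student t statistic, and
* the log2-median-ratio (difference of group medians), the fold-change
  statistic.

Empirical null distributions of both statistics are built by reassigning the
group labels over the samples (default: 1000 random reassignments; a 3-vs-3
design also supports exhaustive enumeration of all C(6,3) = 20 assignments).
Two-sided empirical p-values with add-one correction are combined with a
signed Stouffer z-average, and a fold-change cutoff is derived from the
pooled null as the mean of the absolute 2.5th and 97.5th percentiles. A gene
is called differentially expressed when its combined p-value is below alpha
AND its absolute log2 fold change strictly exceeds the cutoff.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .containers import SCALE_LOG2_QNORM, ExpressionMatrix, GroupDesign
from .errors import DesignError, ParameterError, StateError
from .simulate import stream_rng

NULL_MODES = ("pooled", "per_gene", "exhaustive")
CUTOFF_READINGS = ("mean_of_abs", "abs_of_mean")


@dataclass(frozen=True)
class DegCallParams:
    """Tuning knobs of the DEG caller.

    ``null_mode`` chooses the granularity of the permutation null: ``pooled``
    (default) flattens permuted statistics across genes, ``per_gene`` keeps a
    separate null per gene, ``exhaustive`` enumerates every distinct label
    assignment. ``cutoff_reading`` selects between the two readings of the
    percentile cutoff: (|q2.5| + |q97.5|) / 2 (default) or |(q2.5 + q97.5) / 2|.
    """

    n_perm: int = 1000
    alpha: float = 0.05
    fc_cutoff_mode: str = "null_percentile"  # or "fixed"
    fixed_cutoff_log2: float | None = None
    null_mode: str = "pooled"
    cutoff_reading: str = "mean_of_abs"
    bh_fdr: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ParameterError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.null_mode not in NULL_MODES:
            raise ParameterError(f"null_mode must be one of {NULL_MODES}")
        if self.fc_cutoff_mode not in ("null_percentile", "fixed"):
            raise ParameterError("fc_cutoff_mode must be null_percentile or fixed")
        if self.fc_cutoff_mode == "fixed" and self.fixed_cutoff_log2 is None:
            raise ParameterError("fixed cutoff mode requires fixed_cutoff_log2")
        if self.cutoff_reading not in CUTOFF_READINGS:
            raise ParameterError(f"cutoff_reading must be one of {CUTOFF_READINGS}")


@dataclass
class NullDistribution:
    """Permuted statistic values, one row per gene, one column per
    permutation (label assignment)."""

    mode: str
    n_perm: int
    t_null: np.ndarray  # (n_genes, n_perm)
    fc_null: np.ndarray  # (n_genes, n_perm)
    seed: int

    def pooled_t(self) -> np.ndarray:
        return self.t_null.ravel()

    def pooled_fc(self) -> np.ndarray:
        return self.fc_null.ravel()


def t_statistic(group_a, group_b) -> float:
    """Pooled-variance two-sample t of mean(a) - mean(b).

    Zero pooled variance with equal means gives 0; with unequal means a
    signed infinity, ranked as more extreme than any finite null value.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DesignError("each group needs at least two values")
    return float(_t_stats(a[None, :], b[None, :])[0])


def _t_stats(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Vectorized pooled t over the last axis; degenerate-variance rules as
    in :func:`t_statistic`."""
    na, nb = A.shape[-1], B.shape[-1]
    ma, mb = A.mean(axis=-1), B.mean(axis=-1)
    va = A.var(axis=-1, ddof=1)
    vb = B.var(axis=-1, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    zero_var = sp2 == 0
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & (diff == 0), 0.0, t)
        t = np.where(zero_var & (diff != 0), np.sign(diff) * np.inf, t)
    return t


def log2_median_ratio(group_a, group_b) -> float:
    """median(a) - median(b) on the log2 scale (the fold-change statistic)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise DesignError("each group needs at least one value")
    return float(np.median(a) - np.median(b))


def _fc_stats(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return np.median(A, axis=-1) - np.median(B, axis=-1)


def _assignments(
    n_samples: int, n_test: int, params: DegCallParams
) -> np.ndarray:
    """Rows of sample indices forming the pseudo test group."""
    if params.null_mode == "exhaustive":
        combos = list(itertools.combinations(range(n_samples), n_test))
        return np.array(combos, dtype=int)
    rng = stream_rng(params.seed, "permutation")
    rows = np.empty((params.n_perm, n_test), dtype=int)
    for i in range(params.n_perm):
        rows[i] = rng.permutation(n_samples)[:n_test]
    return rows


def build_null(
    matrix: ExpressionMatrix, design: GroupDesign, params: DegCallParams
) -> NullDistribution:
    """Permutation null of both statistics for every gene.

    Each permutation reassigns the group labels over the samples preserving
    group sizes, then recomputes t and the log2-median-ratio per gene.
    """
    matrix.require_scale(SCALE_LOG2_QNORM)
    X = matrix.values()
    n_samples = matrix.n_samples
    test_idx = design.indices(matrix.sample_ids, design.test_group)
    n_test = len(test_idx)
    assignments = _assignments(n_samples, n_test, params)
    K = len(assignments)
    all_idx = np.arange(n_samples)
    comp = np.array(
        [np.setdiff1d(all_idx, row, assume_unique=True) for row in assignments]
    )
    g = X.shape[0]
    t_null = np.empty((g, K))
    fc_null = np.empty((g, K))
    # chunk over permutations to bound the (genes x perms x group) scratch
    chunk = max(1, int(4_000_000 // max(1, g * n_samples)) or 1)
    for lo in range(0, K, chunk):
        hi = min(K, lo + chunk)
        A = X[:, assignments[lo:hi]]  # (g, c, n_test)
        B = X[:, comp[lo:hi]]
        t_null[:, lo:hi] = _t_stats(A, B)
        fc_null[:, lo:hi] = _fc_stats(A, B)
    return NullDistribution(
        mode=params.null_mode,
        n_perm=K,
        t_null=t_null,
        fc_null=fc_null,
        seed=params.seed,
    )


def empirical_pvalue(observed: float, null_values) -> float:
    """Two-sided empirical p with add-one correction:
    (1 + #{|null| >= |observed|}) / (1 + N); always in (0, 1]."""
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise StateError("empty null distribution")
    count = int((np.abs(null) >= abs(observed)).sum())
    return (1 + count) / (1 + null.size)


def _empirical_pvalues(
    observed: np.ndarray, null_matrix: np.ndarray, pooled: bool
) -> np.ndarray:
    obs = np.abs(np.asarray(observed, dtype=float))
    if null_matrix.size == 0:
        raise StateError("empty null distribution")
    if pooled:
        flat = np.sort(np.abs(null_matrix.ravel()))
        n = flat.size
        count = n - np.searchsorted(flat, obs, side="left")
        return (1 + count) / (1 + n)
    count = (np.abs(null_matrix) >= obs[:, None]).sum(axis=1)
    return (1 + count) / (1 + null_matrix.shape[1])


def _z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    """Directional evidence z = max(Phi^-1(1 - p), 0) * sign.

    The floor at zero makes p = 1 contribute nothing rather than flipping
    direction; p values above 0.5 carry no directional evidence.
    """
    return np.maximum(norm.isf(p), 0.0) * sign


def stouffer_combine(
    p_t: float, p_fc: float, sign_t: float, sign_fc: float
) -> float:
    """Signed Stouffer combination of two two-sided empirical p-values.

    z_i = max(Phi^-1(1 - p_i), 0) * sign_i; z_c = (z_t + z_fc) / sqrt(2);
    returns 2 * (1 - Phi(|z_c|)). Concordant signs reinforce, discordant
    signs cancel.
    """
    for p in (p_t, p_fc):
        if not 0.0 < p <= 1.0:
            raise ParameterError(f"p-value {p} outside (0, 1]")
    z = _z_from_p(np.array([p_t, p_fc]), np.array([sign_t, sign_fc]))
    z_c = z.sum() / math.sqrt(2.0)
    return float(min(1.0, 2.0 * norm.sf(abs(z_c))))


def fold_change_cutoff(
    fc_null, reading: str = "mean_of_abs"
) -> float:
    """Fold-change cutoff from the pooled null: the mean of the absolute
    2.5th and 97.5th percentiles (default reading), or the absolute mean of
    the two percentiles. Percentiles use linear interpolation."""
    values = np.asarray(fc_null, dtype=float).ravel()
    if values.size == 0:
        raise StateError("empty fold-change null")
    q_lo, q_hi = np.percentile(values, [2.5, 97.5])
    if reading == "mean_of_abs":
        return float((abs(q_lo) + abs(q_hi)) / 2.0)
    if reading == "abs_of_mean":
        return float(abs((q_lo + q_hi) / 2.0))
    raise ParameterError(f"unknown cutoff reading {reading!r}")


def call_degs(
    matrix: ExpressionMatrix,
    design: GroupDesign,
    params: DegCallParams | None = None,
) -> tuple[pd.DataFrame, dict, NullDistribution]:
    """Full DEG call on a preprocessed (quantile-normalized log2) matrix.

    Returns the per-gene statistics table, a run summary, and the null
    distribution. A gene is a DEG iff combined p < alpha and |log2 fold
    change| strictly exceeds the cutoff; direction follows the sign of the
    fold change (test group minus reference).
    """
    params = params or DegCallParams()
    matrix.require_scale(SCALE_LOG2_QNORM)
    X = matrix.values()
    test_idx = design.indices(matrix.sample_ids, design.test_group)
    ref_idx = design.indices(matrix.sample_ids, design.reference)
    if len(test_idx) < 2 or len(ref_idx) < 2:
        raise DesignError("each group needs at least two samples")
    A = X[:, test_idx]
    B = X[:, ref_idx]
    t_obs = _t_stats(A, B)
    fc_obs = _fc_stats(A, B)

    null = build_null(matrix, design, params)
    pooled = params.null_mode == "pooled"
    p_t = _empirical_pvalues(t_obs, null.t_null, pooled)
    p_fc = _empirical_pvalues(fc_obs, null.fc_null, pooled)

    z = _z_from_p(p_t, np.sign(t_obs)) + _z_from_p(p_fc, np.sign(fc_obs))
    z_c = z / math.sqrt(2.0)
    p_combined = np.minimum(1.0, 2.0 * norm.sf(np.abs(z_c)))

    p_select = p_combined
    q_values = None
    if params.bh_fdr and len(p_combined):
        from statsmodels.stats.multitest import multipletests

        _, q_values, _, _ = multipletests(p_combined, method="fdr_bh")
        p_select = q_values

    if params.fc_cutoff_mode == "fixed":
        cutoff = float(params.fixed_cutoff_log2)
    else:
        cutoff = fold_change_cutoff(null.pooled_fc(), params.cutoff_reading)

    is_deg = (p_select < params.alpha) & (np.abs(fc_obs) > cutoff)
    direction = np.where(
        is_deg, np.where(fc_obs > 0, "up", "down"), "none"
    )

    table = pd.DataFrame(
        {
            "t_stat": t_obs,
            "log2_fc": fc_obs,
            "p_t": p_t,
            "p_fc": p_fc,
            "p_combined": p_combined,
            "direction": direction,
            "is_deg": is_deg,
        },
        index=pd.Index(matrix.gene_ids, name="gene_id"),
    )
    if q_values is not None:
        table.insert(5, "q_combined", q_values)

    n_up = int((direction == "up").sum())
    n_down = int((direction == "down").sum())
    summary = {
        "n_genes_expressed": matrix.n_genes,
        "cutoff_log2": cutoff,
        "cutoff_fold": float(2.0**cutoff),
        "n_deg": n_up + n_down,
        "n_up": n_up,
        "n_down": n_down,
        "alpha": params.alpha,
        "n_perm": null.n_perm,
        "null_mode": params.null_mode,
        "seed": params.seed,
    }
    return table, summary, null
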