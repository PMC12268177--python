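"""Expression normalization and time-course differential expression.

Counts are scaled between libraries by TMM (trimmed mean of M-values) and
converted to a length-normalized per-million "expression value":

    value = count / (library_size * factor) * 1e6 / (length_bp / 1000)

Time-course differential expression fits, per gene, a polynomial in stage
time (degree min(3, n_stages - 1)) to log(value + 1) and tests the full
polynomial against the intercept-only model with an F-test; Benjamini-
Hochberg FDR across genes flags DEGs at q < 0.05.  Significant genes are
grouped into k temporal profiles (default nine) by k-means on z-scored mean
stage profiles.  This single full-vs-null F-test plus profile clustering is
a deliberate simplification of maSigPro's two-step stepwise selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

DEFAULT_TRIM_M = 0.30
DEFAULT_TRIM_A = 0.05
DEFAULT_ALPHA = 0.05
DEFAULT_MAX_DEGREE = 3
DEFAULT_K = 9
KMEANS_RESTARTS = 25


@dataclass
class CountMatrix:
    """Integer counts (genes x samples) with stage/replicate metadata.

    ``samples`` has one row per column of ``counts`` with columns
    (sample, stage, replicate, time); ``lengths`` maps gene -> exonic bp.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.lengths.loc[self.counts.index] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if list(self.samples["sample"]) != list(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)


def tmm_factors(
    counts: pd.DataFrame,
    trim_M: float = DEFAULT_TRIM_M,
    trim_A: float = DEFAULT_TRIM_A,
    library_sizes: pd.Series | np.ndarray | None = None,
) -> pd.Series:
    """TMM scaling factor per sample, geometric mean 1.

    M-values are log2 ratios of depth-normalized counts against a reference
    sample (the one whose upper quartile is closest to the mean upper
    quartile); genes with a zero in either sample are excluded, the most
    extreme ``trim_M`` of M-values and ``trim_A`` of A-values are trimmed,
    and the remaining M-values are averaged with inverse-variance weights.
    ``library_sizes`` defaults to column sums; passing equal sizes reduces
    M-values to raw count ratios.
    """
    X = counts.to_numpy(dtype=np.float64)
    if X.shape[1] == 0:
        raise ValueError("no samples")
    if library_sizes is None:
        lib = X.sum(axis=0)
    else:
        lib = np.asarray(library_sizes, dtype=np.float64)
    if np.any(lib <= 0):
        raise ValueError("all-zero sample: TMM factor undefined")

    # reference: upper quartile of depth-normalized counts closest to the mean
    uq = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref:
            continue
        mask = (X[:, j] > 0) & (X[:, ref] > 0)
        if not mask.any():
            raise ValueError(f"sample {counts.columns[j]}: no genes shared with reference")
        cj, cr = X[mask, j], X[mask, ref]
        pj, pr = cj / lib[j], cr / lib[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        n = M.size
        # rank-based double trimming (edgeR convention)
        rM = stats.rankdata(M, method="average")
        rA = stats.rankdata(A, method="average")
        keep = (
            (rM >= np.floor(n * trim_M) + 1)
            & (rM <= n + 1 - (np.floor(n * trim_M) + 1))
            & (rA >= np.floor(n * trim_A) + 1)
            & (rA <= n + 1 - (np.floor(n * trim_A) + 1))
        )
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        # precision weights on count proportions (the deep-sequencing limit
        # of the binomial M-value variance): factors then depend on library
        # composition only, so rescaling a library leaves them unchanged
        w = 1.0 / pj + 1.0 / pr
        log_factors[j] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def expression_values(
    counts: CountMatrix, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Length- and depth-normalized expression values.

    ``value = count / (library_size * factor) * 1e6 / (length_bp / 1000)``.
    """
    if factors is None:
        factors = tmm_factors(counts.counts)
    lib = counts.library_sizes
    eff = lib * factors.loc[lib.index]
    lengths_kb = counts.lengths.loc[counts.counts.index] / 1000.0
    values = counts.counts.div(eff, axis=1) * 1e6
    return values.div(lengths_kb, axis=0)


def log_display(values: pd.DataFrame | pd.Series, offset: float = 1.0):
    """The "expression value + 1" display transform (monotone shift)."""
    return values + offset


@dataclass
class DegResult:
    """Per-gene time-course test results plus profile cluster assignment."""

    table: pd.DataFrame  # columns: F, pvalue, qvalue, is_deg, cluster

    @property
    def deg_genes(self) -> set[str]:
        return set(self.table.index[self.table["is_deg"]])

    def cluster_genes(self, cluster: int) -> set[str]:
        return set(self.table.index[self.table["cluster"] == cluster])

    @property
    def cluster_sets(self) -> dict[int, set[str]]:
        ids = sorted(int(c) for c in self.table["cluster"].dropna().unique())
        return {c: self.cluster_genes(c) for c in ids}


def timecourse_deg(
    expr: pd.DataFrame,
    times: pd.Series | np.ndarray,
    max_degree: int = DEFAULT_MAX_DEGREE,
    alpha: float = DEFAULT_ALPHA,
) -> DegResult:
    """Polynomial-in-time F-test per gene on log(value + 1).

    ``times`` gives the numeric stage time of each sample column (e.g.
    embryonic days 12, 13, 14, 16, honoring unequal spacing).  The full
    polynomial of degree ``min(max_degree, n_stages - 1)`` is tested against
    the intercept-only model; genes with zero variance and zero trend get
    p = 1 by convention.  Requires replication (more samples than model
    parameters).
    """
    t = np.asarray(times, dtype=np.float64)
    if t.size != expr.shape[1]:
        raise ValueError("times must match sample columns")
    n_stages = np.unique(t).size
    degree = min(max_degree, n_stages - 1)
    n = t.size
    df1 = degree
    df2 = n - (degree + 1)
    if df2 <= 0:
        raise ValueError("not enough replication for the variance estimate")

    tc = t - t.mean()
    X = np.vander(tc, degree + 1, increasing=True)
    Y = np.log(expr.to_numpy(dtype=np.float64) + 1.0)

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta
    rss1 = np.sum(resid**2, axis=0)
    rss0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)

    scale = np.maximum(rss0, 1.0)
    tiny = np.finfo(float).eps * n
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    p = np.where(
        rss0 / scale < tiny,  # zero variance, zero trend
        1.0,
        np.where(rss1 / scale < tiny, 0.0, stats.f.sf(F, df1, df2)),
    )
    F = np.where(np.isfinite(F), F, np.inf)
    q = bh_adjust(p)
    table = pd.DataFrame(
        {"F": F, "pvalue": p, "qvalue": q, "is_deg": q < alpha, "cluster": np.nan},
        index=expr.index,
    )
    return DegResult(table)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def cluster_profiles(
    deg_expr: pd.DataFrame,
    stage_of_sample: pd.Series | list[str],
    k: int = DEFAULT_K,
    seed: int = 0,
) -> pd.Series:
    """k-means clustering of z-scored mean stage profiles of DEGs.

    Profiles are per-gene mean expression per stage, z-scored across stages
    (flat genes get an all-zero profile).  Deterministic under a fixed seed;
    cluster ids are 1-based.
    """
    if len(deg_expr) < k:
        raise ValueError(
            f"only {len(deg_expr)} genes for k={k} clusters; use a smaller k"
        )
    stage = pd.Series(list(stage_of_sample), index=deg_expr.columns)
    means = deg_expr.T.groupby(stage, sort=False).mean().T
    prof = means.to_numpy(dtype=np.float64)
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True)
    z = np.where(sd > 0, (prof - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    km = KMeans(n_clusters=k, n_init=KMEANS_RESTARTS, random_state=seed)
    labels = km.fit_predict(z) + 1
    return pd.Series(labels, index=deg_expr.index, name="cluster")


def fold_change_deg(
    values_a: pd.Series,
    values_b: pd.Series,
    threshold: float = 2.0,
    offset: float = 1.0,
) -> tuple[set[str], set[str]]:
    """Twofold rule for single-replicate comparisons.

    With pseudocount ``offset``: up iff (b+1)/(a+1) > threshold, down iff
    (a+1)/(b+1) > threshold.  Returns (up_genes, down_genes).
    """
    a = values_a + offset
    b = values_b.loc[values_a.index] + offset
    up = set(values_a.index[(b / a) > threshold])
    down = set(values_a.index[(a / b) > threshold])
    return up, down


def two_group_test(
    values_a: pd.DataFrame,
    values_b: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Per-gene unpaired two-tailed Student's t-test with BH q-values.

    Genes with zero variance in both groups get p = 1 when the means are
    equal (and p = 0 when they differ).
    """
    if values_a.shape[1] < 2 or values_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    A = values_a.to_numpy(dtype=np.float64)
    B = values_b.loc[values_a.index].to_numpy(dtype=np.float64)
    t, p = stats.ttest_ind(A, B, axis=1, equal_var=True)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal = np.isclose(A.mean(axis=1), B.mean(axis=1))
        p = np.where(degenerate, np.where(equal, 1.0, 0.0), p)
        t = np.where(np.isfinite(t), t, np.where(equal, 0.0, np.inf))
    q = bh_adjust(p)
    return pd.DataFrame(
        {"t": t, "pvalue": p, "qvalue": q, "is_deg": q < alpha},
        index=values_a.index,
    )
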