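"""Gene-set overlap statistics and preranked GSEA.

Overlap between two gene sets within a finite universe is tested with
Fisher's exact test on the 2x2 table (a = in both, b = set1 only, c = set2
only, d = neither); whole families of sets (e.g. DEG clusters x DHS pattern
sets) are tested cell-by-cell with a joint Benjamini-Hochberg correction
across the matrix.

Preranked GSEA computes the classic weighted Kolmogorov-Smirnov running-sum
enrichment score: walking down the ranked list, hits increment the sum by
|score|^weight (normalized over hits) and misses decrement it by
1/(N - |S|); ES is the maximum deviation from zero.  The null is generated
by gene-label permutation; NES divides ES by the mean |null ES| of the same
sign and p comes from the same-sign null tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import bh_adjust

bh_fdr = bh_adjust


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for the overlap of two sets in a universe of N = a+b+c+d."""

    a: int  # in both sets
    b: int  # set1 only
    c: int  # set2 only
    d: int  # neither

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @classmethod
    def from_sets(cls, set1: set, set2: set, universe: set) -> "ContingencyTable2x2":
        bad = (set1 | set2) - universe
        if bad:
            raise ValueError(f"genes outside the universe: {sorted(bad)[:10]}")
        a = len(set1 & set2)
        b = len(set1 - set2)
        c = len(set2 - set1)
        return cls(a, b, c, len(universe) - a - b - c)


def fisher_exact(table: ContingencyTable2x2, alternative: str = "greater") -> float:
    """Exact hypergeometric tail probability of the observed overlap.

    ``alternative='greater'`` (default) tests for enrichment; 'less' and
    'two-sided' (summing outcomes no more probable than the observed one)
    are available.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    _, p = stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative=alternative
    )
    return float(p)


@dataclass
class OverlapMatrix:
    """Family-by-family Fisher overlap results.

    ``pvalue``, ``qvalue``, ``odds_ratio`` and ``overlap`` are frames with
    family-1 sets as rows and family-2 sets as columns; q-values are BH
    across all cells jointly.
    """

    pvalue: pd.DataFrame
    qvalue: pd.DataFrame
    odds_ratio: pd.DataFrame
    overlap: pd.DataFrame
    alternative: str

    def neg_log10_p(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return -np.log10(self.pvalue)


def overlap_matrix(
    family1: dict[str, set],
    family2: dict[str, set],
    universe: set,
    alternative: str = "greater",
) -> OverlapMatrix:
    """Fisher's exact test for every pair of sets across two families."""
    rows = list(family1)
    cols = list(family2)
    p = np.ones((len(rows), len(cols)))
    odds = np.full_like(p, np.nan)
    olap = np.zeros_like(p, dtype=int)
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            t = ContingencyTable2x2.from_sets(family1[r], family2[c], universe)
            p[i, j] = fisher_exact(t, alternative)
            olap[i, j] = t.a
            odds[i, j] = (t.a * t.d) / (t.b * t.c) if t.b * t.c > 0 else np.inf
    q = bh_adjust(p.ravel()).reshape(p.shape)
    mk = lambda x: pd.DataFrame(x, index=rows, columns=cols)
    return OverlapMatrix(mk(p), mk(q), mk(odds), mk(olap), alternative)


@dataclass
class GseaResult:
    """Enrichment score, normalized score, permutation p and leading edge."""

    es: float
    nes: float
    pvalue: float
    qvalue: float
    leading_edge: list[str]
    n_perm: int


def _running_es(is_hit: np.ndarray, weights: np.ndarray) -> tuple[float, int]:
    """Peak of the weighted KS running sum; returns (ES, peak index)."""
    n = is_hit.size
    n_hit = int(is_hit.sum())
    hit_w = np.where(is_hit, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all-zero scores in the set: fall back to unweighted hits
        hit_w = is_hit.astype(float)
        total = float(n_hit)
    steps = hit_w / total - (~is_hit) / (n - n_hit)
    running = np.cumsum(steps)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak]), peak


def gsea_preranked(
    scores: pd.Series,
    gene_set: set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Preranked GSEA of one gene set against a scored gene list.

    ``scores`` maps gene -> ranking score; genes are ranked by descending
    score.  The null is gene-label permutation (random sets of the same
    size) with a fixed seed.
    """
    ranked = scores.sort_values(ascending=False, kind="mergesort")
    genes = ranked.index.to_numpy()
    n = genes.size
    in_set = np.isin(genes, list(gene_set))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == n:
        raise ValueError("gene set covers the whole ranked list; ES degenerate")
    weights = np.abs(ranked.to_numpy(dtype=np.float64)) ** weight
    if not np.all(np.isfinite(weights)):
        raise ValueError("ranking scores must be finite")

    es, peak = _running_es(in_set, weights)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm_hits = np.zeros(n, dtype=bool)
        perm_hits[rng.choice(n, size=n_hit, replace=False)] = True
        null[i], _ = _running_es(perm_hits, weights)

    same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
    if same_sign.size:
        nes = es / np.mean(np.abs(same_sign))
        p = (1 + np.sum(np.abs(same_sign) >= abs(es))) / (1 + same_sign.size)
    else:
        nes = 0.0
        p = 1.0 / (1 + n_perm)

    if es >= 0:
        leading = [g for g, h in zip(genes[: peak + 1], in_set[: peak + 1]) if h]
    else:
        leading = [g for g, h in zip(genes[peak:], in_set[peak:]) if h]
    return GseaResult(es, float(nes), float(p), float(p), leading, n_perm)


def gsea_many(
    scores: pd.Series,
    gene_sets: dict[str, set],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """GSEA over several gene sets with BH correction across sets."""
    results = {
        name: gsea_preranked(scores, s, weight=weight, n_perm=n_perm, seed=seed)
        for name, s in gene_sets.items()
    }
    df = pd.DataFrame(
        {
            "es": {k: r.es for k, r in results.items()},
            "nes": {k: r.nes for k, r in results.items()},
            "pvalue": {k: r.pvalue for k, r in results.items()},
            "leading_edge_size": {k: len(r.leading_edge) for k, r in results.items()},
        }
    )
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    return df
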