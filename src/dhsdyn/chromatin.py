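"""Per-gene chromatin accessibility status across stages.

Builds the per-stage promoter DHS status table, the family of presence/
absence pattern gene sets (2^k - 1 patterns for k stages; the all-absent
pattern is flagged "no-DHS" and excluded), opening/closing calls between the
endpoint stages, and bivalent-promoter classification from H3K4me3 /
H3K27me3 peaks (both-replicate rule reused from the DNase caller).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .core import DhsSet, GeneModel, GenomeModel
from .features import DEFAULT_PROMOTER_DOWN, DEFAULT_PROMOTER_UP, promoter_window
from .peaks import Peak, reproducible_dhs

DYNAMIC_CLASSES = ["opening", "closing", "stable_open", "stable_closed", "other"]
MARK_CATEGORIES = ["neither", "K4_only", "K27_only", "bivalent"]


@dataclass
class StagePatternTable:
    """Boolean promoter-DHS status per gene per stage.

    ``status`` is a genes x stages boolean frame; ``enhancer_counts`` (same
    shape, optional) holds per-stage DHS counts in each gene's linked
    enhancers.  Genes with the all-false pattern carry no DHS at any stage
    and are excluded from the pattern gene-set family.
    """

    status: pd.DataFrame
    enhancer_counts: pd.DataFrame | None = None

    @property
    def stages(self) -> list[str]:
        return list(self.status.columns)

    def pattern_codes(self) -> pd.Series:
        """Per-gene tuple of booleans across stages."""
        return pd.Series(
            [tuple(bool(v) for v in row) for row in self.status.to_numpy()],
            index=self.status.index,
            name="pattern",
        )

    def no_dhs_genes(self) -> set[str]:
        return set(self.status.index[~self.status.any(axis=1)])


def promoter_dhs_status(
    genes: list[GeneModel],
    genome: GenomeModel,
    dhs_by_stage: dict[str, DhsSet],
    up: int = DEFAULT_PROMOTER_UP,
    down: int = DEFAULT_PROMOTER_DOWN,
) -> StagePatternTable:
    """A gene is positive at a stage iff >= 1 DHS overlaps its promoter window."""
    stages = list(dhs_by_stage)
    data = {}
    windows = {g.gene_id: promoter_window(g, genome, up, down) for g in genes}
    for stage in stages:
        idx = dhs_by_stage[stage].index
        data[stage] = [
            idx.overlaps(w.chrom, w.start, w.end) for w in windows.values()
        ]
    status = pd.DataFrame(data, index=[g.gene_id for g in genes], columns=stages)
    return StagePatternTable(status=status)


def pattern_gene_sets(table: StagePatternTable) -> dict[tuple[bool, ...], set[str]]:
    """One gene set per non-all-false presence/absence pattern.

    Every gene with at least one positive stage lands in exactly one set;
    with k stages there are at most 2^k - 1 sets.
    """
    codes = table.pattern_codes()
    k = len(table.stages)
    sets: dict[tuple[bool, ...], set[str]] = {}
    for pattern in product([False, True], repeat=k):
        if not any(pattern):
            continue
        members = set(codes.index[codes == pattern])
        if members:
            sets[pattern] = members
    return sets


def all_patterns(n_stages: int) -> list[tuple[bool, ...]]:
    """The 2^k - 1 non-all-false patterns, in lexicographic order."""
    return [p for p in product([False, True], repeat=n_stages) if any(p)]


def classify_region_dynamics(
    dhs_first: DhsSet, dhs_last: DhsSet
) -> pd.DataFrame:
    """Opening/closing calls for endpoint-stage DHSs.

    A last-stage DHS overlapping no first-stage DHS is *opening*; a
    first-stage DHS overlapping no last-stage DHS is *closing*; DHSs present
    at both endpoints (>= 1 bp overlap) are *stable_open*.  Cross-stage
    correspondence is by >= 1 bp overlap.
    """
    rows = []
    for row in dhs_last.regions.itertuples(index=False):
        shared = dhs_first.index.overlaps(row.chrom, row.start, row.end)
        rows.append((row.chrom, row.start, row.end,
                     "stable_open" if shared else "opening"))
    for row in dhs_first.regions.itertuples(index=False):
        if not dhs_last.index.overlaps(row.chrom, row.start, row.end):
            rows.append((row.chrom, row.start, row.end, "closing"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "class"])


def classify_gene_dynamics(
    table: StagePatternTable,
    first_stage: str | None = None,
    last_stage: str | None = None,
) -> pd.Series:
    """Gene-level dynamics from the two endpoint promoter statuses.

    (first, last) = (False, True) -> opening; (True, False) -> closing;
    (True, True) -> stable_open; (False, False) -> stable_closed.
    """
    first_stage = first_stage or table.stages[0]
    last_stage = last_stage or table.stages[-1]
    first = table.status[first_stage]
    last = table.status[last_stage]
    out = np.where(
        ~first & last, "opening",
        np.where(first & ~last, "closing",
                 np.where(first & last, "stable_open", "stable_closed")),
    )
    return pd.Series(out, index=table.status.index, name="dynamic_class")


@dataclass
class MarkStatus:
    """Promoter histone-mark flags and the derived four-way category."""

    table: pd.DataFrame  # columns: k4, k27, category

    def genes_in(self, category: str) -> set[str]:
        if category not in MARK_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return set(self.table.index[self.table["category"] == category])

    @property
    def bivalent_genes(self) -> set[str]:
        return self.genes_in("bivalent")


def _categorize(k4: bool, k27: bool) -> str:
    if k4 and k27:
        return "bivalent"
    if k4:
        return "K4_only"
    if k27:
        return "K27_only"
    return "neither"


def promoter_mark_status(
    genes: list[GeneModel],
    genome: GenomeModel,
    k4_peaks_by_rep: list[list[Peak] | pd.DataFrame],
    k27_peaks_by_rep: list[list[Peak] | pd.DataFrame],
    up: int = DEFAULT_PROMOTER_UP,
    down: int = DEFAULT_PROMOTER_DOWN,
) -> MarkStatus:
    """Bivalency classification from replicate ChIP peak sets.

    A mark flag is set iff a replicate-reproducible peak (both-replicate
    rule, as for DHSs) overlaps the promoter window.  A mark seen in only
    one replicate does not count.
    """
    marks = {}
    for name, reps in (("k4", k4_peaks_by_rep), ("k27", k27_peaks_by_rep)):
        if len(reps) != 2:
            raise ValueError(f"{name}: need exactly 2 replicate peak sets")
        marks[name] = reproducible_dhs(reps[0], reps[1], stage=name)
    rows = []
    for gene in genes:
        w = promoter_window(gene, genome, up, down)
        k4 = marks["k4"].index.overlaps(w.chrom, w.start, w.end)
        k27 = marks["k27"].index.overlaps(w.chrom, w.start, w.end)
        rows.append((gene.gene_id, k4, k27, _categorize(k4, k27)))
    table = pd.DataFrame(rows, columns=["gene_id", "k4", "k27", "category"])
    return MarkStatus(table.set_index("gene_id"))
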