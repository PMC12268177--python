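"""End-to-end analysis: cut sites -> DHSs -> gene categories -> statistics.

Mirrors the study flow: per-stage replicate peak calling with the KDE
caller, the both-replicate DHS rule, feature annotation, per-gene stage
patterns, opening/closing and bivalency calls, expression normalization and
time-course DEG clustering, then the overlap matrices (DEG clusters x DHS
pattern sets, bivalency x DHS status, regulator-bound x opening).  When a
planted truth table is present the result also carries recall/precision of
the opening and bivalent calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chromatin, expression, features, peaks, setstats
from .core import DhsSet, GeneModel, GenomeModel
from .synthetic import MARKS, SimBundle, is_opening


@dataclass
class AnalysisParams:
    """Tunable analysis parameters (defaults match the module defaults)."""

    bandwidth: float = peaks.DEFAULT_BANDWIDTH
    chip_bandwidth: float = peaks.CHIP_BANDWIDTH
    grid_step: int = peaks.DEFAULT_GRID_STEP
    tail_p: float = peaks.DEFAULT_TAIL_P
    min_length: int = peaks.DEFAULT_MIN_LENGTH
    merge_gap: int = peaks.DEFAULT_MERGE_GAP
    promoter_up: int = features.DEFAULT_PROMOTER_UP
    promoter_down: int = features.DEFAULT_PROMOTER_DOWN
    downstream_len: int = features.DEFAULT_DOWNSTREAM_LEN
    alpha: float = expression.DEFAULT_ALPHA
    n_clusters: int = expression.DEFAULT_K
    max_degree: int = expression.DEFAULT_MAX_DEGREE
    seed: int = 0


@dataclass
class AnalysisResult:
    params: AnalysisParams
    peaks_by_stage_rep: dict[tuple[str, int], list[peaks.Peak]]
    dhs_by_stage: dict[str, DhsSet]
    partition: features.FeaturePartition
    feature_fractions_by_stage: dict[str, dict[str, float]]
    pattern_table: chromatin.StagePatternTable
    gene_dynamics: pd.Series
    mark_status: chromatin.MarkStatus | None
    expr: pd.DataFrame
    deg: expression.DegResult
    clusters: pd.Series | None
    overlap_deg_vs_pattern: setstats.OverlapMatrix | None
    overlap_bivalent_vs_dhs: setstats.OverlapMatrix | None
    recovery: dict[str, float] = field(default_factory=dict)


def call_stage_dhs(
    bundle: SimBundle, params: AnalysisParams
) -> tuple[dict[tuple[str, int], list[peaks.Peak]], dict[str, DhsSet]]:
    """Replicate peak calling plus the both-replicate DHS rule, per stage."""
    peaks_by: dict[tuple[str, int], list[peaks.Peak]] = {}
    dhs_by: dict[str, DhsSet] = {}
    for stage in bundle.config.stage_labels:
        reps = []
        for rep in range(1, bundle.config.n_replicates + 1):
            called = peaks.call_peaks(
                bundle.cut_tracks[(stage, rep)],
                bandwidth=params.bandwidth,
                p=params.tail_p,
                min_length=params.min_length,
                merge_gap=params.merge_gap,
                grid_step=params.grid_step,
            )
            peaks_by[(stage, rep)] = called
            reps.append(called)
        dhs_by[stage] = peaks.reproducible_dhs(reps[0], reps[1], stage=stage)
    return peaks_by, dhs_by


def call_mark_status(
    bundle: SimBundle, params: AnalysisParams
) -> chromatin.MarkStatus:
    """Bivalency classification from the simulated ChIP tracks."""
    rep_peaks = {
        mark: [
            peaks.call_peaks(
                bundle.mark_tracks[(mark, rep)],
                bandwidth=params.chip_bandwidth,
                p=params.tail_p,
                min_length=params.min_length,
                merge_gap=params.merge_gap,
                grid_step=params.grid_step,
            )
            for rep in range(1, bundle.config.n_replicates + 1)
        ]
        for mark in MARKS
    }
    return chromatin.promoter_mark_status(
        bundle.genes,
        bundle.genome,
        rep_peaks["H3K4me3"],
        rep_peaks["H3K27me3"],
        up=params.promoter_up,
        down=params.promoter_down,
    )


def _precision_recall(called: set[str], planted: set[str]) -> tuple[float, float]:
    tp = len(called & planted)
    precision = tp / len(called) if called else float("nan")
    recall = tp / len(planted) if planted else float("nan")
    return precision, recall


def score_recovery(
    bundle: SimBundle,
    gene_dynamics: pd.Series,
    mark_status: chromatin.MarkStatus | None,
) -> dict[str, float]:
    """Recall/precision of opening and bivalent calls against planted truth."""
    planted_opening = {t.gene_id for t in bundle.truth if is_opening(t.dynamic_class)}
    called_opening = set(gene_dynamics.index[gene_dynamics == "opening"])
    out: dict[str, float] = {}
    out["opening_precision"], out["opening_recall"] = _precision_recall(
        called_opening, planted_opening
    )
    planted_closing = {t.gene_id for t in bundle.truth
                       if t.dynamic_class.startswith("closing_at_")}
    called_closing = set(gene_dynamics.index[gene_dynamics == "closing"])
    out["closing_precision"], out["closing_recall"] = _precision_recall(
        called_closing, planted_closing
    )
    if mark_status is not None:
        planted_biv = {t.gene_id for t in bundle.truth if t.bivalent}
        out["bivalent_precision"], out["bivalent_recall"] = _precision_recall(
            mark_status.bivalent_genes, planted_biv
        )
    return out


def analyze_bundle(
    bundle: SimBundle,
    params: AnalysisParams | None = None,
    with_marks: bool = True,
    with_overlaps: bool = True,
) -> AnalysisResult:
    """Run the full analysis on one (synthetic or loaded) bundle."""
    params = params or AnalysisParams()
    peaks_by, dhs_by = call_stage_dhs(bundle, params)

    partition = features.partition_genome(
        bundle.genes, bundle.genome,
        up=params.promoter_up, down=params.promoter_down,
        downstream_len=params.downstream_len,
    )
    fractions = {
        stage: features.feature_fractions(dhs, partition)
        for stage, dhs in dhs_by.items()
    }
    table = chromatin.promoter_dhs_status(
        bundle.genes, bundle.genome, dhs_by,
        up=params.promoter_up, down=params.promoter_down,
    )
    table.enhancer_counts = pd.DataFrame(
        {
            stage: pd.Series(features.enhancer_overlap(dhs, bundle.links))
            for stage, dhs in dhs_by.items()
        }
    ).reindex(table.status.index).fillna(0).astype(int)
    dynamics = chromatin.classify_gene_dynamics(table)

    mark_status = call_mark_status(bundle, params) if with_marks else None

    factors = expression.tmm_factors(bundle.counts.counts)
    expr = expression.expression_values(bundle.counts, factors)
    times = bundle.counts.samples["time"].to_numpy()
    deg = expression.timecourse_deg(
        expr, times, max_degree=params.max_degree, alpha=params.alpha
    )
    clusters = None
    if len(deg.deg_genes) >= params.n_clusters:
        clusters = expression.cluster_profiles(
            expr.loc[sorted(deg.deg_genes)],
            bundle.counts.samples["stage"].tolist(),
            k=params.n_clusters,
            seed=params.seed,
        )
        deg.table.loc[clusters.index, "cluster"] = clusters.astype(float)

    overlap_deg = overlap_biv = None
    if with_overlaps:
        universe = set(table.status.index)
        pattern_sets = {
            "".join("+" if b else "-" for b in pat): s
            for pat, s in chromatin.pattern_gene_sets(table).items()
        }
        if clusters is not None and pattern_sets:
            deg_sets = {f"cluster_{c}": g for c, g in deg.cluster_sets.items()}
            overlap_deg = setstats.overlap_matrix(deg_sets, pattern_sets, universe)
        if mark_status is not None and pattern_sets:
            biv_sets = {"bivalent": mark_status.bivalent_genes & universe}
            overlap_biv = setstats.overlap_matrix(biv_sets, pattern_sets, universe)

    result = AnalysisResult(
        params=params,
        peaks_by_stage_rep=peaks_by,
        dhs_by_stage=dhs_by,
        partition=partition,
        feature_fractions_by_stage=fractions,
        pattern_table=table,
        gene_dynamics=dynamics,
        mark_status=mark_status,
        expr=expr,
        deg=deg,
        clusters=clusters,
        overlap_deg_vs_pattern=overlap_deg,
        overlap_bivalent_vs_dhs=overlap_biv,
    )
    if bundle.truth:
        result.recovery = score_recovery(bundle, dynamics, mark_status)
    return result
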