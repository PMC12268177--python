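"""Strand-aware priority partition of the genome into functional features.

Every base is labeled exactly once, with conflicts resolved by the priority

    promoter > exon > intron > downstream > distal

Promoters span 1 kb upstream through 0.5 kb downstream of the TSS
(strand-aware); downstream windows extend 1 kb past the transcription end;
introns are the transcribed span not covered by exons; everything else is
distal.  A region (e.g. a DHS) is assigned the highest-priority label it
overlaps by at least one base (bp-majority assignment is available as an
option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DhsSet, GeneModel, GenomeModel, Region

FEATURE_LABELS = ["promoter", "exon", "intron", "downstream", "distal"]
_CODE = {label: i for i, label in enumerate(FEATURE_LABELS)}

DEFAULT_PROMOTER_UP = 1000
DEFAULT_PROMOTER_DOWN = 500
DEFAULT_DOWNSTREAM_LEN = 1000


def promoter_window(
    gene: GeneModel,
    genome: GenomeModel,
    up: int = DEFAULT_PROMOTER_UP,
    down: int = DEFAULT_PROMOTER_DOWN,
) -> Region:
    """Strand-aware promoter window around the TSS, clipped to the chromosome.

    ``+`` strand: ``[TSS - up, TSS + down)``; ``-`` strand (mirror image):
    ``[TSS - down, TSS + up)``.
    """
    tss = gene.tss
    if gene.strand == "+":
        start, end = tss - up, tss + down
    else:
        start, end = tss - down, tss + up
    start, end = genome.clip(gene.chrom, start, end)
    return Region(gene.chrom, start, end)


def downstream_window(
    gene: GeneModel,
    genome: GenomeModel,
    length: int = DEFAULT_DOWNSTREAM_LEN,
) -> Region | None:
    """Strand-aware window past the transcription termination site."""
    if gene.strand == "+":
        start, end = gene.tx_end, gene.tx_end + length
    else:
        start, end = gene.tx_start - length, gene.tx_start
    start, end = genome.clip(gene.chrom, start, end)
    if end <= start:
        return None
    return Region(gene.chrom, start, end)


@dataclass
class FeaturePartition:
    """Exhaustive, disjoint labeling of every base of the genome.

    Stored as per-chromosome run-length encoding: ``starts[i]`` begins a run
    with label code ``codes[i]``; runs abut, covering the chromosome.
    """

    genome: GenomeModel
    run_starts: dict[str, np.ndarray]
    run_codes: dict[str, np.ndarray]

    def runs_frame(self) -> pd.DataFrame:
        """(chrom, start, end, label) rows covering the genome."""
        rows = []
        for chrom in self.genome.chroms:
            starts = self.run_starts[chrom]
            length = self.genome.chrom_lengths[chrom]
            ends = np.append(starts[1:], length)
            for s, e, c in zip(starts, ends, self.run_codes[chrom]):
                rows.append((chrom, int(s), int(e), FEATURE_LABELS[c]))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])

    def label_lengths(self) -> dict[str, int]:
        """Total bp per label across the genome."""
        totals = dict.fromkeys(FEATURE_LABELS, 0)
        for chrom in self.genome.chroms:
            starts = self.run_starts[chrom]
            ends = np.append(starts[1:], self.genome.chrom_lengths[chrom])
            widths = ends - starts
            for code, label in enumerate(FEATURE_LABELS):
                totals[label] += int(widths[self.run_codes[chrom] == code].sum())
        return totals

    def bp_fractions(self) -> dict[str, float]:
        lengths = self.label_lengths()
        total = self.genome.total_length
        return {label: lengths[label] / total for label in FEATURE_LABELS}

    def _overlapped_codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        starts = self.run_starts[chrom]
        i0 = int(np.searchsorted(starts, start, side="right")) - 1
        i1 = int(np.searchsorted(starts, end, side="left"))
        return self.run_codes[chrom][max(i0, 0):i1]

    def assign(self, region: Region, mode: str = "priority") -> str:
        """Label of a region: highest-priority overlapped label (default) or
        the label covering the most bases (``mode='majority'``)."""
        if region.chrom not in self.run_starts:
            raise KeyError(f"unknown chromosome {region.chrom}")
        start, end = self.genome.clip(region.chrom, region.start, region.end)
        if mode == "priority":
            codes = self._overlapped_codes(region.chrom, start, end)
            return FEATURE_LABELS[int(codes.min())]
        if mode == "majority":
            starts = self.run_starts[region.chrom]
            length = self.genome.chrom_lengths[region.chrom]
            ends = np.append(starts[1:], length)
            i0 = max(int(np.searchsorted(starts, start, side="right")) - 1, 0)
            i1 = int(np.searchsorted(starts, end, side="left"))
            bp = dict.fromkeys(range(len(FEATURE_LABELS)), 0)
            for s, e, c in zip(starts[i0:i1], ends[i0:i1], self.run_codes[region.chrom][i0:i1]):
                bp[int(c)] += max(0, min(e, end) - max(s, start))
            # ties broken by priority (lower code wins)
            best = max(sorted(bp), key=lambda c: bp[c])
            return FEATURE_LABELS[best]
        raise ValueError("mode must be 'priority' or 'majority'")


def partition_genome(
    genes: list[GeneModel],
    genome: GenomeModel,
    up: int = DEFAULT_PROMOTER_UP,
    down: int = DEFAULT_PROMOTER_DOWN,
    downstream_len: int = DEFAULT_DOWNSTREAM_LEN,
) -> FeaturePartition:
    """Label every base by painting features in increasing priority order.

    Later paints overwrite earlier ones, so the final label of a base is the
    highest-priority feature covering it; the result is independent of gene
    input order.  Overlapping genes are allowed.
    """
    arrays = {
        chrom: np.full(length, _CODE["distal"], dtype=np.int8)
        for chrom, length in genome.chrom_lengths.items()
    }
    by_chrom: dict[str, list[GeneModel]] = {c: [] for c in genome.chroms}
    for gene in genes:
        if gene.chrom not in arrays:
            raise KeyError(f"{gene.gene_id}: unknown chromosome {gene.chrom}")
        by_chrom[gene.chrom].append(gene)

    for chrom, chrom_genes in by_chrom.items():
        arr = arrays[chrom]
        # downstream, then intron (whole span), then exons, then promoters
        for gene in chrom_genes:
            w = downstream_window(gene, genome, downstream_len)
            if w is not None:
                arr[w.start:w.end] = _CODE["downstream"]
        for gene in chrom_genes:
            arr[gene.tx_start:gene.tx_end] = _CODE["intron"]
        for gene in chrom_genes:
            for s, e in gene.exons:
                arr[s:e] = _CODE["exon"]
        for gene in chrom_genes:
            w = promoter_window(gene, genome, up, down)
            arr[w.start:w.end] = _CODE["promoter"]

    run_starts = {}
    run_codes = {}
    for chrom, arr in arrays.items():
        change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
        starts = np.concatenate(([0], change)).astype(np.int64)
        run_starts[chrom] = starts
        run_codes[chrom] = arr[starts].copy()
    return FeaturePartition(genome, run_starts, run_codes)


def assign_feature(region: Region, partition: FeaturePartition, mode: str = "priority") -> str:
    """Feature label of a region under the partition's priority rule."""
    return partition.assign(region, mode=mode)


def feature_fractions(
    dhs: DhsSet, partition: FeaturePartition, mode: str = "priority"
) -> dict[str, float]:
    """Fraction of DHSs assigned to each feature label (sums to 1)."""
    counts = dict.fromkeys(FEATURE_LABELS, 0)
    for row in dhs.regions.itertuples(index=False):
        label = partition.assign(Region(row.chrom, row.start, row.end), mode=mode)
        counts[label] += 1
    total = sum(counts.values())
    if total == 0:
        return dict.fromkeys(FEATURE_LABELS, 0.0)
    return {label: counts[label] / total for label in FEATURE_LABELS}


def enhancer_overlap(dhs: DhsSet, links: pd.DataFrame) -> dict[str, int]:
    """DHS counts in each gene's linked enhancers.

    ``links`` has columns (enh_chrom, enh_start, enh_end, gene_id).  Counting
    is per (DHS, enhancer) pair: a DHS overlapping two enhancers linked to
    the same gene contributes twice.
    """
    out: dict[str, int] = {}
    for row in links.itertuples(index=False):
        n = dhs.index.count_overlaps(row.enh_chrom, int(row.enh_start), int(row.enh_end))
        if n:
            out[row.gene_id] = out.get(row.gene_id, 0) + n
    return out
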