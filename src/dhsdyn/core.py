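"""Core genomic types shared across the pipeline.

Every coordinate in this package is 0-based and half-open (BED convention):
a region ``[start, end)`` covers bases ``start .. end-1``.  The transcription
start site (TSS) of a ``+`` strand gene is ``tx_start``; for a ``-`` strand
gene it is ``tx_end - 1`` (the last base of the transcribed span).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_COLUMNS = ["chrom", "start", "end"]


@dataclass(frozen=True, order=True)
class Region:
    """Half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted region: {self}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenomeModel:
    """Ordered chromosome name -> length (bp) map anchoring all coordinates."""

    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def contains(self, region: Region) -> bool:
        length = self.chrom_lengths.get(region.chrom)
        return length is not None and 0 <= region.start and region.end <= length

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Clip an interval to chromosome bounds."""
        length = self.chrom_lengths[chrom]
        return max(0, int(start)), min(length, int(end))


@dataclass
class GeneModel:
    """Strand-aware gene structure.

    ``exons`` are sorted, disjoint half-open intervals inside
    ``[tx_start, tx_end)``.  ``length_bp`` is the exonic length used for
    expression normalization.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]]
    length_bp: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not 0 <= self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene_id}: invalid span")
        prev_end = self.tx_start
        for s, e in self.exons:
            if s < prev_end or e <= s or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exons must be sorted, disjoint, in span")
            prev_end = e
        if self.length_bp == 0:
            self.length_bp = sum(e - s for s, e in self.exons) or (self.tx_end - self.tx_start)
        if self.length_bp <= 0:
            raise ValueError(f"{self.gene_id}: non-positive length_bp")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


class CutSiteTrack:
    """Sorted per-chromosome cut positions for one stage/replicate.

    Positions are integer base coordinates; each cut occupies a single base
    (BED3 line with ``end = start + 1``).
    """

    def __init__(self, positions: dict[str, np.ndarray], genome: GenomeModel):
        self.genome = genome
        self.positions: dict[str, np.ndarray] = {}
        for chrom in genome.chroms:
            pos = np.asarray(positions.get(chrom, np.empty(0, dtype=np.int64)), dtype=np.int64)
            pos = np.sort(pos)
            if pos.size and (pos[0] < 0 or pos[-1] >= genome.chrom_lengths[chrom]):
                raise ValueError(f"cut positions outside chromosome {chrom}")
            self.positions[chrom] = pos
        extra = set(positions) - set(genome.chroms)
        if extra:
            raise ValueError(f"cuts on unknown chromosomes: {sorted(extra)}")

    @property
    def n_cuts(self) -> int:
        return int(sum(p.size for p in self.positions.values()))

    def counts_in(self, chrom: str, start: int, end: int) -> int:
        pos = self.positions.get(chrom)
        if pos is None:
            return 0
        return int(np.searchsorted(pos, end) - np.searchsorted(pos, start))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CutSiteTrack):
            return NotImplemented
        return self.positions.keys() == other.positions.keys() and all(
            np.array_equal(self.positions[c], other.positions[c]) for c in self.positions
        )


def regions_frame(regions) -> pd.DataFrame:
    """Build a normalized (chrom, start, end) frame sorted by coordinate."""
    if isinstance(regions, pd.DataFrame):
        df = regions.loc[:, REGION_COLUMNS].copy()
    else:
        df = pd.DataFrame(
            [(r.chrom, r.start, r.end) for r in regions], columns=REGION_COLUMNS
        )
    if df.empty:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64)})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df.sort_values(REGION_COLUMNS, kind="mergesort").reset_index(drop=True)


def merge_regions(df: pd.DataFrame, gap: int = 0) -> pd.DataFrame:
    """Merge overlapping (or within ``gap`` bp) regions into disjoint spans."""
    df = regions_frame(df)
    if df.empty:
        return df
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e + gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=REGION_COLUMNS)


class RegionIndex:
    """Overlap queries against a set of disjoint, sorted regions."""

    def __init__(self, df: pd.DataFrame):
        df = regions_frame(df)
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"regions on {chrom} overlap; merge first")
            self._starts[chrom] = starts
            self._ends[chrom] = ends

    def count_overlaps(self, chrom: str, start: int, end: int) -> int:
        """Number of indexed regions overlapping ``[start, end)`` by >= 1 bp."""
        starts = self._starts.get(chrom)
        if starts is None:
            return 0
        ends = self._ends[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        return max(0, hi - lo)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.count_overlaps(chrom, start, end) > 0


@dataclass
class DhsSet:
    """Replicate-reproducible DNase-hypersensitive sites for one stage.

    ``regions`` are sorted, non-overlapping merged spans; ``provenance``
    optionally records the replicate peaks each DHS was built from.
    """

    stage: str
    regions: pd.DataFrame
    provenance: pd.DataFrame | None = None
    _index: RegionIndex | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.regions = regions_frame(self.regions)

    @property
    def index(self) -> RegionIndex:
        if self._index is None:
            self._index = RegionIndex(self.regions)
        return self._index

    def __len__(self) -> int:
        return len(self.regions)

    @property
    def total_width(self) -> int:
        if self.regions.empty:
            return 0
        return int((self.regions["end"] - self.regions["start"]).sum())
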