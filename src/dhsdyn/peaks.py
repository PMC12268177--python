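"""Kernel-density peak calling on cut-site tracks.

DNase (or ChIP) cut sites are smoothed with a Gaussian kernel of bandwidth
``b``; a site at position ``c`` contributes ``phi((x - c)/b)/b`` to the
density at ``x`` (``phi`` the standard normal density), truncated beyond
``TRUNCATION_SDS`` bandwidths.  Under a uniform (Poisson) null with ``n``
cuts over an effective length ``L`` the density at a point has

    mean      mu      = n / L
    variance  sigma^2 = n / (L * 2 * b * sqrt(pi))

(the variance follows from the integral of the squared kernel,
``int phi(u)^2 du = 1/(2 sqrt(pi))``).  Peaks are maximal grid runs whose
density exceeds ``mu + z(1 - p) * sigma`` for a chosen tail probability
``p``; runs closer than ``merge_gap`` are merged and runs shorter than
``min_length`` dropped.  This analytic Gaussian null is a deliberate,
documented variant of F-Seq's internal background calibration.

Hypersensitive sites (DHSs) are peaks detected in both replicates; the DHS
span is the union (optionally intersection) of each overlapping replicate
peak pair, with overlapping spans merged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CutSiteTrack, DhsSet, Region, RegionIndex, merge_regions, regions_frame

#: kernel support half-width, in bandwidths
TRUNCATION_SDS = 5.0

#: tracks with fewer cuts than this produce no peaks (degenerate null)
MIN_CUTS_FOR_CALLING = 10

DEFAULT_BANDWIDTH = 100
DEFAULT_GRID_STEP = 10
DEFAULT_MIN_LENGTH = 50
DEFAULT_MERGE_GAP = 50
DEFAULT_TAIL_P = 1e-6

#: ChIP marks are broader; reuse the caller with a wider default bandwidth
CHIP_BANDWIDTH = 200


@dataclass
class KdeProfile:
    """Smoothed cut density for one chromosome, sampled on a regular grid.

    ``values[i]`` is the density (cuts per bp) at position ``i * grid_step``.
    The kernel integrates to 1 per cut, so the profile integral recovers the
    cut count (up to truncation at ``TRUNCATION_SDS`` bandwidths and edge
    clipping).
    """

    chrom: str
    grid_step: int
    values: np.ndarray
    n_cuts: int

    @property
    def grid_positions(self) -> np.ndarray:
        return np.arange(self.values.size, dtype=np.int64) * self.grid_step

    def integral(self) -> float:
        return float(self.values.sum() * self.grid_step)


@dataclass(frozen=True)
class Peak:
    """Called peak with its maximal density and Gaussian-null tail probability."""

    region: Region
    max_density: float
    tail_probability: float


def kde_profile(
    cuts: CutSiteTrack,
    bandwidth: float = DEFAULT_BANDWIDTH,
    grid_step: int = DEFAULT_GRID_STEP,
) -> dict[str, KdeProfile]:
    """Gaussian KDE of cut positions, one profile per chromosome.

    The density at grid point ``x`` is the sum over cuts ``c`` within
    ``TRUNCATION_SDS * bandwidth`` of ``phi((x - c)/bandwidth)/bandwidth``.
    An empty track yields all-zero profiles.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    profiles = {}
    half = TRUNCATION_SDS * bandwidth
    norm = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
    for chrom, length in cuts.genome.chrom_lengths.items():
        n_grid = int(np.floor((length - 1) / grid_step)) + 1
        values = np.zeros(n_grid)
        pos = cuts.positions.get(chrom, np.empty(0, dtype=np.int64))
        if pos.size:
            pos = pos.astype(np.float64)
            # leftmost grid index whose position >= c - half
            i0 = np.ceil((pos - half) / grid_step).astype(np.int64)
            n_span = int(np.floor(2 * half / grid_step)) + 1
            for j in range(n_span):
                idx = i0 + j
                ok = (idx >= 0) & (idx < n_grid)
                if not np.any(ok):
                    continue
                d = idx[ok] * grid_step - pos[ok]
                w = np.where(np.abs(d) <= half,
                             norm * np.exp(-0.5 * (d / bandwidth) ** 2), 0.0)
                np.add.at(values, idx[ok], w)
        profiles[chrom] = KdeProfile(chrom, grid_step, values, int(pos.size))
    return profiles


def background_threshold(
    n_cuts: int, effective_length: float, bandwidth: float, p: float
) -> float:
    """Density threshold whose Gaussian-null tail probability is ``p``.

    Returns ``mu + z(1 - p) * sigma`` with ``mu = n/L`` and
    ``sigma^2 = n / (L * 2 * b * sqrt(pi))``.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("tail probability p must lie in (0, 1)")
    if effective_length <= 0:
        raise ValueError("effective_length must be positive")
    if n_cuts < 0:
        raise ValueError("n_cuts must be non-negative")
    mu = n_cuts / effective_length
    sigma = np.sqrt(n_cuts / (effective_length * 2.0 * bandwidth * np.sqrt(np.pi)))
    return float(mu + stats.norm.ppf(1.0 - p) * sigma)


def _null_tail_probability(
    density: float, n_cuts: int, effective_length: float, bandwidth: float
) -> float:
    mu = n_cuts / effective_length
    sigma = np.sqrt(n_cuts / (effective_length * 2.0 * bandwidth * np.sqrt(np.pi)))
    if sigma == 0:
        return 1.0 if density <= mu else 0.0
    return float(stats.norm.sf((density - mu) / sigma))


def _kernel_values(bandwidth: float) -> np.ndarray:
    """Kernel weights at all integer offsets within the truncation window."""
    half = int(np.ceil(TRUNCATION_SDS * bandwidth))
    d = np.arange(-half, half + 1, dtype=np.float64)
    return np.exp(-0.5 * (d / bandwidth) ** 2) / (bandwidth * np.sqrt(2.0 * np.pi))


def poisson_null_tail(
    density: float, rate: float, bandwidth: float
) -> float:
    """Exact upper-tail probability of the KDE height under a uniform null.

    With cuts a homogeneous Poisson process of ``rate`` per bp, the height at
    a point is a compound Poisson sum over integer offsets of the truncated
    kernel; the tail is evaluated with the Lugannani-Rice saddlepoint
    approximation of that distribution.  The Gaussian approximation badly
    underestimates this tail when the expected number of cuts per kernel
    footprint is small, which is why peak calling uses this null by default.
    """
    if rate <= 0:
        return 1.0 if density <= 0 else 0.0
    k = _kernel_values(bandwidth)
    mu = rate * k.sum()
    var = rate * (k**2).sum()
    if density <= mu:
        # only the far upper tail matters for calling; fall back to Gaussian
        return float(stats.norm.sf((density - mu) / np.sqrt(var)))
    # Newton solve K'(s) = density for the saddlepoint s > 0
    s = (density - mu) / var
    for _ in range(100):
        e = rate * np.exp(s * k)
        k1 = float((e * k).sum())
        k2 = float((e * k**2).sum())
        step = (k1 - density) / k2
        s -= step
        if abs(step) < 1e-12 * max(abs(s), 1.0):
            break
    e = rate * np.exp(s * k)
    K = float((e - rate).sum())
    k2 = float((e * k**2).sum())
    w = np.sqrt(max(2.0 * (s * density - K), 0.0))
    u = s * np.sqrt(k2)
    if w < 1e-8 or u < 1e-8:
        return float(stats.norm.sf((density - mu) / np.sqrt(var)))
    p = stats.norm.sf(w) + stats.norm.pdf(w) * (1.0 / u - 1.0 / w)
    return float(min(max(p, 0.0), 1.0))


def poisson_null_threshold(rate: float, bandwidth: float, p: float) -> float:
    """Density whose exact-null tail probability is ``p`` (bisection).

    Strictly decreasing tail in the density makes the threshold strictly
    increasing as ``p`` decreases.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("tail probability p must lie in (0, 1)")
    if rate <= 0:
        return 0.0
    mu = rate
    sigma = np.sqrt(rate / (2.0 * bandwidth * np.sqrt(np.pi)))
    lo, hi = mu, mu + 200.0 * sigma
    while poisson_null_tail(hi, rate, bandwidth) > p:
        hi *= 2.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if poisson_null_tail(mid, rate, bandwidth) > p:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi))


def call_peaks(
    cuts: CutSiteTrack,
    bandwidth: float = DEFAULT_BANDWIDTH,
    p: float = DEFAULT_TAIL_P,
    min_length: int = DEFAULT_MIN_LENGTH,
    merge_gap: int = DEFAULT_MERGE_GAP,
    grid_step: int = DEFAULT_GRID_STEP,
    effective_length: float | None = None,
    null: str = "exact",
) -> list[Peak]:
    """Call peaks as supra-threshold KDE runs at tail probability ``p``.

    ``effective_length`` defaults to the genome length; pass the genome
    length minus excluded bases when exclusion regions were applied.
    ``null='exact'`` (default) thresholds against the exact compound-Poisson
    height distribution; ``null='gaussian'`` uses the analytic Gaussian
    approximation of :func:`background_threshold`.  Tracks with fewer than
    ``MIN_CUTS_FOR_CALLING`` cuts return no peaks.
    """
    if null not in ("exact", "gaussian"):
        raise ValueError("null must be 'exact' or 'gaussian'")
    n = cuts.n_cuts
    if n < MIN_CUTS_FOR_CALLING:
        return []
    L = float(effective_length if effective_length is not None else cuts.genome.total_length)
    if null == "exact":
        threshold = poisson_null_threshold(n / L, bandwidth, p)
    else:
        threshold = background_threshold(n, L, bandwidth, p)
    profiles = kde_profile(cuts, bandwidth, grid_step)
    peaks: list[Peak] = []
    for chrom, prof in profiles.items():
        above = prof.values > threshold
        if not np.any(above):
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
        run_starts, run_stops = edges[::2], edges[1::2]  # grid index ranges [start, stop)
        # bp spans: grid point i covers position i*step; a run [i, j) spans
        # [i*step, (j-1)*step + step)
        spans = [(int(s * grid_step), int((t - 1) * grid_step + grid_step))
                 for s, t in zip(run_starts, run_stops)]
        # merge runs closer than merge_gap
        merged: list[list[int]] = []
        for s, e in spans:
            if merged and s - merged[-1][1] < merge_gap:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        chrom_len = cuts.genome.chrom_lengths[chrom]
        for s, e in merged:
            e = min(e, chrom_len)
            if e - s < min_length:
                continue
            g0, g1 = int(np.ceil(s / grid_step)), int(np.floor((e - 1) / grid_step)) + 1
            max_density = float(prof.values[g0:g1].max())
            if null == "exact":
                tail = poisson_null_tail(max_density, n / L, bandwidth)
            else:
                tail = _null_tail_probability(max_density, n, L, bandwidth)
            peaks.append(Peak(Region(chrom, s, e), max_density, tail))
    return peaks


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(pk.region.chrom, pk.region.start, pk.region.end, pk.max_density, pk.tail_probability)
         for pk in peaks],
        columns=["chrom", "start", "end", "max_density", "tail_probability"],
    )
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64})
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def reproducible_dhs(
    peaks_rep1: list[Peak] | pd.DataFrame,
    peaks_rep2: list[Peak] | pd.DataFrame,
    stage: str = "",
    span: str = "union",
) -> DhsSet:
    """Both-replicate rule: peaks detected in both replicates become DHSs.

    For every pair of replicate peaks overlapping by >= 1 bp, emit the union
    (default) or intersection span of the pair; overlapping emitted spans are
    merged.  Peaks private to one replicate are discarded.
    """
    if span not in ("union", "intersection"):
        raise ValueError("span must be 'union' or 'intersection'")
    df1 = peaks_to_frame(peaks_rep1) if isinstance(peaks_rep1, list) else regions_frame(peaks_rep1)
    df2 = peaks_to_frame(peaks_rep2) if isinstance(peaks_rep2, list) else regions_frame(peaks_rep2)
    spans = []
    prov = []
    for chrom, sub1 in df1.groupby("chrom", sort=True):
        sub2 = df2[df2["chrom"] == chrom]
        if sub2.empty:
            continue
        s2 = sub2["start"].to_numpy()
        e2 = sub2["end"].to_numpy()
        for s1, e1 in zip(sub1["start"].to_numpy(), sub1["end"].to_numpy()):
            hits = np.flatnonzero((s2 < e1) & (s1 < e2))
            for j in hits:
                if span == "union":
                    lo, hi = min(s1, s2[j]), max(e1, e2[j])
                else:
                    lo, hi = max(s1, s2[j]), min(e1, e2[j])
                spans.append((chrom, int(lo), int(hi)))
                prov.append((chrom, int(s1), int(e1), int(s2[j]), int(e2[j])))
    spans_df = pd.DataFrame(spans, columns=["chrom", "start", "end"])
    prov_df = pd.DataFrame(
        prov, columns=["chrom", "rep1_start", "rep1_end", "rep2_start", "rep2_end"]
    )
    return DhsSet(stage=stage, regions=merge_regions(spans_df), provenance=prov_df)


def filter_excluded_cuts(cuts: CutSiteTrack, exclusion: pd.DataFrame) -> CutSiteTrack:
    """Drop cuts falling inside exclusion regions (blacklist, sex chromosomes)."""
    excl = RegionIndex(merge_regions(exclusion))
    kept = {}
    for chrom, pos in cuts.positions.items():
        if pos.size == 0:
            kept[chrom] = pos
            continue
        mask = np.fromiter(
            (not excl.overlaps(chrom, int(p), int(p) + 1) for p in pos),
            dtype=bool,
            count=pos.size,
        )
        kept[chrom] = pos[mask]
    return CutSiteTrack(kept, cuts.genome)


def filter_excluded_regions(regions: pd.DataFrame, exclusion: pd.DataFrame) -> pd.DataFrame:
    """Drop regions overlapping any exclusion region by >= 1 bp."""
    df = regions.copy()
    if df.empty:
        return df
    excl = RegionIndex(merge_regions(exclusion))
    keep = [
        not excl.overlaps(row.chrom, int(row.start), int(row.end))
        for row in df.itertuples(index=False)
    ]
    return df.loc[keep].reset_index(drop=True)


def effective_length(genome_length: int, exclusion: pd.DataFrame | None) -> int:
    """Genome length minus excluded bases."""
    if exclusion is None or len(exclusion) == 0:
        return int(genome_length)
    merged = merge_regions(exclusion)
    return int(genome_length - (merged["end"] - merged["start"]).sum())
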