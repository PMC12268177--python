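"""Synthetic genome, cut-site and count data with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
miniature multi-chromosome genome carrying non-overlapping gene models; per
stage and replicate, DNase cut sites drawn from a Poisson process whose rate
is ``background_rate`` genome-wide and ``background_rate *
accessible_enrichment`` inside the promoter windows of genes accessible at
that stage; H3K4me3/H3K27me3 cut tracks enriched at promoters of marked
genes (bivalent genes carry both); and a negative-binomial count matrix
following planted temporal trajectories.  Every gene has a truth record so
downstream calls (opening/closing, bivalency, DEGs) can be scored.

Dynamic accessibility classes are applied by exact quota (shuffled
assignment), so planted class counts are deterministic.  All randomness
derives from a single master seed via per-purpose child seeds, making the
whole bundle byte-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CutSiteTrack, GeneModel, GenomeModel
from .expression import CountMatrix
from .features import promoter_window
from . import io as dio

MARKS = ("H3K4me3", "H3K27me3")
TRAJECTORY_CLASSES = ("flat", "up", "down", "transient")


class SizingError(ValueError):
    """Requested genes do not fit in the requested genome."""


def default_class_fractions(stage_labels: tuple[str, ...]) -> dict[str, float]:
    """Default dynamic-class mix: opening/closing at each later stage plus
    stably open/closed genes (fractions sum to 1)."""
    later = stage_labels[1:]
    fractions = {"always_open": 0.35, "never_open": 0.25}
    open_each = 0.20 / len(later)
    close_each = 0.20 / len(later)
    for s in later:
        fractions[f"opening_at_{s}"] = open_each
        fractions[f"closing_at_{s}"] = close_each
    return fractions


@dataclass
class SimConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    The defaults plant a 10 Mb genome (2 x 5 Mb), 1000 genes, 4 stages
    (E12/E13/E14/E16) x 2 replicates, 8-fold promoter enrichment over a
    background of 0.02 cuts/bp (the per-bp depth a ~20M-fragment mouse
    library implies; 240 expected cuts per accessible 1.5 kb promoter
    window per replicate).
    """

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 1000
    stage_labels: tuple[str, ...] = ("E12", "E13", "E14", "E16")
    stage_times: tuple[float, ...] = (12.0, 13.0, 14.0, 16.0)
    n_replicates: int = 2
    class_fractions: dict[str, float] | None = None
    background_rate: float = 0.02
    accessible_enrichment: float = 8.0
    peak_halfwidth: int = 750
    nb_dispersion: float = 0.05
    library_size: int = 1_000_000
    library_size_factors: tuple[float, ...] = (1.0, 1.2)
    seed: int = 0
    # gene geometry
    promoter_up: int = 1000
    promoter_down: int = 500
    downstream_len: int = 1000
    gene_min_length: int = 2000
    gene_max_length: int = 6000
    max_exons: int = 4
    # enhancers
    n_enhancers: int = 300
    enhancer_width: int = 500
    enhancer_open_fraction: float = 0.3
    # histone marks / regulator binding
    bivalent_fraction: float = 0.15
    k4_extra_fraction: float = 0.40
    k27_extra_fraction: float = 0.02
    dmrt_fraction: float = 0.15
    opening_bias: float = 4.0
    mark_enrichment: float = 8.0
    # expression
    base_expression_sigma: float = 0.8
    closed_gene_expression_scale: float = 0.2

    def __post_init__(self) -> None:
        if self.class_fractions is None:
            self.class_fractions = default_class_fractions(self.stage_labels)
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {total}, not 1")
        if min(self.n_chroms, self.chrom_length, self.n_replicates) <= 0:
            raise ValueError("counts must be positive")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.accessible_enrichment <= 1:
            raise ValueError("accessible_enrichment must exceed 1")
        if len(self.stage_labels) != len(self.stage_times):
            raise ValueError("stage_labels and stage_times must align")
        if len(self.library_size_factors) != self.n_replicates:
            raise ValueError("one library_size_factor per replicate")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def sample_names(self) -> list[str]:
        return [f"{s}_rep{r + 1}" for s in self.stage_labels
                for r in range(self.n_replicates)]

    def sample_table(self) -> pd.DataFrame:
        rows = [
            (f"{s}_rep{r + 1}", s, r + 1, t)
            for s, t in zip(self.stage_labels, self.stage_times)
            for r in range(self.n_replicates)
        ]
        return pd.DataFrame(rows, columns=["sample", "stage", "replicate", "time"])

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("stage_labels", "stage_times", "library_size_factors"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key in ("stage_labels", "stage_times", "library_size_factors"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthRecord:
    """Planted ground truth for one gene."""

    gene_id: str
    dynamic_class: str
    trajectory_class: str
    bivalent: bool
    k4: bool
    k27: bool
    dmrt_bound: bool


def child_rng(seed: int, *purpose) -> np.random.Generator:
    """Reproducible, collision-safe child generator for a named purpose."""
    tokens = [zlib.crc32(str(p).encode()) for p in purpose]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *tokens]))


def quota_counts(fractions: dict[str, float], n: int) -> dict[str, int]:
    """Exact largest-remainder apportionment of n items to the fractions."""
    raw = {k: f * n for k, f in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    order = sorted(fractions, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in order[:short]:
        counts[k] += 1
    return counts


def accessibility_flags(dynamic_class: str, stage_labels: tuple[str, ...]) -> tuple[bool, ...]:
    """Per-stage promoter accessibility implied by a dynamic class."""
    k = len(stage_labels)
    if dynamic_class == "always_open":
        return (True,) * k
    if dynamic_class == "never_open":
        return (False,) * k
    if dynamic_class.startswith("opening_at_"):
        s = stage_labels.index(dynamic_class.removeprefix("opening_at_"))
        return tuple(i >= s for i in range(k))
    if dynamic_class.startswith("closing_at_"):
        s = stage_labels.index(dynamic_class.removeprefix("closing_at_"))
        return tuple(i < s for i in range(k))
    raise ValueError(f"unknown dynamic class {dynamic_class!r}")


def is_opening(dynamic_class: str) -> bool:
    return dynamic_class.startswith("opening_at_")


def is_closing(dynamic_class: str) -> bool:
    return dynamic_class.startswith("closing_at_")


def _trajectory_for(dynamic_class: str, slot: int) -> str:
    """Deterministic dynamic-class -> trajectory mapping.

    Opening genes rise, closing genes fall; stably open genes cycle through
    flat/transient/up profiles; stably closed genes stay flat (low).
    """
    if is_opening(dynamic_class):
        return "up"
    if is_closing(dynamic_class):
        return "down"
    if dynamic_class == "always_open":
        return ("flat", "transient", "flat", "up")[slot % 4]
    return "flat"


def _biased_quota_pick(
    rng: np.random.Generator, candidates: np.ndarray, weights: np.ndarray, k: int
) -> np.ndarray:
    """Weighted sample of exactly k items without replacement."""
    if k >= candidates.size:
        return candidates.copy()
    p = weights / weights.sum()
    return rng.choice(candidates, size=k, replace=False, p=p)


def generate_genome(
    config: SimConfig,
) -> tuple[GenomeModel, list[GeneModel], pd.DataFrame, list[TruthRecord]]:
    """Build the genome, gene models, enhancer links and truth table.

    Genes are laid out on a regular grid of slots (one gene per slot) so
    promoter and downstream windows never overlap between genes; raises
    :class:`SizingError` if the requested genes do not fit.
    """
    genome = GenomeModel(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    empty_links = pd.DataFrame(
        columns=["enh_chrom", "enh_start", "enh_end", "gene_id", "open"]
    )
    if config.n_genes == 0:
        return genome, [], empty_links, []

    # room upstream of tx_start for +strand promoters and -strand downstream
    # windows, and past tx_end for the converse; enhancers squeeze into the
    # intergenic tail of a slot when its gene leaves room
    margin = config.promoter_up + config.downstream_len + 500
    slot_min = (margin + 500 + config.gene_max_length
                + max(config.downstream_len, config.promoter_up))
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    slot = config.chrom_length // max(per_chrom, 1)
    if slot < slot_min:
        raise SizingError(
            f"{config.n_genes} genes at >= {slot_min} bp each exceed the "
            f"{config.n_chroms} x {config.chrom_length} bp genome"
        )

    rng = child_rng(config.seed, "genome")
    genes: list[GeneModel] = []
    enh_rows = []
    for gi in range(config.n_genes):
        chrom = f"chr{gi % config.n_chroms + 1}"
        slot_start = (gi // config.n_chroms) * slot
        length = int(rng.integers(config.gene_min_length, config.gene_max_length + 1))
        tx_start = slot_start + margin + int(rng.integers(0, 500))
        tx_end = tx_start + length
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, config.max_exons + 1))
        cuts = np.sort(rng.choice(np.arange(1, 2 * n_exons), size=2 * n_exons - 2,
                                  replace=False))
        bounds = np.concatenate(([0], cuts, [2 * n_exons])) / (2 * n_exons)
        pts = tx_start + np.round(bounds * length).astype(int)
        exons = [(int(pts[i]), int(pts[i + 1])) for i in range(0, 2 * n_exons - 1, 2)]
        exons = [(s, e) for s, e in exons if e > s]
        genes.append(GeneModel(f"gene_{gi + 1:05d}", chrom, strand, tx_start, tx_end, exons))

    # enhancers: one per row, in the intergenic tail of a random gene's slot
    enh_rng = child_rng(config.seed, "enhancers")
    open_quota = quota_counts(
        {"open": config.enhancer_open_fraction, "closed": 1 - config.enhancer_open_fraction},
        config.n_enhancers,
    )["open"]
    open_flags = np.zeros(config.n_enhancers, dtype=bool)
    open_flags[:open_quota] = True
    enh_rng.shuffle(open_flags)
    for ei in range(config.n_enhancers):
        gi = int(enh_rng.integers(0, config.n_genes))
        g = genes[gi]
        slot_start = (gi // config.n_chroms) * slot
        tail_lo = g.tx_end + config.downstream_len + 200
        tail_hi = slot_start + slot - config.enhancer_width - config.promoter_up - 200
        if tail_hi <= tail_lo:
            continue
        start = int(enh_rng.integers(tail_lo, tail_hi))
        enh_rows.append(
            (g.chrom, start, start + config.enhancer_width, g.gene_id, bool(open_flags[ei]))
        )
    links = (
        pd.DataFrame(enh_rows, columns=empty_links.columns)
        if enh_rows
        else empty_links
    )

    # dynamic classes by exact quota, shuffled
    truth_rng = child_rng(config.seed, "truth")
    counts = quota_counts(config.class_fractions, config.n_genes)
    classes: list[str] = []
    for name in config.class_fractions:  # stable key order
        classes.extend([name] * counts[name])
    order = truth_rng.permutation(config.n_genes)
    class_of = np.empty(config.n_genes, dtype=object)
    class_of[order] = classes

    opening_mask = np.array([is_opening(c) for c in class_of])
    idx = np.arange(config.n_genes)
    weights = np.where(opening_mask, config.opening_bias, 1.0)

    n_biv = quota_counts({"x": config.bivalent_fraction, "y": 1 - config.bivalent_fraction},
                         config.n_genes)["x"]
    bivalent = np.zeros(config.n_genes, dtype=bool)
    bivalent[_biased_quota_pick(truth_rng, idx, weights, n_biv)] = True

    n_dmrt = quota_counts({"x": config.dmrt_fraction, "y": 1 - config.dmrt_fraction},
                          config.n_genes)["x"]
    dmrt = np.zeros(config.n_genes, dtype=bool)
    dmrt[_biased_quota_pick(truth_rng, idx, weights, n_dmrt)] = True

    # extra K4-only (active promoters) and K27-only (repressed) genes
    k4 = bivalent.copy()
    k27 = bivalent.copy()
    non_biv = idx[~bivalent]
    n_k4 = min(int(round(config.k4_extra_fraction * config.n_genes)), non_biv.size)
    k4[truth_rng.choice(non_biv, size=n_k4, replace=False)] = True
    pool = idx[~k4]
    n_k27 = min(int(round(config.k27_extra_fraction * config.n_genes)), pool.size)
    if n_k27:
        k27[truth_rng.choice(pool, size=n_k27, replace=False)] = True

    truth = [
        TruthRecord(
            gene_id=genes[i].gene_id,
            dynamic_class=str(class_of[i]),
            trajectory_class=_trajectory_for(str(class_of[i]), i),
            bivalent=bool(bivalent[i]),
            k4=bool(k4[i]),
            k27=bool(k27[i]),
            dmrt_bound=bool(dmrt[i]),
        )
        for i in range(config.n_genes)
    ]
    return genome, genes, links, truth


def _poisson_positions(
    rng: np.random.Generator, rate: float, start: int, end: int
) -> np.ndarray:
    """Positions of a homogeneous Poisson process on [start, end)."""
    if rate <= 0 or end <= start:
        return np.empty(0, dtype=np.int64)
    n = rng.poisson(rate * (end - start))
    return rng.integers(start, end, size=n).astype(np.int64)


def simulate_cut_sites(
    truth: list[TruthRecord],
    genes: list[GeneModel],
    genome: GenomeModel,
    stage: str,
    replicate: int,
    config: SimConfig,
    links: pd.DataFrame | None = None,
) -> CutSiteTrack:
    """DNase cut sites for one stage/replicate.

    Poisson background everywhere at ``background_rate``; promoter windows
    of genes accessible at this stage (and linked enhancers planted open)
    carry ``background_rate * accessible_enrichment``.  Rates scale with the
    replicate's library-size factor.
    """
    if stage not in config.stage_labels:
        raise ValueError(f"unknown stage {stage!r}")
    if not 1 <= replicate <= config.n_replicates:
        raise ValueError(f"replicate {replicate} outside 1..{config.n_replicates}")
    rng = child_rng(config.seed, "dnase", stage, replicate)
    factor = config.library_size_factors[replicate - 1]
    bg_rate = config.background_rate * factor
    extra_rate = config.background_rate * (config.accessible_enrichment - 1.0) * factor
    stage_idx = config.stage_labels.index(stage)
    truth_by_id = {t.gene_id: t for t in truth}

    positions: dict[str, list[np.ndarray]] = {c: [] for c in genome.chroms}
    for chrom, length in genome.chrom_lengths.items():
        positions[chrom].append(_poisson_positions(rng, bg_rate, 0, length))
    for gene in genes:
        flags = accessibility_flags(truth_by_id[gene.gene_id].dynamic_class,
                                    config.stage_labels)
        if flags[stage_idx]:
            w = promoter_window(gene, genome, config.promoter_up, config.promoter_down)
            positions[w.chrom].append(_poisson_positions(rng, extra_rate, w.start, w.end))
    if links is not None and len(links):
        for row in links.itertuples(index=False):
            if row.open:
                positions[row.enh_chrom].append(
                    _poisson_positions(rng, extra_rate, int(row.enh_start), int(row.enh_end))
                )
    return CutSiteTrack(
        {c: np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
         for c, parts in positions.items()},
        genome,
    )


def simulate_mark_track(
    truth: list[TruthRecord],
    genes: list[GeneModel],
    genome: GenomeModel,
    mark: str,
    replicate: int,
    config: SimConfig,
) -> CutSiteTrack:
    """ChIP cut-site track for one histone mark and replicate.

    Windows of ``2 * peak_halfwidth`` centered on the promoters of genes
    carrying the mark (bivalent genes carry both marks) are enriched
    ``mark_enrichment``-fold over the Poisson background.
    """
    if mark not in MARKS:
        raise ValueError(f"unknown mark {mark!r}; expected one of {MARKS}")
    rng = child_rng(config.seed, "mark", mark, replicate)
    factor = config.library_size_factors[replicate - 1]
    bg_rate = config.background_rate * factor
    extra_rate = config.background_rate * (config.mark_enrichment - 1.0) * factor
    flag = "k4" if mark == "H3K4me3" else "k27"
    truth_by_id = {t.gene_id: t for t in truth}

    positions: dict[str, list[np.ndarray]] = {c: [] for c in genome.chroms}
    for chrom, length in genome.chrom_lengths.items():
        positions[chrom].append(_poisson_positions(rng, bg_rate, 0, length))
    for gene in genes:
        if getattr(truth_by_id[gene.gene_id], flag):
            w = promoter_window(gene, genome, config.promoter_up, config.promoter_down)
            center = (w.start + w.end) // 2
            s, e = genome.clip(gene.chrom, center - config.peak_halfwidth,
                               center + config.peak_halfwidth)
            positions[gene.chrom].append(_poisson_positions(rng, extra_rate, s, e))
    return CutSiteTrack(
        {c: np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
         for c, parts in positions.items()},
        genome,
    )


def trajectory_means(trajectory_class: str, n_stages: int) -> np.ndarray:
    """Relative stage means of a planted expression trajectory.

    flat: constant; up: geometric rise to 4x; down: the mirror; transient:
    rise-and-return peaking ~3x mid-course.
    """
    i = np.arange(n_stages)
    if trajectory_class == "flat":
        return np.ones(n_stages)
    if trajectory_class == "up":
        return 4.0 ** (i / (n_stages - 1))
    if trajectory_class == "down":
        return 4.0 ** (1 - i / (n_stages - 1))
    if trajectory_class == "transient":
        return 1.0 + 2.0 * np.sin(np.pi * i / (n_stages - 1))
    raise ValueError(f"unknown trajectory class {trajectory_class!r}")


def simulate_counts(
    truth: list[TruthRecord],
    genes: list[GeneModel],
    config: SimConfig,
) -> CountMatrix:
    """Negative-binomial counts following the planted trajectories.

    Mean = trajectory mean x base rate x gene length (kb) x library factor,
    globally scaled to ``library_size`` expected reads per unit-factor
    sample; variance = mu + nb_dispersion * mu^2 (Poisson in the
    nb_dispersion -> 0 limit).
    """
    rng = child_rng(config.seed, "counts")
    samples = config.sample_table()
    truth_by_id = {t.gene_id: t for t in truth}
    gene_ids = [g.gene_id for g in genes]
    lengths = pd.Series({g.gene_id: g.length_bp for g in genes}, name="length_bp")
    if not genes:
        counts = pd.DataFrame(
            np.zeros((0, len(samples)), dtype=np.int64),
            columns=list(samples["sample"]), index=pd.Index([], name="gene_id"),
        )
        return CountMatrix(counts, lengths, samples)

    base = rng.lognormal(mean=np.log(30.0), sigma=config.base_expression_sigma,
                         size=len(genes))
    mu = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        rec = truth_by_id[gene.gene_id]
        rel = trajectory_means(rec.trajectory_class, config.n_stages)
        scale = base[gi] * gene.length_bp / 1000.0
        if rec.dynamic_class == "never_open":
            scale *= config.closed_gene_expression_scale
        for sj, row in enumerate(samples.itertuples(index=False)):
            stage_idx = config.stage_labels.index(row.stage)
            lib_factor = config.library_size_factors[row.replicate - 1]
            mu[gi, sj] = rel[stage_idx] * scale * lib_factor
    # scale so a unit-factor sample expects ~library_size reads
    factors = np.array([config.library_size_factors[r - 1] for r in samples["replicate"]])
    mu *= config.library_size / np.mean(mu.sum(axis=0) / factors)

    if config.nb_dispersion < 1e-12:
        X = rng.poisson(mu)
    else:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mu * config.nb_dispersion)
        X = rng.poisson(lam)
    counts = pd.DataFrame(X.astype(np.int64), index=pd.Index(gene_ids, name="gene_id"),
                          columns=list(samples["sample"]))
    return CountMatrix(counts, lengths, samples)


@dataclass
class SimBundle:
    """Everything one simulated study produces, plus its ground truth."""

    config: SimConfig
    genome: GenomeModel
    genes: list[GeneModel]
    links: pd.DataFrame
    truth: list[TruthRecord]
    cut_tracks: dict[tuple[str, int], CutSiteTrack]
    mark_tracks: dict[tuple[str, int], CutSiteTrack]
    counts: CountMatrix

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.truth])


def simulate_bundle(config: SimConfig) -> SimBundle:
    """Run the full generator for one configuration."""
    genome, genes, links, truth = generate_genome(config)
    cut_tracks = {
        (stage, rep): simulate_cut_sites(truth, genes, genome, stage, rep, config, links)
        for stage in config.stage_labels
        for rep in range(1, config.n_replicates + 1)
    }
    mark_tracks = {
        (mark, rep): simulate_mark_track(truth, genes, genome, mark, rep, config)
        for mark in MARKS
        for rep in range(1, config.n_replicates + 1)
    }
    counts = simulate_counts(truth, genes, config)
    return SimBundle(config, genome, genes, links, truth, cut_tracks, mark_tracks, counts)


def write_fixture_bundle(bundle: SimBundle, directory: str | Path) -> dict:
    """Serialize a bundle to text files; returns the file -> row-count manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    try:
        dio.write_config_yaml(bundle.config.to_dict(), directory / "config.yaml")
        manifest["config.yaml"] = 1
        manifest["genome.tsv"] = dio.write_genome_tsv(bundle.genome, directory / "genome.tsv")
        manifest["genes.bed"] = dio.write_genes_bed12(bundle.genes, directory / "genes.bed")
        manifest["enhancers.tsv"] = dio.write_tsv(bundle.links, directory / "enhancers.tsv")
        manifest["truth.tsv"] = dio.write_tsv(bundle.truth_frame(), directory / "truth.tsv")
        manifest["counts.tsv"] = dio.write_counts_tsv(bundle.counts, directory / "counts.tsv")
        manifest["samples.tsv"] = dio.write_tsv(bundle.counts.samples,
                                                directory / "samples.tsv")
        for (stage, rep), track in bundle.cut_tracks.items():
            name = f"cuts_{stage}_rep{rep}.bed"
            manifest[name] = dio.write_bed3(track, directory / name)
        for (mark, rep), track in bundle.mark_tracks.items():
            name = f"marks_{mark}_rep{rep}.bed"
            manifest[name] = dio.write_bed3(track, directory / name)
        dio.write_manifest(manifest, directory / "manifest.json")
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle under {directory}: {exc}") from exc
    return manifest


def read_fixture_bundle(directory: str | Path) -> SimBundle:
    """Round-trip loader for :func:`write_fixture_bundle` output."""
    directory = Path(directory)
    config = SimConfig.from_dict(dio.read_config_yaml(directory / "config.yaml"))
    genome = dio.read_genome_tsv(directory / "genome.tsv")
    genes = dio.read_genes_bed12(directory / "genes.bed")
    links = dio.read_tsv(directory / "enhancers.tsv")
    if links.empty:
        links = pd.DataFrame(columns=["enh_chrom", "enh_start", "enh_end", "gene_id", "open"])
    truth_df = dio.read_tsv(directory / "truth.tsv")
    truth = [
        TruthRecord(
            gene_id=row.gene_id,
            dynamic_class=row.dynamic_class,
            trajectory_class=row.trajectory_class,
            bivalent=bool(row.bivalent),
            k4=bool(row.k4),
            k27=bool(row.k27),
            dmrt_bound=bool(row.dmrt_bound),
        )
        for row in truth_df.itertuples(index=False)
    ] if len(truth_df) else []
    samples = dio.read_tsv(directory / "samples.tsv")
    counts = dio.read_counts_tsv(directory / "counts.tsv", samples)
    cut_tracks = {
        (stage, rep): dio.read_bed3(directory / f"cuts_{stage}_rep{rep}.bed", genome)
        for stage in config.stage_labels
        for rep in range(1, config.n_replicates + 1)
    }
    mark_tracks = {
        (mark, rep): dio.read_bed3(directory / f"marks_{mark}_rep{rep}.bed", genome)
        for mark in MARKS
        for rep in range(1, config.n_replicates + 1)
    }
    return SimBundle(config, genome, genes, links, truth, cut_tracks, mark_tracks, counts)
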