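"""Readers and writers for the standard text formats the pipeline uses.

Cut sites are BED3 (one cut per line, ``end = start + 1``); gene models are
BED12; enhancer links, count matrices and truth tables are TSV; configs are
YAML.  All coordinates are 0-based half-open.  Writers can prepend ``#``
header comments (used by the CLI to record the coordinate convention and
config hash); readers skip them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import CutSiteTrack, GeneModel, GenomeModel
from .expression import CountMatrix


def _write_lines(path: Path, lines: list[str], header: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for comment in header or []:
            fh.write(f"# {comment}\n")
        for line in lines:
            fh.write(line + "\n")


def write_bed3(track: CutSiteTrack, path: str | Path, header: list[str] | None = None) -> int:
    """Write cut positions as BED3; returns the number of data rows."""
    lines = []
    for chrom in track.genome.chroms:
        for p in track.positions[chrom]:
            lines.append(f"{chrom}\t{p}\t{p + 1}")
    _write_lines(Path(path), lines, header)
    return len(lines)


def read_bed3(path: str | Path, genome: GenomeModel) -> CutSiteTrack:
    positions: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, start, _ = line.rstrip("\n").split("\t")[:3]
            positions.setdefault(chrom, []).append(int(start))
    return CutSiteTrack(
        {c: np.array(v, dtype=np.int64) for c, v in positions.items()}, genome
    )


def write_regions_bed(df: pd.DataFrame, path: str | Path,
                      header: list[str] | None = None) -> int:
    """Write a (chrom, start, end[, ...extra]) frame as BED."""
    lines = ["\t".join(str(v) for v in row) for row in df.itertuples(index=False)]
    _write_lines(Path(path), lines, header)
    return len(lines)


def read_regions_bed(path: str | Path, names: list[str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=None)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names or ["chrom", "start", "end"])
    names = names or ["chrom", "start", "end"]
    df = df.iloc[:, : len(names)]
    df.columns = names
    return df


def write_genes_bed12(genes: list[GeneModel], path: str | Path,
                      header: list[str] | None = None) -> int:
    lines = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons) + ","
        starts = ",".join(str(s - g.tx_start) for s, e in g.exons) + ","
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    g.chrom, g.tx_start, g.tx_end, g.gene_id, 0, g.strand,
                    g.tx_start, g.tx_end, 0, len(g.exons), sizes, starts,
                )
            )
        )
    _write_lines(Path(path), lines, header)
    return len(lines)


def read_genes_bed12(path: str | Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(name, chrom, strand, start, end, exons))
    return genes


def write_narrowpeak(peaks, path: str | Path, header: list[str] | None = None) -> int:
    """ENCODE narrowPeak: col 7 = max density, col 8 = -log10 tail probability."""
    lines = []
    for i, pk in enumerate(peaks):
        neglogp = -np.log10(max(pk.tail_probability, 1e-300))
        score = int(min(1000, round(10 * neglogp)))
        lines.append(
            "\t".join(
                str(v)
                for v in (
                    pk.region.chrom, pk.region.start, pk.region.end,
                    f"peak_{i + 1}", score, ".",
                    f"{pk.max_density:.6g}", f"{neglogp:.4f}", -1, -1,
                )
            )
        )
    _write_lines(Path(path), lines, header)
    return len(lines)


def write_tsv(df: pd.DataFrame, path: str | Path, header: list[str] | None = None,
              index: bool = False) -> int:
    with open(path, "w") as fh:
        for comment in header or []:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=index)
    return len(df)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_genome_tsv(genome: GenomeModel, path: str | Path,
                     header: list[str] | None = None) -> int:
    df = pd.DataFrame(
        {"chrom": genome.chroms, "length": [genome.chrom_lengths[c] for c in genome.chroms]}
    )
    return write_tsv(df, path, header)


def read_genome_tsv(path: str | Path) -> GenomeModel:
    df = read_tsv(path)
    return GenomeModel(dict(zip(df["chrom"], df["length"].astype(int))))


def write_counts_tsv(counts: CountMatrix, path: str | Path,
                     header: list[str] | None = None) -> int:
    df = counts.counts.copy()
    df.insert(0, "length_bp", counts.lengths.loc[df.index])
    df.index.name = "gene_id"
    return write_tsv(df.reset_index(), path, header)


def read_counts_tsv(path: str | Path, samples: pd.DataFrame) -> CountMatrix:
    df = read_tsv(path).set_index("gene_id")
    lengths = df.pop("length_bp").astype(int)
    return CountMatrix(df.astype(np.int64), lengths, samples)


def write_config_yaml(config_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)


def read_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_manifest(manifest: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
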