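"""Planted-truth generator: determinism, quotas, rates, serialization."""

import numpy as np
import pandas as pd
import pytest

from dhsdyn.core import GenomeModel
from dhsdyn.features import promoter_window
from dhsdyn.synthetic import (
    SimConfig,
    SizingError,
    accessibility_flags,
    generate_genome,
    quota_counts,
    read_fixture_bundle,
    simulate_bundle,
    simulate_counts,
    simulate_cut_sites,
    simulate_mark_track,
    write_fixture_bundle,
)


def tiny_config(**kw):
    base = dict(seed=3, n_genes=20, n_chroms=1, chrom_length=400_000, n_enhancers=8)
    base.update(kw)
    return SimConfig(**base)


class TestConfig:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            SimConfig(class_fractions={"always_open": 0.5, "never_open": 0.4})

    def test_enrichment_must_exceed_one(self):
        with pytest.raises(ValueError, match="enrichment"):
            SimConfig(accessible_enrichment=1.0)

    def test_roundtrips_through_dict(self):
        cfg = tiny_config()
        assert SimConfig.from_dict(cfg.to_dict()) == cfg

    def test_sizing_error_when_genes_do_not_fit(self):
        with pytest.raises(SizingError, match="exceed"):
            generate_genome(SimConfig(n_genes=500, n_chroms=1, chrom_length=100_000))


class TestGenerateGenome:
    def test_empty_case(self):
        genome, genes, links, truth = generate_genome(tiny_config(n_genes=0))
        assert genes == [] and truth == [] and links.empty
        assert genome.total_length == 400_000

    def test_deterministic_under_seed(self):
        a = generate_genome(tiny_config())
        b = generate_genome(tiny_config())
        assert a[1] == b[1]
        assert [vars(t) for t in a[3]] == [vars(t) for t in b[3]]
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_exact_quota_of_dynamic_classes(self):
        fractions = {
            "always_open": 0.3, "never_open": 0.3,
            "opening_at_E16": 0.2, "closing_at_E16": 0.2,
        }
        cfg = SimConfig(seed=5, n_genes=1000, class_fractions=fractions)
        _, _, _, truth = generate_genome(cfg)
        classes = pd.Series([t.dynamic_class for t in truth]).value_counts()
        assert classes["opening_at_E16"] == 200
        assert classes["always_open"] == 300

    def test_quota_counts_largest_remainder(self):
        assert quota_counts({"a": 0.5, "b": 0.3, "c": 0.2}, 7) == {"a": 4, "b": 2, "c": 1}

    def test_promoter_windows_disjoint_by_construction(self):
        genome, genes, _, _ = generate_genome(tiny_config())
        wins = sorted(
            (promoter_window(g, genome).start, promoter_window(g, genome).end)
            for g in genes
        )
        assert all(a[1] <= b[0] for a, b in zip(wins, wins[1:]))

    def test_truth_consistent_with_accessibility_flags(self):
        cfg = tiny_config()
        _, _, _, truth = generate_genome(cfg)
        for t in truth:
            flags = accessibility_flags(t.dynamic_class, cfg.stage_labels)
            assert len(flags) == 4
            if t.dynamic_class == "always_open":
                assert all(flags)
            if t.dynamic_class.startswith("opening"):
                assert not flags[0] and flags[-1]
            if t.dynamic_class.startswith("closing"):
                assert flags[0] and not flags[-1]


class TestCutSites:
    def test_uniform_when_enrichment_marginal(self):
        cfg = tiny_config(accessible_enrichment=1.0 + 1e-9)
        genome, genes, links, truth = generate_genome(cfg)
        track = simulate_cut_sites(truth, genes, genome, "E12", 1, cfg)
        expected = cfg.background_rate * genome.total_length
        assert abs(track.n_cuts - expected) < 3 * np.sqrt(expected)

    def test_zero_background_puts_all_cuts_in_windows(self):
        cfg = tiny_config(background_rate=0.0)
        genome, genes, links, truth = generate_genome(cfg)
        track = simulate_cut_sites(truth, genes, genome, "E16", 1, cfg)
        # inside-window rate is background x enrichment, so zero background
        # silences the whole genome: no cut may fall outside a window
        windows = [promoter_window(g, genome) for g in genes]
        for pos in np.concatenate(list(track.positions.values())):
            assert any(w.start <= pos < w.end for w in windows) or track.n_cuts == 0

    def test_determinism_per_stage_replicate(self):
        cfg = tiny_config()
        genome, genes, links, truth = generate_genome(cfg)
        t1 = simulate_cut_sites(truth, genes, genome, "E13", 2, cfg, links)
        t2 = simulate_cut_sites(truth, genes, genome, "E13", 2, cfg, links)
        assert t1 == t2

    def test_replicates_differ(self):
        cfg = tiny_config()
        genome, genes, links, truth = generate_genome(cfg)
        t1 = simulate_cut_sites(truth, genes, genome, "E13", 1, cfg)
        t2 = simulate_cut_sites(truth, genes, genome, "E13", 2, cfg)
        assert t1 != t2

    def test_unknown_stage_errors(self):
        cfg = tiny_config()
        genome, genes, links, truth = generate_genome(cfg)
        with pytest.raises(ValueError, match="stage"):
            simulate_cut_sites(truth, genes, genome, "E99", 1, cfg)


class TestMarkTracks:
    def test_unknown_mark_rejected(self):
        cfg = tiny_config()
        genome, genes, links, truth = generate_genome(cfg)
        with pytest.raises(ValueError, match="mark"):
            simulate_mark_track(truth, genes, genome, "H3K9me3", 1, cfg)

    def test_bivalent_gene_enriched_in_both_marks(self):
        cfg = tiny_config()
        genome, genes, links, truth = generate_genome(cfg)
        biv = next(t for t in truth if t.bivalent)
        gene = next(g for g in genes if g.gene_id == biv.gene_id)
        w = promoter_window(gene, genome)
        background = cfg.background_rate * (w.end - w.start)
        for mark in ("H3K4me3", "H3K27me3"):
            track = simulate_mark_track(truth, genes, genome, mark, 1, cfg)
            n = track.counts_in(w.chrom, w.start - 500, w.end + 500)
            assert n > 3 * background

    def test_no_marked_genes_gives_background_only(self):
        cfg = tiny_config()
        genome, genes, links, truth = generate_genome(cfg)
        for t in truth:
            t.bivalent = t.k4 = t.k27 = False
        track = simulate_mark_track(truth, genes, genome, "H3K4me3", 1, cfg)
        expected = cfg.background_rate * genome.total_length
        assert abs(track.n_cuts - expected) < 4 * np.sqrt(expected)


class TestCounts:
    def test_poisson_limit_of_dispersion(self):
        cfg = tiny_config(nb_dispersion=0.0, n_genes=40,
                          library_size_factors=(1.0, 1.0))
        genome, genes, links, truth = generate_genome(cfg)
        cm = simulate_counts(truth, genes, cfg)
        X = cm.counts.to_numpy(dtype=float)
        # within-stage replicate differences: E[(x1-x2)^2 / 2] = mu for Poisson
        r1, r2 = X[:, 0::2], X[:, 1::2]
        ratio = ((r1 - r2) ** 2 / 2).mean(axis=1) / X.mean(axis=1)
        assert 0.4 < np.median(ratio) < 1.8

    def test_flat_genes_have_equal_stage_means(self):
        cfg = tiny_config(nb_dispersion=0.01, library_size_factors=(1.0, 1.0),
                          n_genes=40)
        genome, genes, links, truth = generate_genome(cfg)
        cm = simulate_counts(truth, genes, cfg)
        flat = [t.gene_id for t in truth
                if t.trajectory_class == "flat" and t.dynamic_class != "never_open"]
        stage = cm.samples.set_index("sample")["stage"]
        means = cm.counts.loc[flat].T.groupby(stage).mean().T
        m = means.mean(axis=1)
        se = np.sqrt((m + cfg.nb_dispersion * m**2) / 2)  # NB SE of a 2-replicate mean
        spread = (means.max(axis=1) - means.min(axis=1)) / se
        assert (spread < 6).mean() > 0.9  # pairwise 3 SE-ish tolerance

    def test_seed_fixed_identical_matrix(self):
        cfg = tiny_config()
        genome, genes, links, truth = generate_genome(cfg)
        a = simulate_counts(truth, genes, cfg)
        b = simulate_counts(truth, genes, cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)


class TestBundleSerialization:
    def test_roundtrip_identity(self, tmp_path):
        bundle = simulate_bundle(tiny_config())
        write_fixture_bundle(bundle, tmp_path / "fx")
        back = read_fixture_bundle(tmp_path / "fx")
        assert back.config == bundle.config
        assert back.genes == bundle.genes
        assert [vars(t) for t in back.truth] == [vars(t) for t in bundle.truth]
        pd.testing.assert_frame_equal(back.links, bundle.links)
        pd.testing.assert_frame_equal(back.counts.counts, bundle.counts.counts)
        for key, track in bundle.cut_tracks.items():
            assert back.cut_tracks[key] == track
        for key, track in bundle.mark_tracks.items():
            assert back.mark_tracks[key] == track

    def test_manifest_counts_match_file_lines(self, tmp_path):
        bundle = simulate_bundle(tiny_config())
        manifest = write_fixture_bundle(bundle, tmp_path / "fx")
        for name, rows in manifest.items():
            if not name.endswith(".bed"):
                continue
            with open(tmp_path / "fx" / name) as fh:
                lines = sum(1 for line in fh if not line.startswith("#"))
            assert lines == rows

    def test_empty_simulation_writes_headers_only(self, tmp_path):
        bundle = simulate_bundle(tiny_config(n_genes=0, n_enhancers=0,
                                             background_rate=0.0))
        manifest = write_fixture_bundle(bundle, tmp_path / "fx")
        assert manifest["genes.bed"] == 0
        assert manifest["truth.tsv"] == 0
        assert all(v == 0 for k, v in manifest.items() if k.startswith("cuts_"))

    def test_bundle_determinism_byte_identical(self, tmp_path):
        import hashlib

        def digest(d):
            h = hashlib.sha256()
            for f in sorted(p.name for p in d.iterdir()):
                h.update(f.encode())
                h.update((d / f).read_bytes())
            return h.hexdigest()

        write_fixture_bundle(simulate_bundle(tiny_config()), tmp_path / "a")
        write_fixture_bundle(simulate_bundle(tiny_config()), tmp_path / "b")
        assert digest(tmp_path / "a") == digest(tmp_path / "b")
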