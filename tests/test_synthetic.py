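"""Generator construction constraints and format conformance."""

import warnings

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from screenkit.metrics import distance_to_nearest_catalytic
from screenkit.profiles import parse_pssm, parse_hmm, sigmoid_normalize
from screenkit.structure import read_structure
from screenkit.synthetic import (GeneratorConfig, generate_backbone,
                                 plant_catalytic, synthesize_features,
                                 generate_dataset, emit_fixture_set,
                                 analytic_cutoff, generate_variant_table)
from screenkit.triage import gaussian_cutoff


class TestBackbone:
    def test_consecutive_spacing_within_tolerance(self, rng):
        coords = generate_backbone(60, rng)
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        assert ((steps >= 3.75) & (steps <= 3.85)).all()

    def test_non_consecutive_minimum_separation(self, rng):
        coords = generate_backbone(60, rng)
        d = squareform(pdist(coords))
        off = ~np.eye(60, dtype=bool) & ~np.eye(60, k=1, dtype=bool) \
            & ~np.eye(60, k=-1, dtype=bool)
        assert d[off].min() >= 4.0

    def test_same_seed_is_bit_identical(self):
        a = generate_backbone(40, np.random.default_rng(9))
        b = generate_backbone(40, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_too_short_chain_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_backbone(1, rng)


class TestPlantCatalytic:
    def test_every_planted_residue_has_close_planted_neighbor(self, rng):
        coords = generate_backbone(80, rng)
        mask = plant_catalytic(coords, k=6, radius=8.0, rng=rng)
        assert mask.sum() == 6
        idx = np.nonzero(mask)[0]
        d = squareform(pdist(coords[idx]))
        np.fill_diagonal(d, np.inf)
        assert (d.min(axis=1) <= 8.0).all()

    def test_pair_within_radius(self, rng):
        coords = generate_backbone(40, rng)
        mask = plant_catalytic(coords, k=2, radius=8.0, rng=rng)
        i, j = np.nonzero(mask)[0]
        assert np.linalg.norm(coords[i] - coords[j]) <= 8.0

    def test_default_config_cohesion(self, small_dataset):
        """Planted sites are tighter than the rest of the chain is to them."""
        records, _ = small_dataset
        cat, non = [], []
        for r in records:
            m = r.catalytic_mask.astype(bool)
            cat.extend(distance_to_nearest_catalytic(r.ca_coords, m, m))
            non.extend(distance_to_nearest_catalytic(r.ca_coords, m, ~m))
        assert np.median(cat) < np.median(non)

    def test_infeasible_radius_rejected(self, rng):
        coords = generate_backbone(30, rng)
        with pytest.raises(RuntimeError):
            plant_catalytic(coords, k=10, radius=0.5, rng=rng)


class TestSynthesizeFeatures:
    def test_catalytic_rows_are_more_conserved(self, rng):
        cfg = GeneratorConfig()
        mask = np.zeros(200, dtype=int)
        mask[:20] = 1
        pssm, hmm, _ = synthesize_features(mask, cfg, rng)
        assert pssm[:20].mean() > pssm[20:].mean()
        assert hmm[:20, :20].mean() > hmm[20:, :20].mean()

    def test_zero_signal_yields_exchangeable_features(self, rng):
        from scipy.stats import mannwhitneyu
        cfg = GeneratorConfig(conservation_lift=0.0)
        mask = np.zeros(400, dtype=int)
        mask[:200] = 1
        pssm, _, _ = synthesize_features(mask, cfg, rng)
        p = mannwhitneyu(pssm[:200].ravel(), pssm[200:].ravel()).pvalue
        assert p > 0.01  # no planted difference to detect

    def test_same_seed_is_bit_identical(self):
        cfg = GeneratorConfig()
        mask = np.zeros(50, dtype=int)
        mask[:5] = 1
        a = synthesize_features(mask, cfg, np.random.default_rng(3))
        b = synthesize_features(mask, cfg, np.random.default_rng(3))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_embedding_is_low_rank_plus_residual(self, rng):
        cfg = GeneratorConfig()
        mask = np.zeros(80, dtype=int)
        _, _, emb = synthesize_features(mask, cfg, rng)
        s = np.linalg.svd(emb - emb.mean(0), compute_uv=False)
        # dominant variance inside the planted rank: basis variance is
        # embed_rank * embed_noise^2 = 16 against an isotropic residual of
        # 1024 * embed_residual^2 = 2.56, i.e. ~86% in the planted subspace
        top = (s[:cfg.embed_rank + 1] ** 2).sum() / (s ** 2).sum()
        assert top > 0.8


class TestDatasetDeterminism:
    def test_same_config_reproduces_graphs(self):
        cfg = GeneratorConfig(n_enzymes=2, residues_per_enzyme=25,
                              catalytic_per_enzyme=3, seed=77)
        _, g1 = generate_dataset(cfg)
        _, g2 = generate_dataset(cfg)
        for a, b in zip(g1, g2):
            np.testing.assert_array_equal(a.adjacency, b.adjacency)
            np.testing.assert_array_equal(a.x_l, b.x_l)
            np.testing.assert_array_equal(a.x_g, b.x_g)
            np.testing.assert_array_equal(a.x_a, b.x_a)

    def test_all_classes_populated(self, small_dataset):
        _, graphs = small_dataset
        assert {g.ec_class for g in graphs} == {1, 2, 3}


class TestEmittedFixtures:
    def test_structure_round_trip_to_format_precision(self, fixture_dir):
        out, cfg = fixture_dir
        rng = np.random.default_rng(cfg.seed)
        # regenerate the same first enzyme the emitter wrote
        from screenkit.synthetic import generate_enzyme, _embedding_basis
        from screenkit.types import EMBED_WIDTH
        class_vectors = {
            c: rng.normal(size=EMBED_WIDTH) / np.sqrt(EMBED_WIDTH) * 10.0
            for c in range(1, cfg.n_classes + 1)}
        record, _, _ = generate_enzyme(cfg, rng, "SYN0000_A", 1,
                                       class_vector=class_vectors[1])
        reread = read_structure(out / "SYN0000.pdb", "A")
        assert reread.sequence == record.sequence
        np.testing.assert_allclose(reread.ca_coords, record.ca_coords,
                                   atol=5e-4)

    def test_emitted_pssm_parses_cleanly(self, fixture_dir):
        out, _ = fixture_dir
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            m = parse_pssm(out / "SYN0001.pssm")
        assert m.shape[1] == 20
        normalized = sigmoid_normalize(m)
        assert ((normalized > 0) & (normalized < 1)).all()

    def test_emitted_hmm_round_trips_probabilities(self, fixture_dir):
        out, _ = fixture_dir
        m = parse_hmm(out / "SYN0001.hmm")
        assert m.shape[1] == 30
        assert ((m >= 0) & (m <= 1)).all()

    def test_labels_and_manifest_consistent(self, fixture_dir):
        out, cfg = fixture_dir
        from screenkit.structure import read_catalytic_labels
        labels = read_catalytic_labels(out / "catalytic_labels.tsv")
        assert len(labels) == cfg.n_enzymes
        for (sid, chain), residues in labels.items():
            assert len(residues) == cfg.catalytic_per_enzyme

    def test_emitted_variant_scores_recover_planted_cutoff(self, fixture_dir):
        out, cfg = fixture_dir
        from screenkit.triage import read_variant_table
        table = read_variant_table(out / "SYN0000.variants.tsv",
                                   orientation=True)
        # pool several tables for a stable fit
        scores = [table.scores]
        for i in (1, 2):
            scores.append(read_variant_table(
                out / f"SYN000{i}.variants.tsv", orientation=True).scores)
        pooled = np.concatenate(scores)
        got = gaussian_cutoff(pooled, seed=0)
        assert got == pytest.approx(analytic_cutoff(cfg), abs=0.25)

    def test_manifest_records_config_and_seed(self, fixture_dir):
        import json
        out, cfg = fixture_dir
        manifest = json.loads((out / "MANIFEST.json").read_text())
        assert manifest["seed"] == cfg.seed
        assert manifest["config"]["n_enzymes"] == cfg.n_enzymes
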