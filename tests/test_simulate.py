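"""Synthetic-data generator: determinism, marginal laws, planted structure."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cryodiff import (
    PlantedSet,
    SimConfig,
    compute_tpm,
    simulate_annotations,
    simulate_counts,
    simulate_network,
    simulate_phenotypes,
)
from cryodiff.simulate import ConfigError


def small_config(**kw):
    kw.setdefault("n_genes", 300)
    kw.setdefault("seed", 7)
    return SimConfig(**kw)


class TestSimConfig:
    def test_duplicate_set_names_rejected(self):
        with pytest.raises(ConfigError):
            small_config(
                planted_down_sets=(PlantedSet("s", 5, -1.0),),
                planted_up_sets=(PlantedSet("s", 5, 1.0),),
            )

    def test_oversized_planting_rejected(self):
        with pytest.raises(ConfigError):
            small_config(n_genes=10, planted_down_sets=(PlantedSet("s", 11, -1.0),))

    def test_sign_conventions_enforced(self):
        with pytest.raises(ConfigError):
            small_config(planted_down_sets=(PlantedSet("s", 5, 1.0),))
        with pytest.raises(ConfigError):
            small_config(planted_up_sets=(PlantedSet("s", 5, -1.0),))

    def test_invalid_scalars_rejected(self):
        with pytest.raises(ConfigError):
            small_config(nb_dispersion=0.0)
        with pytest.raises(ConfigError):
            small_config(gene_length_range=(0.0, 100.0))

    def test_from_dict_parses_planted_sets(self):
        cfg = SimConfig.from_dict(
            {
                "n_genes": 50,
                "planted_down_sets": [{"name": "s", "size": 5, "log2_effect": -2.0}],
            }
        )
        assert cfg.planted_down_sets[0] == PlantedSet("s", 5, -2.0)


class TestSimulateCounts:
    def test_shape_matches_design(self):
        cfg = small_config(n_days=3, replicates_per_condition=2)
        counts, sheet, truth = simulate_counts(cfg)
        assert counts.counts.shape == (300, 12)
        assert sheet.days == [8, 10, 12]
        assert len(sheet.samples_for(10, "CRYO")) == 2
        assert len(truth.table) == 300

    def test_identical_seed_identical_output(self):
        a = simulate_counts(small_config())
        b = simulate_counts(small_config())
        pd.testing.assert_frame_equal(a[0].counts, b[0].counts)
        pd.testing.assert_series_equal(a[0].lengths, b[0].lengths)
        pd.testing.assert_frame_equal(a[2].table, b[2].table)

    def test_different_seed_changes_counts(self):
        a = simulate_counts(small_config(seed=1))
        b = simulate_counts(small_config(seed=2))
        assert not a[0].counts.equals(b[0].counts)

    def test_all_null_config_centers_condition_ratio_on_one(self):
        cfg = small_config(n_genes=2000, nb_dispersion=0.05, seed=3)
        counts, sheet, truth = simulate_counts(cfg)
        assert (truth.table["status"] == "null").all()
        # TPM removes the library-size noise, leaving only counting noise
        tpm = compute_tpm(counts).values
        frsh = tpm[[s for s in counts.sample_ids if "FRSH" in s]].mean(axis=1)
        cryo = tpm[[s for s in counts.sample_ids if "CRYO" in s]].mean(axis=1)
        expressed = (frsh > 20) & (cryo > 20)
        log_ratio = np.log2(cryo[expressed] / frsh[expressed])
        assert abs(log_ratio.mean()) < 0.05

    def test_planted_tpm_ratio_approaches_generating_means(self):
        # effect -2, near-zero dispersion, deep library: TPM ratio -> 0.25
        cfg = small_config(
            n_genes=1000,
            nb_dispersion=1e-9,
            mean_library_size=2e7,
            planted_down_sets=(PlantedSet("down", 20, -2.0),),
            planted_baseline_log2_boost=0.0,
            planted_baseline_sd=1.5,
            library_size_cv=0.0,
            seed=5,
        )
        counts, sheet, truth = simulate_counts(cfg)
        tpm = compute_tpm(counts).values
        planted = truth.genes_with_status("down")
        frsh = tpm.loc[planted, [s for s in tpm.columns if "FRSH" in s]].mean(axis=1)
        cryo = tpm.loc[planted, [s for s in tpm.columns if "CRYO" in s]].mean(axis=1)
        ratio = (cryo / frsh).mean()
        assert ratio == pytest.approx(0.25, rel=0.10)

    def test_planted_effects_recovered_from_generating_means(self):
        cfg = small_config(
            n_genes=1000,
            nb_dispersion=1e-9,
            mean_library_size=2e7,
            planted_down_sets=(PlantedSet("dn", 15, -1.5),),
            planted_up_sets=(PlantedSet("up", 15, 1.0),),
            library_size_cv=0.0,
            seed=9,
        )
        counts, _, truth = simulate_counts(cfg)
        tpm = compute_tpm(counts).values
        for status, effect in (("down", -1.5), ("up", 1.0)):
            genes = truth.genes_with_status(status)
            frsh = tpm.loc[genes, [s for s in tpm.columns if "FRSH" in s]].mean(axis=1)
            cryo = tpm.loc[genes, [s for s in tpm.columns if "CRYO" in s]].mean(axis=1)
            observed = np.log2(cryo / frsh).mean()
            assert observed == pytest.approx(effect, abs=0.1)

    def test_negative_binomial_marginal_law(self):
        # many replicates of one condition, fixed library: var ~ m + d m^2
        cfg = SimConfig(
            n_genes=5,
            n_days=1,
            replicates_per_condition=5000,
            mean_library_size=5e4,
            nb_dispersion=0.3,
            baseline_log_mean_sd=0.8,
            library_size_cv=0.0,
            seed=13,
        )
        counts, sheet, _ = simulate_counts(cfg)
        frsh = counts.counts[[s for s in counts.sample_ids if "FRSH" in s]]
        m = frsh.mean(axis=1).to_numpy()
        v = frsh.var(axis=1).to_numpy()
        expected = m + 0.3 * m**2
        np.testing.assert_allclose(v, expected, rtol=0.15)

    def test_truth_partitions_planted_genes(self):
        cfg = small_config(
            planted_down_sets=(PlantedSet("a", 10, -1.0),),
            planted_up_sets=(PlantedSet("b", 10, 1.0),),
        )
        _, _, truth = simulate_counts(cfg)
        planted = truth.table[truth.table["set_label"] != ""]
        assert not planted["gene"].duplicated().any()
        assert set(planted.groupby("set_label").size().to_dict().items()) == {
            ("a", 10),
            ("b", 10),
        }
        nulls = truth.table[truth.table["status"] == "null"]
        assert (nulls["log2_effect"] == 0).all()


class TestSimulateAnnotations:
    def make_truth(self):
        cfg = small_config(
            planted_down_sets=(PlantedSet("dn", 12, -2.0),),
            planted_up_sets=(PlantedSet("up", 8, 2.0),),
        )
        return simulate_counts(cfg)[2]

    def test_zero_decoys_equals_planted_sets(self):
        truth = self.make_truth()
        coll = simulate_annotations(truth, n_decoy_sets=0, seed=1)
        assert {t: set(s.members) for t, s in coll.sets.items()} == {
            name: set(members) for name, members in truth.planted_sets().items()
        }

    def test_decoys_drawn_only_from_null_genes(self):
        truth = self.make_truth()
        coll = simulate_annotations(truth, n_decoy_sets=10, seed=2)
        nulls = set(truth.genes_with_status("null"))
        for term, gs in coll.sets.items():
            if term.startswith("decoy"):
                assert set(gs.members) <= nulls

    def test_decoy_overlap_matches_hypergeometric_expectation(self):
        # overlap of a random decoy with a fixed null subset ~ hypergeometric
        truth = self.make_truth()
        nulls = sorted(truth.genes_with_status("null"))
        probe = set(nulls[:50])
        overlaps = []
        for seed in range(150):
            coll = simulate_annotations(truth, n_decoy_sets=1, seed=seed, decoy_set_size=20)
            decoy = coll.sets["decoy_000"].members
            overlaps.append(len(decoy & probe))
        expected = 20 * 50 / len(nulls)
        sd = np.std(overlaps, ddof=1) / np.sqrt(len(overlaps))
        assert abs(np.mean(overlaps) - expected) < 4 * sd + 0.2

    def test_fixed_seed_reproducibility(self):
        truth = self.make_truth()
        a = simulate_annotations(truth, n_decoy_sets=5, seed=3)
        b = simulate_annotations(truth, n_decoy_sets=5, seed=3)
        assert {t: s.members for t, s in a.sets.items()} == {
            t: s.members for t, s in b.sets.items()
        }


class TestSimulateNetwork:
    def make_truth(self, set_sizes=(10, 10)):
        cfg = small_config(
            n_genes=120,
            planted_down_sets=(PlantedSet("m1", set_sizes[0], -1.0),),
            planted_up_sets=(PlantedSet("m2", set_sizes[1], 1.0),),
        )
        return simulate_counts(cfg)[2]

    def test_no_probabilities_no_edges(self):
        net = simulate_network(self.make_truth(), 0.0, 0.0, seed=1)
        assert net.n_edges == 0

    def test_full_intra_connectivity_above_cutoff(self):
        truth = self.make_truth()
        net = simulate_network(truth, 1.0, 0.0, score_means=(0.95, 0.4), score_sd=0.01, seed=2)
        for members in truth.planted_sets().values():
            for u, v in itertools.combinations(sorted(members), 2):
                assert net.graph.has_edge(u, v)
                assert net.graph[u][v]["score"] >= 0.700

    def test_expected_edge_count_closed_form(self):
        truth = self.make_truth()
        n = len(truth.gene_ids)
        intra_pairs = 2 * (10 * 9 // 2)
        remaining = n * (n - 1) // 2 - intra_pairs
        p_in, p_bg = 0.5, 0.05
        expected = p_in * intra_pairs + p_bg * remaining
        counts = [
            simulate_network(truth, p_in, p_bg, seed=s).n_edges for s in range(30)
        ]
        sd = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < 4 * sd

    def test_probability_ordering_enforced(self):
        with pytest.raises(ConfigError):
            simulate_network(self.make_truth(), 0.1, 0.5, seed=0)

    def test_scores_clipped_to_unit_interval(self):
        net = simulate_network(
            self.make_truth(), 1.0, 0.1, score_means=(0.99, 0.01), score_sd=0.5, seed=4
        )
        scores = [d["score"] for _, _, d in net.graph.edges(data=True)]
        assert all(0.0 <= s <= 1.0 for s in scores)


class TestSimulatePhenotypes:
    def test_down_genes_are_enriched_for_lethality_terms(self):
        cfg = small_config(
            n_genes=400, planted_down_sets=(PlantedSet("dn", 80, -2.0),), seed=11
        )
        truth = simulate_counts(cfg)[2]
        pmap = simulate_phenotypes(truth, seed=1)
        from cryodiff.simulate import LETHALITY_TERMS

        def lethal_rate(genes):
            annotated = [
                g
                for g in genes
                if any(set(t) & set(LETHALITY_TERMS) for _, t in pmap.entries.get(g, []))
            ]
            return len(annotated) / len(genes)

        assert lethal_rate(truth.genes_with_status("down")) > 2 * lethal_rate(
            truth.genes_with_status("null")
        )

    def test_ortholog_mapping_is_partial(self):
        truth = simulate_counts(small_config(n_genes=500))[2]
        pmap = simulate_phenotypes(truth, seed=2, ortholog_prob=0.5)
        assert 0 < len(pmap.entries) < 500
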