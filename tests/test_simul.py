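import numpy as np
import pytest
from scipy.integrate import quad

from opsinkit.config import SimulationConfig, PlantedEvent
from opsinkit.simul import (
    simulate_species_tree,
    speciation_time_cdf,
    simulate_gene_family_history,
    replay_ledger,
    true_gene_trees,
    evolve_codon_sequences,
    simulate_codon_pair,
    emit_genomes,
    simulate_expression,
)
from opsinkit.simul.species_tree import node_age
from opsinkit.simul.codon_evolve import evolve_branch, random_root_cds
from opsinkit.codons import cds_to_indices, indices_to_cds, AA_OF, SENSE_CODONS
from opsinkit.selection import ng86_dnds
from opsinkit.simul.expression_sim import biased_profiles


class TestSpeciesTree:
    def test_leaf_count_and_ultrametric(self):
        tree = simulate_species_tree(5, birth=1.0, death=0.0, seed=7)
        assert len(tree.leaf_nodes()) == 5
        depths = []
        for leaf in tree.leaf_node_iter():
            d, n = 0.0, leaf
            while n.parent_node is not None:
                d += n.edge.length
                n = n.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9

    def test_seed_determinism(self):
        a = simulate_species_tree(5, 1.0, 0.0, seed=7).as_string(schema="newick")
        b = simulate_species_tree(5, 1.0, 0.0, seed=7).as_string(schema="newick")
        assert a == b
        c = simulate_species_tree(5, 1.0, 0.0, seed=8).as_string(schema="newick")
        assert a != c

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_species_tree(1, 1.0, 0.0, seed=1)

    def test_root_age_matches_conditioned_birth_death_theory(self):
        # mean root age over replicates vs numerical integration of the
        # conditioned speciation-age law: E[max of n-1 iid] = ∫(1 − F^(n−1))
        lam, mu, n, reps = 1.0, 0.5, 50, 500
        ages = [node_age(simulate_species_tree(n, lam, mu, 20_000 + i).seed_node)
                for i in range(reps)]
        expected = quad(lambda t: 1.0 - speciation_time_cdf(t, lam, mu) ** (n - 1),
                        0, np.inf)[0]
        se = np.std(ages, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ages) - expected) < 3 * se


class TestGeneFamilyHistory:
    def test_no_events_means_single_copies(self):
        tree = simulate_species_tree(6, 1.0, 0.0, seed=3)
        cfg = SimulationConfig(seed=3, n_species=6)
        ledger = simulate_gene_family_history(tree, cfg)
        assert ledger.events == []
        for sp in ledger.extant:
            for fam in cfg.families:
                assert ledger.copy_number(sp, fam) == 1

    def test_retro_products_are_single_exon_elsewhere(self):
        tree = simulate_species_tree(6, 1.0, 0.0, seed=3)
        cfg = SimulationConfig(seed=3, n_species=6, rate_retro=0.4)
        ledger = simulate_gene_family_history(tree, cfg)
        retro = [e for e in ledger.events if e.kind == "duplication_retro"]
        assert ledger.events == retro  # only retro events possible
        assert retro, "expected at least one retro event at this rate"
        for e in retro:
            assert e.dest_chrom != e.source_chrom
        for sp, copies in ledger.extant.items():
            for c in copies:
                parentish = c.exon_count == cfg.n_introns + 1
                assert parentish or c.exon_count == 1

    def test_replay_matches_extant_complement(self):
        tree = simulate_species_tree(8, 1.0, 0.0, seed=5)
        cfg = SimulationConfig(seed=5, n_species=8, rate_tandem=0.1,
                               rate_retro=0.1, rate_loss=0.05,
                               rate_translocation=0.1)
        ledger = simulate_gene_family_history(tree, cfg)
        replayed = replay_ledger(ledger)
        for sp in ledger.extant:
            for fam in cfg.families:
                assert replayed[sp].get(fam, 0) == ledger.copy_number(sp, fam)

    def test_event_count_matches_poisson_expectation(self):
        # per-lineage rates: expected events = rate x total branch length
        tree = simulate_species_tree(10, 1.0, 0.0, seed=2)
        total_len = sum(e.length or 0.0 for e in tree.preorder_edge_iter()
                        if e.head_node.parent_node is not None)
        rate = 2.0 / total_len  # ~2 expected duplications
        counts = []
        for i in range(1000):
            cfg = SimulationConfig(seed=30_000 + i, n_species=10,
                                   rate_tandem=rate)
            counts.append(len(simulate_gene_family_history(tree, cfg).events))
        mean = np.mean(counts)
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(mean - 2.0) < 3 * se

    def test_planted_event_branch_and_ids(self):
        tree = simulate_species_tree(6, 1.0, 0.0, seed=3)
        cfg = SimulationConfig(seed=3, n_species=6, planted_events=[
            PlantedEvent("duplication_tandem", "n2", family="blue")])
        ledger = simulate_gene_family_history(tree, cfg)
        assert [e.kind for e in ledger.events] == ["duplication_tandem"]
        assert ledger.events[0].branch == "n2"
        gts = true_gene_trees(ledger)
        assert "blue" in gts  # family with >1 copy has a gene tree


class TestCodonEvolution:
    def test_omega_zero_gives_only_synonymous_differences(self):
        rng = np.random.default_rng(4)
        root = cds_to_indices(random_root_cds(200, rng))
        tip = evolve_branch(root, 0.3, omega=0.0, kappa=2.0, rng=rng)
        changed = np.flatnonzero(tip != root)
        assert changed.size > 0
        for i in changed:
            assert AA_OF[SENSE_CODONS[root[i]]] == AA_OF[SENSE_CODONS[tip[i]]]

    def test_zero_branch_length_is_identity(self):
        rng = np.random.default_rng(4)
        root = cds_to_indices(random_root_cds(100, rng))
        assert np.array_equal(evolve_branch(root, 0.0, 1.0, 2.0, rng), root)

    def test_no_stop_codons_ever(self):
        a, b = simulate_codon_pair(300, 1.0, 0.5, 2.0, seed=9)
        cds_to_indices(a), cds_to_indices(b)  # raises on stops

    def test_ng86_round_trip_near_truth(self):
        # spec-scale check: omega 0.2, 500 codons, mean within ±0.1
        est = [ng86_dnds(*simulate_codon_pair(500, 0.4, 0.2, 1.0, 500 + i)).omega
               for i in range(40)]
        assert abs(np.nanmean(est) - 0.2) < 0.1

    def test_invalid_root_cds_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            evolve_codon_sequences(small_dataset["ledger"],
                                   root_cds_map={"UV": "ATGTAAAAA"})

    def test_deterministic_given_seed(self, small_dataset):
        led = small_dataset["ledger"]
        s1 = evolve_codon_sequences(led)
        s2 = evolve_codon_sequences(led)
        assert s1 == s2


class TestExpressionSimulation:
    STAGES = ["larva_instar1", "adult_male_head", "adult_female_head"]

    def test_poisson_limit_mean(self):
        genes = [f"g{i}" for i in range(1000)]
        prof = biased_profiles(genes, self.STAGES, base_mean=100.0)
        counts, _, _ = simulate_expression(genes, prof, seed=1,
                                           dispersion=1e9,
                                           replicates_per_stage=1)
        m = counts.to_numpy().mean()
        se = counts.to_numpy().std(ddof=1) / np.sqrt(counts.size)
        assert abs(m - 100.0) < 3 * se

    def test_zero_mean_stage_gives_zero_counts(self):
        prof = {"g1": {"larva_instar1": 0.0, "adult_male_head": 50.0}}
        counts, _, stages = simulate_expression(["g1"], prof, seed=2)
        larva_cols = stages[stages == "larva_instar1"].index
        assert (counts.loc["g1", larva_cols] == 0).all()

    def test_deterministic(self):
        prof = biased_profiles(["a", "b"], self.STAGES, 50.0)
        c1, _, _ = simulate_expression(["a", "b"], prof, seed=3)
        c2, _, _ = simulate_expression(["a", "b"], prof, seed=3)
        assert c1.equals(c2)
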