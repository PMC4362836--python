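import numpy as np
import pytest

from karyograph.breakpoint_stats import window_recombination_rates
from karyograph.genome_io import PhyloTree
from karyograph.rearrangement import replay_scenario
from karyograph.simulate import (
    SimulationConfig,
    emit_leaf_tables,
    simulate_annotations,
    simulate_genetic_map,
    simulate_history,
)
from karyograph.synteny import call_ebrs


class TestHistory:
    def test_same_seed_reproduces_everything(self):
        t1 = simulate_history(SimulationConfig(seed=42))
        t2 = simulate_history(SimulationConfig(seed=42))
        assert t1.block_lengths == t2.block_lengths
        assert [
            (e.branch, e.event_type, sorted(e.broken_ends)) for e in t1.event_log
        ] == [(e.branch, e.event_type, sorted(e.broken_ends)) for e in t2.event_log]
        for node in t1.node_arrangements:
            assert (
                t1.node_arrangements[node].chromosomes
                == t2.node_arrangements[node].chromosomes
            )

    def test_zero_rates_freeze_the_genome(self, quiet_truth):
        root = quiet_truth.node_arrangements[quiet_truth.tree.root_label]
        assert quiet_truth.event_log == []
        for node, arr in quiet_truth.node_arrangements.items():
            assert arr.chromosomes == root.chromosomes

    def test_default_root_is_bird_like(self, default_truth):
        cfg = default_truth.config
        root = default_truth.node_arrangements[default_truth.tree.root_label]
        assert cfg.n_macro + cfg.n_micro == 40  # haploid 40
        assert len(root.chromosomes) == 40
        micro_chrom_sizes = [len(c) for c in root.chromosomes[cfg.n_macro:]]
        macro_chrom_sizes = [len(c) for c in root.chromosomes[:cfg.n_macro]]
        assert max(micro_chrom_sizes) < min(macro_chrom_sizes)
        assert min(length for length in default_truth.block_lengths.values()) >= 300_000

    def test_replay_reproduces_each_leaf(self, default_truth):
        truth = default_truth
        root = truth.node_arrangements[truth.tree.root_label]
        for leaf in truth.tree.leaves:
            replayed = replay_scenario(root, truth.lineage_events(leaf), name=leaf)
            assert (
                replayed.canonical().chromosomes
                == truth.node_arrangements[leaf].canonical().chromosomes
            )

    def test_poisson_event_counts_match_rate(self):
        tree = PhyloTree.from_newick("(A:10,B:10);")
        rates = {"inversion": 0.5, "translocation": 0.0, "fusion": 0.0, "fission": 0.0}
        counts = []
        for seed in range(150):
            truth = simulate_history(
                SimulationConfig(tree=tree, rates=rates, seed=seed)
            )
            counts.append(len(truth.events_on_branch("A")))
        mean = np.mean(counts)
        se = np.sqrt(5.0 / len(counts))
        assert abs(mean - 5.0) < 3 * se + 0.15  # small slack: rejected no-op draws

    def test_uniform_event_range_override(self):
        cfg = SimulationConfig(seed=3, events_per_branch_range=(5, 15))
        truth = simulate_history(cfg)
        for _, child, _ in truth.tree.branches():
            assert len(truth.events_on_branch(child)) <= 15

    def test_degenerate_rate_rejected(self):
        rates = {"inversion": 1e3, "translocation": 0.0, "fusion": 0.0, "fission": 0.0}
        with pytest.raises(ValueError, match="degenerate"):
            simulate_history(SimulationConfig(seed=0, rates=rates))


class TestEmittedTables:
    def test_reference_leaf_is_one_forward_block_per_chromosome(self, quiet_truth):
        tables = emit_leaf_tables(quiet_truth, "chicken")
        ref_genome = quiet_truth.node_arrangements["chicken"]
        blocks = tables["chicken"]
        assert len(blocks) == len(ref_genome.chromosomes)
        assert all(b.orientation == 1 for b in blocks)
        # identical leaves produce the same single-block-per-chromosome map
        assert len(tables["turkey"]) == len(blocks)

    def test_single_inversion_leaves_signed_block_with_flanking_ebrs(self):
        rates = {"inversion": 0.0, "translocation": 0.0, "fusion": 0.0, "fission": 0.0}
        truth = simulate_history(SimulationConfig(seed=7, rates=rates))
        # manufacture a one-inversion leaf directly from the frozen history
        chicken = [list(c) for c in truth.node_arrangements["chicken"].chromosomes]
        big = max(range(len(chicken)), key=lambda i: len(chicken[i]))
        chicken[big][2] = -chicken[big][2]
        truth.node_arrangements["turkey"] = type(
            truth.node_arrangements["turkey"]
        ).from_lists("turkey", chicken)
        tables = emit_leaf_tables(truth, "chicken")
        inverted = [b for b in tables["turkey"] if b.orientation == -1]
        assert len(inverted) == 1
        ebrs = [e for e in call_ebrs(tables) if e.species == "turkey"]
        assert len(ebrs) == 2
        assert {e.start for e in ebrs} == {
            inverted[0].ref_start, inverted[0].ref_end,
        }

    def test_unknown_reference_rejected(self, default_truth):
        with pytest.raises(KeyError):
            emit_leaf_tables(default_truth, "archaeopteryx")


class TestGeneticMap:
    def test_window_rates_recoverable_by_interpolation(self, default_truth):
        markers = simulate_genetic_map(default_truth, "chicken", seed=5)
        _, chrom_lengths = default_truth.reference_layout("chicken")
        wins = window_recombination_rates(markers, chrom_lengths)
        rated = [w for w in wins if w.rate is not None]
        assert len(rated) > 100
        assert all(w.rate >= 0 for w in rated)
        # marker spacing divides the window size, so rates are exact lognormals
        rates = np.array([w.rate for w in rated])
        assert 1.5 < np.median(rates) < 4.0

    def test_hotspot_coupling_raises_flagged_windows(self, default_truth):
        base = simulate_genetic_map(default_truth, "chicken", seed=5, hotspot_coupling=0.0)
        hot = simulate_genetic_map(default_truth, "chicken", seed=5, hotspot_coupling=5.0)
        _, chrom_lengths = default_truth.reference_layout("chicken")
        base_w = {(w.chrom, w.start): w.rate for w in window_recombination_rates(base, chrom_lengths)}
        hot_w = {(w.chrom, w.start): w.rate for w in window_recombination_rates(hot, chrom_lengths)}
        bumped = [
            k for k in base_w
            if base_w[k] and hot_w[k] and hot_w[k] > 3 * base_w[k]
        ]
        breakpoints = default_truth.breakpoint_positions("chicken")
        n_break_windows = len(
            {(c, p // 10**6 * 10**6) for c, ps in breakpoints.items() for p in ps}
        )
        assert len(bumped) >= 0.5 * n_break_windows


class TestAnnotations:
    def test_deterministic_given_seed(self, default_truth):
        a1, pair1 = simulate_annotations(default_truth, "chicken", seed=9)
        a2, pair2 = simulate_annotations(default_truth, "chicken", seed=9)
        assert pair1 == pair2
        assert [(g.gene_id, g.chrom, g.family_id, sorted(g.terms)) for g in a1] == [
            (g.gene_id, g.chrom, g.family_id, sorted(g.terms)) for g in a2
        ]

    def test_families_repeat_within_chromosomes(self, default_truth):
        annots, _ = simulate_annotations(default_truth, "chicken", seed=9)
        by_key = {}
        for g in annots:
            by_key.setdefault((g.chrom, g.family_id), []).append(g)
        assert any(len(v) > 1 for v in by_key.values())

    def test_invalid_counts_rejected(self, default_truth):
        with pytest.raises(ValueError):
            simulate_annotations(default_truth, "chicken", genes_per_chrom=0)
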