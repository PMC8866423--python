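import numpy as np
import pytest

import dendropy

from bgcphylo.bgc_similarity import build_network
from bgcphylo.records import ValidationError
from bgcphylo.synthetic_data import (
    SimParams,
    evolve_repertoires,
    simulate_inhibition,
    simulate_knockouts,
    simulate_tree,
)


class TestSimulateTree:
    def test_three_taxa_topology(self):
        tree = simulate_tree(3, 1.0, seed=0)
        internal = [n for n in tree.nodes.values() if not n.is_leaf]
        assert len(tree.leaves) == 3
        assert len(internal) == 2

    def test_seed_determinism(self):
        assert simulate_tree(8, 1.0, seed=5).to_newick() == simulate_tree(
            8, 1.0, seed=5
        ).to_newick()

    def test_positive_branch_lengths(self):
        tree = simulate_tree(12, 1.0, seed=3)
        for node in tree.nodes.values():
            if node.parent is not None:
                assert node.branch_length > 0

    def test_ultrametric_after_newick_round_trip(self):
        for seed in range(100):
            tree = simulate_tree(10, 1.0, seed=seed)
            dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
            depths = [
                leaf.distance_from_root() for leaf in dt.leaf_node_iter()
            ]
            assert max(depths) - min(depths) < 1e-9

    def test_too_few_taxa(self):
        with pytest.raises(ValidationError):
            simulate_tree(2, 1.0, seed=0)


class TestEvolveRepertoires:
    def test_frozen_evolution_identical_repertoires(self):
        params = SimParams(
            n_taxa=6, gain_rate=0, loss_rate=0, hgt_rate=0, mutation_rate=0, seed=2
        )
        tree = simulate_tree(6, 1.0, seed=2)
        sim = evolve_repertoires(tree, params)
        per_genome = sim.records_by_genome()
        contents = {
            g: tuple(r.domains for r in recs) for g, recs in per_genome.items()
        }
        assert len(set(contents.values())) == 1
        # copies of the same ancestral cluster are at distance 0 everywhere
        net = build_network(sim.records)
        for e in net.edges.itertuples(index=False):
            if sim.lineage_of[e.bgc_a] == sim.lineage_of[e.bgc_b]:
                assert abs(e.distance) < 1e-12
        # and genome-level BGC distances vanish for every metric
        from bgcphylo.gcf_clustering import assign_families_and_clans
        from bgcphylo.genome_profiles import build_abundance_matrix, genome_bgc_distance

        asn = assign_families_and_clans(net)
        mat = build_abundance_matrix(asn, sim.records)
        for metric in ("braycurtis", "jaccard"):
            assert np.allclose(genome_bgc_distance(mat, metric).values, 0.0)

    def test_heavy_loss_empties_repertoires(self):
        params = SimParams(
            n_taxa=5, gain_rate=0, loss_rate=50.0, hgt_rate=0, seed=0
        )
        tree = simulate_tree(5, 1.0, seed=0)
        sim = evolve_repertoires(tree, params)
        assert len(sim.records) == 0

    def test_mean_repertoire_size_matches_birth_death_expectation(self):
        """Per-leaf cluster count matches N0*exp(-l*T) + g/l*(1-exp(-l*T))."""
        diffs = []
        for seed in range(200):
            params = SimParams(
                n_taxa=4, gain_rate=1.2, loss_rate=0.4, hgt_rate=0,
                mutation_rate=0.0, seed=seed,
            )
            tree = simulate_tree(4, 1.0, seed=seed)
            sim = evolve_repertoires(tree, params)
            T = tree.height
            expected = params.root_n_clusters * np.exp(
                -params.loss_rate * T
            ) + params.gain_rate / params.loss_rate * (1 - np.exp(-params.loss_rate * T))
            diffs.append(np.mean(list(sim.bgc_counts().values())) - expected)
        d = np.asarray(diffs)
        assert abs(d.mean()) < 4 * d.std() / np.sqrt(len(d))

    def test_event_log_conservation(self):
        """Per leaf: root clusters - losses + gains + transfers on the
        root-to-leaf path equals the emitted repertoire size."""
        for seed in range(5):
            params = SimParams(n_taxa=8, hgt_rate=0.1, seed=seed)
            tree = simulate_tree(8, 1.0, seed=seed)
            sim = evolve_repertoires(tree, params)
            counts = sim.bgc_counts()
            ev = sim.events
            for leaf in tree.leaf_labels:
                path = set(tree.path_to_root(leaf))
                on_path = ev[ev["branch"].isin(path)]
                n = (
                    params.root_n_clusters
                    - (on_path["event"] == "loss").sum()
                    + (on_path["event"] == "gain").sum()
                    + (on_path["event"] == "transfer").sum()
                )
                assert n == counts[leaf]

    def test_determinism(self):
        params = SimParams(n_taxa=6, hgt_rate=0.1, seed=9)
        tree1 = simulate_tree(6, 1.0, seed=9)
        tree2 = simulate_tree(6, 1.0, seed=9)
        s1 = evolve_repertoires(tree1, params)
        s2 = evolve_repertoires(tree2, params)
        assert [r.domains for r in s1.records] == [r.domains for r in s2.records]
        assert s1.potencies == s2.potencies


def small_inhibition_setup(seed=4):
    params = SimParams(n_taxa=6, seed=seed)
    tree = simulate_tree(6, 1.0, seed=seed)
    sim = evolve_repertoires(tree, params)
    return sim


class TestSimulateInhibition:
    def test_self_pairs_expected_zero(self):
        sim = small_inhibition_setup()
        table = simulate_inhibition(
            sim.records, sim.lineage_of, sim.potencies, noise_sd=0.0, seed=0
        )
        means = table.mean_zones()
        self_rows = means[means["antagonist"] == means["target"]]
        assert (self_rows["zone_mm"] == 0.0).all()

    def test_superset_target_immune_with_noise(self):
        """A target carrying every antagonist lineage sees only noise."""
        sim = small_inhibition_setup()
        noise = 0.5
        table = simulate_inhibition(
            sim.records, sim.lineage_of, sim.potencies, noise_sd=noise, seed=11
        )
        data = table.data
        self_rows = data[data["antagonist"] == data["target"]]
        assert (self_rows["zone_mm"] <= 3.5 * noise).all()

    def test_noiseless_additivity(self):
        from bgcphylo.records import BGCRecord

        recs = [
            BGCRecord("a1", "A", "A", "NRPS", (("X", "AAAA"),)),
            BGCRecord("a2", "A", "A", "NRPS", (("Y", "CCCC"),)),
            BGCRecord("t1", "T", "T", "NRPS", (("Z", "GGGG"),)),
        ]
        lineage = {"a1": "L1", "a2": "L2", "t1": "L3"}
        pot = {"L1": 4.0, "L2": 6.0, "L3": 2.0}
        table = simulate_inhibition(recs, lineage, pot, noise_sd=0.0, n_replicates=2, seed=0)
        means = table.mean_zones()
        zone = means[(means["antagonist"] == "A") & (means["target"] == "T")]["zone_mm"]
        assert float(zone.iloc[0]) == pytest.approx(10.0, abs=1e-12)

    def test_replicate_mean_clt(self):
        """Mean of 100 replicates is within 2*noise_sd/sqrt(100) of the
        expected zone (expected zone large enough that truncation is idle)."""
        from bgcphylo.records import BGCRecord

        recs = [
            BGCRecord("a1", "A", "A", "NRPS", (("X", "AAAA"),)),
            BGCRecord("t1", "T", "T", "NRPS", (("Z", "GGGG"),)),
        ]
        lineage = {"a1": "L1", "t1": "L2"}
        pot = {"L1": 20.0, "L2": 1.0}
        noise = 2.0
        table = simulate_inhibition(
            recs, lineage, pot, noise_sd=noise, n_replicates=100, seed=21
        )
        data = table.data
        vals = data[(data["antagonist"] == "A") & (data["target"] == "T")]["zone_mm"]
        assert abs(vals.mean() - 20.0) <= 2 * noise / 10

    def test_unmapped_cluster_rejected(self):
        sim = small_inhibition_setup()
        bad = dict(sim.lineage_of)
        bad.pop(sim.records[0].bgc_id)
        with pytest.raises(ValidationError):
            simulate_inhibition(sim.records, bad, sim.potencies)


class TestSimulateKnockouts:
    def _noiseless(self, seed=4):
        sim = small_inhibition_setup(seed)
        counts = sim.bgc_counts()
        antagonist = max(sorted(counts), key=lambda g: counts[g])
        targets = [g for g in sorted(counts) if g != antagonist]
        table, mm = simulate_knockouts(
            antagonist, sim.records, sim.lineage_of, sim.potencies, targets,
            noise_sd=0.0, n_replicates=2, seed=1,
        )
        return sim, antagonist, targets, table, mm

    def test_all_null_mutant_loses_all_antagonism(self):
        sim, antagonist, targets, table, mm = self._noiseless()
        null_name = [n for n, k in mm.items() if k == "__all__"][0]
        rows = table.data[table.data["antagonist"] == null_name]
        assert (rows["zone_mm"] == 0.0).all()

    def test_shared_lineage_knockout_neutral(self):
        sim, antagonist, targets, table, mm = self._noiseless()
        means = table.mean_zones()
        sets = {}
        for r in sim.records:
            sets.setdefault(r.genome_id, set()).add(sim.lineage_of[r.bgc_id])
        wt = means[means["antagonist"] == antagonist].set_index("target")["zone_mm"]
        for name, knocked in mm.items():
            if knocked in (None, "__all__"):
                continue
            mut = means[means["antagonist"] == name].set_index("target")["zone_mm"]
            for t in targets:
                if knocked in sets[t]:  # target carries it: no contribution
                    assert mut[t] == pytest.approx(wt[t], abs=1e-12)
                else:
                    assert wt[t] - mut[t] == pytest.approx(
                        sim.potencies[knocked], abs=1e-9
                    )

    def test_unknown_antagonist_rejected(self):
        sim = small_inhibition_setup()
        with pytest.raises(KeyError):
            simulate_knockouts(
                "NOPE", sim.records, sim.lineage_of, sim.potencies, ["G001"]
            )


def test_invalid_params_rejected():
    with pytest.raises(ValidationError):
        SimParams(n_taxa=2)
    with pytest.raises(ValidationError):
        SimParams(loss_rate=-0.1)
    with pytest.raises(ValidationError):
        SimParams(domain_len=2)
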