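"""Community detection, the relative-damage percentile and clustering."""

from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ppiload.interactome import Interactome
from ppiload.modules import (
    ModulePartition,
    RelativeDamageMatrix,
    centrality_damage_correlation,
    cluster_profiles,
    damage_matrix,
    detect_modules,
    midrank_percentile,
    module_graph,
    observed_module_proportions,
    relative_damage,
    relative_damage_cohort,
)
from ppiload.variants import AffectionState, IndividualProfile


def clique(prefix, size):
    nodes = [f"{prefix}{i}" for i in range(size)]
    return [(a, b) for a, b in combinations(nodes, 2)], nodes


def profile(sample, affected, population="POP"):
    return IndividualProfile(
        sample, population, {p: AffectionState.HET_AFFECTED for p in affected}
    )


class TestDetectModules:
    def test_two_cliques_one_bridge(self):
        e1, n1 = clique("a", 6)
        e2, n2 = clique("b", 6)
        g = Interactome.from_edges(e1 + e2 + [("a0", "b0")])
        for algorithm in ("walktrap", "infomap"):
            part = detect_modules(g, algorithm, seed=1)
            assert len(part.modules) == 2
            assert {frozenset(n1), frozenset(n2)} == set(part.modules.values())

    def test_small_component_discarded(self):
        e1, n1 = clique("a", 6)
        e2, n2 = clique("x", 4)  # lone 4-clique component: below min_size
        g = Interactome.from_edges(e1 + e2)
        part = detect_modules(g, "walktrap", min_size=5)
        assert set(part.modules.values()) == {frozenset(n1)}
        assert part.unassigned == frozenset(n2)
        assert part.universe == frozenset(n1) | frozenset(n2)

    def test_single_clique_single_module(self):
        e, n = clique("c", 8)
        part = detect_modules(Interactome.from_edges(e), "walktrap")
        assert list(part.modules.values()) == [frozenset(n)]

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError):
            detect_modules(Interactome.from_edges(clique("a", 6)[0]), "louvain")

    def test_brute_force_modularity_agrees_on_toy(self):
        """On the 12-node two-clique toy the detected split maximizes
        Newman modularity over all 2-part splits (exhaustive check)."""
        e1, n1 = clique("a", 6)
        e2, n2 = clique("b", 6)
        g = Interactome.from_edges(e1 + e2 + [("a0", "b0")])
        nodes = sorted(g.nodes)
        best, best_q = None, -1
        for r in range(1, len(nodes) // 2 + 1):
            for left in combinations(nodes, r):
                partition = [set(left), set(nodes) - set(left)]
                q = nx.community.modularity(g.graph, partition)
                if q > best_q:
                    best_q, best = q, partition
        part = detect_modules(g, "walktrap")
        assert set(frozenset(s) for s in best) == set(part.modules.values())


class TestModuleGraph:
    def test_spanning_edge_connects_modules(self):
        e1, n1 = clique("a", 5)
        e2, n2 = clique("b", 5)
        g = Interactome.from_edges(e1 + e2 + [("a0", "b0")])
        part = detect_modules(g, "walktrap")
        mg = module_graph(g, part)
        assert mg.graph.number_of_edges() == 1

    def test_no_spanning_edges_isolated(self):
        e1, _ = clique("a", 5)
        e2, _ = clique("b", 5)
        g = Interactome.from_edges(e1 + e2)
        mg = module_graph(g, detect_modules(g, "walktrap"))
        assert mg.graph.number_of_edges() == 0
        assert (mg.closeness == 0).all()

    def test_module_chain_closeness_ranks_middle_highest(self):
        # 4 modules in a chain: middle two most central in the module graph
        edges = []
        for i in range(4):
            e, _ = clique(f"m{i}_", 5)
            edges += e
        edges += [("m0_0", "m1_0"), ("m1_1", "m2_1"), ("m2_0", "m3_0")]
        g = Interactome.from_edges(edges)
        part = detect_modules(g, "walktrap")
        mg = module_graph(g, part)
        ends = {part.module_of["m0_0"], part.module_of["m3_0"]}
        middles = {part.module_of["m1_0"], part.module_of["m2_0"]}
        assert min(mg.closeness[mid] for mid in middles) > max(mg.closeness[e] for e in ends)


def toy_partition():
    """6 proteins, two modules of 3."""
    return ModulePartition(
        modules={1: frozenset({"a", "b", "c"}), 2: frozenset({"d", "e", "f"})},
        algorithm="walktrap",
        min_size=3,
        universe=frozenset("abcdef"),
    )


class TestRelativeDamage:
    def test_exhaustive_enumeration_toy(self):
        """Monte-Carlo percentile converges to the exact value enumerated
        over all C(6,2)=15 placements of 2 affected proteins."""
        part = toy_partition()
        affected = {"a", "b"}  # both in module 1: observed proportions (2/3, 0)
        obs = observed_module_proportions(part, affected)
        exact = {}
        for mid in part.modules:
            null = []
            for placed in combinations(sorted(part.universe), 2):
                null.append(len(set(placed) & part.modules[mid]) / 3)
            null = np.array(null)
            exact[mid] = (np.sum(null < obs[mid]) + 0.5 * np.sum(null == obs[mid])) / 15
        # the formula applied to the exhaustive null is exact...
        for mid in part.modules:
            null = np.array([
                len(set(placed) & part.modules[mid]) / 3
                for placed in combinations(sorted(part.universe), 2)
            ])
            assert midrank_percentile(obs[mid], null) == pytest.approx(exact[mid])
        # ...and the sampled permutation version converges to it
        damages = relative_damage(part, profile("s1", affected), n_perm=4000, seed=9)
        for mid in part.modules:
            se = np.sqrt(exact[mid] * (1 - exact[mid]) / 4000)
            assert abs(damages[mid] - exact[mid]) <= 4 * se + 1e-9

    def test_values_in_unit_interval_and_extreme_case(self):
        part = toy_partition()
        damages = relative_damage(part, profile("s1", {"a", "b", "c"}), n_perm=500, seed=1)
        assert all(0.0 <= v <= 1.0 for v in damages.values())
        # all three affected in module 1 (observed proportion 1): only the
        # 1-in-20 placement {a,b,c} ties, everything else falls below, so the
        # mid-rank percentile sits within a few tie half-counts of 1
        assert 1 - 3 * (0.5 / 20) <= damages[1] <= 1.0
        # an observation strictly above every null value maps to exactly 1
        assert midrank_percentile(1.1, np.linspace(0, 1, 500)) == 1.0

    def test_empty_affected_set_gives_null_median(self):
        damages = relative_damage(toy_partition(), profile("s1", set()), n_perm=100, seed=0)
        assert set(damages.values()) == {0.5}

    def test_null_median_observation_maps_to_half(self):
        # even-length tie-free null symmetric around the observation
        null = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        assert midrank_percentile(0.5, null) == 0.5

    def test_unbiased_placement_mean_half(self):
        """Pooled over modules and replicates, uniform placement gives mean
        relative damage 0.5 within 3 SE."""
        rng = np.random.default_rng(12)
        part = toy_partition()
        values = []
        for i in range(300):
            affected = set(rng.choice(sorted(part.universe), size=2, replace=False))
            damages = relative_damage(part, profile(f"s{i}", affected), n_perm=200, seed=i)
            values.extend(damages.values())
        values = np.array(values)
        se = values.std(ddof=1) / np.sqrt(len(values))
        assert abs(values.mean() - 0.5) <= 3 * se

    def test_conservation_of_affected_counts(self):
        part = toy_partition()
        affected = {"a", "d", "e"}
        props = observed_module_proportions(part, affected)
        total = sum(props[mid] * len(part.modules[mid]) for mid in part.modules)
        assert total == len(affected & (part.modules[1] | part.modules[2]))

    def test_deterministic_under_seed(self):
        part = toy_partition()
        p = profile("s1", {"a", "d"})
        assert relative_damage(part, p, n_perm=300, seed=5) == relative_damage(
            part, p, n_perm=300, seed=5
        )


class TestDamageMatrix:
    def test_single_individual_identity(self):
        m = damage_matrix({"s1": {1: 0.2, 2: 0.9}}, {"s1": "POP"})
        assert m.values.loc[1, "POP"] == 0.2
        assert m.values.loc[2, "POP"] == 0.9

    def test_population_mean(self):
        m = damage_matrix(
            {"s1": {1: 0.2}, "s2": {1: 0.8}}, {"s1": "POP", "s2": "POP"}
        )
        assert m.values.loc[1, "POP"] == pytest.approx(0.5)

    def test_unknown_sample_raises(self):
        with pytest.raises(KeyError):
            damage_matrix({"ghost": {1: 0.5}}, {"s1": "POP"})


class TestCentralityDamageCorrelation:
    def test_perfect_monotone_signs(self):
        mg_graph = nx.path_graph(5)
        closeness = pd.Series(nx.closeness_centrality(mg_graph, wf_improved=True))
        from ppiload.modules import ModuleGraph

        mg = ModuleGraph(graph=mg_graph, closeness=closeness)
        decreasing = pd.Series(
            1 - closeness.rank(method="first") / 10, index=closeness.index
        )
        res = centrality_damage_correlation(mg, decreasing)
        assert res.rho < -0.9
        res_up = centrality_damage_correlation(mg, -decreasing)
        assert res_up.rho > 0.9


class TestClusterProfiles:
    def _matrix(self, columns):
        return RelativeDamageMatrix(pd.DataFrame(columns), n_perm=100, zygosity_mode="any_allele")

    def test_identical_columns_merge_at_zero(self):
        m = self._matrix({"A": [0.1, 0.5, 0.9], "B": [0.1, 0.5, 0.9], "C": [0.9, 0.1, 0.2]})
        res = cluster_profiles(m, axis="populations")
        assert res.linkage_matrix[0, 2] == 0.0
        merged = {res.labels[int(res.linkage_matrix[0, 0])], res.labels[int(res.linkage_matrix[0, 1])]}
        assert merged == {"A", "B"}

    def test_close_pair_merges_first(self):
        m = self._matrix({"A": [0.0, 0.0], "B": [1.0, 0.0], "C": [10.0, 0.0]})
        res = cluster_profiles(m, axis="populations")
        first = {res.labels[int(res.linkage_matrix[0, 0])], res.labels[int(res.linkage_matrix[0, 1])]}
        assert first == {"A", "B"}

    def test_inverted_population_is_last_singleton(self):
        rng = np.random.default_rng(4)
        base = rng.uniform(0.2, 0.8, size=12)
        cols = {f"N{i}": base + rng.normal(0, 0.02, 12) for i in range(4)}
        cols["ODD"] = 1 - base  # inverted damage profile
        res = cluster_profiles(self._matrix(cols), axis="populations")
        # the outlier joins only at the final merge
        final = res.linkage_matrix[-1]
        odd = res.labels.index("ODD")
        assert odd in (int(final[0]), int(final[1]))

    def test_newick_is_parseable_and_complete(self):
        m = self._matrix({"A": [0.1, 0.2], "B": [0.3, 0.1], "C": [0.9, 0.8]})
        res = cluster_profiles(m, axis="populations")
        import io

        from Bio import Phylo

        tree = Phylo.read(io.StringIO(res.newick), "newick")
        assert {t.name for t in tree.get_terminals()} == {"A", "B", "C"}

    def test_modules_axis_and_errors(self):
        m = self._matrix({"A": [0.1, 0.9], "B": [0.2, 0.8]})
        res = cluster_profiles(m, axis="modules")
        assert len(res.labels) == 2
        with pytest.raises(ValueError):
            cluster_profiles(m, axis="rows")


class TestAlgorithmRobustness:
    def test_walktrap_and_infomap_agree_on_planted_bias_sign(self, tmp_path):
        """Both community algorithms recover the same correlation sign on a
        peripheral-biased synthetic cohort."""
        from ppiload.synth import SynthSpec, generate_interactome, generate_population, truth_profiles

        spec = SynthSpec(n_proteins=500, n_modules=10, n_individuals=15,
                         placement_bias=-0.8, seed=37)
        g, _ = generate_interactome(spec)
        data = generate_population(g, spec, tmp_path)
        profiles = truth_profiles(data)
        rhos = {}
        for algorithm in ("walktrap", "infomap"):
            part = detect_modules(g, algorithm, seed=3)
            mg = module_graph(g, part)
            per_ind = relative_damage_cohort(part, profiles, n_perm=200, seed=11)
            mat = damage_matrix(per_ind, data.manifest)
            rhos[algorithm] = centrality_damage_correlation(mg, mat.values.iloc[:, 0]).rho
        assert rhos["walktrap"] < 0 and rhos["infomap"] < 0
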