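"""Community structure and the module-level relative-damage statistic.

The interactome is partitioned into modules with the random-walk community
algorithms Walktrap (walk length 4) or Infomap (two-level); communities with
fewer than five proteins are discarded and their proteins left unassigned.
For each individual, the observed proportion of affected proteins per module
is ranked against an empirical null in which the same number of affected
proteins is placed uniformly over all interactome nodes; the mid-rank
percentile of the observed proportion is the module's *relative damage*,
in [0, 1] with 0.5 at the null median.  Population profiles are the mean of
per-individual values, compared across populations by hierarchical
clustering on Euclidean distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from ppiload.interactome import Interactome
from ppiload.metrics import CorrelationResult
from ppiload.variants import IndividualProfile

log = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """Disjoint protein modules over an interactome.

    ``universe`` is the full node set of the graph the partition was made on
    (assigned or not); unassigned proteins still take part in permutation
    placement but belong to no scored module.
    """

    modules: dict[int, frozenset[str]]
    algorithm: str
    min_size: int
    universe: frozenset[str]
    unassigned: frozenset[str] = frozenset()

    @property
    def module_of(self) -> dict[str, int]:
        return {p: mid for mid, members in self.modules.items() for p in members}

    def sizes(self) -> pd.Series:
        return pd.Series({mid: len(m) for mid, m in self.modules.items()}, name="size")


@dataclass
class ModuleGraph:
    """Module-level graph: modules are nodes, an edge joins two modules when
    at least one interactome edge spans them.  ``closeness`` is the
    (component-scaled) closeness of each module in this graph."""

    graph: nx.Graph
    closeness: pd.Series


@dataclass
class RelativeDamageMatrix:
    """Modules x populations matrix of relative-damage percentiles."""

    values: pd.DataFrame
    n_perm: int
    zygosity_mode: str


def _to_igraph(g: Interactome) -> tuple[ig.Graph, list[str]]:
    nodes = sorted(g.graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in g.graph.edges]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def detect_modules(
    g: Interactome,
    algorithm: str = "walktrap",
    min_size: int = 5,
    seed: int = 0,
    walktrap_steps: int = 4,
) -> ModulePartition:
    """Partition the interactome into modules.

    Walktrap (deterministic, walk length ``walktrap_steps``) or Infomap
    (stochastic two-level; seeded).  Communities smaller than ``min_size``
    are discarded; their proteins are reported as unassigned.
    """
    if algorithm not in ("walktrap", "infomap"):
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    graph, nodes = _to_igraph(g)
    if algorithm == "walktrap":
        clustering = graph.community_walktrap(steps=walktrap_steps).as_clustering()
    else:
        import random as _random

        state = _random.Random(seed)
        ig.set_random_number_generator(state)
        try:
            clustering = graph.community_infomap()
        finally:
            ig.set_random_number_generator(_random)
    modules: dict[int, frozenset[str]] = {}
    unassigned: set[str] = set()
    next_id = 1
    for members_idx in sorted(clustering, key=len, reverse=True):
        members = frozenset(nodes[i] for i in members_idx)
        if len(members) >= min_size:
            modules[next_id] = members
            next_id += 1
        else:
            unassigned.update(members)
    if not modules:
        log.warning("no community reached min_size=%d", min_size)
    return ModulePartition(
        modules=modules,
        algorithm=algorithm,
        min_size=min_size,
        universe=frozenset(g.graph.nodes),
        unassigned=frozenset(unassigned),
    )


def module_graph(g: Interactome, part: ModulePartition) -> ModuleGraph:
    """Collapse the interactome onto its modules."""
    module_of = part.module_of
    mg = nx.Graph()
    mg.add_nodes_from(part.modules)
    for a, b in g.graph.edges:
        ma, mb = module_of.get(a), module_of.get(b)
        if ma is not None and mb is not None and ma != mb:
            mg.add_edge(ma, mb)
    closeness = pd.Series(nx.closeness_centrality(mg, wf_improved=True), name="closeness")
    return ModuleGraph(graph=mg, closeness=closeness.sort_index())


def midrank_percentile(observed: float, null_values: np.ndarray) -> float:
    """Empirical mid-rank percentile of ``observed`` within ``null_values``:
    ``(#null < obs + 0.5 * #null == obs) / len(null)``, in [0, 1].  An
    observation at the median of a tie-free even-length null maps to 0.5."""
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empty null sample")
    below = np.count_nonzero(null_values < observed)
    equal = np.count_nonzero(null_values == observed)
    return (below + 0.5 * equal) / null_values.size


def observed_module_proportions(part: ModulePartition, affected: set[str]) -> pd.Series:
    """Proportion of each module's proteins present in ``affected``."""
    return pd.Series(
        {mid: len(members & affected) / len(members) for mid, members in part.modules.items()}
    ).sort_index()


def relative_damage(
    part: ModulePartition,
    profile: IndividualProfile,
    n_perm: int = 1000,
    seed: int = 0,
    zygosity_mode: str = "any_allele",
) -> dict[int, float]:
    """Relative damage of every module for one individual.

    The observed statistic per module is the proportion of its proteins in
    the individual's affected set (any-allele by default).  The null places
    the same number of affected proteins uniformly over *all* interactome
    nodes (assigned or not), ``n_perm`` times, and the returned value is the
    mid-rank percentile of the observation.  An individual with no affected
    proteins gets 0.5 everywhere (flagged by a log message).
    """
    module_ids = sorted(part.modules)
    affected = profile.affected_proteins(zygosity_mode) & part.universe
    k = len(affected)
    if k == 0:
        log.info("sample %s has no affected proteins; relative damage set to 0.5", profile.sample)
        return {mid: 0.5 for mid in module_ids}
    nodes = np.array(sorted(part.universe))
    module_of = part.module_of
    # module index per node; -1 = unassigned
    mod_index = {mid: j for j, mid in enumerate(module_ids)}
    node_mod = np.array([mod_index.get(module_of.get(p, -1), -1) for p in nodes])
    sizes = np.array([len(part.modules[mid]) for mid in module_ids], dtype=float)

    affected_mask = np.isin(nodes, list(affected))
    obs_counts = np.bincount(node_mod[affected_mask & (node_mod >= 0)], minlength=len(module_ids))
    obs_prop = obs_counts / sizes

    rng = np.random.default_rng(seed)
    n = len(nodes)
    null_counts = np.empty((n_perm, len(module_ids)), dtype=np.int64)
    for i in range(n_perm):
        placed = rng.choice(n, size=k, replace=False)
        mods = node_mod[placed]
        null_counts[i] = np.bincount(mods[mods >= 0], minlength=len(module_ids))
    null_prop = null_counts / sizes
    out = {}
    for j, mid in enumerate(module_ids):
        out[mid] = midrank_percentile(obs_prop[j], null_prop[:, j])
    return out


def relative_damage_cohort(
    part: ModulePartition,
    profiles: Sequence[IndividualProfile],
    n_perm: int = 1000,
    seed: int = 0,
    zygosity_mode: str = "any_allele",
) -> dict[str, dict[int, float]]:
    """Per-individual relative damage for a cohort; each individual gets an
    independent permutation stream derived from ``seed``."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(profiles))
    return {
        p.sample: relative_damage(part, p, n_perm=n_perm, seed=int(s), zygosity_mode=zygosity_mode)
        for p, s in zip(profiles, child_seeds)
    }


def damage_matrix(
    per_individual: Mapping[str, Mapping[int, float]],
    manifest: Mapping[str, str],
    n_perm: int = 0,
    zygosity_mode: str = "any_allele",
) -> RelativeDamageMatrix:
    """Aggregate per-individual relative damages into a modules x populations
    matrix; a population's value is the arithmetic mean over its individuals."""
    rows = []
    for sample, damages in per_individual.items():
        if sample not in manifest:
            raise KeyError(f"sample {sample!r} absent from manifest")
        for mid, value in damages.items():
            rows.append((mid, manifest[sample], value))
    df = pd.DataFrame(rows, columns=["module", "population", "value"])
    if df.empty:
        raise ValueError("no per-individual damages supplied")
    mat = df.pivot_table(index="module", columns="population", values="value", aggfunc="mean")
    return RelativeDamageMatrix(values=mat, n_perm=n_perm, zygosity_mode=zygosity_mode)


def centrality_damage_correlation(mg: ModuleGraph, col: pd.Series) -> CorrelationResult:
    """Spearman correlation between module closeness and one population's
    relative-damage column."""
    common = mg.closeness.index.intersection(col.index)
    if len(common) < 3:
        raise ValueError("need >=3 modules")
    x = mg.closeness.loc[common].to_numpy(dtype=float)
    y = col.loc[common].to_numpy(dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(float("nan"), float("nan"), len(common))
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), len(common))


@dataclass
class ClusterResult:
    labels: list
    linkage_matrix: np.ndarray
    newick: str
    cophenetic: np.ndarray  # condensed distances


def _tree_to_newick(node: hierarchy.ClusterNode, labels: Sequence) -> str:
    if node.is_leaf():
        return str(labels[node.id])
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:g},{right}:{dr:g})"


def cluster_profiles(
    m: RelativeDamageMatrix,
    axis: str = "populations",
    linkage: str = "complete",
) -> ClusterResult:
    """Agglomerative clustering of populations (columns) or modules (rows)
    on Euclidean distances between their damage profiles."""
    if axis == "populations":
        data = m.values.T
    elif axis == "modules":
        data = m.values
    else:
        raise ValueError(f"unknown axis: {axis!r}")
    if len(data) < 2:
        raise ValueError("need >=2 items to cluster")
    if linkage not in ("complete", "average"):
        raise ValueError(f"unknown linkage: {linkage!r}")
    X = data.to_numpy(dtype=float)
    Z = hierarchy.linkage(X, method=linkage, metric="euclidean")
    tree = hierarchy.to_tree(Z)
    labels = list(data.index)
    newick = _tree_to_newick(tree, labels) + ";"
    coph = hierarchy.cophenet(Z)
    return ClusterResult(labels=labels, linkage_matrix=Z, newick=newick, cophenetic=coph)
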