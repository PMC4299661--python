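"""Node-level centralities, whole-graph integrity metrics and rank statistics.

Centralities come from exact all-pairs shortest paths (networkx); the
integrity metrics of node-depleted graphs are computed on a sparse adjacency
matrix with BFS-based shortest paths (scipy.sparse.csgraph) so that
thousands of removal draws stay cheap.  Closeness uses the Wasserman–Faust
component-size correction, making values comparable across components of a
disconnected graph; betweenness is unnormalized (all downstream use is
rank-based).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components, shortest_path

from ppiload.interactome import Interactome
from ppiload.variants import IndividualProfile, ProteinFrequencyTable


def centralities(g: Interactome) -> pd.DataFrame:
    """Degree, betweenness and closeness per protein.

    Betweenness is the unnormalized shortest-path count; closeness is
    Wasserman–Faust component-scaled, i.e. within a component of size k,
    ``(k-1)/(n-1) * (k-1)/sum(d)``; isolated nodes get 0.
    """
    if g.n_nodes == 0:
        raise ValueError("centralities requires a non-empty graph")
    graph = g.graph
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness = nx.closeness_centrality(graph, wf_improved=True)
    df = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
        }
    )
    df.index.name = "protein"
    return df.sort_index()


@dataclass(frozen=True)
class NetworkStateMetrics:
    """Integrity metrics of an (optionally node-depleted) graph.

    ``avg_shortest_path`` averages over connected node pairs only;
    ``diameter`` is the largest shortest path over all components.  An empty
    remaining graph is flagged and all-zero.
    """

    n_edges: int
    n_components: int
    giant_size: int
    avg_shortest_path: float
    diameter: int
    empty: bool = False

    def as_dict(self) -> dict:
        return {
            "n_edges": self.n_edges,
            "n_components": self.n_components,
            "giant_size": self.giant_size,
            "avg_shortest_path": self.avg_shortest_path,
            "diameter": self.diameter,
        }


class GraphState:
    """Cached sparse adjacency for repeated node-removal metric evaluation."""

    def __init__(self, g: Interactome):
        self.nodes: list[str] = sorted(g.graph.nodes)
        self.index: dict[str, int] = {n: i for i, n in enumerate(self.nodes)}
        self.adjacency = nx.to_scipy_sparse_array(g.graph, nodelist=self.nodes, format="csr")

    def metrics(self, removed: Iterable[str] = (), paths: bool = True) -> NetworkStateMetrics:
        """Integrity metrics of the induced subgraph on the surviving nodes.

        ``removed`` entries outside the graph are ignored.  ``paths=False``
        skips the all-pairs shortest-path metrics (reported as NaN/0), which
        makes large permutation ensembles much cheaper when only edge and
        component counts are needed.
        """
        removed_idx = {self.index[r] for r in removed if r in self.index}
        keep = np.array([i for i in range(len(self.nodes)) if i not in removed_idx])
        if keep.size == 0:
            return NetworkStateMetrics(0, 0, 0, 0.0, 0, empty=True)
        sub = self.adjacency[keep][:, keep]
        n_edges = int(sub.nnz // 2)
        n_comp, labels = connected_components(sub, directed=False)
        sizes = np.bincount(labels)
        giant = int(sizes.max())
        if not paths:
            return NetworkStateMetrics(n_edges, int(n_comp), giant, float("nan"), 0)
        dist = shortest_path(sub, method="D", directed=False, unweighted=True)
        finite = np.isfinite(dist) & (dist > 0)
        n_pairs = int(finite.sum())  # ordered pairs; symmetric, ratio unchanged
        avg = float(dist[finite].sum() / n_pairs) if n_pairs else 0.0
        diameter = int(dist[finite].max()) if n_pairs else 0
        return NetworkStateMetrics(n_edges, int(n_comp), giant, avg, diameter)


def state_metrics(g: Interactome, removed: Iterable[str] = (), paths: bool = True) -> NetworkStateMetrics:
    """One-shot integrity metrics; see :meth:`GraphState.metrics`."""
    return GraphState(g).metrics(removed, paths=paths)


@dataclass(frozen=True)
class GroupComparisonResult:
    group_a: str
    group_b: str
    statistic: float  # Mann-Whitney U for group_a
    p_raw: float
    p_fdr: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def _mannwhitney(a: Sequence[float], b: Sequence[float], exact_max_n: int = 25) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; exact null below ``exact_max_n`` per group
    (ties permitting), normal approximation with tie correction otherwise."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (len(a) <= exact_max_n and len(b) <= exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    values: Mapping[str, Sequence[float]],
    tests: Sequence[tuple[str, str]],
) -> list[GroupComparisonResult]:
    """Pairwise two-sided Mann-Whitney U tests with Benjamini-Hochberg FDR
    correction across the requested pairs."""
    for name, v in values.items():
        if len(v) < 2:
            raise ValueError(f"group {name!r} needs >=2 values")
    raw = []
    for a, b in tests:
        u, p = _mannwhitney(values[a], values[b])
        raw.append((a, b, u, p))
    p_adj = stats.false_discovery_control([p for *_, p in raw], method="bh")
    return [
        GroupComparisonResult(a, b, u, p, float(q))
        for (a, b, u, p), q in zip(raw, p_adj)
    ]


def centrality_frequency_correlation(
    cent: pd.DataFrame,
    freq: ProteinFrequencyTable,
    mode: str = "het_or_hom",
    metrics: Sequence[str] = ("degree", "betweenness", "closeness"),
) -> dict[str, CorrelationResult]:
    """Spearman correlation of each centrality with the per-protein frequency
    of deleterious variation, over proteins observed affected at least once.

    ``mode``: ``hom`` uses both-alleles counts, ``het_or_hom`` any-allele
    counts, ``somatic_recurrence`` is an alias of ``het_or_hom`` (recurrence
    across patients).
    """
    col = {"hom": "n_hom", "het_or_hom": "n_het_or_hom", "somatic_recurrence": "n_het_or_hom"}[mode]
    f = freq.counts[col]
    f = f[f >= 1]
    common = cent.index.intersection(f.index)
    if len(common) < 3:
        raise ValueError("need >=3 proteins with defined frequency and centrality")
    out = {}
    for metric in metrics:
        x = cent.loc[common, metric].to_numpy(dtype=float)
        y = f.loc[common].to_numpy(dtype=float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            out[metric] = CorrelationResult(float("nan"), float("nan"), len(common))
            continue
        rho, p = stats.spearmanr(x, y)
        out[metric] = CorrelationResult(float(rho), float(p), len(common))
    return out


@dataclass
class QuartileDamageResult:
    """Per-closeness-quartile distribution of each individual's affected
    proteins, with a matched-null Mann-Whitney test per quartile.

    ``proportions``: individuals x 4 (Q1 = most peripheral quartile).
    ``null_proportions``: same shape, one uniform re-placement of each
    individual's affected count.  ``tests[q]`` compares the two samples.
    """

    proportions: pd.DataFrame
    null_proportions: pd.DataFrame
    tests: dict[str, GroupComparisonResult]


def quartile_damage_distribution(
    cent: pd.DataFrame,
    profiles: Sequence[IndividualProfile],
    zygosity_mode: str = "any_allele",
    seed: int = 0,
) -> QuartileDamageResult:
    """Bin proteins by closeness quartile and locate each individual's
    affected proteins among the bins.

    The uniform expectation is materialized as a matched null cohort (each
    individual's affected count re-placed uniformly over all proteins, one
    draw per individual) and each quartile's observed proportions are
    compared to the null proportions by two-sided Mann-Whitney with BH
    correction across the four bins.
    """
    if len(cent) < 4:
        raise ValueError("need >=4 proteins to form quartiles")
    closeness = cent["closeness"]
    quart = pd.qcut(closeness.rank(method="first"), 4, labels=["Q1", "Q2", "Q3", "Q4"])
    proteins = np.array(closeness.index)
    bin_of = dict(zip(proteins, quart))
    rng = np.random.default_rng(seed)
    rows, null_rows, samples = [], [], []
    labels = ["Q1", "Q2", "Q3", "Q4"]
    for profile in profiles:
        affected = [p for p in profile.affected_proteins(zygosity_mode) if p in bin_of]
        if not affected:
            continue
        counts = pd.Series([bin_of[p] for p in affected]).value_counts()
        rows.append([counts.get(q, 0) / len(affected) for q in labels])
        placed = rng.choice(proteins, size=len(affected), replace=False)
        ncounts = pd.Series([bin_of[p] for p in placed]).value_counts()
        null_rows.append([ncounts.get(q, 0) / len(affected) for q in labels])
        samples.append(profile.sample)
    obs = pd.DataFrame(rows, index=samples, columns=labels)
    null = pd.DataFrame(null_rows, index=samples, columns=labels)
    values = {}
    tests = []
    for q in labels:
        values[f"obs_{q}"] = obs[q].to_numpy()
        values[f"null_{q}"] = null[q].to_numpy()
        tests.append((f"obs_{q}", f"null_{q}"))
    results = compare_groups(values, tests)
    return QuartileDamageResult(obs, null, {q: r for q, r in zip(labels, results)})
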