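"""Per-individual interactome damage and the permutation null models.

Each individual's interactome is the curated graph minus the proteins with
both alleles impaired by deleterious variants.  The observed integrity
metrics are compared to two null ensembles: a *uniform* null, in which the
same numbers of proteins are removed with equal probability anywhere in the
network, and a *frequency-weighted* null, in which removal probability is
proportional to how often each protein is observed damaged in a reference
population (random combinations of the observed proteins).  Per-population,
the paper-style design draws 1,000 null interactomes whose removal counts
are resampled from the counts observed in that population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ppiload.interactome import Interactome
from ppiload.metrics import (
    GraphState,
    GroupComparisonResult,
    NetworkStateMetrics,
    compare_groups,
)
from ppiload.variants import IndividualProfile, ProteinFrequencyTable

log = logging.getLogger(__name__)

PATH_METRICS = ("avg_shortest_path", "diameter")
DEFAULT_TEST_METRICS = ("n_edges", "avg_shortest_path", "n_components")


@dataclass(frozen=True)
class DamageObservation:
    sample: str
    population: str
    n_removed: int
    metrics: NetworkStateMetrics


@dataclass
class NullEnsemble:
    model: str  # "uniform" | "frequency_weighted"
    population: str
    draws: list[NetworkStateMetrics]
    k_drawn: list[int]
    seed: int

    def metric_values(self, name: str) -> np.ndarray:
        return np.array([getattr(m, name) for m in self.draws], dtype=float)


def observe_damage(
    g: Interactome,
    profiles: Sequence[IndividualProfile],
    zygosity_mode: str = "recessive",
    paths: bool = True,
    state: Optional[GraphState] = None,
) -> list[DamageObservation]:
    """Metrics of each individual's node-depleted interactome.

    The removal set is the individual's both-alleles-affected proteins
    (recessive model) intersected with the graph nodes.
    """
    state = state or GraphState(g)
    out = []
    for profile in profiles:
        removal = profile.affected_proteins(zygosity_mode) & set(state.index)
        out.append(
            DamageObservation(
                sample=profile.sample,
                population=profile.population,
                n_removed=len(removal),
                metrics=state.metrics(removal, paths=paths),
            )
        )
    return out


def _weighted_sample_without_replacement(
    rng: np.random.Generator, items: np.ndarray, weights: np.ndarray, k: int
) -> np.ndarray:
    """Successive sampling without replacement, probability proportional to
    weight, via the Gumbel-top-k (Efraimidis-Spirakis) construction."""
    keys = np.log(weights) + rng.gumbel(size=len(items))
    return items[np.argsort(keys)[-k:]]


def simulate_null(
    g: Interactome,
    observed_k: Sequence[int],
    model: str = "uniform",
    weights: Optional[ProteinFrequencyTable] = None,
    n_sim: int = 1000,
    seed: int = 0,
    population: str = "",
    paths: bool = True,
    state: Optional[GraphState] = None,
) -> NullEnsemble:
    """Draw ``n_sim`` randomly damaged interactomes.

    Each draw samples a removal count k uniformly from ``observed_k`` (the
    multiset of removal counts seen in the population), then removes k
    distinct proteins: uniformly (``model="uniform"``) or proportionally to
    pseudo-counted observed damage frequencies ``n_hom + 1`` restricted to
    proteins with ``n_hom > 0`` (``model="frequency_weighted"``), so that
    simulated individuals only damage proteins seen damaged in the reference
    population, but in random combinations.  Bit-reproducible given ``seed``.
    """
    if model not in ("uniform", "frequency_weighted"):
        raise ValueError(f"unknown null model: {model!r}")
    observed_k = list(observed_k)
    if not observed_k:
        raise ValueError("observed_k must be non-empty")
    state = state or GraphState(g)
    n = len(state.nodes)
    if max(observed_k) > n:
        raise ValueError("a removal count exceeds the number of nodes")
    nodes = np.array(state.nodes)
    if model == "frequency_weighted":
        if weights is None:
            raise ValueError("frequency_weighted model requires a frequency table")
        hom = weights.counts["n_hom"]
        hom = hom[hom.index.isin(state.index)]
        pool = hom[hom > 0]
        if len(pool) == 0:
            raise ValueError("frequency_weighted model requires >=1 positive-weight protein")
        if max(observed_k) > len(pool):
            raise ValueError(
                f"removal count {max(observed_k)} exceeds the {len(pool)} positive-weight proteins"
            )
        pool_items = pool.index.to_numpy()
        pool_weights = pool.to_numpy(dtype=float) + 1.0  # pseudo-count
    rng = np.random.default_rng(seed)
    draws, ks = [], []
    for _ in range(n_sim):
        k = int(rng.choice(observed_k))
        if k == 0:
            removal = np.array([], dtype=nodes.dtype)
        elif model == "uniform":
            removal = nodes[rng.choice(n, size=k, replace=False)]
        else:
            removal = _weighted_sample_without_replacement(rng, pool_items, pool_weights, k)
        draws.append(state.metrics(removal, paths=paths))
        ks.append(k)
    return NullEnsemble(model=model, population=population, draws=draws, k_drawn=ks, seed=seed)


def test_real_vs_null(
    obs: Sequence[DamageObservation],
    nulls: Sequence[NullEnsemble],
    metrics: Sequence[str] = DEFAULT_TEST_METRICS,
) -> list[GroupComparisonResult]:
    """Per metric and null model, two-sided Mann-Whitney of per-individual
    real values vs per-draw null values, BH-corrected across metrics x models.

    Group labels are ``real:<metric>`` and ``<model>:<metric>``.
    """
    if not obs or not nulls:
        raise ValueError("both real observations and null ensembles are required")
    values: dict[str, list[float]] = {}
    tests = []
    for metric in metrics:
        real_key = f"real:{metric}"
        values[real_key] = [getattr(o.metrics, metric) for o in obs]
        for ens in nulls:
            null_key = f"{ens.model}:{metric}"
            values[null_key] = list(ens.metric_values(metric))
            tests.append((real_key, null_key))
    return compare_groups(values, tests)
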