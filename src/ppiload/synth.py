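"""Synthetic interactomes, cohorts and interaction evidence with ground truth.

The generator emulates the statistical structure the pipeline is built to
detect: a modular, hub-containing protein interaction network (planted
partition with a dense core module carrying hubs, so closeness varies), and
multi-sample genotypes whose per-protein deleterious-variant carrier
probability depends on network centrality with a signed, tunable strength
(``placement_bias``; negative = damage concentrated in the periphery, the
healthy-population pattern; positive = central concentration, the
cancer-somatic pattern).  Every output is a pure function of the spec and
seed, and each generated file is accompanied by the generator's own
bookkeeping (true carrier probabilities, per-protein counts, per-individual
affected sets) so downstream recovery tests never read truth from the code
under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ppiload.interactome import Interactome
from ppiload.variants import (
    AffectionState,
    IndividualProfile,
    ProteinFrequencyTable,
)


@dataclass
class SynthSpec:
    """Parameters of the synthetic study.

    Defaults describe a desk-scale healthy cohort: a 400-protein, 8-module
    interactome; one population of 25 individuals; a peripheral placement
    bias of -0.6 (healthy-like); 3% mean carrier rate per protein with 30%
    of carrier genotypes homozygous.
    """

    n_proteins: int = 400
    n_modules: int = 8
    intra_module_edge_prob: float = 0.12
    inter_module_edge_prob: float = 0.004
    hub_fraction: float = 0.05
    leaf_fraction: float = 0.2
    populations: tuple[str, ...] = ("POP1",)
    n_individuals: int = 25
    placement_bias: float = -0.6
    population_bias: dict[str, float] = field(default_factory=dict)
    carrier_rate: float = 0.03
    hom_fraction: float = 0.3
    benign_variant_prob: float = 0.6
    synonymous_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intra_module_edge_prob", "inter_module_edge_prob", "hub_fraction",
                     "leaf_fraction", "carrier_rate", "hom_fraction", "benign_variant_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for b in [self.placement_bias, *self.population_bias.values()]:
            if not -1.0 <= b <= 1.0:
                raise ValueError(f"placement bias must be in [-1, 1], got {b}")

    def bias_for(self, population: str) -> float:
        return self.population_bias.get(population, self.placement_bias)


def generate_interactome(spec: SynthSpec) -> tuple[Interactome, dict[str, int]]:
    """Planted-partition interactome with a core-and-periphery module layout.

    Modules are wired densely inside (module 0, the core, twice as densely)
    and sparsely between, but only along a planted module topology: a chain
    of modules with the core at its centre, so the module-level graph has a
    genuine centrality gradient (the dense, hub-bearing core is central
    both by degree and by distance, chain ends are peripheral) instead of
    being complete.  A ``hub_fraction`` of nodes, drawn from the core
    module, receive extra attachments within the core — a high-degree tail
    that neither short-circuits the module chain nor blurs the planted
    partition — and a ``leaf_fraction`` of each module's nodes are attached
    by a single edge to a random non-leaf member of their module, the
    degree-1 tail that makes real interactomes shed small components under
    random node removal.  Returns the graph and the true module label of
    every protein.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_proteins, spec.n_modules
    names = [f"P{i:05d}" for i in range(n)]
    labels = {names[i]: i % m for i in range(n)}
    lab = np.array([labels[x] for x in names])
    g = nx.Graph()
    g.add_nodes_from(names)
    # designate per-module leaves, excluded from the block model
    is_leaf = np.zeros(n, dtype=bool)
    for mod in range(m):
        members = np.flatnonzero(lab == mod)
        n_leaves = int(round(spec.leaf_fraction * len(members)))
        if n_leaves and len(members) - n_leaves >= 1:
            is_leaf[rng.choice(members, size=n_leaves, replace=False)] = True
    # Bernoulli block model over non-leaf upper-triangle pairs; between-module
    # blocks carry edges only along the planted chain topology
    inner = np.flatnonzero(~is_leaf)
    iu_l, ju_l = np.triu_indices(len(inner), k=1)
    iu, ju = inner[iu_l], inner[ju_l]
    li, lj = lab[iu], lab[ju]
    same = li == lj
    core = (li == 0) & (lj == 0)
    # chain order with the core module at the centre
    others = list(range(1, m))
    order = others[0::2][::-1] + [0] + others[1::2]
    pos = np.empty(m, dtype=int)
    pos[order] = np.arange(m)
    linked = np.abs(pos[li] - pos[lj]) == 1
    p = np.where(same, spec.intra_module_edge_prob,
                 np.where(linked, spec.inter_module_edge_prob, 0.0))
    p = np.where(core, np.minimum(1.0, 2.0 * spec.intra_module_edge_prob), p)
    draw = rng.random(len(p)) < p
    g.add_edges_from((names[a], names[b]) for a, b in zip(iu[draw], ju[draw]))
    # each leaf hangs off one random non-leaf member of its module
    for idx in np.flatnonzero(is_leaf):
        anchors = np.flatnonzero((lab == lab[idx]) & ~is_leaf)
        g.add_edge(names[idx], names[int(rng.choice(anchors))])
    # hubs: non-leaf core-module nodes with extra attachments
    n_hubs = int(round(spec.hub_fraction * n))
    core_nodes = [names[i] for i in np.flatnonzero((lab == 0) & ~is_leaf)]
    hubs = list(rng.choice(core_nodes, size=min(n_hubs, len(core_nodes)), replace=False))
    n_extra = max(1, int(0.02 * n))
    target_pool = core_nodes
    for hub in hubs:
        targets = rng.choice(len(target_pool), size=min(n_extra, len(target_pool)), replace=False)
        g.add_edges_from((hub, target_pool[t]) for t in targets if target_pool[t] != hub)
    n_singletons = sum(1 for x in names if g.degree(x) == 0)
    if n_singletons > 0.1 * n:
        import warnings

        warnings.warn(f"{n_singletons} isolated proteins generated; consider denser parameters")
    return Interactome(g, provenance={"synthetic": True, "seed": spec.seed}), labels


def _closeness_rank(g: Interactome) -> pd.Series:
    """Rank of each protein's closeness, rescaled to [0, 1]; 1 = most central."""
    closeness = pd.Series(nx.closeness_centrality(g.graph, wf_improved=True))
    r = closeness.rank(method="average")
    return (r - 1) / max(len(r) - 1, 1)


def carrier_probabilities(g: Interactome, spec: SynthSpec, population: str) -> pd.Series:
    """True per-protein carrier probability for one population.

    ``p_i = carrier_rate * (1 + beta * (2 r_i - 1))`` clipped to [0, 0.95],
    where ``r_i`` is the closeness rank in [0, 1] and ``beta`` the signed
    placement bias: negative biases carriers to the periphery.
    """
    beta = spec.bias_for(population)
    r = _closeness_rank(g)
    p = spec.carrier_rate * (1.0 + beta * (2.0 * r - 1.0))
    return p.clip(0.0, 0.95)


@dataclass
class PopulationData:
    """Generated cohort files plus the generator's ground truth."""

    vcf_path: Path
    annotation_path: Path
    manifest_path: Path
    manifest: dict[str, str]
    carrier_prob: dict[str, pd.Series]
    truth_frequency: dict[str, ProteinFrequencyTable]
    affected_hom: dict[str, set[str]]  # sample -> proteins with both alleles impaired
    affected_any: dict[str, set[str]]  # sample -> proteins with >=1 deleterious allele
    seed: int


def generate_population(g: Interactome, spec: SynthSpec, out_dir) -> PopulationData:
    """Write a multi-sample VCF 4.2, annotation TSV and manifest for the
    cohorts described by ``spec``, with full bookkeeping.

    Every protein carries one planted deleterious missense variant whose
    SIFT/PolyPhen scores pass the deleteriousness rule; with probability
    ``benign_variant_prob`` a benign missense (scores failing both clauses)
    is added, plus Poisson(``synonymous_rate``) synonymous variants, so the
    classifier and the NS/S ratio see realistic mixtures.  Carrier genotypes
    at the deleterious site are homozygous with probability ``hom_fraction``,
    heterozygous otherwise; benign and synonymous genotypes are sprinkled
    uniformly and never contribute to truth.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    proteins = sorted(g.graph.nodes)
    samples = []
    manifest: dict[str, str] = {}
    for pop in spec.populations:
        for i in range(spec.n_individuals):
            s = f"{pop}_S{i:03d}"
            samples.append(s)
            manifest[s] = pop

    probs = {pop: carrier_probabilities(g, spec, pop) for pop in spec.populations}

    # genotype draw at the planted deleterious site, per sample x protein
    hom_sets: dict[str, set[str]] = {s: set() for s in samples}
    any_sets: dict[str, set[str]] = {s: set() for s in samples}
    del_gt: dict[str, dict[str, str]] = {p: {} for p in proteins}
    for s in samples:
        p_carrier = probs[manifest[s]].loc[proteins].to_numpy()
        carrier = rng.random(len(proteins)) < p_carrier
        hom = carrier & (rng.random(len(proteins)) < spec.hom_fraction)
        for j, protein in enumerate(proteins):
            if hom[j]:
                del_gt[protein][s] = "1/1"
                hom_sets[s].add(protein)
                any_sets[s].add(protein)
            elif carrier[j]:
                del_gt[protein][s] = "0/1"
                any_sets[s].add(protein)

    truth_frequency = {}
    for pop in spec.populations:
        pop_samples = [s for s in samples if manifest[s] == pop]
        counts = pd.DataFrame(
            0, index=pd.Index(proteins, name="protein"), columns=["n_het_or_hom", "n_hom"]
        )
        for s in pop_samples:
            for protein in any_sets[s]:
                counts.at[protein, "n_het_or_hom"] += 1
            for protein in hom_sets[s]:
                counts.at[protein, "n_hom"] += 1
        truth_frequency[pop] = ProteinFrequencyTable(counts, n_total=len(pop_samples))

    # variant rows: (chrom, pos, ref, alt, protein, consequence, sift, polyphen, phastcons, gts)
    rows = []
    pos = 0
    for j, protein in enumerate(proteins):
        chrom = "1"
        pos += 10
        rows.append(
            (chrom, pos, "A", "G", protein, "missense",
             round(float(rng.uniform(0.0, 0.04)), 4),
             round(float(rng.uniform(0.96, 0.999)), 4),
             "", del_gt[protein])
        )
        if rng.random() < spec.benign_variant_prob:
            pos += 10
            carriers = rng.random(len(samples)) < 0.05
            gts = {s: "0/1" for s, c in zip(samples, carriers) if c}
            rows.append(
                (chrom, pos, "C", "T", protein, "missense",
                 round(float(rng.uniform(0.1, 0.9)), 4),
                 round(float(rng.uniform(0.0, 0.9)), 4),
                 "", gts)
            )
        for _ in range(rng.poisson(spec.synonymous_rate)):
            pos += 10
            carriers = rng.random(len(samples)) < 0.1
            gts = {s: "0/1" for s, c in zip(samples, carriers) if c}
            rows.append((chrom, pos, "G", "A", protein, "synonymous", "", "", "", gts))

    vcf_path = out_dir / "cohort.vcf"
    ann_path = out_dir / "annotation.tsv"
    manifest_path = out_dir / "manifest.tsv"
    with open(vcf_path, "w") as vcf:
        vcf.write("##fileformat=VCFv4.2\n")
        vcf.write("##contig=<ID=1>\n")
        vcf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        vcf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for chrom, p, ref, alt, *_rest, gts in rows:
            gt_fields = "\t".join(gts.get(s, "0/0") for s in samples)
            vcf.write(f"{chrom}\t{p}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gt_fields}\n")
    with open(ann_path, "w") as ann:
        ann.write("chrom\tpos\tref\talt\tprotein\tconsequence\tsift\tpolyphen\tphastcons\n")
        for chrom, p, ref, alt, protein, cons, sift, poly, phast, _gts in rows:
            ann.write(f"{chrom}\t{p}\t{ref}\t{alt}\t{protein}\t{cons}\t{sift}\t{poly}\t{phast}\n")
    with open(manifest_path, "w") as mf:
        mf.write("sample\tpopulation\n")
        for s in samples:
            mf.write(f"{s}\t{manifest[s]}\n")

    return PopulationData(
        vcf_path=vcf_path,
        annotation_path=ann_path,
        manifest_path=manifest_path,
        manifest=manifest,
        carrier_prob=probs,
        truth_frequency=truth_frequency,
        affected_hom=hom_sets,
        affected_any=any_sets,
        seed=spec.seed,
    )


def truth_profiles(data: PopulationData) -> list[IndividualProfile]:
    """Individual profiles built from the generator's bookkeeping (not from
    the VCF) — the oracle side of end-to-end recovery tests."""
    profiles = []
    for sample, pop in data.manifest.items():
        state = {}
        for protein in data.affected_any[sample]:
            state[protein] = (
                AffectionState.BOTH_ALLELES_AFFECTED
                if protein in data.affected_hom[sample]
                else AffectionState.HET_AFFECTED
            )
        profiles.append(IndividualProfile(sample, pop, state))
    return profiles


def generate_mitab(
    spec: SynthSpec,
    out_path,
    n_pairs: int = 20,
    method_multiplicities: Sequence[int] = (1, 2, 2, 3),
    nonphysical_fraction: float = 0.2,
) -> tuple[Path, set[tuple[str, str]]]:
    """Write a MITAB 2.5 file with planted evidence structure.

    Pairs cycle through ``method_multiplicities`` detection-method counts
    (one record per method, exercising cross-record pooling) and a
    ``nonphysical_fraction`` of pairs is planted as colocalization instead
    of physical association.  Returns the file path and the exact edge set
    the default curation (>=2 methods, physical association) must produce.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2]))
    methods = [
        ('psi-mi:"MI:0018"(two hybrid)', "MI:0018"),
        ('psi-mi:"MI:0019"(coimmunoprecipitation)', "MI:0019"),
        ('psi-mi:"MI:0071"(molecular sieving)', "MI:0071"),
        ('psi-mi:"MI:0096"(pull down)', "MI:0096"),
    ]
    t_phys = 'psi-mi:"MI:0915"(physical association)'
    t_coloc = 'psi-mi:"MI:0403"(colocalization)'
    pairs = []
    seen = set()
    while len(pairs) < n_pairs:
        a, b = rng.integers(0, 4 * n_pairs, size=2)
        if a == b:
            continue
        pair = tuple(sorted((f"Q{a:05d}", f"Q{b:05d}")))
        if pair in seen:
            continue
        seen.add(pair)
        pairs.append(pair)
    expected: set[tuple[str, str]] = set()
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for i, (a, b) in enumerate(pairs):
            n_methods = method_multiplicities[i % len(method_multiplicities)]
            physical = rng.random() >= nonphysical_fraction
            itype = t_phys if physical else t_coloc
            for k in range(n_methods):
                method, _mid = methods[k]
                fh.write(
                    "\t".join(
                        [
                            f"uniprotkb:{a}",
                            f"uniprotkb:{b}",
                            "-", "-", "-", "-",
                            method,
                            "-", "pubmed:0000000",
                            "taxid:9606", "taxid:9606",
                            itype,
                            'psi-mi:"MI:0463"(biogrid)',
                            "-", "-",
                        ]
                    )
                    + "\n"
                )
            if n_methods >= 2 and physical:
                expected.add((a, b))
    return out_path, expected


def constrained_removal_sets(
    g: Interactome,
    sizes: Sequence[int],
    beta: float = -0.8,
    max_disconnected: int = 2,
    seed: int = 0,
    max_tries: int = 500,
) -> list[set[str]]:
    """Removal sets emulating healthy individuals' damage combinations.

    Candidates are drawn with the closeness-rank placement bias ``beta``
    and rejected unless removing them knocks at most ``max_disconnected``
    *additional* nodes out of the giant component — i.e. combinations that
    preserve connectivity.  Used to plant the healthy-cohort combination
    structure for null-model comparisons.
    """
    r = _closeness_rank(g)
    nodes = np.array(r.index)
    w = np.clip(1.0 + beta * (2.0 * r.to_numpy() - 1.0), 1e-6, None)
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    comp_sizes = [len(c) for c in nx.connected_components(g.graph)]
    giant_before = max(comp_sizes)
    giant_nodes = max(nx.connected_components(g.graph), key=len)
    out = []
    for k in sizes:
        accepted = None
        for _ in range(max_tries):
            cand = set(rng.choice(nodes, size=k, replace=False, p=w))
            sub = g.graph.subgraph(set(g.graph.nodes) - cand)
            giant_after = max((len(c) for c in nx.connected_components(sub)), default=0)
            removed_in_giant = len(cand & giant_nodes)
            if giant_before - giant_after - removed_in_giant <= max_disconnected:
                accepted = cand
                break
        if accepted is None:  # fall back to the least damaging candidate seen last
            accepted = cand
        out.append(accepted)
    return out


def profiles_from_removals(
    removals: Sequence[set[str]],
    population: str = "SYN",
) -> list[IndividualProfile]:
    """Wrap raw removal sets as individual profiles (both alleles affected)."""
    return [
        IndividualProfile(
            sample=f"{population}_S{i:03d}",
            population=population,
            state={p: AffectionState.BOTH_ALLELES_AFFECTED for p in rm},
        )
        for i, rm in enumerate(removals)
    ]
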