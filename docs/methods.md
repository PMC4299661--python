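# Methods

## Scope and model

`ppiload` treats the curated human interactome as an undirected simple
graph and asks how the deleterious variants carried by individuals are
placed on it. Three statistics carry the analysis:

1. **Per-individual structural damage.** Under a recessive model, a protein
   is lost when both alleles are impaired: a homozygous deleterious
   genotype, or two distinct heterozygous deleterious variants in the same
   protein (compound heterozygote; genotypes are assumed unphased, so two
   hets are always counted in trans — the conservative choice for a
   loss-of-function screen). The individual's interactome is the graph
   minus these proteins, summarized by surviving edges, number of
   components, giant-component size, mean shortest-path length over
   connected pairs, and diameter (the largest shortest path over all
   components).
2. **Permutation nulls.** Per population, 1,000 simulated individuals (the
   default `n_sim`) each remove k proteins, with k resampled uniformly from
   the multiset of removal counts observed in that population. The
   *uniform* null removes any protein with equal probability. The
   *frequency-weighted* null removes proteins with probability proportional
   to `n_hom + 1` restricted to proteins observed damaged at least once in
   the reference population — simulated individuals damage only genuinely
   damaged proteins, but in random combinations. Weighted sampling without
   replacement uses the Gumbel-top-k construction, which is exactly
   successive draws proportional to weight. Real and simulated metric
   distributions are compared by two-sided Mann–Whitney U with
   Benjamini–Hochberg correction across metrics × null models.
3. **Module relative damage.** Communities come from Walktrap (walk length
   4, its common default) or Infomap (two-level, default settings), both
   via igraph; communities under 5 proteins are discarded and their
   proteins marked unassigned. For one individual with a affected proteins
   (any-allele definition by default), the null re-places a proteins
   uniformly over *all* interactome nodes — including unassigned ones, so
   the null matches the observed placement universe — `n_perm` times. The
   module's relative damage is the mid-rank percentile of the observed
   proportion of affected module members within the null proportions.
   Mid-rank tie handling makes an observation at the null median score
   exactly 0.5 and keeps the statistic in [0, 1]; a plain min–max
   rescaling of the observed proportion was considered and rejected as the
   default because it has no calibrated null anchor (it remains available
   to callers via the raw proportions from
   `observed_module_proportions`). Population values are arithmetic means
   of per-individual values; profiles are compared by agglomerative
   clustering (complete linkage by default) on Euclidean distances, with
   the dendrogram serialized as Newick.

## Deleteriousness rule

Truncating and splice-disrupting variants are damaging iff their phastCons
conservation score exceeds 200; the conservation score is taken verbatim
from the annotation input (annotation pipelines in this domain emit it on a
scaled, not [0, 1], axis), and the threshold is configurable. Missense
variants are damaging iff SIFT ≤ 0.05 **or** PolyPhen > 0.95; a missing
score fails its own clause only. The SIFT comparator is inclusive (≤) by
default: the frozen 20-variant validation panel contains a substitution
with SIFT exactly 0.05 and PolyPhen 0.042 whose expert verdict is
deleterious, which a strict `<` cannot reproduce; `sift_cmp="lt"` restores
the strict reading. The classifier is monotone: lowering SIFT or raising
PolyPhen can never flip a deleterious call to benign (property-tested).

## Curation

Evidence rows are pooled per unordered protein pair across source
databases before counting distinct detection methods (identified by PSI-MI
term id when present, else lowercased label). An edge needs ≥ 2 methods
and at least one pooled record of an allowed interaction type
(`physical association` by default); requiring the type on *every* record
is stricter than the evidence model warrants, since databases re-export
the same physical interaction under varying vocabulary. Self-loops are
dropped and counted. Curation is monotone (raising `min_methods` never
adds edges) and idempotent under record duplication — both property-tested.

## Numerical choices

- Closeness uses the Wasserman–Faust component-size correction
  `(k−1)/(n−1) · (k−1)/Σd`, bounded and comparable across components of a
  disconnected graph; isolated nodes score 0. Betweenness is unnormalized;
  every downstream use is rank-based, so normalization is immaterial.
- Mean shortest-path length averages over connected pairs (not giant
  component only); node-depleted metrics run on a cached sparse adjacency
  matrix with BFS-based all-pairs distances, and permutation ensembles may
  skip the path metrics (`paths=False`) when only edge/component counts
  are tested.
- Mann–Whitney uses the exact null when both groups have ≤ 25 tie-free
  values, else the normal approximation with tie correction.
- Spearman correlations with a constant vector are reported as NaN and
  flagged rather than raised.
- Centrality–frequency correlations are restricted to proteins observed
  affected at least once, so the mass of never-affected proteins does not
  dominate the ranks.
- The closeness-quartile analysis compares each quartile's per-individual
  observed proportions against a matched null cohort (each individual's
  affected count re-placed uniformly once, seeded) by Mann–Whitney — a
  proper two-sample formulation of "compared to the uniform expectation".
- Every stochastic routine takes an explicit seed; cohort-level permutation
  streams are spawned per individual from a `SeedSequence`, making results
  bit-reproducible and order-independent.

## Synthetic data: what it emulates, what it does not

`generate_interactome` plants a partition of `n_proteins` into `n_modules`
wired densely inside (Bernoulli `intra_module_edge_prob`, default 0.12)
and sparsely between, but only along a module chain with a twice-as-dense
core module at its centre; a `hub_fraction` (5%) of core nodes receive
extra in-core attachments and a `leaf_fraction` (20%) of each module's
nodes hang by a single edge. The defaults are chosen so the 400-node
default graph has mean degree ≈ 5–6 and a sizeable degree-1 tail — the
degree regime of curated human interactomes (≈ 7,300 proteins, ≈ 21,600
interactions, power-law-ish) — while remaining recoverable by Walktrap
(≥ 0.8 adjusted Rand agreement with the planted labels, tested).

`generate_population` gives protein i a carrier probability
`p_i = carrier_rate · (1 + β · (2 r_i − 1))`, clipped to [0, 0.95], where
`r_i` is the protein's closeness *rank* rescaled to [0, 1] (rank, not raw
closeness, so β is comparable across graph sizes) and β ∈ [−1, 1] is the
signed placement bias: β < 0 concentrates carriers in the periphery (the
healthy-population pattern), β > 0 centrally (the cancer-somatic pattern),
β = 0 is calibrated null (|ρ| < 0.1 at 500 proteins, tested). Defaults —
3% carrier rate, 30% of carrier genotypes homozygous, β = −0.6, 25
individuals per population — produce per-individual loads of a few dozen
affected proteins, a desk-scale stand-in for the hundreds seen in real
exomes. Each protein carries one planted deleterious missense variant
(scores drawn to pass the rule), optionally a benign missense (scores
drawn to fail both clauses) and Poisson-distributed synonymous variants.
The generator writes a valid multi-sample VCF 4.2, annotation TSV and
manifest, and returns its own bookkeeping (true carrier probabilities,
counts, per-individual affected sets); recovery tests read truth only from
the bookkeeping, never from the pipeline under test.

`constrained_removal_sets` emulates the healthy-cohort *combination*
effect: candidate removal sets are drawn with peripheral bias and rejected
unless they knock at most `max_disconnected` additional nodes out of the
giant component.

Not emulated: linkage disequilibrium and population structure, realistic
allele-frequency spectra, per-gene variant-density variation, genotype
errors and missingness, phased haplotypes, annotation disagreement between
scores. Passing tests therefore demonstrate that the statistics recover
planted placement structure of realistic sign and scale — not that any
particular real cohort shows that structure.

## Problem sizes

The test suite and acceptance script run at desk scale as the package's own
choice of default experiment: interactomes of 120–1,000 proteins, cohorts
of 5–50 individuals, 100–500 permutations per individual, null ensembles
of 200–2,000 draws. The statistics are size-independent (percentiles,
ranks, signs); real-data magnitudes additionally depend on cohort size and
interactome completeness and are not targets of the synthetic runs.

## Known limitations

- Walktrap is deterministic, but Infomap partitions depend on the seeded
  igraph RNG; module identifiers are arbitrary (sorted by size).
- The frequency-weighted null requires at least as many positive-weight
  proteins as the largest removal count and raises otherwise.
- Compound-heterozygote detection cannot see phase; two hets in cis are
  over-called as both-alleles-affected.
- The merged-TSV genotype reader understands diploid GT strings only.
- Dense all-pairs distance matrices bound practical node-depleted path
  metrics to a few thousand nodes; edge/component metrics scale further.
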