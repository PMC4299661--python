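# ppiload

**Where does a genome's deleterious mutational load sit in the protein
interaction network — and why does it so often not hurt?**

Healthy human genomes carry a surprising number of predicted loss-of-function
variants. `ppiload` is a pipeline for testing one systems-level explanation:
that the protein–protein interaction network (the interactome) buffers this
load because tolerated deleterious variants concentrate in *peripheral*
network regions, in *combinations* that preserve connectivity, while
pathogenic variation (e.g. cancer somatic mutations) hits *central* regions.
It is aimed at computational and systems biologists working with
multi-sample exome VCFs and curated interaction data.

## What it computes

1. **Curated interactome** — interaction evidence (MITAB 2.5 or edge-list
   TSV) is pooled per protein pair across databases; an edge is kept only if
   supported by ≥ 2 distinct detection methods and a `physical association`
   record.
2. **Deleteriousness calls** — truncating/splicing variants are damaging if
   their phastCons conservation score exceeds 200 (annotation scale);
   missense variants if SIFT ≤ 0.05 or PolyPhen > 0.95. Multi-sample
   genotypes reduce per individual to protein states: unaffected, one allele
   affected, or both alleles affected (homozygous or compound-heterozygous).
3. **Individual damage vs permutation nulls** — each individual's
   interactome is the graph minus their both-alleles-affected proteins.
   Surviving edges, components, giant-component size, mean shortest path and
   diameter are compared (Mann–Whitney U, BH-FDR) against 1,000 simulated
   interactomes per population under two nulls: *uniform* removal, and
   removal *proportional to observed population damage frequencies* (random
   combinations of genuinely damaged proteins).
4. **Module relative damage** — the interactome is partitioned with
   Walktrap (walk length 4) or Infomap (modules < 5 proteins discarded).
   For each individual and module, the observed proportion of affected
   proteins is ranked against 1,000 uniform re-placements of the same number
   of affected proteins; the mid-rank empirical percentile is the module's
   **relative damage** `RD ∈ [0, 1]`, with `RD = 0.5` at the null median:

   `RD = (#{null < obs} + ½·#{null = obs}) / n_perm`

   Population profiles (mean over individuals) are correlated with module
   closeness centrality (Spearman ρ) and clustered hierarchically on
   Euclidean distances.
5. **Residue-level scores** — polarity-group (hydrophobicity scale
   0 = LIFWCMVY, 1 = PATGS, 2 = HQRKNED) and charge-class (+ = RK, − = ED,
   0 = rest) changes for missense substitutions.

A fully seeded synthetic-data generator (`ppiload.synth`) produces modular
interactomes and cohort VCFs whose per-protein deleterious-variant
probability depends on network centrality with signed, tunable strength —
so every stage is testable end to end with known ground truth.

## Worked example

Run the whole pipeline on a synthetic healthy-like cohort (400 proteins,
8 modules, 20 individuals, placement bias −0.8 toward the periphery):

```yaml
# config.yaml
seed: 7
out_dir: demo_out
synth:
  n_proteins: 400
  n_modules: 8
  n_individuals: 20
  placement_bias: -0.8
  seed: 7
parameters:
  n_sim: 200
  n_perm: 300
```

```bash
ppiload run config.yaml
```

prints

```json
{
  "interactome": {"n_proteins": 400, "n_interactions": 1035},
  "variants": {"n_input": 1017, "n_deleterious": 400},
  "modules": {"algorithm": "walktrap", "n_modules": 8, "n_unassigned": 11}
}
```

and `demo_out/summary.json` contains, among other things, the
module-centrality vs relative-damage correlation for the cohort:

```json
"module_damage_correlation": {
  "POP1": {"rho": -0.878, "p": 0.0041, "n": 8}
}
```

The negative ρ says exactly what the planted bias put there: the more
peripheral a module, the higher its relative damage — peripheral modules
soak up the deleterious load. Mean surviving edges confirm the combination
effect (real 1023.2 > frequency-weighted null 1022.7 > uniform null
1018.1): the cohort's removal sets damage the network less than random
removals of the same sizes, and restricting the null to genuinely damaged
proteins explains most, but not all, of that protection. Re-running with
`placement_bias: 0.8` (the cancer-somatic pattern) flips the correlation
sign to positive.

Individual subcommands (`ppiload curate`, `classify`, `profile`, `damage`,
`simulate-null`, `modules`, `relative-damage`, `correlate`, `cluster`,
`synth`) expose each stage over TSV/VCF/GraphML/Newick files; see
`ppiload --help`.

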