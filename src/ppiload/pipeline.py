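"""End-to-end pipeline: curation -> classification -> profiles -> analyses.

``run_pipeline`` executes the three headline analyses on either real input
files or a synthetic study, writing per-stage TSVs and one JSON summary:

* topology of affected proteins — centrality group comparisons
  (both-alleles / one-allele / unaffected) and centrality-frequency
  Spearman correlations;
* interactome damage of each individual vs the uniform and
  frequency-weighted permutation nulls (Mann-Whitney);
* module-level relative damage — community detection, the modules x
  populations percentile matrix, module-centrality vs damage correlation,
  and hierarchical clustering of population profiles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from ppiload import interactome as iio
from ppiload import metrics as met
from ppiload import modules as mod
from ppiload import simulation as sim
from ppiload import synth
from ppiload import variants as var

log = logging.getLogger(__name__)

DEFAULT_PARAMETERS = {
    "min_methods": 2,
    "sift_cmp": "le",
    "sift_thr": 0.05,
    "polyphen_thr": 0.95,
    "phastcons_thr": 200.0,
    "algorithm": "walktrap",
    "min_module_size": 5,
    "n_sim": 500,
    "n_perm": 500,
    "null_paths": False,
    "zygosity_mode_removal": "recessive",
    "zygosity_mode_modules": "any_allele",
    "linkage": "complete",
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    return config


def _build_interactome(config: dict, out_dir: Path, seed: int):
    inputs = config.get("inputs") or {}
    if "synth" in config:
        spec = synth.SynthSpec(**{**config["synth"], "seed": config["synth"].get("seed", seed)})
        g, labels = synth.generate_interactome(spec)
        data = synth.generate_population(g, spec, out_dir / "synth")
        return g, spec, data
    if not inputs:
        raise ConfigError("config needs either a 'synth' section or an 'inputs' section")
    params = {**DEFAULT_PARAMETERS, **config.get("parameters", {})}
    if "mitab" in inputs:
        records, _ = iio.parse_mitab(inputs["mitab"], dialect="mitab25")
    elif "edgelist" in inputs:
        records, _ = iio.parse_mitab(inputs["edgelist"], dialect="edgelist_tsv")
    else:
        raise ConfigError("stage interactome: missing input 'mitab' or 'edgelist'")
    whitelist = None
    if "accession_whitelist" in inputs:
        whitelist = {l.strip() for l in open(inputs["accession_whitelist"]) if l.strip()}
    g, report = iio.curate(records, min_methods=params["min_methods"], accession_whitelist=whitelist)
    iio.write_curation_report(report, out_dir / "curation_report.tsv")
    return g, None, None


def _read_variants(config: dict, data: Optional[synth.PopulationData]):
    inputs = config.get("inputs") or {}
    if data is not None:
        calls = var.read_vcf(data.vcf_path, data.annotation_path)
        manifest = dict(data.manifest)
        return calls, manifest
    if "merged_tsv" in inputs:
        calls = var.read_merged_tsv(inputs["merged_tsv"])
    elif "vcf" in inputs and "annotation" in inputs:
        calls = var.read_vcf(inputs["vcf"], inputs["annotation"])
    else:
        raise ConfigError("stage variants: missing 'vcf'+'annotation' or 'merged_tsv'")
    if "manifest" not in inputs:
        raise ConfigError("stage variants: missing 'manifest'")
    manifest = var.read_manifest(inputs["manifest"])
    return calls, manifest


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the full analysis described by ``config`` (mapping or YAML
    path); returns the JSON-serializable summary and writes the report
    bundle under ``out_dir``."""
    if not isinstance(config, Mapping):
        config = load_config(config)
    out_dir = Path(out_dir or config.get("out_dir", "ppiload_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    params = {**DEFAULT_PARAMETERS, **config.get("parameters", {})}
    summary: dict = {"seed": seed, "parameters": params, "filters": {}}

    g, spec, data = _build_interactome(config, out_dir, seed)
    summary["interactome"] = {"n_proteins": g.n_nodes, "n_interactions": g.n_edges}
    iio.write_graph(g, out_dir / "interactome.tsv", format="edgelist_tsv")

    calls_raw, manifest = _read_variants(config, data)
    classified = [
        var.classify_variant(
            v,
            sift_cmp=params["sift_cmp"],
            sift_thr=params["sift_thr"],
            polyphen_thr=params["polyphen_thr"],
            phastcons_thr=params["phastcons_thr"],
        )
        for v in calls_raw
    ]
    n_del = sum(c.deleterious for c in classified)
    summary["variants"] = {"n_input": len(classified), "n_deleterious": n_del}
    log.info("classified %d variants, %d deleterious", len(classified), n_del)

    profiles = var.build_profiles(classified, g, manifest, zygosity_mode=params["zygosity_mode_removal"])
    var.write_profiles_tsv(profiles, out_dir / "profiles.tsv")
    freq = var.frequency_table(profiles, interactome=g)
    var.write_frequency_tsv(freq, out_dir / "frequency_table.tsv")

    # --- topology of affected proteins -----------------------------------
    cent = met.centralities(g)
    cent.to_csv(out_dir / "centralities.tsv", sep="\t")
    hom = freq.counts.index[freq.counts["n_hom"] >= 1]
    het = freq.counts.index[(freq.counts["n_het_or_hom"] >= 1) & (freq.counts["n_hom"] == 0)]
    unaffected = freq.counts.index[freq.counts["n_het_or_hom"] == 0]
    groups_summary = {}
    for metric in ("degree", "betweenness", "closeness"):
        values = {
            "both_alleles": cent.loc[cent.index.intersection(hom), metric].tolist(),
            "one_allele": cent.loc[cent.index.intersection(het), metric].tolist(),
            "unaffected": cent.loc[cent.index.intersection(unaffected), metric].tolist(),
        }
        usable = {k: v for k, v in values.items() if len(v) >= 2}
        pairs = [(a, b) for i, a in enumerate(sorted(usable)) for b in sorted(usable)[i + 1:]]
        if pairs:
            groups_summary[metric] = [
                dataclasses.asdict(r) for r in met.compare_groups(usable, pairs)
            ]
    summary["group_comparisons"] = groups_summary
    corr = met.centrality_frequency_correlation(cent, freq, mode="het_or_hom")
    summary["centrality_frequency_spearman"] = {k: dataclasses.asdict(v) for k, v in corr.items()}

    # --- individual damage vs permutation nulls --------------------------
    state = met.GraphState(g)
    obs = sim.observe_damage(g, profiles, paths=True, state=state)
    observed_k = [o.n_removed for o in obs]
    nulls = []
    if any(k > 0 for k in observed_k):
        uniform = sim.simulate_null(
            g, observed_k, model="uniform", n_sim=params["n_sim"], seed=seed,
            paths=bool(params["null_paths"]), state=state,
        )
        nulls.append(uniform)
        try:
            weighted = sim.simulate_null(
                g, observed_k, model="frequency_weighted", weights=freq,
                n_sim=params["n_sim"], seed=seed + 1,
                paths=bool(params["null_paths"]), state=state,
            )
            nulls.append(weighted)
        except ValueError as exc:
            log.warning("frequency-weighted null skipped: %s", exc)
        metrics_to_test = ["n_edges", "n_components"]
        if params["null_paths"]:
            metrics_to_test.insert(1, "avg_shortest_path")
        damage_tests = sim.test_real_vs_null(obs, nulls, metrics=metrics_to_test)
        summary["damage_vs_null"] = [dataclasses.asdict(r) for r in damage_tests]
        summary["damage_means"] = {
            "real": {m: float(np.mean([getattr(o.metrics, m) for o in obs])) for m in metrics_to_test},
            **{
                ens.model: {m: float(np.nanmean(ens.metric_values(m))) for m in metrics_to_test}
                for ens in nulls
            },
        }
    else:
        summary["damage_vs_null"] = []
        log.warning("no individual has a non-empty removal set; null comparison skipped")
    pd.DataFrame(
        [(o.sample, o.population, o.n_removed, *o.metrics.as_dict().values()) for o in obs],
        columns=["sample", "population", "n_removed", *obs[0].metrics.as_dict().keys()],
    ).to_csv(out_dir / "damage_observations.tsv", sep="\t", index=False)

    # --- module-level relative damage ------------------------------------
    part = mod.detect_modules(g, algorithm=params["algorithm"], min_size=params["min_module_size"], seed=seed)
    summary["modules"] = {
        "algorithm": part.algorithm,
        "n_modules": len(part.modules),
        "n_unassigned": len(part.unassigned),
    }
    if part.modules:
        mg = mod.module_graph(g, part)
        per_individual = mod.relative_damage_cohort(
            part, profiles, n_perm=params["n_perm"], seed=seed,
            zygosity_mode=params["zygosity_mode_modules"],
        )
        matrix = mod.damage_matrix(per_individual, manifest, n_perm=params["n_perm"],
                                   zygosity_mode=params["zygosity_mode_modules"])
        matrix.values.to_csv(out_dir / "relative_damage_matrix.tsv", sep="\t")
        summary["module_damage_correlation"] = {
            pop: dataclasses.asdict(mod.centrality_damage_correlation(mg, matrix.values[pop]))
            for pop in matrix.values.columns
            if len(part.modules) >= 3
        }
        if matrix.values.shape[1] >= 2:
            clustering = mod.cluster_profiles(matrix, axis="populations", linkage=params["linkage"])
            (out_dir / "population_dendrogram.nwk").write_text(clustering.newick + "\n")
            summary["population_clustering"] = {"newick": clustering.newick}

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default, sort_keys=True)
    return summary
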