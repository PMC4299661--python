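"""Deleteriousness classification and per-individual affection profiles.

A variant is called deleterious by the pathogenicity-score rule used
throughout this package: protein-truncating classes (stop gain/loss, splice
disrupting) are damaging when their phastCons conservation score exceeds a
threshold; missense (non-synonymous) variants are damaging when SIFT <= 0.05
or PolyPhen > 0.95.  Multi-sample genotypes then reduce, per individual, to
a three-state affection map over interactome proteins: unaffected, one
allele affected (het), or both alleles affected (a homozygous deleterious
genotype, or two distinct heterozygous deleterious variants in the same
protein — a compound heterozygote under the unphased assumption).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from ppiload.interactome import Interactome

log = logging.getLogger(__name__)


class Consequence(str, Enum):
    MISSENSE = "missense"
    STOP_GAIN = "stop_gain"
    STOP_LOSS = "stop_loss"
    SPLICE_DISRUPTING = "splice_disrupting"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: consequence classes entering the deleteriousness rule at all
CANDIDATE_CONSEQUENCES = frozenset(
    {Consequence.MISSENSE, Consequence.STOP_GAIN, Consequence.STOP_LOSS, Consequence.SPLICE_DISRUPTING}
)
#: truncating / splicing classes filtered on conservation only
TRUNCATING_CONSEQUENCES = frozenset(
    {Consequence.STOP_GAIN, Consequence.STOP_LOSS, Consequence.SPLICE_DISRUPTING}
)
#: protein-altering classes counted as non-synonymous in the NS/S ratio
NONSYNONYMOUS_CONSEQUENCES = CANDIDATE_CONSEQUENCES


class Zygosity(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"


class AffectionState(str, Enum):
    UNAFFECTED = "unaffected"
    HET_AFFECTED = "het_affected"
    BOTH_ALLELES_AFFECTED = "both_alleles_affected"


@dataclass(frozen=True)
class VariantCall:
    """One annotated variant (one alt allele) with per-sample genotypes."""

    chrom: str
    pos: int
    ref: str
    alt: str
    protein: str
    consequence: Consequence
    sift: Optional[float] = None
    polyphen: Optional[float] = None
    phastcons: Optional[float] = None
    genotypes: Mapping[str, Zygosity] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be 1-based and >= 1")
        for name, score in (("sift", self.sift), ("polyphen", self.polyphen)):
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(f"{name} score {score} outside [0, 1]")
        if self.phastcons is not None and self.phastcons < 0:
            raise ValueError("phastcons must be non-negative")


class Rule(str, Enum):
    SIFT = "sift"
    POLYPHEN = "polyphen"
    CONSERVATION = "conservation"
    NONE = "none"
    EXCLUDED_CONSEQUENCE = "excluded_consequence"


@dataclass(frozen=True)
class DeleteriousnessCall:
    variant: VariantCall
    deleterious: bool
    rule_fired: Rule

    def __post_init__(self) -> None:
        if self.deleterious and self.rule_fired not in (Rule.SIFT, Rule.POLYPHEN, Rule.CONSERVATION):
            raise ValueError("deleterious call must name the rule that fired")


@dataclass
class IndividualProfile:
    """Affection state of every interactome protein for one individual.

    Proteins absent from ``state`` are unaffected.
    """

    sample: str
    population: str
    state: dict[str, AffectionState] = field(default_factory=dict)

    def affected_proteins(self, zygosity_mode: str = "recessive") -> set[str]:
        """Proteins counted as affected under the given zygosity model.

        ``recessive``: both alleles must be impaired (homozygous deleterious
        or compound het) — the set removed in the damage simulation.
        ``any_allele``: one deleterious allele suffices — the set used for
        module damage profiles.
        """
        if zygosity_mode == "recessive":
            return {p for p, s in self.state.items() if s is AffectionState.BOTH_ALLELES_AFFECTED}
        if zygosity_mode == "any_allele":
            return {p for p, s in self.state.items() if s is not AffectionState.UNAFFECTED}
        raise ValueError(f"unknown zygosity_mode: {zygosity_mode!r}")


@dataclass
class ProteinFrequencyTable:
    """Per-protein counts of affected individuals in a population.

    ``counts`` is indexed by protein with columns ``n_het_or_hom`` (number of
    individuals carrying >=1 deleterious allele in the protein) and ``n_hom``
    (both alleles affected); ``n_total`` is the population size.
    """

    counts: pd.DataFrame
    n_total: int

    def __post_init__(self) -> None:
        c = self.counts
        bad = (c["n_hom"] > c["n_het_or_hom"]) | (c["n_het_or_hom"] > self.n_total) | (c["n_hom"] < 0)
        if bad.any():
            raise ValueError("inconsistent frequency counts")


def classify_variant(
    v: VariantCall,
    sift_cmp: str = "le",
    sift_thr: float = 0.05,
    polyphen_thr: float = 0.95,
    phastcons_thr: float = 200.0,
) -> DeleteriousnessCall:
    """Apply the deleteriousness rule to one variant.

    Truncating/splicing variants are damaging iff phastCons exceeds
    ``phastcons_thr`` (the conservation score is assumed pre-scaled as in
    the annotation input).  Missense variants are damaging iff SIFT passes
    its threshold (``<=`` by default, ``<`` with ``sift_cmp="lt"``) or
    PolyPhen exceeds its threshold; a missing score simply fails its clause.
    All other consequence classes are excluded.
    """
    if sift_cmp not in ("le", "lt"):
        raise ValueError(f"unknown sift_cmp: {sift_cmp!r}")
    cons = v.consequence
    if cons not in CANDIDATE_CONSEQUENCES:
        return DeleteriousnessCall(v, False, Rule.EXCLUDED_CONSEQUENCE)
    if cons in TRUNCATING_CONSEQUENCES:
        if v.phastcons is not None and v.phastcons > phastcons_thr:
            return DeleteriousnessCall(v, True, Rule.CONSERVATION)
        return DeleteriousnessCall(v, False, Rule.NONE)
    # missense
    if v.sift is not None and (v.sift <= sift_thr if sift_cmp == "le" else v.sift < sift_thr):
        return DeleteriousnessCall(v, True, Rule.SIFT)
    if v.polyphen is not None and v.polyphen > polyphen_thr:
        return DeleteriousnessCall(v, True, Rule.POLYPHEN)
    return DeleteriousnessCall(v, False, Rule.NONE)


def build_profiles(
    calls: Iterable[DeleteriousnessCall],
    interactome: Interactome,
    manifest: Mapping[str, str],
    zygosity_mode: str = "recessive",
    lenient: bool = False,
) -> list[IndividualProfile]:
    """Reduce deleterious calls + genotypes to per-individual affection maps.

    Only ``deleterious=True`` calls whose protein is an interactome node
    contribute (others are counted and dropped).  Per individual and protein:
    a hom-alt genotype at any deleterious site, or heterozygous genotypes at
    two or more distinct deleterious sites (compound het, unphased), yields
    ``both_alleles_affected``; exactly one het deleterious site yields
    ``het_affected``.  Missing genotypes contribute nothing.

    Samples present in genotype maps but absent from the manifest raise,
    unless ``lenient`` is set (then they are skipped with a warning).
    """
    if zygosity_mode not in ("recessive", "any_allele"):
        raise ValueError(f"unknown zygosity_mode: {zygosity_mode!r}")
    n_outside = 0
    n_nondel = 0
    # (sample, protein) -> [n_hom_sites, n_het_sites]
    tallies: dict[str, dict[str, list[int]]] = {s: {} for s in manifest}
    unknown: set[str] = set()
    for call in calls:
        if not call.deleterious:
            n_nondel += 1
            continue
        v = call.variant
        if v.protein not in interactome:
            n_outside += 1
            continue
        for sample, gt in v.genotypes.items():
            if sample not in tallies:
                unknown.add(sample)
                continue
            if gt is Zygosity.HOM_ALT:
                tallies[sample].setdefault(v.protein, [0, 0])[0] += 1
            elif gt is Zygosity.HET:
                tallies[sample].setdefault(v.protein, [0, 0])[1] += 1
    if unknown:
        if not lenient:
            raise KeyError(f"samples absent from manifest: {sorted(unknown)[:5]}...")
        log.warning("skipped %d samples absent from manifest", len(unknown))
    if n_outside:
        log.info("dropped %d deleterious calls on proteins outside the interactome", n_outside)
    profiles = []
    for sample, population in manifest.items():
        state = {}
        for protein, (n_hom, n_het) in tallies[sample].items():
            if n_hom >= 1 or n_het >= 2:
                state[protein] = AffectionState.BOTH_ALLELES_AFFECTED
            elif n_het == 1:
                state[protein] = AffectionState.HET_AFFECTED
        profiles.append(IndividualProfile(sample, population, state))
    return profiles


def frequency_table(
    profiles: Sequence[IndividualProfile],
    interactome: Optional[Interactome] = None,
) -> ProteinFrequencyTable:
    """Count, per protein, individuals affected in >=1 allele and in both.

    When ``interactome`` is given, never-affected proteins appear as explicit
    zero rows.
    """
    if not profiles:
        raise ValueError("frequency_table requires at least one profile")
    proteins: set[str] = set(interactome.nodes) if interactome is not None else set()
    for p in profiles:
        proteins.update(p.state)
    index = sorted(proteins)
    counts = pd.DataFrame(0, index=pd.Index(index, name="protein"), columns=["n_het_or_hom", "n_hom"])
    for p in profiles:
        for protein, s in p.state.items():
            if s is not AffectionState.UNAFFECTED:
                counts.at[protein, "n_het_or_hom"] += 1
            if s is AffectionState.BOTH_ALLELES_AFFECTED:
                counts.at[protein, "n_hom"] += 1
    return ProteinFrequencyTable(counts, n_total=len(profiles))


def ns_s_ratio(variants: Iterable[VariantCall]) -> pd.Series:
    """Per-protein ratio of non-synonymous to synonymous variant counts.

    A crude per-protein selective-pressure proxy.  Proteins with zero
    synonymous variants get NaN (undefined — excluded downstream), never
    infinity; proteins with synonymous but no non-synonymous variants get 0.
    """
    ns: dict[str, int] = {}
    syn: dict[str, int] = {}
    for v in variants:
        if v.consequence in NONSYNONYMOUS_CONSEQUENCES:
            ns[v.protein] = ns.get(v.protein, 0) + 1
            syn.setdefault(v.protein, 0)
        elif v.consequence is Consequence.SYNONYMOUS:
            syn[v.protein] = syn.get(v.protein, 0) + 1
            ns.setdefault(v.protein, 0)
    out = {}
    for protein in syn:
        out[protein] = ns[protein] / syn[protein] if syn[protein] > 0 else math.nan
    return pd.Series(out, name="ns_s_ratio").sort_index()


# ---------------------------------------------------------------------------
# I/O: VCF + annotation TSV, merged TSV, manifest
# ---------------------------------------------------------------------------

_CONSEQUENCE_ALIASES = {
    "missense": Consequence.MISSENSE,
    "missense_variant": Consequence.MISSENSE,
    "non_synonymous": Consequence.MISSENSE,
    "nonsynonymous": Consequence.MISSENSE,
    "stop_gain": Consequence.STOP_GAIN,
    "stop_gained": Consequence.STOP_GAIN,
    "stop_loss": Consequence.STOP_LOSS,
    "stop_lost": Consequence.STOP_LOSS,
    "splice_disrupting": Consequence.SPLICE_DISRUPTING,
    "splice_acceptor_variant": Consequence.SPLICE_DISRUPTING,
    "splice_donor_variant": Consequence.SPLICE_DISRUPTING,
    "synonymous": Consequence.SYNONYMOUS,
    "synonymous_variant": Consequence.SYNONYMOUS,
}


def _parse_consequence(text: str) -> Consequence:
    return _CONSEQUENCE_ALIASES.get(text.strip().lower(), Consequence.OTHER)


def _parse_score(text: str) -> Optional[float]:
    text = (text or "").strip()
    if not text or text.upper() in ("NA", "NAN", "."):
        return None
    return float(text)


def read_annotation_tsv(path) -> dict[tuple[str, int, str, str], dict]:
    """Annotation rows keyed by (chrom, pos, ref, alt).

    Required columns: chrom, pos, ref, alt, protein, consequence; optional:
    sift, polyphen, phastcons.
    """
    out = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            out[key] = {
                "protein": row["protein"],
                "consequence": _parse_consequence(row["consequence"]),
                "sift": _parse_score(row.get("sift", "")),
                "polyphen": _parse_score(row.get("polyphen", "")),
                "phastcons": _parse_score(row.get("phastcons", "")),
            }
    return out


def read_vcf(vcf_path, annotation_path) -> list[VariantCall]:
    """Read a multi-sample VCF, split multi-allelic records per alt allele,
    and join each (chrom, pos, ref, alt) against the annotation TSV.

    Unannotated alleles are skipped with a log count.  Genotype calls use
    the GT field only; half-missing genotypes count as missing.
    """
    from cyvcf2 import VCF  # deferred: keeps import cost off the library path

    ann = read_annotation_tsv(annotation_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    calls: list[VariantCall] = []
    n_unannotated = 0
    for record in vcf:
        gts = record.genotypes  # [[a0, a1, phased], ...]
        for alt_index, alt in enumerate(record.ALT, start=1):
            key = (record.CHROM, record.POS, record.REF, alt)
            meta = ann.get(key)
            if meta is None:
                n_unannotated += 1
                continue
            genotypes = {}
            for sample, gt in zip(samples, gts):
                alleles = [a for a in gt[:-1] if a is not None]
                if len(alleles) < 2 or any(a < 0 for a in alleles):
                    genotypes[sample] = Zygosity.MISSING
                    continue
                n_alt = sum(1 for a in alleles if a == alt_index)
                if n_alt == 0:
                    genotypes[sample] = Zygosity.HOM_REF
                elif n_alt == 1:
                    genotypes[sample] = Zygosity.HET
                else:
                    genotypes[sample] = Zygosity.HOM_ALT
            calls.append(
                VariantCall(
                    chrom=record.CHROM,
                    pos=record.POS,
                    ref=record.REF,
                    alt=alt,
                    genotypes=genotypes,
                    **meta,
                )
            )
    if n_unannotated:
        log.info("skipped %d alt alleles without annotation", n_unannotated)
    return calls


_GT_STRINGS = {
    "0/0": Zygosity.HOM_REF, "0|0": Zygosity.HOM_REF,
    "0/1": Zygosity.HET, "1/0": Zygosity.HET, "0|1": Zygosity.HET, "1|0": Zygosity.HET,
    "1/1": Zygosity.HOM_ALT, "1|1": Zygosity.HOM_ALT,
}


def read_merged_tsv(path) -> list[VariantCall]:
    """Read a single merged annotated TSV.

    Fixed columns chrom, pos, ref, alt, protein, consequence, sift, polyphen,
    phastcons; every remaining column is a sample with a GT string.
    """
    fixed = {"chrom", "pos", "ref", "alt", "protein", "consequence", "sift", "polyphen", "phastcons"}
    calls = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        sample_cols = [c for c in reader.fieldnames or [] if c not in fixed]
        for row in reader:
            genotypes = {
                s: _GT_STRINGS.get(row[s].strip(), Zygosity.MISSING) for s in sample_cols
            }
            calls.append(
                VariantCall(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    protein=row["protein"],
                    consequence=_parse_consequence(row["consequence"]),
                    sift=_parse_score(row.get("sift", "")),
                    polyphen=_parse_score(row.get("polyphen", "")),
                    phastcons=_parse_score(row.get("phastcons", "")),
                    genotypes=genotypes,
                )
            )
    return calls


def read_manifest(path) -> dict[str, str]:
    """Sample manifest TSV with columns ``sample`` and ``population``."""
    out = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out[row["sample"]] = row["population"]
    return out


def write_profiles_tsv(profiles: Sequence[IndividualProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tprotein\tstate\n")
        for p in profiles:
            for protein, s in sorted(p.state.items()):
                fh.write(f"{p.sample}\t{p.population}\t{protein}\t{s.value}\n")


def write_frequency_tsv(table: ProteinFrequencyTable, path) -> None:
    df = table.counts.copy()
    df["n_total"] = table.n_total
    df.to_csv(path, sep="\t")
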