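"""Interaction evidence parsing, curation and the interactome graph.

Evidence rows (MITAB 2.5 or a plain edge-list TSV) are pooled per unordered
protein pair across source databases.  A pair becomes an edge of the curated
interactome when it is supported by at least ``min_methods`` distinct
detection methods and at least one pooled record carries an allowed
interaction type (by default ``physical association``).  This mirrors the
standard two-independent-methods curation used to suppress false-positive
interactions in literature-derived PPI networks.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx

log = logging.getLogger(__name__)

_TERM_RE = re.compile(r'psi-mi:"?(MI:\d+)"?\s*\(([^)]*)\)', re.IGNORECASE)

DEFAULT_ALLOWED_TYPES = frozenset({"physical association"})


@dataclass(frozen=True)
class InteractionRecord:
    """One row of interaction evidence.

    ``detection_methods`` identifies methods by PSI-MI term id when present,
    else by the lowercased free-text label; duplicates collapse in the set.
    """

    protein_a: str
    protein_b: str
    interaction_type: str
    detection_methods: frozenset[str]
    source_db: str = ""

    def __post_init__(self) -> None:
        if not self.protein_a or not self.protein_b:
            raise ValueError("interaction record requires two non-empty accessions")
        if not self.detection_methods:
            raise ValueError("interaction record requires at least one detection method")

    @property
    def pair(self) -> tuple[str, str]:
        """Unordered pair, canonically sorted."""
        a, b = sorted((self.protein_a, self.protein_b))
        return a, b


@dataclass
class ParseReport:
    n_rows: int = 0
    n_records: int = 0
    n_skipped: int = 0
    skip_reasons: Counter = field(default_factory=Counter)


@dataclass
class CurationReport:
    n_records: int = 0
    n_pairs: int = 0
    n_kept: int = 0
    dropped: Counter = field(default_factory=Counter)
    n_self_loops: int = 0


class Interactome:
    """Curated undirected PPI graph.

    Thin wrapper over :class:`networkx.Graph` guaranteeing no self-loops and
    no duplicate edges, carrying the curation settings as provenance.
    """

    def __init__(self, graph: Optional[nx.Graph] = None, provenance: Optional[dict] = None):
        g = nx.Graph()
        if graph is not None:
            g.add_nodes_from(graph.nodes)
            g.add_edges_from((a, b) for a, b in graph.edges if a != b)
        self.graph = g
        self.provenance = dict(provenance or {})

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]], nodes: Iterable[str] = (),
                   provenance: Optional[dict] = None) -> "Interactome":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from((a, b) for a, b in edges if a != b)
        return cls(g, provenance)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {tuple(sorted((a, b))) for a, b in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __repr__(self) -> str:
        return f"Interactome({self.n_nodes} proteins, {self.n_edges} interactions)"


def _parse_accession(field_value: str) -> Optional[str]:
    """Primary identifier from a MITAB id column (``uniprotkb:P12345|...``)."""
    if not field_value or field_value == "-":
        return None
    for token in field_value.split("|"):
        token = token.strip()
        if not token:
            continue
        if token.lower().startswith("uniprotkb:"):
            return token.split(":", 1)[1]
    token = field_value.split("|", 1)[0].strip()
    if ":" in token:
        token = token.split(":", 1)[1]
    return token or None


def _parse_terms(field_value: str) -> list[str]:
    """PSI-MI terms from a column; identity is the MI id, else the label."""
    out = []
    if not field_value or field_value == "-":
        return out
    for token in field_value.split("|"):
        m = _TERM_RE.search(token)
        if m:
            label = m.group(2).strip().lower()
            out.append(m.group(1).upper() if m.group(1) else label)
        elif token.strip():
            out.append(token.strip().lower())
    return out


def _term_labels(field_value: str) -> list[str]:
    """Human-readable labels for interaction types (``physical association``)."""
    out = []
    if not field_value or field_value == "-":
        return out
    for token in field_value.split("|"):
        m = _TERM_RE.search(token)
        if m and m.group(2).strip():
            out.append(m.group(2).strip().lower())
        elif token.strip():
            out.append(token.strip().lower())
    return out


def parse_mitab(path, dialect: str = "mitab25", strict: bool = False) -> tuple[list[InteractionRecord], ParseReport]:
    """Parse interaction evidence into records.

    Parameters
    ----------
    path
        MITAB 2.5 file (>=15 tab-separated columns) or an edge-list TSV with
        columns ``protein_a, protein_b[, type[, methods]]`` (methods
        semicolon-separated).
    dialect
        ``"mitab25"`` or ``"edgelist_tsv"``.
    strict
        Raise on malformed rows instead of logging and skipping.

    Returns
    -------
    (records, report)
        Records in file order and a :class:`ParseReport` counting skips.
    """
    if dialect not in ("mitab25", "edgelist_tsv"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    records: list[InteractionRecord] = []
    report = ParseReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            low = line.lower()
            if lineno == 1 and (low.startswith("id interactor") or low.startswith("protein_a")):
                continue  # header row
            report.n_rows += 1
            try:
                rec = _parse_row(line, dialect)
            except ValueError as exc:
                if strict:
                    raise
                report.n_skipped += 1
                report.skip_reasons[str(exc)] += 1
                log.warning("skipping row %d: %s", lineno, exc)
                continue
            if rec is None:
                report.n_skipped += 1
                report.skip_reasons["no usable accession pair"] += 1
                continue
            records.append(rec)
    report.n_records = len(records)
    return records, report


def _parse_row(line: str, dialect: str) -> Optional[InteractionRecord]:
    cols = line.split("\t")
    if dialect == "mitab25":
        if len(cols) < 15:
            raise ValueError(f"expected >=15 columns, got {len(cols)}")
        a = _parse_accession(cols[0])
        b = _parse_accession(cols[1])
        if a is None or b is None:
            return None
        methods = frozenset(_parse_terms(cols[6]))
        types = _term_labels(cols[11])
        source = _term_labels(cols[12])
        return InteractionRecord(
            protein_a=a,
            protein_b=b,
            interaction_type=types[0] if types else "",
            detection_methods=methods or frozenset({"unspecified"}),
            source_db=source[0] if source else "",
        )
    # edge-list TSV
    if len(cols) < 2:
        raise ValueError("expected >=2 columns")
    a, b = cols[0].strip(), cols[1].strip()
    if not a or not b:
        return None
    itype = cols[2].strip().lower() if len(cols) > 2 and cols[2].strip() else "physical association"
    methods = frozenset(
        m.strip().lower() for m in (cols[3].split(";") if len(cols) > 3 else []) if m.strip()
    ) or frozenset({"unspecified"})
    return InteractionRecord(a, b, itype, methods)


def curate(
    records: Iterable[InteractionRecord],
    min_methods: int = 2,
    allowed_types: Optional[frozenset[str]] = DEFAULT_ALLOWED_TYPES,
    accession_whitelist: Optional[set[str]] = None,
) -> tuple[Interactome, CurationReport]:
    """Build the curated interactome from pooled evidence.

    Evidence for the same unordered pair is pooled across all records (and
    hence across source databases) before counting distinct detection
    methods.  An edge is kept iff the pooled method set has at least
    ``min_methods`` members, at least one pooled record carries an allowed
    interaction type (``allowed_types=None`` accepts any), and, when a
    whitelist is given, both accessions are whitelisted.  Self-loops are
    removed and counted.
    """
    if min_methods < 1:
        raise ValueError("min_methods must be >= 1")
    report = CurationReport()
    pooled_methods: dict[tuple[str, str], set[str]] = {}
    pooled_types: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        report.n_records += 1
        if rec.protein_a == rec.protein_b:
            report.n_self_loops += 1
            continue
        pair = rec.pair
        pooled_methods.setdefault(pair, set()).update(rec.detection_methods)
        pooled_types.setdefault(pair, set()).add(rec.interaction_type)
    if report.n_records == 0:
        log.warning("curate called with no interaction records")
    report.n_pairs = len(pooled_methods)
    kept = []
    for pair, methods in pooled_methods.items():
        if len(methods) < min_methods:
            report.dropped["too_few_methods"] += 1
            continue
        if allowed_types is not None and not (pooled_types[pair] & allowed_types):
            report.dropped["disallowed_type"] += 1
            continue
        if accession_whitelist is not None and not (
            pair[0] in accession_whitelist and pair[1] in accession_whitelist
        ):
            report.dropped["not_whitelisted"] += 1
            continue
        kept.append(pair)
    report.n_kept = len(kept)
    provenance = {
        "min_methods": min_methods,
        "allowed_types": sorted(allowed_types) if allowed_types is not None else None,
        "whitelist_size": len(accession_whitelist) if accession_whitelist is not None else None,
    }
    return Interactome.from_edges(kept, provenance=provenance), report


def write_graph(g: Interactome, path, format: str = "edgelist_tsv") -> None:
    """Serialize the interactome; round-trips through :func:`read_graph`."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g.graph, path)
    elif format == "edgelist_tsv":
        isolated = sorted(n for n in g.graph.nodes if g.graph.degree(n) == 0)
        with open(path, "w") as fh:
            fh.write("protein_a\tprotein_b\n")
            for node in isolated:
                fh.write(f"# isolated\t{node}\n")
            for a, b in sorted(g.edges):
                fh.write(f"{a}\t{b}\n")
    else:
        raise ValueError(f"unknown format: {format!r}")


def read_graph(path, format: str = "edgelist_tsv") -> Interactome:
    """Inverse of :func:`write_graph`."""
    path = Path(path)
    if format == "graphml":
        return Interactome(nx.read_graphml(path))
    if format != "edgelist_tsv":
        raise ValueError(f"unknown format: {format!r}")
    g = nx.Graph()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.lower().startswith("protein_a"):
                continue
            if line.startswith("# isolated\t"):
                g.add_node(line.split("\t", 1)[1])
                continue
            if line.startswith("#"):
                continue
            a, b = line.split("\t")[:2]
            g.add_edge(a, b)
    return Interactome(g)


def write_curation_report(report: CurationReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("key\tcount\n")
        fh.write(f"records\t{report.n_records}\n")
        fh.write(f"pairs\t{report.n_pairs}\n")
        fh.write(f"kept\t{report.n_kept}\n")
        fh.write(f"self_loops\t{report.n_self_loops}\n")
        for reason, n in sorted(report.dropped.items()):
            fh.write(f"dropped_{reason}\t{n}\n")
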