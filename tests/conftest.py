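"""Shared fixtures: a frozen missense validation panel and small graphs."""

from __future__ import annotations

import pytest

from ppiload.interactome import Interactome
from ppiload.synth import SynthSpec, generate_interactome, generate_population

# Frozen validation panel of 20 missense variants: residue change, SIFT score
# (None = not available), PolyPhen score, expected deleteriousness verdict
# under the SIFT<=0.05 / PolyPhen>0.95 rule, expected polarity groups
# (wild, mutant) on the 0/1/2 hydrophobicity scale and expected charge
# classes (wild, mutant).
MISSENSE_PANEL = [
    # change,  sift, polyphen, deleterious, polarity, charge
    ("T503A", 0.37, 0.001, False, (1, 1), ("0", "0")),
    ("R171Q", 0.36, 0.2249, False, (2, 2), ("+", "0")),
    ("K267R", None, 0.314, False, (2, 2), ("+", "+")),
    ("A7S", 0.1, 0.0, False, (1, 1), ("0", "0")),
    ("K215R", 0.28, 0.0, False, (2, 2), ("+", "+")),
    ("L56M", 0.46, 0.003, False, (0, 0), ("0", "0")),
    ("R48K", 0.95, 0.0, False, (2, 2), ("+", "+")),
    ("P459L", 0.62, 0.397, False, (1, 0), ("0", "0")),
    ("Y623C", 0.0, 0.999, True, (0, 0), ("0", "0")),
    ("T663I", 0.0, 0.998, True, (1, 0), ("0", "0")),
    ("K700E", 0.0, 0.999, True, (2, 2), ("+", "-")),
    ("E372G", 0.0, 0.86, True, (2, 1), ("-", "0")),
    ("R374C", 0.0, 0.998, True, (2, 0), ("+", "0")),
    ("E114G", 0.0, 0.234, True, (2, 1), ("-", "0")),
    ("R251G", 0.05, 0.998, True, (2, 1), ("+", "0")),
    ("T207M", None, 0.991, True, (1, 0), ("0", "0")),
    ("E322D", 0.01, 0.998, True, (2, 2), ("-", "-")),
    ("T287M", 0.03, 0.895, True, (1, 0), ("0", "0")),
    ("C79F", 0.0, 0.999, True, (0, 0), ("0", "0")),
    ("T124I", 0.05, 0.042, True, (1, 0), ("0", "0")),
]


@pytest.fixture(scope="session")
def missense_panel():
    return MISSENSE_PANEL


@pytest.fixture
def path_graph():
    """a - b - c"""
    return Interactome.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture
def star_graph():
    """hub with 3 leaves"""
    return Interactome.from_edges([("hub", "l1"), ("hub", "l2"), ("hub", "l3")])


@pytest.fixture(scope="session")
def small_synth():
    """Deterministic small synthetic study shared across tests."""
    spec = SynthSpec(n_proteins=150, n_modules=5, n_individuals=8, seed=17)
    g, labels = generate_interactome(spec)
    return spec, g, labels


@pytest.fixture(scope="session")
def small_cohort(small_synth, tmp_path_factory):
    spec, g, _labels = small_synth
    out = tmp_path_factory.mktemp("cohort")
    data = generate_population(g, spec, out)
    return g, data
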