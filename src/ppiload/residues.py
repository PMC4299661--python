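"""Residue-level polarity-group and charge-class scoring of missense changes.

Both scores depend only on the identity of the wild-type and mutant residue.
Polarity uses a three-level hydrophobicity scale — group 0 (hydrophobic:
L I F W C M V Y), group 1 (P A T G S), group 2 (H Q R K N E D) — and charge
uses positive (R K), negative (E D) and non-charged (everything else;
histidine is scored non-charged on this scale).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

POLARITY_GROUPS: dict[int, frozenset[str]] = {
    0: frozenset("LIFWCMVY"),
    1: frozenset("PATGS"),
    2: frozenset("HQRKNED"),
}

CHARGE_CLASSES: dict[str, frozenset[str]] = {
    "+": frozenset("RK"),
    "-": frozenset("ED"),
    "0": frozenset("LIFWCMVYPATGSHQN"),
}

STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

_CHANGE_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


@dataclass(frozen=True)
class ResidueChange:
    """An amino-acid substitution in one-letter code, e.g. E372G."""

    wild: str
    mutant: str
    position: int

    def __post_init__(self) -> None:
        for aa in (self.wild, self.mutant):
            if aa not in STANDARD_AA:
                raise ValueError(f"non-standard residue: {aa!r}")
        if self.position < 1:
            raise ValueError("position must be >= 1")

    @classmethod
    def parse(cls, text: str) -> "ResidueChange":
        m = _CHANGE_RE.match(text.strip())
        if not m:
            raise ValueError(f"cannot parse residue change: {text!r}")
        return cls(wild=m.group(1).upper(), mutant=m.group(3).upper(), position=int(m.group(2)))


def _polarity_group(aa: str) -> int:
    for group, members in POLARITY_GROUPS.items():
        if aa in members:
            return group
    raise ValueError(f"non-standard residue: {aa!r}")


def _charge_class(aa: str) -> str:
    for cls, members in CHARGE_CLASSES.items():
        if aa in members:
            return cls
    raise ValueError(f"non-standard residue: {aa!r}")


def polarity_groups(rc: ResidueChange) -> tuple[int, int]:
    """Hydrophobicity-scale groups of (wild, mutant); a differing pair marks
    a polarity change."""
    return _polarity_group(rc.wild), _polarity_group(rc.mutant)


def charge_classes(rc: ResidueChange) -> tuple[str, str]:
    """Charge classes of (wild, mutant) in {'+', '-', '0'}."""
    return _charge_class(rc.wild), _charge_class(rc.mutant)
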