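"""Lipid species annotation in the ``Class(C:DB)`` shorthand.

Direct-infusion lipidomics features are annotated by lipid class, total acyl
carbons and total double bonds, e.g. ``TAG(50:1)`` is a triacylglycerol with
50 carbons and one double bond summed over its three fatty-acid chains.
``TG``/``DG`` and ``lyso-PC`` are accepted as aliases; unknown classes are
retained with class ``other``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = ["LipidSpecies", "LipidParseError", "parse_lipid_label", "format_lipid_label"]

KNOWN_CLASSES = ("LPC", "PC", "PE", "SM", "CE", "DAG", "TAG", "PI", "other")

_ALIASES = {
    "LPC": "LPC",
    "LYSO-PC": "LPC",
    "LYSOPC": "LPC",
    "PC": "PC",
    "PE": "PE",
    "SM": "SM",
    "CE": "CE",
    "DAG": "DAG",
    "DG": "DAG",
    "TAG": "TAG",
    "TG": "TAG",
    "PI": "PI",
}

# Class(C:DB), "Class C:DB" also tolerated.
_LABEL_RE = re.compile(
    r"""^\s*(?P<cls>[A-Za-z][A-Za-z0-9-]*)\s*
        (?:\(\s*(?P<c1>\d+)\s*:\s*(?P<d1>\d+)\s*\)|\s+(?P<c2>\d+)\s*:\s*(?P<d2>\d+))\s*$""",
    re.VERBOSE,
)


class LipidParseError(ValueError):
    """Raised when a feature label does not follow the Class(C:DB) dialect."""


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid annotation.

    Attributes
    ----------
    lipid_class : canonical class name (one of ``KNOWN_CLASSES``).
    carbons, double_bonds : totals over the acyl chains.
    label : the original input label.
    """

    lipid_class: str
    carbons: int
    double_bonds: int
    label: str

    def __post_init__(self) -> None:
        if self.lipid_class not in KNOWN_CLASSES:
            raise LipidParseError(f"unknown canonical class {self.lipid_class!r}")
        if self.double_bonds < 0 or self.carbons <= self.double_bonds:
            raise LipidParseError(
                f"invalid composition in {self.label!r}: need carbons > double_bonds >= 0, "
                f"got {self.carbons}:{self.double_bonds}"
            )

    @property
    def canonical(self) -> str:
        """Canonical ``Class(C:DB)`` form (class name normalized)."""
        cls = self.lipid_class if self.lipid_class != "other" else _other_class_text(self.label)
        return f"{cls}({self.carbons}:{self.double_bonds})"


def _other_class_text(label: str) -> str:
    m = _LABEL_RE.match(label)
    return m.group("cls") if m else label


def parse_lipid_label(label: str) -> LipidSpecies:
    """Parse ``Class(C:DB)`` (or ``Class C:DB``) into a :class:`LipidSpecies`.

    Unknown class names map to class ``other`` (the original class text is
    preserved in the label). Malformed carbon:double-bond parts raise
    :class:`LipidParseError` naming the offending label.
    """
    m = _LABEL_RE.match(label)
    if m is None:
        raise LipidParseError(f"cannot parse lipid label {label!r}: expected Class(C:DB)")
    cls_raw = m.group("cls")
    carbons = int(m.group("c1") or m.group("c2"))
    dbonds = int(m.group("d1") or m.group("d2"))
    lipid_class = _ALIASES.get(cls_raw.upper(), "other")
    return LipidSpecies(lipid_class=lipid_class, carbons=carbons, double_bonds=dbonds, label=label)


def format_lipid_label(species: LipidSpecies) -> str:
    """Canonical text form; ``format(parse(label))`` round-trips canonical labels."""
    return species.canonical
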