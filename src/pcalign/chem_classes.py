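"""Coarse-grained chemical typing of amino acids.

Each of the 20 standard residues is reduced to one of six classes based on
the prominent functional group of its side chain: hydrogen-bond donor
(K, R), acceptor (E, D), mixed donor/acceptor (N, Q, S, T), aromatic
(F, W), aliphatic (C, A, I, L, M, P, V, G), and mixed donor/acceptor or
aromatic (H, Y).  Classes are not mutually exclusive in the functional
groups they carry, so two residues of *different* classes can still be
matched during hashing whenever their group sets overlap (e.g. Asn can
match Arg through the shared donor group, or Asp through the shared
acceptor group).  Scoring, by contrast, uses strict class identity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ClassificationError

__all__ = [
    "ChemClass",
    "ChemLabel",
    "Group",
    "classify_residue",
    "chem_compatible",
    "same_chem",
    "STANDARD_AA",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class Group(enum.Flag):
    DONOR = enum.auto()
    ACCEPTOR = enum.auto()
    AROMATIC = enum.auto()
    ALIPHATIC = enum.auto()


class ChemLabel(enum.Enum):
    DONOR = "donor"
    ACCEPTOR = "acceptor"
    MIXED_DA = "mixed_da"
    AROMATIC = "aromatic"
    ALIPHATIC = "aliphatic"
    MIXED_DA_AROMATIC = "mixed_da_aromatic"


@dataclass(frozen=True)
class ChemClass:
    label: ChemLabel
    groups: Group

    def __str__(self) -> str:  # used in output tables
        return self.label.value


_CLASSES = {
    ChemLabel.DONOR: ChemClass(ChemLabel.DONOR, Group.DONOR),
    ChemLabel.ACCEPTOR: ChemClass(ChemLabel.ACCEPTOR, Group.ACCEPTOR),
    ChemLabel.MIXED_DA: ChemClass(ChemLabel.MIXED_DA, Group.DONOR | Group.ACCEPTOR),
    ChemLabel.AROMATIC: ChemClass(ChemLabel.AROMATIC, Group.AROMATIC),
    ChemLabel.ALIPHATIC: ChemClass(ChemLabel.ALIPHATIC, Group.ALIPHATIC),
    ChemLabel.MIXED_DA_AROMATIC: ChemClass(
        ChemLabel.MIXED_DA_AROMATIC, Group.DONOR | Group.ACCEPTOR | Group.AROMATIC
    ),
}

_AA_TO_LABEL = {}
for _aa in "KR":
    _AA_TO_LABEL[_aa] = ChemLabel.DONOR
for _aa in "ED":
    _AA_TO_LABEL[_aa] = ChemLabel.ACCEPTOR
for _aa in "NQST":
    _AA_TO_LABEL[_aa] = ChemLabel.MIXED_DA
for _aa in "FW":
    _AA_TO_LABEL[_aa] = ChemLabel.AROMATIC
for _aa in "CAILMPVG":
    _AA_TO_LABEL[_aa] = ChemLabel.ALIPHATIC
for _aa in "HY":
    _AA_TO_LABEL[_aa] = ChemLabel.MIXED_DA_AROMATIC


def classify_residue(aa: str) -> ChemClass:
    """Return the chemical class of a one-letter amino-acid code."""
    try:
        return _CLASSES[_AA_TO_LABEL[aa.upper()]]
    except KeyError:
        raise ClassificationError(f"unknown amino-acid code {aa!r}") from None


def chem_compatible(c1: ChemClass, c2: ChemClass) -> bool:
    """True iff the two classes share at least one functional group.

    Symmetric and reflexive; this is the matching rule used during
    geometric hashing ("not necessarily identical").
    """
    return bool(c1.groups & c2.groups)


def same_chem(c1: ChemClass, c2: ChemClass) -> bool:
    """Strict class identity, the indicator used in the equivalence score."""
    return c1.label is c2.label
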