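"""Residue contacts and interface extraction.

At atomic resolution two residues from different binding partners are in
contact when at least one heavy-atom pair (one atom from each residue)
lies within 4.5 A.  For Cα-only models the criterion is a Cα–Cα distance
below an amino-acid-pair-specific cutoff

    cutoff(i, j) = mean(i, j) + xi * sd(i, j)

where mean/sd are statistics of Cα–Cα distances over observed intermolecular
contacts of that residue-type pair and xi defaults to 0.5.  The table is
regenerable from any atomic structure set with `compute_cutoff_table`;
a uniform fallback table (mean 8.0 A, sd 0) keeps the package self-contained.

An :class:`Interface` is the extracted object the rest of the pipeline works
on: two fragments (A from side 1, B from side 2) of interfacial residues,
reduced to Cα coordinates with chemical classes, plus the inter-fragment
contact map.  Distance boundaries are inclusive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .chem_classes import STANDARD_AA, ChemClass, classify_residue
from .errors import (
    InsufficientDataError,
    LookupTableError,
    MissingAtomsError,
    MissingChainError,
    NoInterfaceError,
    ShapeError,
)
from .structure_io import Residue, Structure

logger = logging.getLogger(__name__)

__all__ = [
    "CutoffTable",
    "InterfaceResidue",
    "Interface",
    "heavy_atom_contact",
    "ca_cutoff",
    "compute_cutoff_table",
    "extract_interface",
    "contact_map_for",
]

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}


@dataclass
class CutoffTable:
    """Symmetric 20x20 per-residue-pair Cα–Cα contact statistics."""

    mean: np.ndarray  # (20, 20) in Angstroms
    sd: np.ndarray    # (20, 20) in Angstroms
    xi: float = 0.5

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (20, 20) or self.sd.shape != (20, 20):
            raise ShapeError("cutoff table matrices must be 20x20")
        if not (np.allclose(self.mean, self.mean.T) and np.allclose(self.sd, self.sd.T)):
            raise ShapeError("cutoff table matrices must be symmetric")
        if np.any(self.mean <= 0) or np.any(self.sd < 0) or self.xi < 0:
            raise ShapeError("cutoff table values out of range")

    @classmethod
    def uniform(cls, mean: float = 8.0, sd: float = 0.0, xi: float = 0.5) -> "CutoffTable":
        """Uniform fallback table: one cutoff for every residue-type pair."""
        return cls(np.full((20, 20), mean), np.full((20, 20), sd), xi)

    def cutoff_matrix(self) -> np.ndarray:
        return self.mean + self.xi * self.sd

    def to_text(self, path: str | Path) -> None:
        lines = [f"# xi {self.xi}"]
        for i, a in enumerate(STANDARD_AA):
            for j in range(i, 20):
                b = STANDARD_AA[j]
                lines.append(f"{a} {b} {self.mean[i, j]:.4f} {self.sd[i, j]:.4f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "CutoffTable":
        mean = np.full((20, 20), np.nan)
        sd = np.full((20, 20), np.nan)
        xi = 0.5
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2 and parts[0] == "xi":
                    xi = float(parts[1])
                continue
            a, b, m, s = line.split()
            i, j = _AA_INDEX[a], _AA_INDEX[b]
            mean[i, j] = mean[j, i] = float(m)
            sd[i, j] = sd[j, i] = float(s)
        if np.any(np.isnan(mean)):
            raise LookupTableError(f"cutoff table {path} is incomplete")
        return cls(mean, sd, xi)


@dataclass(frozen=True)
class InterfaceResidue:
    source: tuple[str, int, str, str]  # (chain_id, seq_id, icode, aa)
    ca: np.ndarray                     # (3,)
    chem: ChemClass
    fragment: str                      # "A" | "B"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ca", np.asarray(self.ca, dtype=float).reshape(3))


@dataclass
class Interface:
    """Two fragments of interfacial residues plus their contact map.

    ``residues`` lists the fragment-A block first, then fragment B;
    ``contacts`` is symmetric, all-false on the diagonal and within
    fragments, and every residue has at least one inter-fragment contact.
    """

    id: str
    residues: list[InterfaceResidue]
    contacts: np.ndarray = field(repr=False)  # (n, n) bool

    def __post_init__(self) -> None:
        self.contacts = np.asarray(self.contacts, dtype=bool)
        n = len(self.residues)
        if self.contacts.shape != (n, n):
            raise ShapeError("contact matrix shape does not match residue count")

    @property
    def coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    @property
    def fragments(self) -> np.ndarray:
        return np.array([0 if r.fragment == "A" else 1 for r in self.residues])

    @property
    def n_a(self) -> int:
        return int(np.sum(self.fragments == 0))

    @property
    def n_b(self) -> int:
        return int(np.sum(self.fragments == 1))

    def __len__(self) -> int:
        return len(self.residues)

    def validate(self) -> None:
        if self.n_a == 0 or self.n_b == 0:
            raise NoInterfaceError("interface has an empty fragment")
        if not np.array_equal(self.contacts, self.contacts.T):
            raise ShapeError("contact map must be symmetric")
        frag = self.fragments
        same = frag[:, None] == frag[None, :]
        if np.any(self.contacts & same):
            raise ShapeError("contact map has intra-fragment contacts")
        if np.any(~self.contacts.any(axis=1)):
            raise NoInterfaceError("interface has a residue with no inter-fragment contact")


def _heavy_coords(r: Residue) -> np.ndarray:
    if not r.atoms:
        raise MissingAtomsError(f"residue {r.key} has no atoms")
    return np.array([a.coord for a in r.atoms])


def heavy_atom_contact(r1: Residue, r2: Residue, cutoff: float = 4.5) -> bool:
    """True iff any heavy-atom pair across the two residues is within ``cutoff``."""
    d = cdist(_heavy_coords(r1), _heavy_coords(r2))
    return bool(d.min() <= cutoff)


def ca_cutoff(aa1: str, aa2: str, table: CutoffTable) -> float:
    """Type-dependent Cα–Cα contact cutoff: mean + xi * sd.  Symmetric."""
    try:
        i, j = _AA_INDEX[aa1.upper()], _AA_INDEX[aa2.upper()]
    except KeyError as exc:
        raise LookupTableError(f"amino-acid code not in cutoff table: {exc}") from None
    return float(table.mean[i, j] + table.xi * table.sd[i, j])


def compute_cutoff_table(structures: list[Structure], heavy_cutoff: float = 4.5,
                         xi: float = 0.5) -> CutoffTable:
    """Regenerate the Cα–Cα cutoff table from atomic structures.

    Every inter-chain residue pair in heavy-atom contact contributes its
    Cα–Cα distance, pooled by unordered amino-acid-type pair.  Pairs with
    fewer than two observations are filled with the global mean/sd over all
    observations (logged).  Sample statistics use ddof=1.
    """
    atomic = [s for s in structures if s.mode == "atomic"]
    if not atomic:
        raise InsufficientDataError("no atomic-mode structures to derive cutoffs from")
    samples: dict[tuple[int, int], list[float]] = {}
    for s in atomic:
        cids = list(s.chains)
        for a_i in range(len(cids)):
            for b_i in range(a_i + 1, len(cids)):
                for r1 in s.chains[cids[a_i]]:
                    if r1.ca is None:
                        continue
                    for r2 in s.chains[cids[b_i]]:
                        if r2.ca is None:
                            continue
                        if heavy_atom_contact(r1, r2, heavy_cutoff):
                            i, j = sorted((_AA_INDEX[r1.aa], _AA_INDEX[r2.aa]))
                            d = float(np.linalg.norm(r1.ca - r2.ca))
                            samples.setdefault((i, j), []).append(d)
    if not samples:
        raise InsufficientDataError("no intermolecular contacts observed")
    all_d = np.concatenate([np.asarray(v) for v in samples.values()])
    g_mean = float(all_d.mean())
    g_sd = float(all_d.std(ddof=1)) if all_d.size > 1 else 0.0
    mean = np.full((20, 20), g_mean)
    sd = np.full((20, 20), g_sd)
    n_filled = 210
    for (i, j), vals in samples.items():
        if len(vals) < 2:
            continue
        v = np.asarray(vals)
        mean[i, j] = mean[j, i] = float(v.mean())
        sd[i, j] = sd[j, i] = float(v.std(ddof=1))
        n_filled -= 1
    if n_filled:
        logger.info("cutoff table: %d residue-type pairs filled with global mean %.2f / sd %.2f",
                    n_filled, g_mean, g_sd)
    return CutoffTable(mean, sd, xi)


def _resolve_mode(s: Structure, mode: str) -> str:
    if mode == "auto":
        return s.mode
    if mode not in ("atomic", "ca_only"):
        raise ValueError(f"unknown mode {mode!r}")
    return mode


def extract_interface(s: Structure, chains1, chains2, mode: str = "auto",
                      table: CutoffTable | None = None, heavy_cutoff: float = 4.5,
                      interface_id: str | None = None) -> Interface:
    """Extract the interface between two disjoint chain sets of a complex.

    Contacts are decided with the heavy-atom criterion in atomic mode and
    the type-dependent Cα cutoff in Cα-only mode.  The result keeps only
    Cα coordinates; fragment A holds side-1 residues, fragment B side 2.
    """
    chains1, chains2 = set(chains1), set(chains2)
    if chains1 & chains2:
        raise MissingChainError("the two chain sets must be disjoint")
    for cid in chains1 | chains2:
        if cid not in s.chains:
            raise MissingChainError(f"chain {cid!r} not present in structure {s.id!r}")
    eff_mode = _resolve_mode(s, mode)
    if table is None:
        table = CutoffTable.uniform()

    side1 = s.residues(sorted(chains1))
    side2 = s.residues(sorted(chains2))
    if eff_mode == "atomic":
        contact = np.zeros((len(side1), len(side2)), dtype=bool)
        for i, r1 in enumerate(side1):
            for j, r2 in enumerate(side2):
                contact[i, j] = heavy_atom_contact(r1, r2, heavy_cutoff)
    else:
        ca1 = np.array([r.ca if r.ca is not None else [np.nan] * 3 for r in side1])
        ca2 = np.array([r.ca if r.ca is not None else [np.nan] * 3 for r in side2])
        cmat = table.cutoff_matrix()
        idx1 = np.array([_AA_INDEX[r.aa] for r in side1])
        idx2 = np.array([_AA_INDEX[r.aa] for r in side2])
        with np.errstate(invalid="ignore"):
            contact = cdist(ca1, ca2) <= cmat[np.ix_(idx1, idx2)]

    keep1 = np.where(contact.any(axis=1))[0]
    keep2 = np.where(contact.any(axis=0))[0]
    if keep1.size == 0 or keep2.size == 0:
        raise NoInterfaceError(
            f"no inter-chain contacts between {sorted(chains1)} and {sorted(chains2)}"
        )

    residues: list[InterfaceResidue] = []
    for idx, frag in ((keep1, "A"), (keep2, "B")):
        pool = side1 if frag == "A" else side2
        for k in idx:
            r = pool[k]
            if r.ca is None:
                raise MissingAtomsError(f"interfacial residue {r.key} lacks a CA atom")
            residues.append(InterfaceResidue(
                (r.chain_id, r.seq_id, r.icode, r.aa), r.ca, classify_residue(r.aa), frag))
    n1 = keep1.size
    n = n1 + keep2.size
    contacts = np.zeros((n, n), dtype=bool)
    sub = contact[np.ix_(keep1, keep2)]
    contacts[:n1, n1:] = sub
    contacts[n1:, :n1] = sub.T
    iface = Interface(
        id=interface_id or f"{s.id}:{'+'.join(sorted(chains1))}-{'+'.join(sorted(chains2))}",
        residues=residues,
        contacts=contacts,
    )
    iface.validate()
    return iface


def contact_map_for(iface: Interface, subset) -> np.ndarray:
    """Restriction of the interface contact map to ``subset`` in subset order."""
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        return np.zeros((0, 0), dtype=bool)
    n = len(iface.residues)
    if subset.min() < 0 or subset.max() >= n:
        raise IndexError("subset index out of range")
    if len(set(subset.tolist())) != subset.size:
        raise IndexError("subset indices must be unique")
    return iface.contacts[np.ix_(subset, subset)]
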