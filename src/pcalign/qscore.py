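"""Q-score for quasi-equivalent capsid interfaces.

Icosahedral capsids with triangulation number T > 1 tile the shell with
T x 60 copies of one protein, so chemically identical subunits form
several distinct, "quasi-equivalent" interaction modes.  Because both
binding partners share one sequence, each interface can be written as an
N x N boolean contact map over residue positions (N = protein length),
and two interfaces compare directly through the normalized inner product

    Q = 2 <Na, Nb> / (<Na, Na> + <Nb, Nb>)

which is 1 for identical interfaces and 0 for interfaces sharing no
contact.  Contact maps here are built with the same atomic / Cα-cutoff
criteria used for interface extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DataError, MissingChainError, ShapeError
from .interface_extract import CutoffTable, _AA_INDEX, heavy_atom_contact
from .structure_io import Structure

__all__ = ["CapsidContactMap", "q_score", "capsid_contact_map", "check_same_sequence"]


@dataclass
class CapsidContactMap:
    """Residue-position contact map between two same-sequence subunits.

    Entry (i, j) is True iff residue position i+1 of subunit 1 contacts
    residue position j+1 of subunit 2.  Not required to be symmetric: the
    two subunits are distinct molecules.
    """

    n: int
    map: np.ndarray  # (n, n) bool

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=bool)
        if self.map.shape != (self.n, self.n):
            raise ShapeError("contact map must be n x n")


def q_score(a: CapsidContactMap, b: CapsidContactMap) -> float:
    """Normalized inner product of two capsid interface contact maps."""
    if a.n != b.n:
        raise ShapeError(f"contact map dimensions differ: {a.n} vs {b.n}")
    na = float(np.sum(a.map))
    nb = float(np.sum(b.map))
    if na == 0 and nb == 0:
        raise DataError("both contact maps are empty; Q-score undefined")
    return 2.0 * float(np.sum(a.map & b.map)) / (na + nb)


def _chain(s: Structure, cid: str):
    if cid not in s.chains:
        raise MissingChainError(f"chain {cid!r} not present in structure {s.id!r}")
    return s.chains[cid]


def check_same_sequence(s1: Structure, c1: str, s2: Structure, c2: str) -> None:
    """Verify the two chains agree in amino-acid type at shared residue numbers."""
    seq1 = {r.seq_id: r.aa for r in _chain(s1, c1)}
    seq2 = {r.seq_id: r.aa for r in _chain(s2, c2)}
    shared = set(seq1) & set(seq2)
    if not shared:
        raise DataError(f"chains {c1} and {c2} share no residue numbers")
    bad = [i for i in shared if seq1[i] != seq2[i]]
    if bad:
        raise DataError(
            f"chains {c1} and {c2} differ at residue(s) {sorted(bad)[:5]}; "
            "Q-score requires identical subunit sequences"
        )


def capsid_contact_map(s: Structure, chain1: str, chain2: str, mode: str = "auto",
                       table: CutoffTable | None = None, heavy_cutoff: float = 4.5,
                       n: int | None = None) -> CapsidContactMap:
    """Contact map between two subunit chains, indexed by residue number.

    ``n`` fixes the matrix dimension (protein length); by default it is the
    largest residue number seen in either chain.  Contacts use the
    heavy-atom criterion in atomic mode, the per-type Cα cutoff otherwise.
    """
    res1 = _chain(s, chain1)
    res2 = _chain(s, chain2)
    eff_mode = s.mode if mode == "auto" else mode
    if table is None:
        table = CutoffTable.uniform()
    if n is None:
        n = max(r.seq_id for r in res1 + res2)
    m = np.zeros((n, n), dtype=bool)
    if eff_mode == "atomic":
        for r1 in res1:
            for r2 in res2:
                if r1.seq_id <= n and r2.seq_id <= n and heavy_atom_contact(r1, r2, heavy_cutoff):
                    m[r1.seq_id - 1, r2.seq_id - 1] = True
    else:
        keep1 = [r for r in res1 if r.ca is not None and r.seq_id <= n]
        keep2 = [r for r in res2 if r.ca is not None and r.seq_id <= n]
        if keep1 and keep2:
            d = cdist(np.array([r.ca for r in keep1]), np.array([r.ca for r in keep2]))
            cm = table.cutoff_matrix()
            i1 = np.array([_AA_INDEX[r.aa] for r in keep1])
            i2 = np.array([_AA_INDEX[r.aa] for r in keep2])
            hit = d <= cm[np.ix_(i1, i2)]
            for (a, b) in zip(*np.nonzero(hit)):
                m[keep1[a].seq_id - 1, keep2[b].seq_id - 1] = True
    return CapsidContactMap(n, m)
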