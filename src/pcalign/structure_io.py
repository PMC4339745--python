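"""PDB reading/writing and resolution-mode detection.

Structures are reduced to a minimal representation: heavy atoms only,
one-letter residue codes, one conformation per residue.  The package works
at two resolutions — full atomic models, and coarse "Cα-only" traces typical
of low-resolution cryo-EM — and `detect_resolution_mode` decides which
contact criterion applies to a given model.

Parsing goes through gemmi; output PDB files (transformed Cα traces) are
written directly in fixed-column PDB format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import gemmi
import numpy as np

from .errors import (
    EmptyStructureError,
    MissingChainError,
    MissingModelError,
    ParseError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .interface_extract import Interface
    from .score import AlignmentResult

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "read_structure",
    "detect_resolution_mode",
    "write_ca_pdb",
    "write_alignment",
    "THREE_TO_ONE",
]

# 20 standard residues plus the nonstandard ones we keep (mapped onto the
# standard alphabet); any other residue name is dropped with a warning.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "C", "PYL": "K",
}

ONE_TO_THREE = {v: k for k, v in list(THREE_TO_ONE.items())[:20]}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: np.ndarray  # (3,) in Angstroms

    def __post_init__(self) -> None:
        c = np.asarray(self.coord, dtype=float).reshape(3)
        if not np.all(np.isfinite(c)):
            raise ValueError("atom coordinate is not finite")
        object.__setattr__(self, "coord", c)


@dataclass
class Residue:
    chain_id: str
    seq_id: int
    icode: str
    aa: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def ca(self) -> np.ndarray | None:
        for a in self.atoms:
            if a.name == "CA":
                return a.coord
        return None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    def has_side_chain(self) -> bool:
        return any(a.name not in _BACKBONE for a in self.atoms)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]]
    mode: str = "atomic"  # "atomic" | "ca_only"

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def residues(self, chain_ids: Iterable[str] | None = None) -> list[Residue]:
        if chain_ids is None:
            chain_ids = self.chains.keys()
        out: list[Residue] = []
        for cid in chain_ids:
            if cid not in self.chains:
                raise MissingChainError(f"chain {cid!r} not present in structure {self.id!r}")
            out.extend(self.chains[cid])
        return out


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties prefer altloc 'A', then alphabetic order
    return max(atoms, key=lambda a: (a.occ, a.altloc in ("A", "", "\0"), -ord(a.altloc or "A")))


def read_structure(path: str | Path, model_index: int = 0) -> "Structure":
    """Read a PDB file into a reduced heavy-atom :class:`Structure`.

    Hydrogens and waters are removed, alternate locations are resolved to
    the highest-occupancy conformer (ties prefer altloc 'A'), and HETATM
    records are dropped except for MSE/SEC/PYL which are mapped onto the
    standard alphabet.  Only ``model_index`` (default: first model) is kept.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"could not parse {path}: {exc}") from exc
    st.remove_hydrogens()
    st.remove_waters()
    if len(st) == 0:
        raise EmptyStructureError(f"{path} contains no coordinates")
    if model_index >= len(st):
        raise MissingModelError(
            f"model {model_index} requested but {path} has {len(st)} model(s)"
        )
    model = st[model_index]

    chains: dict[str, list[Residue]] = {}
    seen: set[tuple[str, int, str]] = set()
    for chain in model:
        for res in chain:
            name = res.name.strip().upper()
            aa = THREE_TO_ONE.get(name)
            if aa is None:
                logger.warning("dropping nonstandard residue %s %s%s", name, chain.name, res.seqid.num)
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                if atom.element.is_hydrogen:
                    continue
                by_name.setdefault(atom.name, []).append(atom)
            atoms = []
            for aname, group in by_name.items():
                g = _pick_altloc(group)
                atoms.append(Atom(aname, g.element.name, np.array([g.pos.x, g.pos.y, g.pos.z])))
            if not atoms:
                continue
            icode = res.seqid.icode.strip() if res.seqid.icode else ""
            key = (chain.name, res.seqid.num, icode)
            if key in seen:
                continue
            seen.add(key)
            chains.setdefault(chain.name, []).append(
                Residue(chain.name, res.seqid.num, icode, aa, atoms)
            )
    for cid in chains:
        chains[cid].sort(key=lambda r: (r.seq_id, r.icode))
    if not chains:
        raise EmptyStructureError(f"{path} contains no standard amino-acid ATOM records")
    s = Structure(id=path.stem, chains=chains)
    s.mode = detect_resolution_mode(s)
    return s


def detect_resolution_mode(s: Structure) -> str:
    """Classify a structure as ``atomic`` or ``ca_only``.

    A model is Cα-only when fewer than half of its non-glycine residues
    carry at least one side-chain heavy atom.  Glycine has no side chain
    and is excluded from the denominator.
    """
    residues = s.residues()
    if not residues:
        raise EmptyStructureError("structure has no residues")
    non_gly = [r for r in residues if r.aa != "G"]
    if not non_gly:
        # all-glycine trace: fall back to counting any non-CA atoms
        with_more = sum(1 for r in residues if len(r.atoms) > 1)
        return "atomic" if with_more / len(residues) >= 0.5 else "ca_only"
    with_sc = sum(1 for r in non_gly if r.has_side_chain())
    return "ca_only" if with_sc / len(non_gly) < 0.5 else "atomic"


def _pdb_atom_line(serial: int, name: str, aa3: str, chain: str, seq: int,
                   icode: str, coord: np.ndarray, element: str) -> str:
    name_f = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:>5d} {name_f}{'':1s}{aa3:>3s} {chain:1s}{seq:>4d}{icode or ' ':1s}"
        f"   {coord[0]:8.3f}{coord[1]:8.3f}{coord[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_ca_pdb(records: list[tuple[str, int, str, str, np.ndarray]], path: str | Path) -> None:
    """Write Cα records (chain, seq_id, icode, aa, coord) as a PDB file."""
    lines = []
    prev_chain = None
    serial = 0
    for chain, seq, icode, aa, coord in records:
        if prev_chain is not None and chain != prev_chain:
            lines.append("TER")
        prev_chain = chain
        serial += 1
        lines.append(_pdb_atom_line(serial, "CA", ONE_TO_THREE.get(aa, "UNK"), chain, seq, icode, coord, "C"))
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write a Structure (all retained heavy atoms) in PDB format."""
    lines = []
    serial = 0
    for cid, residues in s.chains.items():
        for r in residues:
            for a in r.atoms:
                serial += 1
                lines.append(_pdb_atom_line(serial, a.name, ONE_TO_THREE.get(r.aa, "UNK"),
                                            cid, r.seq_id, r.icode, a.coord, a.element))
        lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def structure_ca_records(s: Structure) -> list[tuple[str, int, str, str, np.ndarray]]:
    recs = []
    for cid, residues in s.chains.items():
        for r in residues:
            if r.ca is not None:
                recs.append((cid, r.seq_id, r.icode, r.aa, r.ca))
    return recs


def _relabel(chain: str, taken: set[str]) -> str:
    if chain not in taken:
        return chain
    for c in "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789":
        if c not in taken:
            return c
    raise ValueError("ran out of chain labels")


def write_alignment(result: "AlignmentResult", i1: "Interface", i2: "Interface",
                    out_prefix: str | Path) -> tuple[Path, Path]:
    """Write the superposed Cα trace of interface 2 and the residue table.

    Produces ``<prefix>.pdb`` — interface 2's Cα records transformed by the
    alignment (chains relabeled to avoid clashing with interface 1) — and
    ``<prefix>.tsv`` — the matched-pair correspondence table with the score
    summary in '#'-prefixed header lines.
    """
    out_prefix = Path(out_prefix)
    pdb_path = out_prefix.with_suffix(".pdb")
    tsv_path = out_prefix.with_suffix(".tsv")

    chains1 = {r.source[0] for r in i1.residues}
    relabel: dict[str, str] = {}
    taken = set(chains1)
    records = []
    for r in i2.residues:
        cid = r.source[0]
        if cid not in relabel:
            relabel[cid] = _relabel(cid, taken)
            taken.add(relabel[cid])
        records.append((relabel[cid], r.source[1], r.source[2], r.source[3],
                        result.transform.apply(r.ca)))
    write_ca_pdb(records, pdb_path)

    hdr = [
        f"# PC-score\t{result.pc:.6f}",
        f"# PC-score_raw\t{result.pc_raw:.6f}",
        f"# f_c\t{result.f_c:.6f}",
        f"# L_ali\t{result.l_ali}",
        f"# L_ave\t{result.l_ave:.1f}",
        f"# coverage\t{result.coverage:.6f}",
        f"# RMSD\t{result.rmsd:.6f}",
        "chain1\tresnum1\taa1\tchem1\tchain2\tresnum2\taa2\tchem2\t"
        "distance_A\tsame_chem_flag\tequivalence_score",
    ]
    rows = []
    for p in result.pairs:
        r1 = i1.residues[p.idx1]
        r2 = i2.residues[p.idx2]
        rows.append(
            f"{r1.source[0]}\t{r1.source[1]}\t{r1.source[3]}\t{r1.chem}\t"
            f"{r2.source[0]}\t{r2.source[1]}\t{r2.source[3]}\t{r2.chem}\t"
            f"{p.d:.3f}\t{p.same_chem}\t{p.eq_score:.4f}"
        )
    tsv_path.write_text("\n".join(hdr + rows) + "\n")
    return pdb_path, tsv_path
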