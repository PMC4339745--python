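"""Seeded synthetic data: interfaces, rigid copies, noisy backbones, backgrounds.

The generator emulates the geometry of real protein-protein interfaces at
the coarse-grained level the pipeline works at: two roughly planar patches
of Cα positions (fragments A and B) facing each other across a ~5 A gap,
with residue density near one residue per 25 A^2, random side-chain
chemistry, and an 8 A Cα–Cα inter-fragment contact criterion.  Sizes of
10-100 residues per side cover the range of real interfaces; everything is
reproducible from (spec, seed).

`perturb_backbone` implements the corruption protocol used to emulate
low-resolution models: all non-Cα atoms are discarded and each Cα is
displaced along an independent uniform random direction by a half-normal
magnitude |N(0, sigma^2)| with sigma defaulting to 1 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .chem_classes import ChemLabel, classify_residue
from .errors import GenerationError
from .interface_extract import Interface, InterfaceResidue
from .structure_io import Atom, Residue, Structure
from .transforms import RigidTransform

__all__ = [
    "FixtureSpec",
    "generate_synthetic_interface",
    "generate_unrelated_pair",
    "apply_random_rigid",
    "perturb_backbone",
    "make_synthetic_complex",
    "background_scores",
]

CONTACT_RADIUS = 8.0   # A, Cα–Cα criterion used for generated interfaces
_GAP = 5.0             # A, mean separation between the two fragment patches
_THICKNESS = 3.0       # A, half-depth of each fragment's Cα shell

# residues available per class, used to turn class weights into sequences
_CLASS_MEMBERS = {
    ChemLabel.DONOR: "KR",
    ChemLabel.ACCEPTOR: "ED",
    ChemLabel.MIXED_DA: "NQST",
    ChemLabel.AROMATIC: "FW",
    ChemLabel.ALIPHATIC: "CAILMPVG",
    ChemLabel.MIXED_DA_AROMATIC: "HY",
}
_CLASS_ORDER = list(_CLASS_MEMBERS)
# default class weights proportional to class size (uniform over residues)
_DEFAULT_WEIGHTS = np.array([len(_CLASS_MEMBERS[c]) for c in _CLASS_ORDER], dtype=float)
_DEFAULT_WEIGHTS /= _DEFAULT_WEIGHTS.sum()


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic interface."""

    n_per_fragment: int = 20
    spacing: float = 5.0               # A, minimum Cα–Cα separation within a patch
    contact_fraction: float | None = None  # target fraction of cross pairs in contact;
                                           # None = density-determined (≈ 4.9 / n)
    chem_distribution: tuple[float, ...] | None = None  # weights over the 6 classes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_fragment < 3:
            raise GenerationError("need at least 3 residues per fragment")
        if self.spacing <= 0:
            raise GenerationError("spacing must be positive")
        if self.contact_fraction is not None and not 0 < self.contact_fraction <= 1:
            raise GenerationError("contact_fraction must be in (0, 1]")


def _sample_patch(rng: np.random.Generator, n: int, ext_x: float, ext_y: float,
                  spacing: float) -> np.ndarray:
    """Chain-like placement of n xy points in an ext_x * ext_y patch.

    Residues are laid down along gently curling strand segments with a
    fixed virtual-bond step, the way interfacial residues of a real chain
    sit on secondary-structure fragments; segments keep a minimum lateral
    separation from one another.  The resulting point sets are sparse and
    anisotropic, so independently generated interfaces superpose poorly —
    unlike uniformly dense patches, which are trivially alignable.
    """
    step = max(3.8, spacing)
    cross_sep = 1.1 * step
    pts: list[np.ndarray] = []
    guard = 0
    while len(pts) < n:
        guard += 1
        if guard > 40 * n:  # relax so generation always terminates
            cross_sep *= 0.9
            guard = 0
        start = rng.uniform((0.0, 0.0), (ext_x, ext_y))
        if pts and np.min(np.linalg.norm(np.asarray(pts) - start, axis=1)) < cross_sep:
            continue
        theta = rng.uniform(0.0, 2.0 * np.pi)
        seg_len = int(rng.integers(3, 9))
        seg = [start]
        p = start
        while len(seg) < seg_len and len(pts) + len(seg) < n:
            theta += rng.normal(0.0, 0.20)
            cand = p + step * np.array([np.cos(theta), np.sin(theta)])
            if not (0 <= cand[0] <= ext_x and 0 <= cand[1] <= ext_y):
                break
            others = pts + seg[:-1]
            if others and np.min(np.linalg.norm(np.asarray(others) - cand, axis=1)) < cross_sep:
                break
            seg.append(cand)
            p = cand
        pts.extend(seg)
    return np.asarray(pts[:n])


def _curvature(rng: np.random.Generator, center: np.ndarray):
    """A random gentle quadratic height field shared by both fragments.

    Gives each seed its own surface shape so that independently generated
    interfaces are genuinely dissimilar, as unrelated real interfaces are.
    """
    cxx, cyy = rng.uniform(-0.06, 0.06, size=2)
    cxy = rng.uniform(-0.03, 0.03)

    def q(xy: np.ndarray) -> np.ndarray:
        u = xy[:, 0] - center[0]
        v = xy[:, 1] - center[1]
        return cxx * u * u + cyy * v * v + cxy * u * v

    return q


def _sample_sequence(rng: np.random.Generator, n: int, weights) -> list[str]:
    w = np.asarray(weights if weights is not None else _DEFAULT_WEIGHTS, dtype=float)
    if w.shape != (6,) or np.any(w < 0) or w.sum() <= 0:
        raise GenerationError("chem_distribution must be 6 non-negative weights")
    w = w / w.sum()
    classes = rng.choice(6, size=n, p=w)
    return [
        _CLASS_MEMBERS[_CLASS_ORDER[c]][rng.integers(len(_CLASS_MEMBERS[_CLASS_ORDER[c]]))]
        for c in classes
    ]


def generate_synthetic_interface(spec: FixtureSpec) -> Interface:
    """Generate a random interface satisfying every Interface invariant.

    Fragment A sits in a jittered patch near z = 0, fragment B in a parallel
    patch offset by ~5 A; the patch extent is chosen so that approximately
    ``contact_fraction`` of the cross pairs fall within the 8 A Cα contact
    radius.  Residues left without an inter-fragment contact are pulled
    toward their nearest partner, guaranteeing no orphans.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_fragment
    f = spec.contact_fraction if spec.contact_fraction is not None else min(0.9, 4.9 / n)
    rho = float(np.sqrt(CONTACT_RADIUS ** 2 - _GAP ** 2))
    extent = max(rho * np.sqrt(np.pi / f), spec.spacing * np.sqrt(n))
    extent *= rng.uniform(0.9, 1.25)   # per-seed packing-density variation
    aspect = rng.uniform(0.6, 1.7)     # per-seed footprint elongation
    ext_x, ext_y = extent * aspect, extent / aspect
    a_xy = _sample_patch(rng, n, ext_x, ext_y, spec.spacing)
    b_xy = _sample_patch(rng, n, ext_x, ext_y, spec.spacing)
    q = _curvature(rng, np.array([ext_x / 2, ext_y / 2]))
    a = np.column_stack([a_xy, q(a_xy) + rng.uniform(-_THICKNESS, _THICKNESS, size=n)])
    b = np.column_stack([b_xy, q(b_xy) + _GAP + rng.uniform(-_THICKNESS, _THICKNESS, size=n)])

    # pull orphaned residues toward their nearest cross-fragment neighbour
    for _ in range(10):
        d = cdist(a, b)
        contact = d <= CONTACT_RADIUS
        orphan_a = np.where(~contact.any(axis=1))[0]
        orphan_b = np.where(~contact.any(axis=0))[0]
        if orphan_a.size == 0 and orphan_b.size == 0:
            break
        for i in orphan_a:
            j = int(np.argmin(d[i]))
            a[i] = b[j] + (a[i] - b[j]) * (CONTACT_RADIUS - 0.5) / d[i, j]
        d = cdist(a, b)
        for j in orphan_b:
            i = int(np.argmin(d[:, j]))
            b[j] = a[i] + (b[j] - a[i]) * (CONTACT_RADIUS - 0.5) / d[i, j]

    d = cdist(a, b)
    contact = d <= CONTACT_RADIUS
    if not (contact.any(axis=1).all() and contact.any(axis=0).all()):
        raise GenerationError(f"could not satisfy contact invariants for {spec}")

    seq = _sample_sequence(rng, 2 * n, spec.chem_distribution)
    residues = []
    for k in range(n):
        residues.append(InterfaceResidue(("A", k + 1, "", seq[k]), a[k],
                                         classify_residue(seq[k]), "A"))
    for k in range(n):
        residues.append(InterfaceResidue(("B", k + 1, "", seq[n + k]), b[k],
                                         classify_residue(seq[n + k]), "B"))
    contacts = np.zeros((2 * n, 2 * n), dtype=bool)
    contacts[:n, n:] = contact
    contacts[n:, :n] = contact.T
    iface = Interface(id=f"synthetic-seed{spec.seed}-n{n}", residues=residues,
                      contacts=contacts)
    iface.validate()
    return iface


def generate_unrelated_pair(n1: int, n2: int, seed: int) -> tuple[Interface, Interface]:
    """Two independently generated interfaces (distinct sub-seeds)."""
    i1 = generate_synthetic_interface(FixtureSpec(n_per_fragment=n1, seed=2 * seed + 1))
    i2 = generate_synthetic_interface(FixtureSpec(n_per_fragment=n2, seed=2 * seed + 2))
    return i1, i2


def apply_random_rigid(iface: Interface, seed: int) -> tuple[Interface, RigidTransform]:
    """Rigidly move an interface by a random proper rotation + translation.

    Returns the transformed copy and the ground-truth transform T with
    ``new_coords = T.apply(old_coords)``.  The contact map is unchanged.
    """
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    transform = RigidTransform(R, t)
    residues = [replace(r, ca=transform.apply(r.ca)) for r in iface.residues]
    moved = Interface(id=f"{iface.id}-rigid{seed}", residues=residues,
                      contacts=iface.contacts.copy())
    return moved, transform


def _displace(coords: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    n = len(coords)
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    magnitude = np.abs(rng.normal(0.0, sigma, size=n)) if sigma > 0 else np.zeros(n)
    return coords + direction * magnitude[:, None]


def perturb_backbone(obj, sigma: float = 1.0, seed: int = 0):
    """Corrupt a Structure or Interface to a noisy Cα-only version.

    Each Cα moves along an independent uniform random unit vector by a
    half-normal magnitude |N(0, sigma^2)|; all non-Cα atoms are dropped
    first.  For an Interface the contact map (defined before corruption)
    is kept.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    if isinstance(obj, Interface):
        coords = _displace(obj.coords, sigma, rng)
        residues = [replace(r, ca=c) for r, c in zip(obj.residues, coords)]
        return Interface(id=f"{obj.id}-perturbed", residues=residues,
                         contacts=obj.contacts.copy())
    if isinstance(obj, Structure):
        chains: dict[str, list[Residue]] = {}
        for cid, residues in obj.chains.items():
            kept = [r for r in residues if r.ca is not None]
            coords = _displace(np.array([r.ca for r in kept]), sigma, rng)
            chains[cid] = [
                Residue(r.chain_id, r.seq_id, r.icode, r.aa,
                        [Atom("CA", "C", c)])
                for r, c in zip(kept, coords)
            ]
        return Structure(id=f"{obj.id}-perturbed", chains=chains, mode="ca_only")
    raise TypeError(f"cannot perturb object of type {type(obj).__name__}")


def make_synthetic_complex(n_per_chain: int = 8, seed: int = 0,
                           ca_only: bool = False, gap: float = _GAP) -> Structure:
    """A small two-chain Structure for structure-level tests and demos.

    Chains A and B are parallel jittered strands facing each other across
    ``gap``; in atomic mode each residue carries N, CA, C, O backbone atoms
    plus a CB-like side-chain atom pointing at the partner chain, so the
    heavy-atom contact criterion has something to bite on.
    """
    rng = np.random.default_rng(seed)
    seq = _sample_sequence(rng, 2 * n_per_chain, None)
    chains: dict[str, list[Residue]] = {"A": [], "B": []}
    for ci, cid in enumerate(("A", "B")):
        z = 0.0 if ci == 0 else gap
        sign = 1.0 if ci == 0 else -1.0
        for k in range(n_per_chain):
            ca = np.array([3.8 * k + rng.uniform(-0.3, 0.3),
                           rng.uniform(-0.5, 0.5), z + rng.uniform(-0.3, 0.3)])
            aa = seq[ci * n_per_chain + k]
            if ca_only:
                atoms = [Atom("CA", "C", ca)]
            else:
                atoms = [
                    Atom("N", "N", ca + [-1.4, 0.4, 0.0]),
                    Atom("CA", "C", ca),
                    Atom("C", "C", ca + [1.4, 0.4, 0.0]),
                    Atom("O", "O", ca + [1.8, 1.5, 0.0]),
                ]
                if aa != "G":
                    atoms.append(Atom("CB", "C", ca + [0.0, 0.0, sign * 1.5]))
            chains[cid].append(Residue(cid, k + 1, "", aa, atoms))
    return Structure(id=f"synthetic-complex-seed{seed}",
                     chains=chains, mode="ca_only" if ca_only else "atomic")


def background_scores(n: int = 1000, seed: int = 0, size_range: tuple[int, int] = (10, 30),
                      params=None) -> np.ndarray:
    """PC-scores of n unrelated synthetic interface pairs (the null model).

    Fragment sizes are drawn uniformly from ``size_range``; each pair is
    scored with the full pipeline.  Used for empirical p-values.
    """
    from .score import align_and_score  # deferred: avoid import cycle

    rng = np.random.default_rng(seed)
    scores = np.empty(n)
    for k in range(n):
        n1, n2 = rng.integers(size_range[0], size_range[1] + 1, size=2)
        sub = int(rng.integers(0, 2 ** 31 - 1))
        i1, i2 = generate_unrelated_pair(int(n1), int(n2), sub)
        scores[k] = align_and_score(i1, i2, params).pc
    return scores
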