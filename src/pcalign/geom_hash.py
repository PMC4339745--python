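"""Sequence-order-independent candidate superpositions via geometric hashing.

An interface is treated as a cloud of labeled Cα points.  Local reference
frames are built from residue triplets within one fragment; every point of
interface 1 is recorded in every frame's coordinate system, binned on a
regular grid and keyed by (bin, fragment label, functional group).  Probing
with interface 2's frames casts a vote for a frame pair whenever bin,
fragment label (under the current fragment mapping) and chemical
compatibility all agree.  Each high-vote frame pair yields a rigid
transform; near-degenerate transforms are merged by greedy leader
clustering and the top-ranking representatives are handed to refinement.

Both fragment mappings (A→A′/B→B′ and A→B′/B→A′) are always attempted,
since the correspondence of binding fragments is unknown a priori.  Only
proper rotations are generated, so mirror-image interfaces cannot achieve
a full-vote match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .chem_classes import Group
from .errors import DegenerateGeometryError
from .interface_extract import Interface
from .transforms import RigidTransform

logger = logging.getLogger(__name__)

__all__ = ["HashParams", "Candidate", "geometric_hash_candidates", "cluster_transformations"]

_GROUP_INDEX = {Group.DONOR: 0, Group.ACCEPTOR: 1, Group.AROMATIC: 2, Group.ALIPHATIC: 3}
_BIN_SHIFT = 1024  # bins live in [0, 2048); coordinates up to ~±1000 A at 2 A bins
_NEIGHBOR_OFFSETS = np.array(
    [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)],
    dtype=np.int64,
)


@dataclass
class HashParams:
    """Tunable knobs of the hashing stage (all lengths in Angstroms)."""

    bin_width: float = 2.0
    min_votes: int | None = None        # default: max(4, 25% of smaller interface)
    max_candidates: int = 100
    rot_tol_deg: float = 15.0
    trans_tol: float = 3.0
    triplet_min_dist: float = 3.0
    triplet_max_dist: float = 13.0
    min_triangle_area: float = 1.0
    max_frames: int = 200               # deterministic stride subsample per interface
    max_raw_candidates: int = 1000      # pre-clustering cap per fragment mapping


@dataclass(frozen=True)
class Candidate:
    """A candidate rigid transform for interface 2, with its vote count."""

    transform: RigidTransform
    votes: int
    fragment_mapping: str  # "AA" = A→A′/B→B′, "AB" = A→B′/B→A′


def _check_fragment_geometry(iface: Interface) -> None:
    coords = iface.coords
    frag = iface.fragments
    for f in (0, 1):
        pts = coords[frag == f]
        if len(pts) < 3:
            raise DegenerateGeometryError(
                f"fragment {'AB'[f]} of {iface.id} has fewer than 3 residues"
            )
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] < 1e-6:
            raise DegenerateGeometryError(
                f"fragment {'AB'[f]} of {iface.id} is collinear"
            )


def _triplets(pts: np.ndarray, params: HashParams) -> np.ndarray:
    """Vertex triplets (m, 3) with pairwise distances in range and area >= min.

    Vertices are ordered canonically by the length of the opposite triangle
    side (longest first), a rigid-invariant labeling, so corresponding
    triplets on two interfaces produce corresponding frames.
    """
    n = len(pts)
    D = cdist(pts, pts)
    ok = (D >= params.triplet_min_dist) & (D <= params.triplet_max_dist)
    np.fill_diagonal(ok, False)
    combos = []
    for i in range(n - 2):
        for j in np.where(ok[i, i + 1:])[0] + i + 1:
            ks = np.where(ok[i, j + 1:] & ok[j, j + 1:])[0] + j + 1
            for k in ks:
                combos.append((i, j, k))
    if not combos:
        return np.empty((0, 3), dtype=int)
    combos = np.asarray(combos, dtype=int)
    # canonical vertex order: sort by opposite-side length, longest first
    i, j, k = combos.T
    opp = np.stack([D[j, k], D[i, k], D[i, j]], axis=1)  # side opposite each vertex
    order = np.argsort(-opp, axis=1, kind="stable")
    tri = np.take_along_axis(combos, order, axis=1)
    # area filter
    p, q, r = pts[tri[:, 0]], pts[tri[:, 1]], pts[tri[:, 2]]
    cross = np.cross(q - p, r - p)
    area = 0.5 * np.linalg.norm(cross, axis=1)
    return tri[area >= params.min_triangle_area]


def _frames(iface: Interface, params: HashParams) -> tuple[np.ndarray, np.ndarray]:
    """Local frames (origins (F,3), rotation rows (F,3,3)) for an interface."""
    coords = iface.coords
    frag = iface.fragments
    tris = []
    for f in (0, 1):
        idx = np.where(frag == f)[0]
        t = _triplets(coords[idx], params)
        if len(t):
            tris.append(idx[t])
    if not tris:
        return np.empty((0, 3)), np.empty((0, 3, 3))
    tri = np.concatenate(tris, axis=0)
    if len(tri) > params.max_frames:
        sel = np.unique(np.round(np.linspace(0, len(tri) - 1, params.max_frames)).astype(int))
        tri = tri[sel]
    p, q, r = coords[tri[:, 0]], coords[tri[:, 1]], coords[tri[:, 2]]
    x = q - p
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    z = np.cross(q - p, r - p)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    y = np.cross(z, x)
    rots = np.stack([x, y, z], axis=1)  # rows are frame axes: c = R @ (pt - p)
    return p, rots


def _point_groups(iface: Interface) -> tuple[np.ndarray, np.ndarray]:
    """Flatten residues into (point index, functional-group index) pairs."""
    pt, grp = [], []
    for i, res in enumerate(iface.residues):
        for g, gi in _GROUP_INDEX.items():
            if res.chem.groups & g:
                pt.append(i)
                grp.append(gi)
    return np.asarray(pt, dtype=np.int64), np.asarray(grp, dtype=np.int64)


def _bin_coords(coords: np.ndarray, origins: np.ndarray, rots: np.ndarray,
                bin_width: float) -> np.ndarray:
    """Binned frame coordinates, shape (F, n, 3) int64.

    Bins are offset by half a width so that the frame-defining points
    (which have frame coordinates of exactly 0) sit mid-bin rather than on
    a boundary; this keeps voting exactly invariant under rigid motion.
    """
    d = coords[None, :, :] - origins[:, None, :]
    c = np.einsum("fij,fnj->fni", rots, d)
    return np.floor(c / bin_width + 0.5).astype(np.int64) + _BIN_SHIFT


def _pack(bins: np.ndarray, frag: np.ndarray, group: np.ndarray) -> np.ndarray:
    key = (bins[..., 0] * 2048 + bins[..., 1]) * 2048 + bins[..., 2]
    return (key * 2 + frag) * 4 + group


_EMPTY = (np.empty((0, 3, 3)), np.empty((0, 3)), np.empty(0, dtype=np.int64))


def _hash_one_mapping(i1: Interface, i2: Interface, f1_o: np.ndarray, f1_r: np.ndarray,
                      f2_o: np.ndarray, f2_r: np.ndarray, swap: bool,
                      params: HashParams, min_votes: int):
    """Raw voting for one fragment mapping.

    Returns (rotations (m,3,3), translations (m,3), votes (m,)) sorted by
    votes descending (ties: more exact-bin votes, then smaller rotation
    angle, then frame order) and truncated to ``params.max_raw_candidates``.
    Ranking ties by exact-bin matches keeps the top candidate's transform
    at floating-point accuracy for noise-free copies, where many frame
    pairs collect full votes through the neighbor-bin tolerance.
    """
    F, G = len(f1_o), len(f2_o)
    if F == 0 or G == 0:
        return _EMPTY
    pt1, grp1 = _point_groups(i1)
    pt2, grp2 = _point_groups(i2)
    frag1 = i1.fragments.astype(np.int64)
    frag2 = i2.fragments.astype(np.int64)
    if swap:
        frag2 = 1 - frag2

    # hash table: interface-1 points in interface-1 frames
    bins1 = _bin_coords(i1.coords, f1_o, f1_r, params.bin_width)   # (F, n1, 3)
    ekeys = _pack(bins1[:, pt1, :], frag1[pt1][None, :], grp1[None, :]).ravel()
    ef1 = np.repeat(np.arange(F, dtype=np.int64), len(pt1))
    order = np.argsort(ekeys, kind="stable")
    ekeys = ekeys[order]
    ef1 = ef1[order]

    # probes: interface-2 points in interface-2 frames, expanded over the
    # 27 neighboring bins to absorb boundary effects (offset 13 = exact bin)
    bins2 = _bin_coords(i2.coords, f2_o, f2_r, params.bin_width)   # (G, n2, 3)
    pb = bins2[:, pt2, None, :] + _NEIGHBOR_OFFSETS[None, None, :, :]
    pkeys = _pack(pb, frag2[pt2][None, :, None], grp2[None, :, None]).ravel()
    P = len(pkeys)
    n_off = len(_NEIGHBOR_OFFSETS)
    pframe = np.repeat(np.arange(G, dtype=np.int64), len(pt2) * n_off)
    ppoint = np.repeat(np.tile(pt2, G), n_off)
    pexact = np.tile(np.arange(n_off, dtype=np.int64) == 13, G * len(pt2))

    lo = np.searchsorted(ekeys, pkeys, side="left")
    hi = np.searchsorted(ekeys, pkeys, side="right")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return _EMPTY
    starts = np.cumsum(counts) - counts
    flat = np.arange(total, dtype=np.int64) - np.repeat(starts, counts) + np.repeat(lo, counts)
    mf1 = ef1[flat]
    mprobe = np.repeat(np.arange(P, dtype=np.int64), counts)

    # one vote per distinct matched interface-2 point per frame pair:
    # sort-based dedup of (frame1, frame2, point2) triples
    n2 = len(i2)
    triple = (mf1 * G + pframe[mprobe]) * n2 + ppoint[mprobe]

    def _pair_votes(tr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tr = np.sort(tr)
        distinct = tr[np.concatenate(([True], np.diff(tr) != 0))] // n2
        edge = np.concatenate(([True], np.diff(distinct) != 0))
        keys = distinct[edge]
        v = np.diff(np.concatenate((np.nonzero(edge)[0], [len(distinct)])))
        return keys, v

    pair_keys, votes = _pair_votes(triple)
    keep = votes >= min_votes
    pair_keys, votes = pair_keys[keep], votes[keep]
    if len(pair_keys) == 0:
        return _EMPTY
    exact_keys, exact_v = _pair_votes(triple[pexact[mprobe]])
    if len(exact_keys):
        pos = np.clip(np.searchsorted(exact_keys, pair_keys), 0, len(exact_keys) - 1)
        exact_votes = np.where(exact_keys[pos] == pair_keys, exact_v[pos], 0)
    else:
        exact_votes = np.zeros(len(pair_keys), dtype=np.int64)
    f1 = pair_keys // G
    f2 = pair_keys % G

    # candidate transform: world2 -> world1 through the matched frame pair
    R = np.einsum("nji,njk->nik", f1_r[f1], f2_r[f2])   # M1^T @ M2
    t = f1_o[f1] - np.einsum("nij,nj->ni", R, f2_o[f2])
    ang = np.arccos(np.clip((np.trace(R, axis1=1, axis2=2) - 1) / 2, -1, 1))
    order = np.lexsort((f2, f1, ang, -exact_votes, -votes))[: params.max_raw_candidates]
    return R[order], t[order], votes[order]


def geometric_hash_candidates(i1: Interface, i2: Interface,
                              params: HashParams | None = None) -> list[Candidate]:
    """Ranked candidate transforms superposing interface 2 onto interface 1.

    Tries both fragment mappings, filters by vote count, clusters
    near-degenerate transforms within each mapping, and returns at most
    ``params.max_candidates`` representatives sorted by (summed) votes.
    Fully deterministic for fixed inputs and parameters.
    """
    params = params or HashParams()
    _check_fragment_geometry(i1)
    _check_fragment_geometry(i2)
    min_votes = params.min_votes
    if min_votes is None:
        min_votes = max(4, int(round(0.25 * min(len(i1), len(i2)))))

    f1_o, f1_r = _frames(i1, params)
    f2_o, f2_r = _frames(i2, params)
    out: list[Candidate] = []
    for swap in (False, True):
        R, t, votes = _hash_one_mapping(i1, i2, f1_o, f1_r, f2_o, f2_r, swap,
                                        params, min_votes)
        R, t, votes = _cluster_arrays(R, t, votes, params.rot_tol_deg, params.trans_tol)
        mapping = "AB" if swap else "AA"
        out.extend(
            Candidate(RigidTransform(R[i], t[i]), int(votes[i]), mapping)
            for i in range(len(votes))
        )
    out.sort(key=lambda c: (-c.votes, c.transform.angle, c.fragment_mapping))
    return out[: params.max_candidates]


def _cluster_arrays(R: np.ndarray, t: np.ndarray, votes: np.ndarray,
                    rot_tol_deg: float, trans_tol: float):
    """Greedy leader clustering on rotation/translation/vote arrays."""
    m = len(votes)
    if m == 0:
        return R, t, votes
    cos_tol = np.cos(np.radians(rot_tol_deg))
    rep_idx: list[int] = []
    rep_votes: list[int] = []
    rep_R = np.empty((0, 3, 3))
    rep_t = np.empty((0, 3))
    for c in range(m):
        if rep_idx:
            # relative transform c ∘ rep⁻¹: R_rel = Rc @ repR^T, t_rel = tc - R_rel @ rep_t
            tr = np.einsum("ij,nij->n", R[c], rep_R)  # trace(Rc @ repR^T)
            cosang = (tr - 1.0) / 2.0
            R_rel = np.einsum("ij,nkj->nik", R[c], rep_R)
            t_rel = t[c][None, :] - np.einsum("nij,nj->ni", R_rel, rep_t)
            close = (cosang >= cos_tol - 1e-12) & (np.linalg.norm(t_rel, axis=1) <= trans_tol)
            hit = np.nonzero(close)[0]
            if hit.size:
                rep_votes[hit[0]] += int(votes[c])
                continue
        rep_idx.append(c)
        rep_votes.append(int(votes[c]))
        rep_R = np.concatenate([rep_R, R[c][None]], axis=0)
        rep_t = np.concatenate([rep_t, t[c][None]], axis=0)
    order = np.argsort(-np.asarray(rep_votes), kind="stable")
    sel = np.asarray(rep_idx)[order]
    return R[sel], t[sel], np.asarray(rep_votes)[order]


def cluster_transformations(cands: list[Candidate], rot_tol_deg: float,
                            trans_tol: float) -> list[Candidate]:
    """Greedy leader clustering of near-degenerate transforms.

    Candidates (sorted by votes descending) join the first representative
    within ``rot_tol_deg`` relative rotation and ``trans_tol`` translation
    difference (relative transform = candidate composed with the
    representative's inverse); representatives accumulate their cluster's
    votes.  The output is re-sorted by summed votes.
    """
    if not cands:
        return []
    R = np.array([c.transform.rotation for c in cands])
    t = np.array([c.transform.translation for c in cands])
    votes = np.array([c.votes for c in cands], dtype=np.int64)
    Rc, tc, vc = _cluster_arrays(R, t, votes, rot_tol_deg, trans_tol)
    mapping = cands[0].fragment_mapping
    return [Candidate(RigidTransform(Rc[i], tc[i]), int(vc[i]), mapping)
            for i in range(len(vc))]
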