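"""Iterative refinement of a candidate superposition.

Starting from a hashing candidate, the refinement alternates two exact
sub-steps until no further improvement is possible:

1. maximum-weight bipartite matching (Hungarian assignment) of residues
   between the two interfaces, weighted by the equivalence score

       eq(d, I) = 1 / (1 + 0.25*(1 - I) + d^2 / 16)

   where d is the Cα–Cα distance after superposition and I indicates
   identical chemical class; matching is solved independently within each
   fragment pairing so fragments never cross over;

2. least-squares rigid superposition (Kabsch) over the matched pairs,
   constrained to proper rotations.

The objective tracked for convergence is the summed equivalence score of
the matched pairs; the best iterate seen is returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.transform import Rotation

from .chem_classes import same_chem
from .errors import DegenerateGeometryError
from .geom_hash import Candidate
from .interface_extract import Interface
from .transforms import RigidTransform

__all__ = [
    "MatchedPair",
    "RefineParams",
    "equivalence_score",
    "optimal_matching",
    "kabsch_superpose",
    "refine_alignment",
]


@dataclass(frozen=True)
class MatchedPair:
    idx1: int        # residue index in interface 1
    idx2: int        # residue index in interface 2
    d: float         # Cα–Cα distance (A) after superposition
    same_chem: int   # 1 iff identical chemical class
    eq_score: float


@dataclass
class RefineParams:
    tol: float = 1e-6
    max_iter: int = 100
    # if True, pairs below the scoring inclusion threshold are dropped
    # before each Kabsch fit instead of only at scoring time
    prune_during_refine: bool = False
    prune_threshold: float = 0.20


def equivalence_score(d, same_chem):
    """Per-pair equivalence weight in (0, 1]; maximal at d=0 with same class."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    i = np.asarray(same_chem, dtype=float)
    out = 1.0 / (1.0 + 0.25 * (1.0 - i) + d * d / 16.0)
    return float(out) if out.ndim == 0 else out


def _same_chem_matrix(i1: Interface, i2: Interface) -> np.ndarray:
    lab1 = np.array([r.chem.label.value for r in i1.residues])
    lab2 = np.array([r.chem.label.value for r in i2.residues])
    return (lab1[:, None] == lab2[None, :]).astype(float)


def _assignment(x1: np.ndarray, x2t: np.ndarray, frag1: np.ndarray, frag2: np.ndarray,
                chem: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching within each fragment block; (idx1, idx2) sorted by idx1."""
    out_i: list[np.ndarray] = []
    out_j: list[np.ndarray] = []
    for f in (0, 1):
        a = np.where(frag1 == f)[0]
        b = np.where(frag2 == f)[0]
        if a.size == 0 or b.size == 0:
            continue
        diff = x1[a][:, None, :] - x2t[b][None, :, :]
        d2 = np.sum(diff * diff, axis=2)
        w = 1.0 / (1.0 + 0.25 * (1.0 - chem[np.ix_(a, b)]) + d2 / 16.0)
        ri, ci = linear_sum_assignment(-w)
        out_i.append(a[ri])
        out_j.append(b[ci])
    if not out_i:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    i = np.concatenate(out_i)
    j = np.concatenate(out_j)
    order = np.lexsort((j, i))
    return i[order], j[order]


def _pairs_from_arrays(i: np.ndarray, j: np.ndarray, x1: np.ndarray, x2: np.ndarray,
                       t: RigidTransform, chem: np.ndarray) -> list[MatchedPair]:
    d = np.linalg.norm(x1[i] - t.apply(x2[j]), axis=1)
    same = chem[i, j]
    eq = 1.0 / (1.0 + 0.25 * (1.0 - same) + d * d / 16.0)
    return [MatchedPair(int(a), int(b), float(dd), int(s), float(e))
            for a, b, dd, s, e in zip(i, j, d, same, eq)]


def _mapped_frag2(i2: Interface, mapping: str) -> np.ndarray:
    frag2 = i2.fragments
    return 1 - frag2 if mapping == "AB" else frag2


def optimal_matching(i1: Interface, i2: Interface, t: RigidTransform,
                     mapping: str = "AA") -> list[MatchedPair]:
    """Optimal one-to-one residue correspondence under a fixed transform.

    Maximizes the total equivalence score with the Hungarian algorithm,
    solved separately for the two fragment pairings implied by ``mapping``
    ("AA": A↔A′ and B↔B′; "AB": A↔B′ and B↔A′), so fragments never cross.
    Pairs are returned sorted by (idx1, idx2); unmatched residues are omitted.
    """
    chem = _same_chem_matrix(i1, i2)
    x1, x2 = i1.coords, i2.coords
    i, j = _assignment(x1, t.apply(x2), i1.fragments, _mapped_frag2(i2, mapping), chem)
    return _pairs_from_arrays(i, j, x1, x2, t, chem)


def kabsch_superpose(pairs) -> RigidTransform:
    """Least-squares proper-rotation superposition of paired coordinates.

    ``pairs`` is a sequence of (x1, x2) 3-vectors; the returned transform
    minimizes sum ||x1 - (R @ x2 + t)||^2 with det(R) = +1, so a mirror
    relationship yields a proper rotation with positive residual rather
    than a reflection.
    """
    pts = np.asarray(pairs, dtype=float)
    return _kabsch(pts[:, 0, :], pts[:, 1, :])


def _kabsch_raw(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(a) < 3:
        raise DegenerateGeometryError("need at least 3 pairs for superposition")
    ac = a.mean(axis=0)
    bc = b.mean(axis=0)
    a0 = a - ac
    sv = np.linalg.svd(a0, compute_uv=False)
    if sv[1] < 1e-9:
        raise DegenerateGeometryError("paired points are collinear")
    rot, _ = Rotation.align_vectors(a0, b - bc)
    R = rot.as_matrix()
    return R, ac - R @ bc


def _kabsch(a: np.ndarray, b: np.ndarray) -> RigidTransform:
    return RigidTransform(*_kabsch_raw(a, b))


def refine_alignment(i1: Interface, i2: Interface, c: Candidate,
                     params: RefineParams | None = None
                     ) -> tuple[RigidTransform, list[MatchedPair], int, bool]:
    """Alternate matching and superposition until convergence.

    Returns (transform, matched pairs, iterations, degenerate_flag) for the
    best-scoring iterate, where the objective is the summed equivalence
    score of matched pairs.  The iteration stops when the matched set is
    unchanged, the objective improves by less than ``tol``, or ``max_iter``
    is reached.  If matching collapses below 3 pairs the last valid iterate
    is returned flagged degenerate.
    """
    params = params or RefineParams()
    chem = _same_chem_matrix(i1, i2)
    x1 = i1.coords
    x2 = i2.coords
    frag1 = i1.fragments
    frag2 = _mapped_frag2(i2, c.fragment_mapping)
    R = c.transform.rotation
    tv = c.transform.translation
    best: tuple[float, np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None = None
    prev_key: bytes | None = None
    prev_score = -np.inf
    degenerate = False
    it = 0
    for it in range(1, params.max_iter + 1):
        x2t = x2 @ R.T + tv
        i, j = _assignment(x1, x2t, frag1, frag2, chem)
        if i.size:
            # the matching under the incoming transform is itself an iterate,
            # so refinement can never end below its starting point
            d0 = np.linalg.norm(x1[i] - x2t[j], axis=1)
            s0 = float(np.sum(1.0 / (1.0 + 0.25 * (1.0 - chem[i, j]) + d0 * d0 / 16.0)))
            if best is None or s0 > best[0]:
                best = (s0, R, tv, i, j)
        fi, fj = i, j
        if params.prune_during_refine and i.size:
            d = np.linalg.norm(x1[i] - x2t[j], axis=1)
            eq = 1.0 / (1.0 + 0.25 * (1.0 - chem[i, j]) + d * d / 16.0)
            keep = eq >= params.prune_threshold
            if keep.sum() >= 3:
                fi, fj = i[keep], j[keep]
        if len(fi) < 3:
            degenerate = True
            break
        try:
            R_new, tv_new = _kabsch_raw(x1[fi], x2[fj])
        except DegenerateGeometryError:
            degenerate = True
            break
        # evaluate the matched set under the updated superposition
        d = np.linalg.norm(x1[i] - (x2[j] @ R_new.T + tv_new), axis=1)
        score = float(np.sum(1.0 / (1.0 + 0.25 * (1.0 - chem[i, j]) + d * d / 16.0)))
        if best is None or score > best[0]:
            best = (score, R_new, tv_new, i, j)
        key = i.tobytes() + j.tobytes()
        R, tv = R_new, tv_new
        if key == prev_key or score - prev_score < params.tol:
            break
        prev_key = key
        prev_score = score
    if best is None:
        return RigidTransform(R, tv), [], it, True
    _, R_b, tv_b, i, j = best
    t_best = RigidTransform(R_b, tv_b)
    return t_best, _pairs_from_arrays(i, j, x1, x2, t_best, chem), it, degenerate
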