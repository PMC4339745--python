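"""PC-score: normalized physicochemical similarity of two interfaces.

The raw score of a converged alignment is

    PC-score_raw = (f_c / L_ave) * sum_i eq_i

where the sum runs over the L_ali aligned residue pairs with equivalence
score >= 0.20, L_ave is the average number of interfacial residues of the
two interfaces, and f_c is the fraction of common inter-fragment contacts
between the aligned residue subsets,

    f_c = <N1, N2> / (0.5 * (<N1, N1> + <N2, N2>))

with N1, N2 the L_ali x L_ali contact maps of the aligned residues in each
interface.  The raw score depends systematically on interface size; the
final PC-score removes that dependence by the empirical power law

    PC-score = PC-score_raw ^ (ln 0.3 / ln(0.14 + 0.29 * 0.97^L_ave))

and equals 1 when comparing two identical interfaces.  Statistical
significance is an empirical tail probability against a background of
scores from unrelated interface pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import MissingBackgroundError, ShapeError
from .geom_hash import Candidate, HashParams, geometric_hash_candidates
from .interface_extract import Interface, contact_map_for
from .refine import MatchedPair, RefineParams, refine_alignment
from .transforms import RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "AlignParams",
    "AlignmentResult",
    "fraction_common_contacts",
    "pc_score_raw",
    "scale_exponent",
    "scale_pc_score",
    "align_and_score",
    "empirical_pvalue",
]

EQ_SCORE_THRESHOLD = 0.20  # inclusion threshold: d = 8 A for same-class pairs


@dataclass
class AlignParams:
    hashing: HashParams = field(default_factory=HashParams)
    refine: RefineParams = field(default_factory=RefineParams)
    eq_threshold: float = EQ_SCORE_THRESHOLD


@dataclass
class AlignmentResult:
    """Outcome of aligning interface 2 onto interface 1."""

    transform: RigidTransform
    pairs: list[MatchedPair]     # retained pairs only (eq_score >= threshold)
    l_ali: int
    l_ave: float
    f_c: float
    pc_raw: float
    pc: float
    coverage: float
    rmsd: float
    fragment_mapping: str = "AA"
    votes: int = 0
    iterations: int = 0
    p_value: float | None = None

    @classmethod
    def empty(cls, l_ave: float) -> "AlignmentResult":
        return cls(RigidTransform.identity(), [], 0, l_ave, 0.0, 0.0, 0.0, 0.0,
                   float("nan"))


def fraction_common_contacts(map1: np.ndarray, map2: np.ndarray) -> float:
    """Ratio of common contacts between two aligned-subset contact maps.

    Both maps are boolean L_ali x L_ali matrices in the same aligned-pair
    order.  Returns 0 when both maps are empty (no contact evidence).
    """
    m1 = np.asarray(map1, dtype=bool)
    m2 = np.asarray(map2, dtype=bool)
    if m1.shape != m2.shape or m1.ndim != 2 or m1.shape[0] != m1.shape[1]:
        raise ShapeError("contact maps must be square matrices of equal shape")
    num = float(np.sum(m1 & m2))
    denom = 0.5 * (float(np.sum(m1)) + float(np.sum(m2)))
    return num / denom if denom > 0 else 0.0


def pc_score_raw(pairs: list[MatchedPair], f_c: float, l_ave: float) -> float:
    """Raw PC-score: (f_c / L_ave) * summed equivalence score."""
    if l_ave <= 0:
        raise ValueError("L_ave must be positive")
    if not pairs:
        return 0.0
    return f_c * math.fsum(p.eq_score for p in pairs) / l_ave


def scale_exponent(l_ave: float) -> float:
    """Size-scaling exponent; tends to ln 0.3 / ln 0.14 for large interfaces."""
    if l_ave <= 0:
        raise ValueError("L_ave must be positive")
    return math.log(0.3) / math.log(0.14 + 0.29 * 0.97 ** l_ave)


def scale_pc_score(raw: float, l_ave: float) -> float:
    """Remove the interface-size dependence of the raw score."""
    if not 0.0 <= raw <= 1.0:
        raise ValueError(f"raw score {raw} outside [0, 1]")
    return raw ** scale_exponent(l_ave)


def _score_candidate(i1: Interface, i2: Interface, transform: RigidTransform,
                     pairs: list[MatchedPair], l_ave: float,
                     eq_threshold: float) -> tuple[float, dict]:
    kept = [p for p in pairs if p.eq_score >= eq_threshold]
    if not kept:
        return 0.0, {"pairs": [], "f_c": 0.0, "raw": 0.0, "rmsd": float("nan")}
    sub1 = [p.idx1 for p in kept]
    sub2 = [p.idx2 for p in kept]
    f_c = fraction_common_contacts(contact_map_for(i1, sub1), contact_map_for(i2, sub2))
    raw = pc_score_raw(kept, f_c, l_ave)
    raw = min(max(raw, 0.0), 1.0)
    rmsd = float(np.sqrt(np.mean([p.d ** 2 for p in kept])))
    return scale_pc_score(raw, l_ave), {"pairs": kept, "f_c": f_c, "raw": raw, "rmsd": rmsd}


def align_and_score(i1: Interface, i2: Interface,
                    params: AlignParams | None = None) -> AlignmentResult:
    """Full pipeline: hash, refine every top candidate, keep the best PC-score.

    Both fragment mappings are attempted by the hashing stage; each retained
    candidate is iteratively refined and scored, and the candidate with the
    highest final PC-score wins.  Returns an empty result with pc = 0 when
    no candidate clears the vote threshold.
    """
    params = params or AlignParams()
    l_ave = (len(i1) + len(i2)) / 2.0
    candidates = geometric_hash_candidates(i1, i2, params.hashing)
    if not candidates:
        logger.info("no hashing candidate above the vote threshold for %s vs %s",
                    i1.id, i2.id)
        return AlignmentResult.empty(l_ave)
    best: AlignmentResult | None = None
    for cand in candidates:
        transform, pairs, iters, degen = refine_alignment(i1, i2, cand, params.refine)
        if degen and not pairs:
            continue
        pc, info = _score_candidate(i1, i2, transform, pairs, l_ave, params.eq_threshold)
        if best is None or pc > best.pc:
            kept = info["pairs"]
            best = AlignmentResult(
                transform=transform,
                pairs=kept,
                l_ali=len(kept),
                l_ave=l_ave,
                f_c=info["f_c"],
                pc_raw=info["raw"],
                pc=pc,
                coverage=len(kept) / l_ave,
                rmsd=info["rmsd"],
                fragment_mapping=cand.fragment_mapping,
                votes=cand.votes,
                iterations=iters,
            )
    return best if best is not None else AlignmentResult.empty(l_ave)


def empirical_pvalue(score: float, background) -> float:
    """Add-one empirical tail probability of a score against a background."""
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise MissingBackgroundError("background score list is empty")
    return float((1 + np.sum(bg >= score)) / (bg.size + 1))
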