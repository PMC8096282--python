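"""Guidance-loop classification and candidate-structure selection.

Loops in the guidance (MFE) structure are classified by their penalties:
good (penalty = 0), fair (0 < penalty <= 1, or no patterns available for
the motif), poor (penalty > 1).  A candidate from the ensemble is accepted
when (i) every good guidance loop is retained exactly, (ii) no candidate
loop with penalty above the fair threshold overlaps a fair loop region,
(iii) every poor loop is replaced: it is absent from the candidate and any
candidate loop overlapping its region scores strictly below it.  Among the
candidates passing (i)-(iii) the one with the lowest total penalty wins
(iv); if none passes, the lowest-total-penalty candidate is returned as a
fallback.  Loop regions are the loop's residues extended by four
nucleotides on each side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .posterior_model import LoopPenalty, PosteriorModel, loop_penalty
from .rna_structures import Loop, SecondaryStructure, ShapeProfile, extract_loops

logger = logging.getLogger("shaperefine")

FAIR_THRESHOLD = 1.0
REGION_PAD = 4

__all__ = [
    "LoopAssessment",
    "SelectionResult",
    "classify_loops",
    "candidate_satisfies",
    "select_structure",
    "centroid_structure",
    "loop_region",
    "FAIR_THRESHOLD",
    "REGION_PAD",
]


def loop_region(loop: Loop, length: int, pad: int = REGION_PAD) -> list[tuple[int, int]]:
    """Per-side closed intervals extended by ``pad`` nt, clipped to [1, L]."""
    regions = []
    for side in loop.sides:
        if not side:
            continue
        regions.append((max(1, side[0] - pad), min(length, side[-1] + pad)))
    return regions


def _overlaps(positions, regions) -> bool:
    return any(lo <= p <= hi for p in positions for lo, hi in regions)


@dataclass(frozen=True)
class LoopAssessment:
    """A guidance loop with its penalty, category and extended region."""

    scored: LoopPenalty
    category: str  # good | fair | poor
    region: tuple[tuple[int, int], ...]

    @property
    def loop(self) -> Loop:
        return self.scored.loop

    @property
    def penalty(self) -> float:
        return self.scored.penalty


def _categorize(scored: LoopPenalty, fair_threshold: float) -> str:
    if not scored.patterns_available:
        return "fair"
    if scored.penalty == 0.0:
        return "good"
    if scored.penalty <= fair_threshold:
        return "fair"
    return "poor"


def classify_loops(
    guidance: SecondaryStructure,
    profile: ShapeProfile,
    patterns,
    model: PosteriorModel,
    fair_threshold: float = FAIR_THRESHOLD,
    region_pad: int = REGION_PAD,
) -> list[LoopAssessment]:
    """Score and classify every extractable loop of the guidance structure."""
    assessments = []
    for loop in extract_loops(guidance):
        scored = loop_penalty(loop, profile, patterns, model)
        assessments.append(
            LoopAssessment(
                scored,
                _categorize(scored, fair_threshold),
                tuple(loop_region(loop, len(guidance), region_pad)),
            )
        )
    return assessments


def candidate_satisfies(
    candidate: SecondaryStructure,
    assessments: list[LoopAssessment],
    profile: ShapeProfile,
    patterns,
    model: PosteriorModel,
    fair_threshold: float = FAIR_THRESHOLD,
) -> tuple[bool, bool, bool, float]:
    """Evaluate selection criteria (i)-(iii) and the total penalty.

    Candidate loops whose motifs lack patterns contribute nothing to the
    total and can never violate (ii)/(iii) — no penalty is defined for
    them.  Criterion (iii) is vacuously satisfied for a poor region that no
    candidate loop overlaps (the region became fully paired: the desired
    replacement).
    """
    if len(candidate) != len(profile):
        raise ValueError("candidate and profile lengths differ")
    cand_loops = extract_loops(candidate)
    cand_scored = [loop_penalty(lp, profile, patterns, model) for lp in cand_loops]
    cand_keys = {lp.loop.key() for lp in cand_scored}

    crit_i = all(
        a.loop.key() in cand_keys for a in assessments if a.category == "good"
    )

    crit_ii = True
    for a in assessments:
        if a.category != "fair":
            continue
        for sc in cand_scored:
            if not sc.patterns_available:
                continue
            if sc.penalty > fair_threshold and _overlaps(sc.loop.positions, a.region):
                crit_ii = False

    crit_iii = True
    for a in assessments:
        if a.category != "poor":
            continue
        if a.loop.key() in cand_keys:
            crit_iii = False
            continue
        for sc in cand_scored:
            if not sc.patterns_available:
                continue
            if _overlaps(sc.loop.positions, a.region) and sc.penalty >= a.penalty:
                crit_iii = False

    total = sum(sc.penalty for sc in cand_scored if sc.patterns_available)
    return crit_i, crit_ii, crit_iii, total


@dataclass
class SelectionResult:
    """Outcome of candidate selection, with a per-candidate audit table."""

    structure: SecondaryStructure
    satisfied_criteria: tuple[bool, bool, bool, bool]
    total_penalty: float
    fallback_used: bool
    audit: list[dict]


def select_structure(
    guidance: SecondaryStructure,
    candidates: list[SecondaryStructure],
    profile: ShapeProfile,
    patterns,
    model: PosteriorModel,
    fair_threshold: float = FAIR_THRESHOLD,
    region_pad: int = REGION_PAD,
    include_guidance: bool = True,
) -> SelectionResult:
    """Pick the ensemble member most consistent with the SHAPE patterns.

    The guidance structure is appended to the pool (it may legitimately
    win).  Ties in total penalty are broken by input order.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    for c in candidates:
        if len(c) != len(guidance):
            raise ValueError("candidate and guidance sequence lengths differ")
    assessments = classify_loops(
        guidance, profile, patterns, model, fair_threshold, region_pad
    )
    pool = list(candidates)
    if include_guidance and not any(c.pairs == guidance.pairs for c in pool):
        pool.append(guidance)

    audit = []
    best_pass: tuple[float, int] | None = None
    best_any: tuple[float, int] | None = None
    for idx, cand in enumerate(pool):
        ci, cii, ciii, total = candidate_satisfies(
            cand, assessments, profile, patterns, model, fair_threshold
        )
        audit.append(
            {"index": idx, "crit_i": ci, "crit_ii": cii, "crit_iii": ciii,
             "total_penalty": total, "n_pairs": len(cand.pairs)}
        )
        if ci and cii and ciii and (best_pass is None or total < best_pass[0]):
            best_pass = (total, idx)
        if best_any is None or total < best_any[0]:
            best_any = (total, idx)

    if best_pass is not None:
        total, idx = best_pass
        fallback = False
    else:
        total, idx = best_any
        fallback = True
        logger.info("no candidate satisfied criteria (i)-(iii); lowest-penalty fallback")
    row = audit[idx]
    crits = (row["crit_i"], row["crit_ii"], row["crit_iii"], not fallback)
    return SelectionResult(pool[idx], crits, total, fallback, audit)


def centroid_structure(candidates: list[SecondaryStructure]) -> SecondaryStructure:
    """Ensemble member minimizing total base-pair distance to all others.

    Distance is the symmetric difference of pair sets; ties break to the
    lowest input index.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    pair_sets = [set(c.pairs) for c in candidates]
    best_idx, best_sum = 0, float("inf")
    for i, pi in enumerate(pair_sets):
        total = sum(len(pi ^ pj) for pj in pair_sets)
        if total < best_sum:
            best_idx, best_sum = i, total
    return candidates[best_idx]
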