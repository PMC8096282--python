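"""Characteristic SHAPE-pattern identification for loop motifs.

For each loop motif (hairpin-k, bulge-k, internal-axb) the reactivities at
every pair of loop positions are compared across loop instances with a
paired Wilcoxon signed-rank test.  A position pair is retained as a
characteristic pattern when its two-sided p-value is below ``alpha`` AND
ranks among the ``top_k`` smallest p-values of that motif; the direction
(high vs low position) is assigned from the paired means.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rna_structures import (
    Loop,
    MotifSignature,
    ShapeProfile,
    StructureParseError,
    pattern_positions,
)

logger = logging.getLogger("shaperefine")

MIN_ROWS_PER_PAIR = 5  # exact test is powerless below this

__all__ = [
    "MotifMatrix",
    "CharacteristicPattern",
    "PatternTable",
    "build_motif_matrices",
    "wilcoxon_signed_rank",
    "identify_patterns",
    "save_patterns",
    "load_patterns",
]


@dataclass
class MotifMatrix:
    """Loop-instance x loop-position reactivity matrix for one motif."""

    motif: MotifSignature
    values: np.ndarray  # shape (n_loops, k); NaN = missing
    rna_ids: tuple[str, ...]

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class CharacteristicPattern:
    """An ordered (high, low) position inequality for one loop motif."""

    motif: MotifSignature
    high_pos: int  # 1-based motif position with the larger reactivity
    low_pos: int
    p_value: float

    def __post_init__(self) -> None:
        if self.high_pos == self.low_pos:
            raise ValueError("high_pos and low_pos must differ")


PatternTable = dict  # MotifSignature -> list[CharacteristicPattern]


def build_motif_matrices(
    loops_by_rna: Mapping[str, Sequence[Loop]],
    profiles: Mapping[str, ShapeProfile],
    exclude_rna: str | None = None,
) -> dict[MotifSignature, MotifMatrix]:
    """Assemble per-motif reactivity matrices (leave-one-out aware).

    Rows come from every RNA except ``exclude_rna``; loop positions are read
    in motif-position order (shorter side first for internal loops).
    Multibranch loops are skipped: their geometry is too heterogeneous for a
    per-position statistical comparison.
    """
    rows: dict[MotifSignature, list[tuple[str, np.ndarray]]] = {}
    for rna_id, loops in loops_by_rna.items():
        if rna_id == exclude_rna:
            continue
        profile = profiles[rna_id]
        for loop in loops:
            if loop.loop_type == "multibranch":
                continue
            pos = pattern_positions(loop)
            row = np.array([profile.reactivity(p) for p in pos], dtype=float)
            rows.setdefault(loop.motif, []).append((rna_id, row))
    out: dict[MotifSignature, MotifMatrix] = {}
    for motif, items in rows.items():
        ids = tuple(r for r, _ in items)
        mat = np.vstack([v for _, v in items])
        out[motif] = MotifMatrix(motif, mat, ids)
    return out


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _exact_pvalue(diffs: np.ndarray) -> float:
    """Two-sided exact p-value over all 2^n sign assignments.

    Midranks (ties) are doubled to integers and the null distribution of the
    positive rank sum is built by dynamic programming, which is identical to
    full enumeration of sign patterns but polynomial in n.
    """
    n = len(diffs)
    ranks = stats.rankdata(np.abs(diffs))
    scaled = np.rint(ranks * 2).astype(int)
    w_plus = int(scaled[diffs > 0].sum())
    total = int(scaled.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total - r + 1]
        dist = dist + shifted
    dist /= 2.0 ** n
    cdf = float(dist[: w_plus + 1].sum())
    sf = float(dist[w_plus:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def _approx_pvalue(diffs: np.ndarray) -> float:
    """Normal approximation with midranks, tie-corrected variance and continuity correction."""
    n = len(diffs)
    ranks = stats.rankdata(np.abs(diffs))
    w_plus = ranks[diffs > 0].sum()
    mu = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(ranks, return_counts=True)
    var -= (counts ** 3 - counts).sum() / 48.0
    if var <= 0:
        return 1.0
    # continuity correction: shrink the deviation by 0.5 toward the mean
    dev = w_plus - mu
    dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
    z = dev / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], mode: str = "auto"
) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Pairs with a missing (NaN) member and zero differences are dropped
    before ranking.  ``mode='auto'`` uses the exact sign-assignment
    distribution for n <= 25 and the tie-corrected normal approximation
    otherwise.  All differences zero (no usable pairs) yields p = 1 with a
    warning rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    diffs = (x - y)[keep]
    diffs = diffs[diffs != 0.0]
    if len(diffs) == 0:
        warnings.warn("all paired differences are zero; returning p = 1")
        return 1.0
    if mode not in ("exact", "approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" or (mode == "auto" and len(diffs) <= 25):
        return _exact_pvalue(diffs)
    return _approx_pvalue(diffs)


# ---------------------------------------------------------------------------
# Pattern identification
# ---------------------------------------------------------------------------

def identify_patterns(
    matrix: MotifMatrix,
    alpha: float = 0.05,
    top_k: int = 2,
    min_rows: int = MIN_ROWS_PER_PAIR,
) -> list[CharacteristicPattern]:
    """Retain position pairs with p < alpha ranked in the motif's top_k.

    Every unordered position pair (i, j), i < j, is tested on the rows where
    both entries are observed; pairs with fewer than ``min_rows`` usable
    rows are skipped.  The retained patterns are directional: ``high_pos``
    is the position with the larger mean reactivity over the paired rows.
    """
    k = matrix.values.shape[1]
    tested: list[tuple[float, int, int]] = []  # (p, i, j) 1-based
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = matrix.values[:, i], matrix.values[:, j]
            usable = ~(np.isnan(xi) | np.isnan(xj))
            if usable.sum() < min_rows:
                logger.debug(
                    "motif %s pair (%d,%d): %d usable rows < %d, skipped",
                    matrix.motif, i + 1, j + 1, usable.sum(), min_rows,
                )
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = wilcoxon_signed_rank(xi[usable], xj[usable])
            tested.append((p, i + 1, j + 1))
    tested.sort()
    patterns: list[CharacteristicPattern] = []
    for rank, (p, i, j) in enumerate(tested):
        if rank >= top_k or p >= alpha:
            continue
        xi, xj = matrix.values[:, i - 1], matrix.values[:, j - 1]
        usable = ~(np.isnan(xi) | np.isnan(xj))
        if np.nanmean(xi[usable]) >= np.nanmean(xj[usable]):
            high, low = i, j
        else:
            high, low = j, i
        patterns.append(CharacteristicPattern(matrix.motif, high, low, p))
    return patterns


def discover_patterns(
    loops_by_rna: Mapping[str, Sequence[Loop]],
    profiles: Mapping[str, ShapeProfile],
    exclude_rna: str | None = None,
    alpha: float = 0.05,
    top_k: int = 2,
) -> dict[MotifSignature, list[CharacteristicPattern]]:
    """Full discovery pass: matrices then per-motif pattern selection."""
    matrices = build_motif_matrices(loops_by_rna, profiles, exclude_rna)
    table: dict[MotifSignature, list[CharacteristicPattern]] = {}
    for motif, matrix in matrices.items():
        if matrix.n_rows < 2:
            continue
        pats = identify_patterns(matrix, alpha=alpha, top_k=top_k)
        if pats:
            table[motif] = pats
    return table


# ---------------------------------------------------------------------------
# Persistence (TSV: motif, high_pos, low_pos, p_value)
# ---------------------------------------------------------------------------

def save_patterns(
    table: Mapping[MotifSignature, Iterable[CharacteristicPattern]], path
) -> None:
    records = [
        {
            "motif": str(m),
            "high_pos": p.high_pos,
            "low_pos": p.low_pos,
            "p_value": p.p_value,
        }
        for m, pats in table.items()
        for p in pats
    ]
    pd.DataFrame(records, columns=["motif", "high_pos", "low_pos", "p_value"]).to_csv(
        path, sep="\t", index=False
    )


def load_patterns(path) -> dict[MotifSignature, list[CharacteristicPattern]]:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    table: dict[MotifSignature, list[CharacteristicPattern]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            motif = MotifSignature.from_string(str(row.motif))
            pat = CharacteristicPattern(
                motif, int(row.high_pos), int(row.low_pos), float(row.p_value)
            )
        except (ValueError, AttributeError, StructureParseError) as exc:
            raise StructureParseError(f"pattern table line {lineno}: {exc}") from exc
        table.setdefault(motif, []).append(pat)
    return table
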