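"""Structure-accuracy metrics and the SHAPE-noise robustness protocol.

Sensitivity is the fraction of native base pairs that are predicted, PPV
the fraction of predicted pairs that are native.  MCC is reported as
sqrt(sensitivity x PPV), the standard approximation in RNA secondary
structure benchmarking; an exact confusion-matrix variant (TN = all
unordered position pairs in neither structure) is available behind a flag.
Noise robustness shuffles a chosen fraction of the non-missing SHAPE
reactivities and re-runs selection, averaging accuracy over seeded repeats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rna_structures import SecondaryStructure, ShapeProfile

logger = logging.getLogger("shaperefine")

__all__ = ["AccuracyReport", "score", "shuffle_noise", "robustness_run"]


@dataclass(frozen=True)
class AccuracyReport:
    tp: int
    fp: int
    fn: int
    sensitivity: float
    ppv: float
    mcc: float
    undefined: tuple[str, ...] = ()


def _slip_match(native: set, predicted: set) -> int:
    """Count predicted pairs matching a native pair up to +-1 slip on one
    index; each native pair may be consumed by at most one predicted pair."""
    available = set(native)
    tp = 0
    for (i, j) in sorted(predicted):
        for cand in ((i, j), (i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if cand in available:
                available.discard(cand)
                tp += 1
                break
    return tp


def score(
    native: SecondaryStructure,
    predicted: SecondaryStructure,
    allow_slip: bool = False,
    exact_mcc: bool = False,
) -> AccuracyReport:
    """Pair-set accuracy of a predicted structure against the native one."""
    if len(native) != len(predicted):
        raise ValueError("native and predicted sequence lengths differ")
    nat, pred = set(native.pairs), set(predicted.pairs)
    tp = _slip_match(nat, pred) if allow_slip else len(nat & pred)
    fp, fn = len(pred) - tp, len(nat) - tp
    undefined = []
    sens = tp / (tp + fn) if tp + fn else (undefined.append("sensitivity") or 0.0)
    ppv = tp / (tp + fp) if tp + fp else (undefined.append("ppv") or 0.0)
    if exact_mcc:
        L = len(native)
        n_all = L * (L - 1) // 2
        tn = n_all - tp - fp - fn
        denom = math.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = (tp * tn - fp * fn) / denom if denom else (undefined.append("mcc") or 0.0)
    else:
        mcc = math.sqrt(sens * ppv)
    return AccuracyReport(tp, fp, fn, sens, ppv, mcc, tuple(undefined))


def shuffle_noise(profile: ShapeProfile, fraction: float, seed: int) -> ShapeProfile:
    """Shuffle the reactivities of a random fraction of non-missing positions.

    Exactly round(fraction * #non-missing) positions are drawn uniformly
    without replacement and their values permuted among themselves; missing
    entries and all other positions are untouched, so the value multiset is
    preserved.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    values = profile.values.copy()
    observed = np.flatnonzero(~np.isnan(values))
    k = int(round(fraction * len(observed)))
    if k >= 2:
        chosen = rng.choice(observed, size=k, replace=False)
        values[chosen] = values[rng.permutation(chosen)]
    return ShapeProfile(values)


def robustness_run(
    guidance: SecondaryStructure,
    candidates: list[SecondaryStructure],
    profile: ShapeProfile,
    patterns,
    model,
    native: SecondaryStructure,
    fractions: list[float],
    repeats: int = 10,
    seed: int = 0,
    allow_slip: bool = False,
) -> pd.DataFrame:
    """Mean accuracy of refined structures under increasing SHAPE noise.

    For each shuffle fraction the profile is perturbed ``repeats`` times
    (deterministic sub-seeds), selection re-run on the noisy profile, and
    the chosen structure scored against the native; the table reports the
    per-fraction means and standard errors.
    """
    from .refinement import select_structure

    rows = []
    for fi, fraction in enumerate(fractions):
        sens, ppv, mcc = [], [], []
        for rep in range(repeats):
            noisy = shuffle_noise(profile, fraction, seed + 1000 * fi + rep)
            chosen = select_structure(guidance, candidates, noisy, patterns, model)
            rep_score = score(native, chosen.structure, allow_slip=allow_slip)
            sens.append(rep_score.sensitivity)
            ppv.append(rep_score.ppv)
            mcc.append(rep_score.mcc)
        rows.append(
            {
                "fraction": fraction,
                "mean_sensitivity": float(np.mean(sens)),
                "mean_ppv": float(np.mean(ppv)),
                "mean_mcc": float(np.mean(mcc)),
                "se_sensitivity": float(np.std(sens, ddof=1) / math.sqrt(repeats))
                if repeats > 1 else 0.0,
                "se_ppv": float(np.std(ppv, ddof=1) / math.sqrt(repeats))
                if repeats > 1 else 0.0,
                "repeats": repeats,
            }
        )
    return pd.DataFrame(rows)
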