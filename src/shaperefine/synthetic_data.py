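"""Synthetic RNA structures, SHAPE profiles and candidate ensembles.

The generator emulates the statistical structure the scoring model relies
on: paired residues draw low reactivities, loop residues draw higher ones,
and selected loop motifs carry planted position-wise reactivity offsets —
the synthetic analogue of characteristic SHAPE patterns.  Candidate
ensembles are produced by local helix perturbations of a true structure,
standing in for Boltzmann-sampled suboptimal structures.  All randomness
flows through explicit seeds; there is no global random state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pattern_discovery import CharacteristicPattern
from .rna_structures import (
    Loop,
    MotifSignature,
    SecondaryStructure,
    ShapeProfile,
    extract_loops,
    parse_dotbracket,
    pattern_positions,
)

logger = logging.getLogger("shaperefine")

__all__ = [
    "SynthSpec",
    "generate_structure",
    "generate_shape",
    "generate_ensemble",
    "perturb_structure",
    "plant_wrong_loop",
    "make_true_false_training_sets",
    "count_ensemble_pairs",
    "generate_benchmark",
]

_PAIR_CHOICES = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]
_PAIR_WEIGHTS = np.array([0.3, 0.3, 0.15, 0.15, 0.05, 0.05])


def default_offsets(motif: MotifSignature, effect: float = 1.5) -> tuple[float, ...]:
    """Default planted offsets: a single elevated position (the second)."""
    k = motif.total_length
    offs = [0.0] * k
    if k >= 2:
        offs[1] = effect
    return tuple(offs)


@dataclass
class SynthSpec:
    """Generation conditions for one synthetic RNA.

    Reactivity units follow normalized SHAPE convention (unitless, mostly
    in [0, ~2]).  Paired residues draw from a low truncated normal (mean
    0.1, sd 0.1), loop residues from a higher one (mean 0.5, sd 0.25),
    both truncated at zero; planted offsets are added post-truncation so a
    planted mean difference is preserved exactly.
    """

    length: int = 190
    inventory: dict[MotifSignature, int] = field(
        default_factory=lambda: {
            MotifSignature("hairpin", (4,)): 1,
            MotifSignature("hairpin", (5,)): 1,
            MotifSignature("hairpin", (7,)): 1,
            MotifSignature("internal", (1, 2)): 1,
            MotifSignature("internal", (2, 2)): 1,
            MotifSignature("bulge", (2,)): 1,
        }
    )
    paired_mean: float = 0.1
    paired_sd: float = 0.1
    loop_mean: float = 0.5
    loop_sd: float = 0.25
    pattern_offsets: dict[MotifSignature, tuple[float, ...]] = field(default_factory=dict)
    missing_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")
        if self.pattern_offsets:
            for motif, offs in self.pattern_offsets.items():
                if len(offs) != motif.total_length:
                    raise ValueError(f"offsets for {motif} have wrong length")
                if not np.all(np.isfinite(offs)):
                    raise ValueError("effect sizes must be finite")
        else:
            planted = {
                m: default_offsets(m) for m in self.inventory
                if m.loop_type != "multibranch" and m.total_length >= 2
            }
            # the cap hairpin closing bulge/internal arms is a recurring motif
            # of the generated structures, so it too carries a pattern
            cap = MotifSignature("hairpin", (_cap_length(self.inventory),))
            planted.setdefault(cap, default_offsets(cap))
            self.pattern_offsets = planted


# ---------------------------------------------------------------------------
# Structure generation
# ---------------------------------------------------------------------------

def _cap_length(inventory: Mapping[MotifSignature, int]) -> int:
    """Hairpin length for arm caps, avoiding requested hairpin motifs."""
    requested = {m.lengths[0] for m in inventory if m.loop_type == "hairpin"}
    for k in (6, 7, 5, 8, 9):
        if k not in requested:
            return k
    return 10


def _arm_dotbracket(motif: MotifSignature, rng: np.random.Generator, cap: int) -> str:
    """Dot-bracket fragment realizing one loop motif with >=2 stacked pairs
    on every bounding helix (plus a cap hairpin for bulge/internal arms)."""
    h1 = int(rng.integers(3, 6))
    h2 = int(rng.integers(3, 6))
    if motif.loop_type == "hairpin":
        k = motif.lengths[0]
        return "(" * h1 + "." * k + ")" * h1
    if motif.loop_type == "bulge":
        k = motif.lengths[0]
        inner = "(" * h2 + "." * cap + ")" * h2
        if rng.random() < 0.5:  # bulge on the 5' side
            return "(" * h1 + "." * k + inner + ")" * h1
        return "(" * h1 + inner + "." * k + ")" * h1
    if motif.loop_type == "internal":
        a, b = motif.lengths
        if rng.random() < 0.5:
            a, b = b, a
        inner = "(" * h2 + "." * cap + ")" * h2
        return "(" * h1 + "." * a + inner + "." * b + ")" * h1
    if motif.loop_type == "multibranch":
        gaps = motif.lengths
        branches = ["(" * h2 + "." * cap + ")" * h2 for _ in range(len(gaps) - 1)]
        body = "".join(
            "." * g + (branches[i] if i < len(branches) else "")
            for i, g in enumerate(gaps)
        )
        return "(" * h1 + body + ")" * h1
    raise ValueError(f"unknown motif type {motif.loop_type}")


def _sequence_for(db: str, rng: np.random.Generator) -> str:
    seq = [""] * len(db)
    stack = []
    for pos, ch in enumerate(db):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            i = stack.pop()
            a, b = _PAIR_CHOICES[rng.choice(len(_PAIR_CHOICES), p=_PAIR_WEIGHTS)]
            seq[i], seq[pos] = a, b
        else:
            seq[pos] = "ACGU"[rng.integers(4)]
    return "".join(seq)


def generate_structure(spec: SynthSpec) -> SecondaryStructure:
    """Build a nested structure containing the requested loop motifs.

    Each motif instance becomes a stem-loop arm; arms are joined at the
    exterior level by short unpaired linkers and the 3' end padded to the
    requested length.  Raises when the inventory cannot fit.
    """
    rng = np.random.default_rng(spec.seed)
    cap = _cap_length(spec.inventory)
    arms = []
    for motif, count in spec.inventory.items():
        for _ in range(count):
            arms.append(_arm_dotbracket(motif, rng, cap))
    rng.shuffle(arms)
    # generous single-stranded linkers so local helix moves stay realizable
    db = "...." + ("." * 8).join(arms) + "...." if arms else "." * spec.length
    if len(db) > spec.length:
        raise ValueError(
            f"motif inventory needs {len(db)} nt but length is {spec.length}"
        )
    db = db + "." * (spec.length - len(db))
    return SecondaryStructure(_sequence_for(db, rng), parse_dotbracket(db, "N" * len(db)).pairs)


# ---------------------------------------------------------------------------
# SHAPE generation
# ---------------------------------------------------------------------------

def _truncnorm(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Positive-support normal draws by rejection (truncation at zero)."""
    out = rng.normal(mean, sd, size)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < 0
    return out


def generate_shape(structure: SecondaryStructure, spec: SynthSpec) -> ShapeProfile:
    """Simulate a SHAPE profile for a structure.

    Paired positions draw from the low distribution, unpaired from the loop
    base distribution; planted per-position offsets are added to loops
    whose motif appears in ``spec.pattern_offsets``; missing values are
    injected at ``spec.missing_rate``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    L = len(structure)
    paired = {p for pair in structure.pairs for p in pair}
    values = np.empty(L)
    for i in range(1, L + 1):
        if i in paired:
            values[i - 1] = _truncnorm(rng, spec.paired_mean, spec.paired_sd, 1)[0]
        else:
            values[i - 1] = _truncnorm(rng, spec.loop_mean, spec.loop_sd, 1)[0]
    for loop in extract_loops(structure):
        offs = spec.pattern_offsets.get(loop.motif)
        if offs is None:
            continue
        for off, p in zip(offs, pattern_positions(loop)):
            values[p - 1] += off
    if spec.missing_rate > 0:
        values[rng.random(L) < spec.missing_rate] = np.nan
    return ShapeProfile(values)


# ---------------------------------------------------------------------------
# Ensemble generation
# ---------------------------------------------------------------------------

def _helices(pairs: frozenset[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Maximal runs of stacked pairs, outermost first within each helix."""
    remaining = set(pairs)
    helices = []
    for p in sorted(pairs):
        if p not in remaining:
            continue
        run = [p]
        remaining.discard(p)
        i, j = p
        while (i + 1, j - 1) in remaining:
            i, j = i + 1, j - 1
            run.append((i, j))
            remaining.discard((i, j))
        helices.append(run)
    return helices


def _valid_nested(pairs: set[tuple[int, int]], length: int) -> bool:
    seen: set[int] = set()
    plist = sorted(pairs)
    for i, j in plist:
        if not (1 <= i < j <= length) or j - i < 4:
            return False
        if i in seen or j in seen:
            return False
        seen.update((i, j))
    for a in range(len(plist)):
        for b in range(a + 1, len(plist)):
            (i, j), (k, l) = plist[a], plist[b]
            if i < k < j < l:
                return False
    return True


def _perturb_helix(
    pairs: set[tuple[int, int]], helix: list[tuple[int, int]],
    rng: np.random.Generator, length: int,
) -> set[tuple[int, int]]:
    """Apply one random local operation to a helix; returns a new pair set
    (unchanged if the drawn operation would break validity)."""
    ops = ["shrink_outer", "shrink_inner", "grow_inner", "shift_in", "shift_out",
           "translate", "translate"]
    op = ops[rng.integers(len(ops))]
    t = int(rng.integers(1, 4))
    new = set(pairs)
    if op == "shrink_outer":
        new -= set(helix[: min(t, len(helix) - 2)])
    elif op == "shrink_inner":
        new -= set(helix[max(2, len(helix) - t):])
    elif op == "grow_inner":
        i, j = helix[-1]
        for _ in range(t):
            i, j = i + 1, j - 1
            cand = new | {(i, j)}
            if j - i < 4 or not _valid_nested(cand, length):
                break
            new = cand
    elif op in ("shift_in", "shift_out"):
        d = t if op == "shift_in" else -t
        shifted = {(i + d, j - d) for i, j in helix}
        cand = (new - set(helix)) | shifted
        if _valid_nested(cand, length):
            new = cand
    elif op == "translate":
        d = t if rng.random() < 0.5 else -t
        shifted = {(i + d, j + d) for i, j in helix}
        cand = (new - set(helix)) | shifted
        if _valid_nested(cand, length):
            new = cand
    if not _valid_nested(new, length):
        return set(pairs)
    return new


def perturb_structure(
    structure: SecondaryStructure, seed: int, n_ops: int = 1
) -> SecondaryStructure:
    """Locally perturb ``n_ops`` randomly chosen helices (never a no-op when
    a valid perturbation exists)."""
    rng = np.random.default_rng(seed)
    pairs = set(structure.nested_pairs)
    for _ in range(n_ops):
        for _attempt in range(20):
            helices = _helices(frozenset(pairs))
            if not helices:
                break
            helix = helices[rng.integers(len(helices))]
            new = _perturb_helix(pairs, helix, rng, len(structure))
            if new != pairs:
                pairs = new
                break
    return SecondaryStructure(structure.sequence, frozenset(pairs), name=structure.name)


def plant_wrong_loop(
    structure: SecondaryStructure, seed: int, shift: int | None = None
) -> SecondaryStructure:
    """Translate one standalone stem-loop so its hairpin moves fully off
    its true residues — a same-motif loop in the wrong place.

    Used to build guidance structures carrying one falsely predicted loop:
    the moved loop reads paired-level reactivities, so it scores a high
    penalty under a fitted model.  The shift defaults to the hairpin's
    loop length (so old and new loop windows are disjoint); smaller shifts
    are tried as a last resort.  Raises if no helix can be moved.
    """
    rng = np.random.default_rng(seed)
    pairs = set(structure.nested_pairs)
    helices = _helices(frozenset(pairs))
    # standalone stem-loops: innermost (close a hairpin) and not enclosed by
    # any other pair, so the move changes exactly one loop
    hairpin_helices = [
        h for h in helices
        if not any(h[-1][0] < p[0] and p[1] < h[-1][1] for p in pairs - set(h))
        and not any(p[0] < h[0][0] < p[1] for p in pairs - set(h))
    ]
    rng.shuffle(hairpin_helices)
    for helix in hairpin_helices:
        i_in, j_in = helix[-1]
        k = j_in - i_in - 1  # hairpin loop length
        shifts = (shift, -shift) if shift is not None else (k, -k, k + 1, -(k + 1))
        for d in shifts:
            moved = {(i + d, j + d) for i, j in helix}
            cand = (pairs - set(helix)) | moved
            if _valid_nested(cand, len(structure)):
                return SecondaryStructure(
                    structure.sequence, frozenset(cand), name=structure.name
                )
    raise ValueError("no standalone stem-loop can be translated")


def generate_ensemble(
    true_structure: SecondaryStructure,
    n: int,
    perturb_rate: float,
    seed: int,
    include_true: bool = True,
) -> list[SecondaryStructure]:
    """Candidate ensemble from local helix perturbations of the truth.

    Each helix of each candidate is perturbed independently with
    probability ``perturb_rate``.  With ``include_true`` the true structure
    is placed first in the ensemble; without it, candidates identical to
    the truth are re-perturbed (impossible at perturb_rate 0: raises).
    """
    if n < 1:
        raise ValueError("ensemble size must be >= 1")
    if not include_true and perturb_rate == 0:
        raise ValueError("perturb_rate 0 cannot exclude the true structure")
    rng = np.random.default_rng(seed)
    out: list[SecondaryStructure] = []
    if include_true:
        out.append(true_structure)
    while len(out) < n:
        pairs = set(true_structure.nested_pairs)
        for helix in _helices(frozenset(pairs)):
            if rng.random() < perturb_rate:
                live = [h for h in _helices(frozenset(pairs)) if set(h) <= pairs]
                target = next((h for h in live if h[0] == helix[0]), None)
                if target is not None:
                    pairs = _perturb_helix(pairs, target, rng, len(true_structure))
        cand = SecondaryStructure(
            true_structure.sequence, frozenset(pairs),
            name=f"candidate_{len(out)}",
        )
        if not include_true and cand.pairs == true_structure.pairs:
            cand = perturb_structure(cand, int(rng.integers(2 ** 31)), n_ops=1)
            if cand.pairs == true_structure.pairs:
                continue
        out.append(cand)
    return out


# ---------------------------------------------------------------------------
# Training sets for the posterior model
# ---------------------------------------------------------------------------

def make_true_false_training_sets(
    references: Mapping[str, SecondaryStructure],
    profiles: Mapping[str, ShapeProfile],
    ensembles: Mapping[str, Sequence[SecondaryStructure]],
    patterns: Mapping[MotifSignature, Sequence[CharacteristicPattern]],
) -> tuple[np.ndarray, np.ndarray]:
    """Pattern-pair difference samples for true and false loops.

    True samples: D values of pattern pairs in loops of reference
    structures.  False samples: D values in candidate-ensemble loops absent
    from the corresponding reference (absence judged by loop identity:
    type, unpaired positions and closing pairs).
    """
    true_D: list[float] = []
    false_D: list[float] = []

    def pair_diffs(loop: Loop, profile: ShapeProfile) -> list[float]:
        out = []
        pos = pattern_positions(loop)
        for pat in patterns.get(loop.motif, []):
            hi, lo = pos[pat.high_pos - 1], pos[pat.low_pos - 1]
            r_hi, r_lo = profile.reactivity(hi), profile.reactivity(lo)
            if not (np.isnan(r_hi) or np.isnan(r_lo)):
                out.append(r_hi - r_lo)
        return out

    for rna_id, ref in references.items():
        profile = profiles[rna_id]
        ref_loops = extract_loops(ref)
        ref_keys = {lp.key() for lp in ref_loops}
        for loop in ref_loops:
            true_D.extend(pair_diffs(loop, profile))
        seen_false: set[tuple] = set()
        for cand in ensembles.get(rna_id, []):
            for loop in extract_loops(cand):
                key = loop.key()
                if key in ref_keys or key in seen_false:
                    continue
                seen_false.add(key)
                false_D.extend(pair_diffs(loop, profile))
    return np.asarray(true_D), np.asarray(false_D)


def count_ensemble_pairs(
    references: Mapping[str, SecondaryStructure],
    ensembles: Mapping[str, Sequence[SecondaryStructure]],
    patterns: Mapping[MotifSignature, Sequence[CharacteristicPattern]],
) -> tuple[int, int]:
    """Pattern-pair counts in true vs false ensemble loops, with multiplicity.

    Class priors are the fractions of pattern pairs residing in true or
    false loops across the whole candidate ensemble, so a loop present in
    many candidates counts once per candidate — unlike the deduplicated
    samples used for density fitting.
    """
    n_true = n_false = 0
    for rna_id, ref in references.items():
        ref_keys = {lp.key() for lp in extract_loops(ref)}
        for cand in ensembles.get(rna_id, []):
            for loop in extract_loops(cand):
                n = len(patterns.get(loop.motif, []))
                if loop.key() in ref_keys:
                    n_true += n
                else:
                    n_false += n
    return n_true, n_false


def generate_benchmark(
    n_rnas: int,
    seed: int,
    spec: SynthSpec | None = None,
) -> dict[str, tuple[SecondaryStructure, ShapeProfile]]:
    """A set of synthetic RNAs sharing generation conditions.

    Each RNA gets an independent sub-seed; the returned mapping is keyed by
    RNA id ('rna_000', ...).
    """
    base = spec or SynthSpec()
    out: dict[str, tuple[SecondaryStructure, ShapeProfile]] = {}
    for k in range(n_rnas):
        s = SynthSpec(
            length=base.length,
            inventory=dict(base.inventory),
            paired_mean=base.paired_mean,
            paired_sd=base.paired_sd,
            loop_mean=base.loop_mean,
            loop_sd=base.loop_sd,
            pattern_offsets=dict(base.pattern_offsets),
            missing_rate=base.missing_rate,
            seed=seed * 100003 + k,
        )
        structure = generate_structure(s)
        profile = generate_shape(structure, s)
        out[f"rna_{k:03d}"] = (
            SecondaryStructure(structure.sequence, structure.pairs, name=f"rna_{k:03d}"),
            profile,
        )
    return out
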