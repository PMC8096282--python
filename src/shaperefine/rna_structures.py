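"""Domain types and file I/O for RNA secondary structures and SHAPE profiles.

Coordinates are 1-based closed intervals throughout, following the CT and
SHAPE file conventions.  A :class:`SecondaryStructure` keeps a properly
nested base-pair layer plus a set of pseudoknotted (crossing) pairs; loop
extraction operates on the nested layer only and drops loops that touch
pseudoknots, mirroring how reference RNA structure sets treat crossing
interactions.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("shaperefine")

MISSING = -999.0
_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

__all__ = [
    "MISSING",
    "SecondaryStructure",
    "Loop",
    "MotifSignature",
    "ShapeProfile",
    "StructureParseError",
    "parse_dotbracket",
    "write_dotbracket",
    "parse_ct",
    "write_ct",
    "parse_shape",
    "write_shape",
    "read_dotbracket_file",
    "write_dotbracket_file",
    "extract_loops",
    "motif_of",
    "pattern_positions",
]


class StructureParseError(ValueError):
    """Raised for malformed structure or reactivity files."""


def _crossing(p: tuple[int, int], q: tuple[int, int]) -> bool:
    (i, j), (k, l) = p, q
    return (i < k < j < l) or (k < i < l < j)


@dataclass(frozen=True)
class MotifSignature:
    """Equivalence class of loops: type plus canonical length spec.

    For internal loops the two side lengths are stored (min, max) so that
    e.g. 1x2 and 2x1 loops share a motif; hairpins and bulges carry a single
    length.  Multibranch loops carry their ordered side-length tuple.
    """

    loop_type: str
    lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.loop_type == "internal":
            if len(self.lengths) != 2:
                raise ValueError("internal motif needs two side lengths")
            object.__setattr__(self, "lengths", tuple(sorted(self.lengths)))
        elif self.loop_type in ("hairpin", "bulge") and len(self.lengths) != 1:
            raise ValueError(f"{self.loop_type} motif needs one length")

    @property
    def total_length(self) -> int:
        return sum(self.lengths)

    def __str__(self) -> str:
        if self.loop_type == "internal":
            return f"internal-{self.lengths[0]}x{self.lengths[1]}"
        if self.loop_type == "multibranch":
            return "multibranch-" + ",".join(map(str, self.lengths))
        return f"{self.loop_type}-{self.lengths[0]}"

    @classmethod
    def from_string(cls, text: str) -> "MotifSignature":
        try:
            loop_type, spec = text.split("-", 1)
            if loop_type == "internal":
                a, b = spec.split("x")
                return cls("internal", (int(a), int(b)))
            if loop_type == "multibranch":
                return cls("multibranch", tuple(int(x) for x in spec.split(",")))
            if loop_type in ("hairpin", "bulge"):
                return cls(loop_type, (int(spec),))
        except (ValueError, KeyError) as exc:
            raise StructureParseError(f"unparseable motif string {text!r}") from exc
        raise StructureParseError(f"unknown loop type in motif string {text!r}")


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA sequence with its base-pair table.

    ``pairs`` is the full pair set (1-based, i < j); ``pk_pairs`` is the
    subset that crosses the nested layer (pseudoknots).  ``pairs - pk_pairs``
    is guaranteed properly nested.
    """

    sequence: str
    pairs: frozenset[tuple[int, int]]
    pk_pairs: frozenset[tuple[int, int]] = frozenset()
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper().replace("T", "U"))
        pairs = frozenset((min(i, j), max(i, j)) for i, j in self.pairs)
        pk = frozenset((min(i, j), max(i, j)) for i, j in self.pk_pairs)
        if not pk:
            pairs_list = sorted(pairs)
            pk = frozenset(_split_pseudoknots(pairs_list))
        object.__setattr__(self, "pairs", pairs)
        object.__setattr__(self, "pk_pairs", pk)
        self._validate()

    def _validate(self) -> None:
        L = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (1 <= i < j <= L):
                raise ValueError(f"pair ({i},{j}) outside sequence of length {L}")
            if i in seen or j in seen:
                raise ValueError(f"index in more than one pair near ({i},{j})")
            seen.update((i, j))
        if not self.pk_pairs <= self.pairs:
            raise ValueError("pk_pairs must be a subset of pairs")
        nested = sorted(self.pairs - self.pk_pairs)
        for a in range(len(nested)):
            for b in range(a + 1, len(nested)):
                if _crossing(nested[a], nested[b]):
                    raise ValueError(
                        f"nested layer contains crossing pairs {nested[a]} / {nested[b]}"
                    )
        non_canonical = [
            (i, j)
            for i, j in self.pairs - self.pk_pairs
            if (self.sequence[i - 1], self.sequence[j - 1]) not in _CANONICAL
            and "N" not in (self.sequence[i - 1], self.sequence[j - 1])
        ]
        if non_canonical:
            # deduplicated by the default warnings filter; details at DEBUG
            warnings.warn("non-canonical base pairs accepted", stacklevel=2)
            logger.debug("%d non-canonical pair(s): %s", len(non_canonical), non_canonical)

    @property
    def nested_pairs(self) -> frozenset[tuple[int, int]]:
        return self.pairs - self.pk_pairs

    def __len__(self) -> int:
        return len(self.sequence)

    def partner(self, i: int) -> int | None:
        for a, b in self.pairs:
            if a == i:
                return b
            if b == i:
                return a
        return None


def _split_pseudoknots(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy nested-layer extraction: a pair crossing any already-kept pair
    is flagged pseudoknotted.  Pairs are visited 5'-first so the earliest
    helix wins, matching the usual dot-bracket layering of CT files."""
    kept: list[tuple[int, int]] = []
    pk: list[tuple[int, int]] = []
    for p in sorted(pairs):
        if any(_crossing(p, q) for q in kept):
            pk.append(p)
        else:
            kept.append(p)
    return pk


@dataclass(frozen=True)
class Loop:
    """One loop instance inside a parent structure.

    ``sides`` holds the runs of unpaired positions in 5'->3' order: one run
    for hairpins and bulges, two for internal loops, and one run per gap
    (possibly empty) for multibranch loops.  ``closing_pairs`` are the
    helix-terminal pairs bounding the loop (outer pair first);
    ``flanking_pairs`` the second stacked pair of each bounding helix.
    """

    loop_type: str
    sides: tuple[tuple[int, ...], ...]
    closing_pairs: tuple[tuple[int, int], ...]
    flanking_pairs: tuple[tuple[int, int], ...]
    motif: MotifSignature

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(p for side in self.sides for p in side)

    def key(self) -> tuple:
        """Identity used for loop 'retained/absent' comparisons."""
        return (self.loop_type, self.sides, self.closing_pairs)

    def __str__(self) -> str:
        runs = ";".join("-".join(map(str, s)) if s else "." for s in self.sides)
        return f"{self.motif}@{runs}"


class ShapeProfile:
    """Per-nucleotide SHAPE reactivities; NaN marks missing values.

    File representation uses the conventional -999 sentinel; in memory the
    profile is a float array indexed 1..L through :meth:`reactivity`.
    """

    def __init__(self, reactivities: Sequence[float] | np.ndarray):
        arr = np.asarray(reactivities, dtype=float).copy()
        arr[arr <= MISSING] = np.nan
        if np.any(np.isinf(arr)):
            raise ValueError("non-missing reactivities must be finite")
        self.values = arr

    def __len__(self) -> int:
        return len(self.values)

    def reactivity(self, i: int) -> float:
        """1-based lookup; returns NaN for missing."""
        if not 1 <= i <= len(self.values):
            raise IndexError(f"position {i} outside profile of length {len(self.values)}")
        return float(self.values[i - 1])

    def is_missing(self, i: int) -> bool:
        return bool(np.isnan(self.reactivity(i)))

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def copy(self) -> "ShapeProfile":
        return ShapeProfile(self.values)


# ---------------------------------------------------------------------------
# Parsing / writing
# ---------------------------------------------------------------------------

_OPEN = {"(": ")", "[": "]", "{": "}", "<": ">"}
_LAYER_ORDER = "([{<"


def parse_dotbracket(text: str, sequence: str) -> SecondaryStructure:
    """Parse one dot-bracket string against its sequence.

    The round-bracket layer becomes the nested layer; every other bracket
    alphabet ( ``[] {} <>`` ) populates ``pk_pairs``, as does any
    round-layer pair that crosses another.
    """
    text = text.strip()
    sequence = sequence.strip()
    if len(text) != len(sequence):
        raise StructureParseError(
            f"structure length {len(text)} != sequence length {len(sequence)}"
        )
    stacks: dict[str, list[int]] = {c: [] for c in _OPEN}
    close_of = {v: k for k, v in _OPEN.items()}
    pairs_by_layer: dict[str, set[tuple[int, int]]] = {c: set() for c in _OPEN}
    for pos, ch in enumerate(text, start=1):
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks[ch].append(pos)
        elif ch in close_of:
            opener = close_of[ch]
            if not stacks[opener]:
                raise StructureParseError(f"unbalanced {ch!r} at position {pos}")
            i = stacks[opener].pop()
            pairs_by_layer[opener].add((i, pos))
        else:
            raise StructureParseError(f"unexpected character {ch!r} at position {pos}")
    for opener, stack in stacks.items():
        if stack:
            raise StructureParseError(f"unbalanced {opener!r} at position {stack[-1]}")
    pk: set[tuple[int, int]] = set()
    for layer in "[{<":
        pk |= pairs_by_layer[layer]
    round_pairs = sorted(pairs_by_layer["("])
    for a in range(len(round_pairs)):
        for b in range(a + 1, len(round_pairs)):
            if _crossing(round_pairs[a], round_pairs[b]):
                pk.update((round_pairs[a], round_pairs[b]))
    all_pairs = pairs_by_layer["("] | pk
    return SecondaryStructure(sequence, frozenset(all_pairs), frozenset(pk))


def write_dotbracket(s: SecondaryStructure) -> str:
    """Render a structure as multi-layer dot-bracket text."""
    out = ["."] * len(s)
    for i, j in s.nested_pairs:
        out[i - 1], out[j - 1] = "(", ")"
    remaining = sorted(s.pk_pairs)
    layers: list[list[tuple[int, int]]] = []
    for p in remaining:
        for layer in layers:
            if not any(_crossing(p, q) for q in layer):
                layer.append(p)
                break
        else:
            layers.append([p])
    if len(layers) > 3:
        raise ValueError("more pseudoknot layers than bracket alphabets")
    for layer, opener in zip(layers, "[{<"):
        for i, j in layer:
            out[i - 1], out[j - 1] = opener, _OPEN[opener]
    return "".join(out)


def read_dotbracket_file(text: str) -> list[SecondaryStructure]:
    """Read a multi-structure dot-bracket file.

    Format: one ``>name`` header per structure; the sequence line is
    mandatory after the first header and optional afterwards (reused).
    """
    structures: list[SecondaryStructure] = []
    sequence: str | None = None
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise StructureParseError(f"expected '>' header, got {lines[i]!r}")
        name = lines[i][1:].strip()
        i += 1
        if i >= len(lines):
            raise StructureParseError(f"structure missing after header {name!r}")
        if set(lines[i]) <= set("ACGUNT acgunt"):
            sequence = lines[i].upper()
            i += 1
            if i >= len(lines):
                raise StructureParseError(f"structure missing after sequence of {name!r}")
        if sequence is None:
            raise StructureParseError("first record must carry a sequence line")
        s = parse_dotbracket(lines[i], sequence)
        structures.append(SecondaryStructure(s.sequence, s.pairs, s.pk_pairs, name=name))
        i += 1
    return structures


def write_dotbracket_file(structures: Iterable[SecondaryStructure]) -> str:
    buf = io.StringIO()
    last_seq = None
    for k, s in enumerate(structures):
        buf.write(f">{s.name or f'structure_{k + 1}'}\n")
        if s.sequence != last_seq:
            buf.write(s.sequence + "\n")
            last_seq = s.sequence
        buf.write(write_dotbracket(s) + "\n")
    return buf.getvalue()


def parse_ct(text: str) -> SecondaryStructure:
    """Parse a standard 6-column CT record (single structure)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureParseError("empty CT input")
    header = lines[0].split()
    try:
        length = int(header[0])
    except ValueError as exc:
        raise StructureParseError(f"CT header must start with length: {lines[0]!r}") from exc
    name = " ".join(header[1:]) if len(header) > 1 else ""
    seq = ["N"] * length
    pairs: set[tuple[int, int]] = set()
    seen: set[int] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        cols = ln.split()
        if len(cols) < 6:
            raise StructureParseError(f"line {lineno}: expected 6 CT columns, got {len(cols)}")
        try:
            idx, partner = int(cols[0]), int(cols[4])
        except ValueError as exc:
            raise StructureParseError(f"line {lineno}: non-numeric CT index") from exc
        if not 1 <= idx <= length:
            raise StructureParseError(f"line {lineno}: index {idx} out of range 1..{length}")
        if idx in seen:
            raise StructureParseError(f"line {lineno}: duplicate index {idx}")
        seen.add(idx)
        seq[idx - 1] = cols[1].upper()
        if partner:
            if not 1 <= partner <= length:
                raise StructureParseError(f"line {lineno}: partner {partner} out of range")
            pairs.add((min(idx, partner), max(idx, partner)))
    return SecondaryStructure("".join(seq), frozenset(pairs), name=name)


def write_ct(s: SecondaryStructure) -> str:
    partner = {i: j for i, j in s.pairs} | {j: i for i, j in s.pairs}
    buf = io.StringIO()
    buf.write(f"{len(s)} {s.name}".rstrip() + "\n")
    for i, base in enumerate(s.sequence, start=1):
        nxt = i + 1 if i < len(s) else 0
        buf.write(f"{i} {base} {i - 1} {nxt} {partner.get(i, 0)} {i}\n")
    return buf.getvalue()


def parse_shape(text: str) -> ShapeProfile:
    """Parse a two-column SHAPE file (1-based index, reactivity, -999 missing).

    The profile spans 1..max(index); indices absent from the file are
    missing.
    """
    entries: dict[int, float] = {}
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip() or ln.lstrip().startswith("#"):
            continue
        cols = ln.split()
        if len(cols) < 2:
            raise StructureParseError(f"line {lineno}: expected two columns")
        try:
            idx = int(cols[0])
            val = float(cols[1])
        except ValueError as exc:
            raise StructureParseError(f"line {lineno}: non-numeric entry") from exc
        if idx < 1:
            raise StructureParseError(f"line {lineno}: index {idx} out of range")
        if idx in entries:
            raise StructureParseError(f"line {lineno}: duplicate index {idx}")
        entries[idx] = val
    if not entries:
        return ShapeProfile(np.empty(0))
    arr = np.full(max(entries), np.nan)
    for idx, val in entries.items():
        arr[idx - 1] = np.nan if val <= MISSING else val
    return ShapeProfile(arr)


def write_shape(profile: ShapeProfile) -> str:
    lines = []
    for i, v in enumerate(profile.values, start=1):
        lines.append(f"{i}\t{MISSING:.0f}" if np.isnan(v) else f"{i}\t{v:.4f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Loop extraction
# ---------------------------------------------------------------------------

def _faces(s: SecondaryStructure):
    """Enumerate loop faces of the nested layer.

    Yields (closing_pair, sides, child_pairs): for each pair (i, j) that
    directly encloses the face, the unpaired runs between consecutive
    enclosed helices and the child closing pairs, all in 5'->3' order.
    """
    nested = s.nested_pairs
    partner = {}
    for i, j in nested:
        partner[i], partner[j] = j, i
    for (i, j) in sorted(nested):
        sides: list[tuple[int, ...]] = []
        children: list[tuple[int, int]] = []
        run: list[int] = []
        k = i + 1
        while k < j:
            if k in partner:
                sides.append(tuple(run))
                run = []
                children.append((k, partner[k]))
                k = partner[k] + 1
            else:
                run.append(k)
                k += 1
        sides.append(tuple(run))
        yield (i, j), tuple(sides), tuple(children)


def _classify_face(sides, children) -> str | None:
    if len(children) == 0:
        return "hairpin"
    if len(children) == 1:
        left, right = sides
        if left and right:
            return "internal"
        if left or right:
            return "bulge"
        return None  # stacked helix, no loop
    return "multibranch"


def _motif_from(loop_type: str, sides: tuple[tuple[int, ...], ...]) -> MotifSignature:
    if loop_type == "internal":
        return MotifSignature("internal", (len(sides[0]), len(sides[1])))
    if loop_type == "multibranch":
        return MotifSignature("multibranch", tuple(len(s) for s in sides))
    return MotifSignature(loop_type, (sum(len(s) for s in sides),))


def motif_of(loop: Loop) -> MotifSignature:
    """Canonical motif signature of a loop (internal loops: min x max)."""
    return _motif_from(loop.loop_type, loop.sides)


def pattern_positions(loop: Loop) -> tuple[int, ...]:
    """Sequence positions of a loop in motif-position order.

    Hairpins and bulges enumerate from the 5' end of the loop.  Internal
    loops enumerate the shorter side first (mirror-mapped when the 5' side
    is the longer one) so that asymmetric loops of mirrored geometry share
    one position numbering.  Multibranch loops have no pattern order.
    """
    if loop.loop_type == "internal":
        a, b = loop.sides
        return a + b if len(a) <= len(b) else b + a
    return loop.positions


def extract_loops(
    s: SecondaryStructure,
    require_stacked: bool = True,
    drop_pseudoknot: bool = True,
) -> list[Loop]:
    """Extract hairpin/bulge/internal/multibranch loops from a structure.

    Eligibility: every bounding helix must contain at least two consecutive
    stacked pairs (the closing pair plus one flanking pair, which is
    recorded); loops any of whose residues or closing pairs touch a
    pseudoknotted pair are dropped.  Both filters can be disabled for
    exhaustive face enumeration.
    """
    pairs = s.pairs
    pk_positions = {p for pair in s.pk_pairs for p in pair}
    loops: list[Loop] = []
    for (i, j), sides, children in _faces(s):
        loop_type = _classify_face(sides, children)
        if loop_type is None:
            continue
        if loop_type == "hairpin" and not sides[0]:
            continue  # zero-length hairpin face: not a physical loop
        if loop_type == "bulge":
            run_sides = tuple(side for side in sides if side)
        else:
            run_sides = sides
        closing = ((i, j),) + children
        # flanking pair: outward for the outer helix, inward for children
        flanking = [(i - 1, j + 1)] + [(k + 1, l - 1) for k, l in children]
        if require_stacked and any(tuple(f) not in pairs for f in flanking):
            continue
        residues = {p for side in run_sides for p in side}
        touches_pk = bool(residues & pk_positions) or any(
            a in pk_positions or b in pk_positions for a, b in closing
        )
        if drop_pseudoknot and touches_pk:
            continue
        loops.append(
            Loop(
                loop_type=loop_type,
                sides=run_sides,
                closing_pairs=closing,
                flanking_pairs=tuple(
                    tuple(f) if tuple(f) in pairs else (0, 0) for f in flanking
                ),
                motif=_motif_from(loop_type, run_sides),
            )
        )
    return loops
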