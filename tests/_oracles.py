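"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the package's own algorithms: faces are found via
innermost-enclosing-pair scans, Wilcoxon null distributions via explicit
2^n sign enumeration, and random nested structures via direct stack
simulation on bracket strings.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# Random nested structures (independent generator)
# ---------------------------------------------------------------------------

def random_dotbracket(rng: np.random.Generator, length: int, p_open: float = 0.4,
                      min_hairpin: int = 3) -> str:
    """Random balanced dot-bracket string by left-to-right stack simulation."""
    out = []
    stack: list[int] = []
    for pos in range(length):
        remaining = length - pos
        can_close = stack and (pos - stack[-1] - 1 >= min_hairpin)
        must_close = stack and remaining <= len(stack)
        if must_close:
            out.append(")" if can_close else ".")
            if can_close:
                stack.pop()
            continue
        r = rng.random()
        if r < p_open and remaining > len(stack) + min_hairpin + 1:
            stack.append(pos)
            out.append("(")
        elif r < p_open + 0.3 and can_close:
            stack.pop()
            out.append(")")
        else:
            out.append(".")
    # close anything left unclosed as dots
    text = "".join(out)
    if stack:
        chars = list(text)
        for pos in stack:
            chars[pos] = "."
        text = "".join(chars)
    return text


def random_sequence(rng: np.random.Generator, db: str) -> str:
    """Sequence compatible with a dot-bracket string (complementary pairs)."""
    comp = {"G": "C", "C": "G", "A": "U", "U": "A"}
    seq = [""] * len(db)
    stack = []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            b = "ACGU"[rng.integers(4)]
            seq[j], seq[i] = b, comp[b]
        else:
            seq[i] = "ACGU"[rng.integers(4)]
    return "".join(seq)


# ---------------------------------------------------------------------------
# Brute-force loop-face enumeration
# ---------------------------------------------------------------------------

def brute_force_loops(pairs: set[tuple[int, int]], length: int,
                      pk_pairs: set[tuple[int, int]] = frozenset(),
                      require_stacked: bool = True,
                      drop_pseudoknot: bool = True):
    """Enumerate loops by innermost-enclosing-pair scanning.

    For every position/pair, its enclosing face is the innermost nested
    pair containing it; faces are classified by counting child pairs, and
    eligibility (two stacked pairs per bounding helix, no pseudoknot
    contact) is checked by direct membership tests.  Returns a set of
    hashable loop descriptors: (loop_type, sides, closing_pairs).
    """
    nested = sorted(set(pairs) - set(pk_pairs))
    paired = {p for pr in nested for p in pr}

    def innermost_enclosing(x: float):
        best = None
        for (i, j) in nested:
            if i < x < j:
                if best is None or (i > best[0]):
                    best = (i, j)
        return best

    faces: dict[tuple[int, int], dict] = {}
    for (i, j) in nested:
        faces[(i, j)] = {"unpaired": [], "children": []}
    for x in range(1, length + 1):
        if x in paired:
            continue
        enc = innermost_enclosing(x)
        if enc is not None:
            faces[enc]["unpaired"].append(x)
    for (i, j) in nested:
        # a child of face (a,b): innermost pair strictly enclosing (i,j)
        best = None
        for (a, b) in nested:
            if a < i and j < b:
                if best is None or a > best[0]:
                    best = (a, b)
        if best is not None:
            faces[best]["children"].append((i, j))

    pk_positions = {p for pr in pk_pairs for p in pr}
    out = set()
    for (i, j), face in faces.items():
        children = sorted(face["children"])
        unpaired = sorted(face["unpaired"])
        # split unpaired into runs between consecutive helices
        runs = []
        segs = []
        prev = i
        for (k, l) in children:
            segs.append((prev, k))
            prev = l
        segs.append((prev, j))
        for a, b in segs:
            runs.append(tuple(x for x in unpaired if a < x < b))
        n_child = len(children)
        if n_child == 0:
            if not runs[0]:
                continue
            loop_type = "hairpin"
            sides = (runs[0],)
        elif n_child == 1:
            left, right = runs
            if left and right:
                loop_type = "internal"
                sides = (left, right)
            elif left or right:
                loop_type = "bulge"
                sides = (left,) if left else (right,)
            else:
                continue  # stacked pairs
        else:
            loop_type = "multibranch"
            sides = tuple(runs)
        closing = ((i, j),) + tuple(children)
        if require_stacked:
            flanks = [(i - 1, j + 1)] + [(k + 1, l - 1) for k, l in children]
            if any(f not in set(pairs) for f in flanks):
                continue
        if drop_pseudoknot:
            residues = {x for s in sides for x in s}
            if residues & pk_positions:
                continue
            if any(a in pk_positions or b in pk_positions for a, b in closing):
                continue
        out.add((loop_type, sides, closing))
    return out


# ---------------------------------------------------------------------------
# Brute-force Wilcoxon signed-rank (full 2^n enumeration)
# ---------------------------------------------------------------------------

def brute_force_wilcoxon(x, y) -> float:
    """Two-sided exact p-value by enumerating all 2^n sign assignments."""
    diffs = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        return 1.0
    absd = np.abs(diffs)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    # midranks for ties
    i = 0
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    w_obs = ranks[diffs > 0].sum()
    sums = []
    for signs in itertools.product((0, 1), repeat=n):
        sums.append(sum(r for r, s in zip(ranks, signs) if s))
    sums = np.asarray(sums)
    m = 2.0 ** n
    tol = 1e-9
    cdf = np.sum(sums <= w_obs + tol) / m
    sf = np.sum(sums >= w_obs - tol) / m
    return min(1.0, 2.0 * min(cdf, sf))


# ---------------------------------------------------------------------------
# Brute-force candidate selection
# ---------------------------------------------------------------------------

def brute_force_select(guidance, candidates, profile, patterns, model):
    """Independent re-implementation of selection criteria (i)-(iv).

    Used to cross-check select_structure; mirrors the documented rules
    directly: good-loop retention, fair/poor region scans with 4-nt padded
    regions, total penalty over pattern-bearing loops, lowest-total
    fallback.
    """
    import shaperefine as sr
    from shaperefine.refinement import classify_loops
    from shaperefine.posterior_model import loop_penalty
    from shaperefine.refinement import FAIR_THRESHOLD

    assessments = classify_loops(guidance, profile, patterns, model)
    pool = list(candidates)
    if not any(c.pairs == guidance.pairs for c in pool):
        pool.append(guidance)
    rows = []
    for cand in pool:
        scored = [loop_penalty(l, profile, patterns, model)
                  for l in sr.extract_loops(cand)]
        keys = {s.loop.key() for s in scored}
        ok_i = all(a.loop.key() in keys for a in assessments if a.category == "good")
        ok_ii = True
        ok_iii = True
        for a in assessments:
            regions = a.region
            overl = [
                s for s in scored
                if s.patterns_available
                and any(lo <= p <= hi for p in s.loop.positions for lo, hi in regions)
            ]
            if a.category == "fair":
                if any(s.penalty > FAIR_THRESHOLD for s in overl):
                    ok_ii = False
            elif a.category == "poor":
                if a.loop.key() in keys:
                    ok_iii = False
                if any(s.penalty >= a.penalty for s in overl):
                    ok_iii = False
        total = sum(s.penalty for s in scored if s.patterns_available)
        rows.append((ok_i and ok_ii and ok_iii, total))
    passing = [(t, i) for i, (ok, t) in enumerate(rows) if ok]
    if passing:
        t, i = min(passing)
        return pool[i].pairs, False
    t, i = min((t, i) for i, (_, t) in enumerate(rows))
    return pool[i].pairs, True


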