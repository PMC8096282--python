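# Methods

This note documents the models and procedures implemented in
`shaperefine`, the choices made where the design was genuinely open, and
what the synthetic benchmark does and does not establish.

## Structures, loops and coordinates

Coordinates are 1-based closed intervals (the CT/SHAPE convention). A
`SecondaryStructure` carries the full base-pair set plus the subset
flagged pseudoknotted; the remainder is guaranteed properly nested. When
pairs arrive without layer information (CT files), the nested layer is the
greedy 5′-first maximal non-crossing subset and everything that crosses it
is a pseudoknot. In dot-bracket input, round brackets form the nested
layer and `[] {} <>` layers are pseudoknots. Non-canonical pairs (anything
other than A-U, G-C, G-U) are accepted with a warning, since ensembles
from non-canonical-pair folding legitimately contain them.

Loop extraction classifies every face of the nested layer as hairpin,
bulge, internal or multibranch. Two eligibility rules apply, both
motivated by data quality rather than combinatorics:

- **Two flanking base pairs.** Each bounding helix must contain at least
  two consecutive stacked pairs; the closing pair and its stacked
  neighbour are recorded. Lone pairs produce geometrically ill-defined
  loops and are skipped. We enforce the rule on *every* bounding helix of
  internal/bulge/multibranch loops (the weakest defensible alternative —
  recording flanks only when present — would admit loops whose boundaries
  are single unstable pairs).
- **Pseudoknot exclusion.** A loop is dropped when any of its unpaired
  residues or closing pairs touches a pseudoknotted pair; such "loops" are
  actually parts of higher-order interactions and their reactivities do
  not reflect the loop motif.

Motifs are type + length classes: `hairpin-k`, `bulge-k`,
`internal-a×b` with a ≤ b. For asymmetric internal loops the motif
position numbering runs over the **shorter side first** (5′ side first on
ties), mirror-mapping loops whose 5′ side is the longer one. The
published motif labels are unordered (1×2, not 2×1), so some such
convention is required; the mirror rule makes canonicalization idempotent
and is applied consistently in pattern discovery and scoring.

## Pattern discovery

Per motif, loop instances form a matrix (rows = instances, columns = motif
positions, missing values propagated). Every column pair is compared with
a two-sided paired Wilcoxon signed-rank test:

- zero differences are dropped before ranking (classic Wilcoxon);
- ties get midranks; the exact null distribution of the positive rank sum
  is built by dynamic programming over sign assignments (identical to full
  2^n enumeration, used for n ≤ 25); larger n uses the normal
  approximation with tie-corrected variance and continuity correction;
- pairs with fewer than 5 usable rows are skipped — the exact test cannot
  reach p < 0.05 below n = 5, so testing them is noise;
- retained patterns need p < α (default 0.05) **and** a rank among the
  top 2 smallest p-values of the motif. No further multiple-testing
  correction is applied: the top-2 + α rule is itself the selection rule.

The test is two-sided and the direction (high vs low position) is assigned
afterwards from the paired means; patterns are reported and applied with
this globally learned direction. Multibranch loops are excluded from
discovery — their side-length geometry is too heterogeneous for
position-wise comparison.

## Posterior model

The difference D = r(high) − r(low) of a pattern pair applied to one loop
is scored under two maximum-likelihood-fitted families:
normal-inverse Gaussian for the true class and Johnson's S_U for the false
class (`scipy.stats.norminvgauss` / `johnsonsu`), with a Kolmogorov–
Smirnov goodness-of-fit p-value recorded at fit time. A failing KS logs a
warning but does not abort: on real (and synthetic) data the false-class
differences are a mixture over many wrong-loop geometries, which the S_U
family approximates but does not match exactly, and the posterior is
insensitive to tail misfit near the decision boundary.

Priors are the fractions of pattern pairs residing in true vs false loops
**counted with multiplicity across the whole candidate ensemble** — a loop
retained by most candidates contributes once per candidate. Density
fitting, in contrast, uses each distinct loop once. The distinction
matters: distinct-loop counting grossly overweights the false class
(wrong loops are diverse, right loops recur) and produced unusable priors
in early versions of the synthetic benchmark.

Numerical decisions:

- posterior underflow (both densities 0 at an extreme D) returns the
  prior — an uninformative datum — rather than NaN;
- δ = −ln[P/(1−P)] clips P to [1e−12, 1−1e−12] before the log;
- the penalty sums δ over pairs with posterior **strictly** below 0.5;
  a pair at exactly 0.5 contributes nothing (δ = 0 there anyway);
- pairs with a missing reactivity are skipped; a loop whose motif has no
  patterns is flagged `patterns_available = False` and reports penalty 0,
  which callers must treat as "not applicable", not "good" — the
  classifier maps it to *fair*.

Default priors (0.549 / 0.451) ship as configuration defaults and are
replaced by refitted values whenever a benchmark is available.

## Refinement

Good/fair/poor thresholds are penalty = 0, (0, 1] (or patterns
unavailable), and > 1; the boundary 1.0 is inclusive-fair. Loop regions
extend each unpaired side by 4 nt, clipped to the sequence; multi-sided
loops use the union of per-side intervals, and "overlap" means any
unpaired residue of a candidate loop falls inside the region. Candidate
loops without patterns can never violate criteria (ii)/(iii) (they have no
penalty) and contribute 0 to the total; criterion (iii) is vacuously
satisfied when no candidate loop overlaps a poor region (the region was
paired away, which *is* the desired replacement). Loop identity for
criterion (i) is the strict one — same type, same unpaired positions,
same closing pairs. The guidance structure always joins the candidate
pool (it may legitimately win); ties in total penalty break by input
order, making selection deterministic and invariant to candidate
duplication. The open choice of what criterion (iv) sums was resolved to
*all* candidate loops with available patterns (not only loops in guidance
regions): a candidate should not escape scrutiny by moving errors outside
the audited regions.

## Evaluation

Sensitivity = TP/(TP+FN) and PPV = TP/(TP+FP) over base-pair sets, with an
optional ±1-slip match (each native pair consumed at most once). MCC is
reported as √(sensitivity × PPV) — the standard approximation in this
field, where true negatives (position pairs in neither structure) dwarf
everything else; an exact confusion-matrix MCC with
TN = C(L,2) − TP − FP − FN is available behind `exact_mcc=True`. Undefined
ratios (empty native or predicted sets) are reported as 0 with an explicit
flag.

Noise robustness shuffles round(f · #observed) reactivities among
themselves (multiset preserved, missing untouched), re-runs selection and
averages accuracy over seeded repeats (default 10 per noise level).

## Synthetic data

The generator builds the statistical world the model assumes: paired
residues draw from a truncated normal with mean 0.1 and sd 0.1, loop
residues from mean 0.5 and sd 0.25 (both truncated at zero, unitless
normalized SHAPE), and each loop motif in the planted-pattern table gets a
position-wise offset added after truncation, so planted mean differences
are exact. Structures are stem-loop arms (one per requested motif, helix
lengths 3–5 bp so every loop has its two flanking pairs) joined by 8-nt
single-stranded linkers; bulge/internal arms are capped by a hairpin whose
length avoids the requested hairpin motifs. Ensembles perturb helices
locally — shrink/grow/shift/translate by 1–3 bp, keeping at least two
stacked pairs and re-validating nestedness — each helix independently with
the given probability. `plant_wrong_loop` translates one standalone
stem-loop by its full loop length, producing a same-motif loop over
previously paired residues: the canonical "falsely predicted loop".

Key generator defaults and why:

- **Planted effect size 1.5** at one position per motif. This is the
  contrast between a flexible apical residue (reactivity ~2) and an
  ordinary loop residue (~0.5), and it separates the true/false difference
  classes by ≈ 4σ (difference noise √2·0.25 ≈ 0.35). The separation is
  deliberately clear: the benchmark tests the machinery — extraction,
  testing, fitting, Bayes algebra, selection logic — under conditions
  where its assumptions hold.
- **Six-motif inventory plus the cap motif**, all pattern-bearing, so that
  perturbed candidate loops usually land on a motif that can be scored.
  With sparse pattern coverage, candidates can hide errors in patternless
  motifs and the total-penalty criterion loses discrimination — the same
  reason the original benchmark's pattern tables span many motif lengths.
- **Perturbation rate 0.9 per helix** for ensembles, giving the diversity
  (and the roughly balanced true/false pattern-pair priors) of
  Boltzmann-sampled suboptimal sets.
- **Missing rate 0.02**, the typical share of unresolvable positions in a
  normalized SHAPE profile.

What passing on this benchmark does **not** show: performance on real
SHAPE data, where reactivity distributions are heavy-tailed and
sequence-dependent, loop patterns are weaker and partially motif-specific,
structures contain multibranch junctions and pseudoknots at higher
density, and candidate ensembles come from thermodynamic sampling with
correlated errors. The generator's truncated normals deliberately do not
match the fitted NIG/Johnson-S_U families — the scoring model never
assumes the generating family, and the simulate-then-fit recovery tests
use draws from the families themselves.

## Problem sizes and numerical checks in the test suite

The suite trains one shared synthetic benchmark (20 RNAs of 190 nt,
ensembles of 50 at rate 0.9) and runs: loop-extraction equivalence against
a brute-force face oracle on 200 random structures (length ≤ 80); exact
Wilcoxon equivalence against full 2^n enumeration on 500 random paired
sets (n ≤ 12) plus exact-vs-approximation agreement within 0.02 at n = 20;
Bayes arithmetic to 1e−12 on 1000 random tuples; simulate-then-fit
recovery on 10,000 draws per family over 20 seeds, requiring mean relative
parameter error < 10% and KS ≥ 0.05 in at least 18 runs (per-parameter
maxima trade off between shape and location at this sample size and are
not a meaningful recovery measure); planted-pattern recovery (offset 0.4,
sd 0.2, 50 instances) in ≥ 90% of 20 seeds with a one-sided binomial check
that null retention stays at the nominal per-pair rate; selection
equivalence against an independently coded criteria oracle on 50 random
pools, ≥ 90% true-structure recovery over 20 planted-poor trials, and
fallback on truth-free pools; end-to-end mean-MCC improvement over 20
RNAs; and noise degradation from shuffle fraction 0 to 1 over 10 repeats.
The generating parameters for the recovery test — NIG(1.0, 0.5, 1.0, 1.0)
and Johnson-S_U(1.0, 1.0, 1.0, 1.0) — were chosen for identifiability (all
components O(1), none near zero, since relative error is ill-posed at 0).

## Known limitations

- Guidance structures and ensembles are consumed from files; the optional
  external-engine adapter shells out to an installed folding program and
  degrades to an informative error without one. The package neither
  implements nor requires thermodynamic folding.
- Pattern discovery needs multiple instances per motif; single-instance
  motifs yield no patterns and their loops are classified *fair*,
  weakening selection around them.
- The false-class density is a single S_U fit to a heterogeneous mixture;
  its KS test may fail on large training sets (logged, not fatal).
- Multibranch loops are extracted and audited but never scored.
- Criterion (i) uses exact loop identity; a candidate differing by 1-nt
  slippage in a good loop is rejected even though metrics would count the
  pairs as near-matches. Slip tolerance exists only in evaluation.
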