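"""Bayesian posterior scoring of loops against characteristic SHAPE patterns.

For a pattern pair (high, low) applied to one loop instance, the observed
reactivity difference D = r(high) - r(low) is scored under two fitted
class-conditional densities: a normal-inverse Gaussian for differences from
true loops (loops present in reference structures) and a Johnson's SU for
false loops (candidate-ensemble loops absent from references).  Bayes' rule
with class priors gives the posterior probability that the pair resides in
a true loop, and each pair with posterior < 0.5 contributes a positive
log-odds penalty delta = -ln(P / (1 - P)); the loop penalty is the sum of
these deltas.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pattern_discovery import CharacteristicPattern
from .rna_structures import Loop, MotifSignature, ShapeProfile, pattern_positions

logger = logging.getLogger("shaperefine")

#: Class priors estimated in the original benchmark (fraction of pattern
#: pairs residing in true vs false candidate-ensemble loops).
DEFAULT_PRIOR_TRUE = 0.549
DEFAULT_PRIOR_FALSE = 0.451

_EPS = 1e-12
_FAMILIES = {"norminvgauss": stats.norminvgauss, "johnsonsu": stats.johnsonsu}

__all__ = [
    "ClassConditional",
    "PosteriorModel",
    "PairRecord",
    "LoopPenalty",
    "fit_class_conditional",
    "estimate_priors",
    "posterior",
    "delta",
    "loop_penalty",
    "DEFAULT_PRIOR_TRUE",
    "DEFAULT_PRIOR_FALSE",
]


@dataclass(frozen=True)
class ClassConditional:
    """A fitted 4-parameter density for one structure class.

    ``family`` is 'norminvgauss' (true class) or 'johnsonsu' (false class);
    ``params`` are the scipy shape/shape/loc/scale parameters; ``ks_p`` the
    goodness-of-fit p-value recorded at fit time.
    """

    family: str
    params: tuple[float, float, float, float]
    ks_p: float = float("nan")

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.params[3] <= 0:
            raise ValueError("scale parameter must be positive")

    def pdf(self, x) -> np.ndarray:
        return _FAMILIES[self.family].pdf(x, *self.params)


def fit_class_conditional(samples, class_label: str) -> ClassConditional:
    """Maximum-likelihood fit of the class's difference distribution.

    True-class differences are fitted with a normal-inverse Gaussian,
    false-class with a Johnson's SU.  The Kolmogorov-Smirnov p-value against
    the fitted density is recorded; a failing KS (p < 0.05) logs a warning
    but does not raise.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0 or not np.all(np.isfinite(samples)):
        raise ValueError("samples must be non-empty and finite")
    if np.ptp(samples) == 0:
        raise ValueError("constant samples: degenerate scale")
    if class_label not in ("true", "false"):
        raise ValueError("class_label must be 'true' or 'false'")
    if samples.size < 50:
        logger.warning(
            "fitting %s-class density on only %d samples", class_label, samples.size
        )
    family = "norminvgauss" if class_label == "true" else "johnsonsu"
    dist = _FAMILIES[family]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        params = dist.fit(samples)
        ks_p = float(stats.kstest(samples, dist.name, args=params).pvalue)
    if ks_p < 0.05:
        logger.warning(
            "%s fit for %s class fails KS goodness-of-fit (p=%.3g)",
            family, class_label, ks_p,
        )
    return ClassConditional(family, tuple(float(p) for p in params), ks_p)


def estimate_priors(n_true_pairs: int, n_false_pairs: int) -> tuple[float, float]:
    """Class priors as the fractions of pattern pairs in true/false loops."""
    if n_true_pairs < 0 or n_false_pairs < 0:
        raise ValueError("pair counts must be non-negative")
    total = n_true_pairs + n_false_pairs
    if total == 0:
        raise ValueError("at least one pair count must be positive")
    return n_true_pairs / total, n_false_pairs / total


@dataclass(frozen=True)
class PosteriorModel:
    """Priors plus class-conditional densities; scores difference values."""

    f_true: ClassConditional
    f_false: ClassConditional
    prior_true: float = DEFAULT_PRIOR_TRUE
    prior_false: float = DEFAULT_PRIOR_FALSE

    def __post_init__(self) -> None:
        if not (0 < self.prior_true < 1 and 0 < self.prior_false < 1):
            raise ValueError("priors must lie strictly in (0,1)")
        if abs(self.prior_true + self.prior_false - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")

    def posterior(self, D: float) -> float:
        return posterior(self, D)

    def to_dict(self) -> dict:
        return {
            "prior_true": self.prior_true,
            "prior_false": self.prior_false,
            "f_true": {"family": self.f_true.family, "params": list(self.f_true.params),
                       "ks_p": self.f_true.ks_p},
            "f_false": {"family": self.f_false.family, "params": list(self.f_false.params),
                        "ks_p": self.f_false.ks_p},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PosteriorModel":
        return cls(
            f_true=ClassConditional(d["f_true"]["family"],
                                    tuple(d["f_true"]["params"]),
                                    d["f_true"].get("ks_p", float("nan"))),
            f_false=ClassConditional(d["f_false"]["family"],
                                     tuple(d["f_false"]["params"]),
                                     d["f_false"].get("ks_p", float("nan"))),
            prior_true=d["prior_true"],
            prior_false=d["prior_false"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "PosteriorModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_posterior_model(
    true_samples, false_samples, n_true_pairs: int | None = None,
    n_false_pairs: int | None = None,
) -> PosteriorModel:
    """Fit both class conditionals and estimate priors from pair counts.

    When explicit counts are not given the training sample sizes are used.
    """
    f_true = fit_class_conditional(true_samples, "true")
    f_false = fit_class_conditional(false_samples, "false")
    if n_true_pairs is None:
        n_true_pairs = len(np.asarray(true_samples))
    if n_false_pairs is None:
        n_false_pairs = len(np.asarray(false_samples))
    pt, pf = estimate_priors(n_true_pairs, n_false_pairs)
    return PosteriorModel(f_true, f_false, pt, pf)


def posterior(model: PosteriorModel, D: float) -> float:
    """P(true loop | D) by Bayes' rule over the two fitted densities.

    When both densities underflow to zero at D the datum is uninformative
    and the prior is returned with a warning.
    """
    ft = float(model.f_true.pdf(D))
    ff = float(model.f_false.pdf(D))
    num = model.prior_true * ft
    den = num + model.prior_false * ff
    if den == 0.0 or not math.isfinite(den):
        warnings.warn(f"both class densities vanish at D={D}; returning the prior")
        return model.prior_true
    return num / den


def delta(posterior_p: float) -> float:
    """Log-posterior-odds penalty: -ln(P / (1-P)); positive iff P < 0.5.

    Posteriors of exactly 0 or 1 are clipped to avoid infinities.
    """
    if not 0.0 <= posterior_p <= 1.0:
        raise ValueError("posterior must lie in [0, 1]")
    if posterior_p <= 0.0 or posterior_p >= 1.0:
        warnings.warn("posterior at {0,1} clipped before log-odds")
        posterior_p = min(max(posterior_p, _EPS), 1.0 - _EPS)
    return -math.log(posterior_p / (1.0 - posterior_p))


@dataclass(frozen=True)
class PairRecord:
    """Audit record for one pattern pair evaluated on one loop."""

    pattern: CharacteristicPattern
    high_seq_pos: int
    low_seq_pos: int
    D: float
    posterior: float
    delta: float


@dataclass(frozen=True)
class LoopPenalty:
    """Per-loop penalty: sum of deltas over pairs with posterior < 0.5."""

    loop: Loop
    pairs: tuple[PairRecord, ...]
    penalty: float
    patterns_available: bool

    @property
    def applicable(self) -> bool:
        return self.patterns_available


def loop_penalty(
    loop: Loop,
    profile: ShapeProfile,
    patterns: dict[MotifSignature, list[CharacteristicPattern]],
    model: PosteriorModel,
    posterior_cutoff: float = 0.5,
) -> LoopPenalty:
    """Score one loop against its motif's characteristic patterns.

    Pattern positions index into the loop's motif-position order; pairs
    with a missing reactivity are skipped.  Pairs with posterior strictly
    below the cutoff each contribute delta > 0; a motif without patterns
    yields ``patterns_available = False`` (penalty not applicable, reported
    as 0).
    """
    motif_patterns = patterns.get(loop.motif, [])
    if not motif_patterns:
        return LoopPenalty(loop, (), 0.0, patterns_available=False)
    seq_pos = pattern_positions(loop)
    records: list[PairRecord] = []
    total = 0.0
    for pat in motif_patterns:
        hi, lo = seq_pos[pat.high_pos - 1], seq_pos[pat.low_pos - 1]
        r_hi, r_lo = profile.reactivity(hi), profile.reactivity(lo)
        if math.isnan(r_hi) or math.isnan(r_lo):
            continue
        D = r_hi - r_lo
        p = posterior(model, D)
        d = delta(p)
        records.append(PairRecord(pat, hi, lo, D, p, d))
        if p < posterior_cutoff:
            total += d
    return LoopPenalty(loop, tuple(records), total, patterns_available=True)
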