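import warnings

import numpy as np
import pytest

import shaperefine as sr
from shaperefine.pattern_discovery import discover_patterns
from shaperefine.posterior_model import fit_posterior_model
from shaperefine.synthetic_data import (
    count_ensemble_pairs,
    generate_benchmark,
    generate_ensemble,
    make_true_false_training_sets,
)

TRAIN_SEED = 11


@pytest.fixture(scope="session")
def trained():
    """A trained pattern table + posterior model on a synthetic benchmark.

    Shared across refinement/evaluation/acceptance tests: 20 reference RNAs
    under default generation conditions, candidate ensembles of 50 per RNA,
    leave-nothing-out pattern discovery and ML density fits.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bench = generate_benchmark(20, TRAIN_SEED)
        loops_by_rna = {rid: sr.extract_loops(s) for rid, (s, _) in bench.items()}
        profiles = {rid: p for rid, (_, p) in bench.items()}
        patterns = discover_patterns(loops_by_rna, profiles)
        refs = {rid: s for rid, (s, _) in bench.items()}
        ensembles = {
            rid: generate_ensemble(refs[rid], 50, 0.9, seed=TRAIN_SEED + 7 * i + 1)
            for i, rid in enumerate(refs)
        }
        true_D, false_D = make_true_false_training_sets(refs, profiles, ensembles, patterns)
        n_true, n_false = count_ensemble_pairs(refs, ensembles, patterns)
        model = fit_posterior_model(true_D, false_D, n_true, n_false)
    return {"patterns": patterns, "model": model, "benchmark": bench}


@pytest.fixture
def rng():
    return np.random.default_rng(0)
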