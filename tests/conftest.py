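"""Shared fixtures: tiny hand-built matrices and one mid-sized simulated study."""

import numpy as np
import pytest

from hdqtl import association
from hdqtl.io_model import ExpressionMatrix, GenotypeMatrix, MarkerMap
from hdqtl.simulate import SimConfig, simulate_dataset


@pytest.fixture
def toy_markers():
    return MarkerMap(
        ("m1", "m2", "m3"), ("chr1", "chr1", "chr2"), np.array([1.0, 2.0, 1.0])
    )


@pytest.fixture
def toy_geno(toy_markers):
    calls = np.array(
        [
            [0, 0, 1, 1],
            [0, 1, 0, 1],
            [1, 1, 0, 0],
        ],
        dtype=float,
    )
    return GenotypeMatrix(toy_markers, ("a", "b", "c", "d"), calls)


@pytest.fixture
def toy_expr():
    values = np.array(
        [
            [1.0, 1.2, 3.0, 3.4],
            [0.5, -0.5, 0.5, -0.5],
        ]
    )
    return ExpressionMatrix(
        ("t1", "t2"), ("a", "b", "c", "d"), values, {"t1": "chr1", "t2": "chr2"}
    )


@pytest.fixture(scope="session")
def recovery_study():
    """Default study design: 100 markers, 50 strains, 50 single-locus traits
    (beta/sd = 2), 50 five-locus polygenic traits, 100 null traits, with
    corrected p-values from 500 shared permutations."""
    cfg = SimConfig(seed=11)
    geno, expr, truth = simulate_dataset(cfg)
    assoc = association.map_all(geno, expr)
    null = association.permutation_null(geno, expr, n_iterations=500, seed=12)
    pvals = association.corrected_pvalues(assoc, null)
    return {
        "cfg": cfg,
        "geno": geno,
        "expr": expr,
        "truth": truth,
        "assoc": assoc,
        "null": null,
        "pvals": pvals,
    }
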