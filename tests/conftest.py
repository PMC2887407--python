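"""Shared fixtures: small handmade alignments and cached simulations."""

import numpy as np
import pytest

import dupsel as d
from dupsel.simulate import preset_spec, simulate


@pytest.fixture
def tiny_aln():
    """Three short in-frame sequences with a few substitutions."""
    return d.CodonAlignment(
        names=["A", "B", "C"],
        sequences=[
            "ATGTTTCCCAAAGGG",
            "ATGTTCCCGAAAGGA",
            "ATGTTTCCAAAGGGG",
        ],
    )


@pytest.fixture(scope="session")
def sim_small():
    """One-ratio duplication-shaped simulation, 200 codons."""
    spec = preset_spec("one_ratio", seed=5, n_codons=200)
    aln, truth = simulate(spec)
    return spec, aln, truth


@pytest.fixture(scope="session")
def m0_fit_small(sim_small):
    """Cached M0 fit (joint branch lengths + kappa + omega)."""
    spec, aln, _ = sim_small
    model = d.CodonModel(aln, spec.tree.copy())
    return model, model.fit(starts=(0.05,))


@pytest.fixture(scope="session")
def sim_three_ratio():
    """Three-ratio duplication-shaped simulation, 400 codons."""
    spec = preset_spec("three_ratio", seed=8, n_codons=400)
    aln, truth = simulate(spec)
    return spec, aln, truth
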