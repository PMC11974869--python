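"""Shared fixtures.

The expensive spatial-SSA ensembles behind the discrimination analyses
(three layouts, two HLA-C levels, four NKG2DL doses, 30 replicates at
t = 20 s) are computed once per session and shared by the engine-level
ordering tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from nkrsim import build_network
from nkrsim.engine import run_ensemble

HEADLINE_DOSES = (20, 40, 100, 400)
HEADLINE_REPS = 30
HEADLINE_T = 20.0
#: (mode, hlac) conditions the headline analyses need
HEADLINE_CONDITIONS = (
    ("disjoint", 4213), ("disjoint", 11686),
    ("overlapping", 4213), ("homogeneous", 4213),
)


@pytest.fixture(scope="session")
def network():
    return build_network()


@pytest.fixture(scope="session")
def headline_ensembles(network):
    """Replicate ensembles of pVav1 at t = 20 s for the discrimination
    analyses; one master seed, fresh configurations per replicate."""
    out = {}
    for mode, hlac in HEADLINE_CONDITIONS:
        out[(mode, hlac)] = run_ensemble(
            network, mode, doses=HEADLINE_DOSES, n_reps=HEADLINE_REPS,
            t_end=HEADLINE_T, sample_times=[0.0, 10.0, HEADLINE_T],
            seed=11, hlac=hlac)
    return out


@pytest.fixture(scope="session")
def headline_responses(headline_ensembles):
    """Per-condition dict dose -> pVav1 samples at t = 20 s."""
    return {key: ens.responses_at(HEADLINE_T)
            for key, ens in headline_ensembles.items()}
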