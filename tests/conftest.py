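"""Shared fixtures: reduced-size reconstructions solved once per session.

The reconstructions use 20-node networks with 2-peak prescriptions (the
Normal geometric rule truncated to 2 peaks, the Entrained 2.7/8.1 Hz bands)
and a 35% off-diagonal zero constraint — the desk-scale version of the
80-node study.
"""

import warnings

import numpy as np
import pytest

from vbgen import (
    PrescriptionConfig,
    build_prescription,
    solve_iep,
)

N_DESK = 20
SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def desk_config() -> PrescriptionConfig:
    return PrescriptionConfig(n_peaks=2, n_nodes=N_DESK)


@pytest.fixture(scope="session")
def entrained_config() -> PrescriptionConfig:
    return PrescriptionConfig(n_nodes=N_DESK)


def _solve(group, cfg, seed):
    presc = build_prescription(group, cfg, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return solve_iep(presc, seed=seed)


@pytest.fixture(scope="session")
def normal_matrices(desk_config):
    """Five converged Normal-group reconstructions at N=20 (the first three
    match the SEEDS triple used for the Background batch)."""
    return [_solve("Normal", desk_config, s) for s in (1, 2, 3, 4, 5)]


@pytest.fixture(scope="session")
def background_matrices(desk_config):
    """Three converged Background-group reconstructions at N=20."""
    return [_solve("Background", desk_config, s) for s in SEEDS]


@pytest.fixture(scope="session")
def entrained_matrix(entrained_config):
    """One Entrained-group reconstruction (bands 2.7 and 8.1 Hz) at N=20."""
    return _solve("Entrained", entrained_config, SEEDS[0])


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
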