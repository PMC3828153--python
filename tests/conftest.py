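"""Shared fixtures: models, trajectories, rate matrices, toy generators."""

from __future__ import annotations

import numpy as np
import pytest

import proteopath as pp


@pytest.fixture(scope="session")
def default_model():
    return pp.build_model(pp.PROFILES["default"])


@pytest.fixture(scope="session")
def default_traj(default_model):
    return pp.propagate(default_model, pp.AnalysisConfig())


@pytest.fixture(scope="session")
def default_state(default_traj):
    return default_traj[-1]


@pytest.fixture(scope="session")
def default_K(default_model, default_state):
    return pp.extract_rate_matrix(default_model, default_state)


@pytest.fixture(scope="session")
def default_T(default_K):
    return pp.build_transition_matrix(default_K)


@pytest.fixture(scope="session")
def default_decomp(default_T, default_K):
    return pp.pathway_probabilities(default_T, ["M"], ["U"], K=default_K)


@pytest.fixture(scope="session")
def small_model():
    """n_max=3, single occupancy, no Lon:M -- the minimal full-system net."""
    opts = pp.ModelOptions(n_max=3, double_occupancy=False, lon_binds_misfolded=False)
    return pp.build_model(pp.PROFILES["default"], options=opts)


@pytest.fixture(scope="session")
def isolated_client_options():
    """No chaperones, no aggregation, no synthesis: bare U/N/M kinetics."""
    return pp.ModelOptions(
        ribosome_activation_rate=0.0,
        enable_aggregation=False,
        enabled_systems=frozenset(),
    )


def random_rate_matrix(rng: np.random.Generator, n: int, density: float = 0.6):
    """Random irreducible generator on n states (a ring guarantees connectivity)."""
    K = np.where(rng.random((n, n)) < density, rng.uniform(0.1, 2.0, (n, n)), 0.0)
    for i in range(n):
        K[(i + 1) % n, i] = max(K[(i + 1) % n, i], rng.uniform(0.1, 2.0))
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=0))
    return pp.RateMatrix.from_array(K)


def enumerate_conditional_committor(K, A, B, C, start, max_len=80):
    """Brute-force path enumeration oracle for (q_B, h, hbar) from one state.

    Walks the embedded jump chain of the generator, accumulating the
    probability of every absorption sequence up to ``max_len`` jumps; the
    geometric decay of the surviving mass bounds the truncation error.
    Independent of the matrix-squaring and linear-solve machinery.
    """
    A, B, C = set(K.indices(A)), set(K.indices(B)), set(K.indices(C))
    M = K.K
    n = M.shape[0]
    jump = np.zeros((n, n))
    for j in range(n):
        out = sum(M[i, j] for i in range(n) if i != j)
        if out > 0:
            for i in range(n):
                if i != j:
                    jump[i, j] = M[i, j] / out
    q = h = 0.0
    frontier = {(K.index(start), False): 1.0}
    for _ in range(max_len):
        nxt: dict[tuple[int, bool], float] = {}
        for (s, flag), prob in frontier.items():
            for i in range(n):
                p = jump[i, s]
                if p == 0.0:
                    continue
                f2 = flag or (i in C)
                w = prob * p
                if i in B:
                    q += w
                    if f2:
                        h += w
                elif i not in A:
                    key = (i, f2)
                    nxt[key] = nxt.get(key, 0.0) + w
        frontier = nxt
        if sum(frontier.values()) < 1e-13:
            break
    return q, h, q - h
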