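"""Committors and conditional committors on a frozen rate matrix.

The generator K is discretised into a column-stochastic transition matrix
T = I + tau*K with tau = 1/(2*k_max), where k_max is the largest total exit
rate; the factor 1/2 keeps every diagonal >= 1/2, so the chain is aperiodic
and absorption probabilities are independent of tau (verified by the
tau-invariance tests).

Committors are obtained the absorbing-chain way: sinks are installed at the
two boundary sets A and B (their columns become unit vectors) and the
modified matrix is squared iteratively -- T~^(2^m) -- until the probability
remaining in non-sink states is below tolerance; the committor q_B(i) is the
mass absorbed at B starting from i.  A direct linear solve of the committor
system is provided as an alternative route and used as a cross-check.

Conditional committors split q_B by whether a mediator set C was visited en
route.  They are computed on a doubled state space (state, visited-C flag):
the flag is set on first entry into C, sinks sit at A and B in both
ensembles, and h (visited) and h-bar (not visited) are read from the
absorbed-at-B mass of the two ensembles.  Conservation of probability gives
h + h-bar = q_B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space
from scipy.sparse.csgraph import connected_components

from .tagged import RateMatrix

__all__ = [
    "TransitionMatrix",
    "CommittorResult",
    "ConditionalCommittorResult",
    "build_transition_matrix",
    "committor",
    "conditional_committor",
    "stationary_weights",
    "NonConvergenceError",
    "ReducibleMatrixError",
]


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, trapped=None):
        super().__init__(msg)
        self.trapped = trapped or []


class ReducibleMatrixError(RuntimeError):
    pass


@dataclass
class TransitionMatrix:
    """Column-stochastic discretisation of a rate matrix."""

    T: np.ndarray
    tau: float
    k_max: float
    states: list

    def index(self, label):
        for s in self.states:
            if s.label == label or s is label:
                return s.id
        if isinstance(label, (int, np.integer)):
            return int(label)
        raise KeyError(label)

    def indices(self, labels):
        lookup = {s.label: s.id for s in self.states}
        out = []
        for l in labels:
            if isinstance(l, (int, np.integer)):
                out.append(int(l))
            elif hasattr(l, "id"):
                out.append(l.id)
            else:
                out.append(lookup[l])
        return out

    @property
    def labels(self):
        return [s.label for s in self.states]


@dataclass
class CommittorResult:
    A: list[int]
    B: list[int]
    q_B: np.ndarray
    q_A: np.ndarray
    iterations: int
    labels: list[str] = field(default_factory=list)

    def to_csv(self, path, metadata_path=None, **metadata):
        import json

        with open(path, "w") as fh:
            fh.write("state,q_B,q_A\n")
            for lab, qb, qa in zip(self.labels, self.q_B, self.q_A):
                fh.write(f"{lab},{qb:.17g},{qa:.17g}\n")
        if metadata_path:
            with open(metadata_path, "w") as fh:
                json.dump({"iterations": self.iterations, **metadata}, fh, indent=2)


@dataclass
class ConditionalCommittorResult:
    C: list[int]
    h: np.ndarray
    hbar: np.ndarray
    committor: CommittorResult


def build_transition_matrix(K: RateMatrix, safety: float = 0.5) -> TransitionMatrix:
    """Discretise K with time step tau = safety / k_max (default 1/(2 k_max))."""
    if not 0 < safety <= 1:
        raise ValueError("safety must be in (0, 1]")
    exit_rates = -np.diag(K.K)
    k_max = float(np.max(exit_rates))
    if k_max <= 0:
        raise ValueError("empty dynamics: no state has a positive exit rate")
    tau = safety / k_max
    T = np.eye(K.K.shape[0]) + tau * K.K
    return TransitionMatrix(T=T, tau=tau, k_max=k_max, states=list(K.states))


def _install_sinks(T: np.ndarray, sinks: list[int]) -> np.ndarray:
    Ts = T.copy()
    Ts[:, sinks] = 0.0
    Ts[sinks, sinks] = 1.0
    return Ts


def _square_to_absorption(
    Ts: np.ndarray, nonsink: np.ndarray, tol: float, max_squarings: int
):
    """Square Ts until the non-sink column mass is below tol."""
    M = Ts
    for it in range(max_squarings + 1):
        residual = M[nonsink, :].sum(axis=0).max() if nonsink.size else 0.0
        if residual < tol:
            return M, it
        M = M @ M
    trapped = np.where(M[nonsink, :].sum(axis=1) > tol)[0]
    raise NonConvergenceError(
        f"absorption not reached after {max_squarings} squarings "
        f"(residual {residual:.3g}); reducible or trap states present",
        trapped=[int(nonsink[i]) for i in trapped],
    )


def committor(
    T: TransitionMatrix,
    A,
    B,
    method: str = "squaring",
    tol: float = 1e-12,
    max_squarings: int = 200,
) -> CommittorResult:
    """Probability of reaching sink set B before sink set A from every state."""
    iA = T.indices(A)
    iB = T.indices(B)
    if not iA or not iB:
        raise ValueError("sink sets must be nonempty")
    if set(iA) & set(iB):
        raise ValueError("sink sets must be disjoint")
    n = T.T.shape[0]
    sinks = iA + iB
    iterations = 0
    if method == "squaring":
        Ts = _install_sinks(T.T, sinks)
        nonsink = np.array([i for i in range(n) if i not in set(sinks)], dtype=int)
        M, iterations = _square_to_absorption(Ts, nonsink, tol, max_squarings)
        q_B = M[iB, :].sum(axis=0)
        q_A = M[iA, :].sum(axis=0)
        # assign the residual (below tol) so the identity holds exactly on sinks
        q_B[iB] = 1.0
        q_B[iA] = 0.0
        q_A[iA] = 1.0
        q_A[iB] = 0.0
    elif method == "linear":
        q_B = _committor_linear(T.T, iA, iB)
        q_A = 1.0 - q_B
    else:
        raise ValueError(f"unknown method {method!r}")
    return CommittorResult(iA, iB, q_B, q_A, iterations, labels=T.labels)


def _committor_linear(T: np.ndarray, iA: list[int], iB: list[int]) -> np.ndarray:
    n = T.shape[0]
    sinks = set(iA) | set(iB)
    trans = [i for i in range(n) if i not in sinks]
    q = np.zeros(n)
    q[iB] = 1.0
    if trans:
        M = T[np.ix_(trans, trans)]
        b = T[np.ix_(iB, trans)].sum(axis=0)
        x = np.linalg.solve(np.eye(len(trans)) - M.T, b)
        q[trans] = x
    return q


def conditional_committor(
    T: TransitionMatrix,
    A,
    B,
    C,
    tol: float = 1e-12,
    max_squarings: int = 200,
    method: str = "squaring",
) -> ConditionalCommittorResult:
    """Split the committor q_B by visitation of the mediator set C.

    ``h[i]`` is the probability of reaching B before A from i having entered
    C on the way; ``hbar[i]`` the same without entering C (flag is set on
    first *entry* into C after leaving i).  ``h + hbar = q_B`` elementwise.
    """
    iA, iB, iC = T.indices(A), T.indices(B), T.indices(C)
    if (set(iA) & set(iB)) or (set(iA) & set(iC)) or (set(iB) & set(iC)):
        raise ValueError("A, B, C must be pairwise disjoint")
    base = committor(T, A, B, tol=tol, max_squarings=max_squarings, method=method)
    n = T.T.shape[0]
    if not iC:
        return ConditionalCommittorResult(iC, np.zeros(n), base.q_B.copy(), base)
    # doubled space: index i = not-visited ensemble, n + i = visited ensemble
    T2 = np.zeros((2 * n, 2 * n))
    Tm = T.T
    inC = np.zeros(n, dtype=bool)
    inC[iC] = True
    T2[n:, n:] = Tm  # visited stays visited
    T2[np.ix_(np.where(~inC)[0], np.arange(n))] = Tm[~inC, :]
    T2[np.ix_(n + np.where(inC)[0], np.arange(n))] = Tm[inC, :]
    sinks = iA + iB + [n + i for i in iA + iB]
    T2s = _install_sinks(T2, sinks)
    nonsink = np.array(sorted(set(range(2 * n)) - set(sinks)), dtype=int)
    if method == "linear":
        hbar = _committor_linear(T2s, [a for a in iA] + [n + a for a in iA] + [n + b for b in iB],
                                 iB)[:n]
        h = _committor_linear(T2s, [a for a in iA] + [n + a for a in iA] + iB,
                              [n + b for b in iB])[:n]
    else:
        M, _ = _square_to_absorption(T2s, nonsink, tol, max_squarings)
        start = np.arange(n)  # start in the not-visited ensemble
        hbar = M[np.ix_(iB, start)].sum(axis=0)
        h = M[np.ix_([n + b for b in iB], start)].sum(axis=0)
    # boundary conventions: sinks keep their unconditional values
    h[iA] = 0.0
    hbar[iA] = 0.0
    h[iB] = 0.0
    hbar[iB] = 1.0
    return ConditionalCommittorResult(iC, h, hbar, base)


def stationary_weights(K: RateMatrix, tol: float = 1e-10) -> np.ndarray:
    """Stationary probability vector of the generator (null space of K).

    Raises :class:`ReducibleMatrixError` when the chain has more than one
    recurrent class (the stationary distribution is then not unique).
    """
    A = K.K
    n = A.shape[0]
    adjacency = (A > 0).astype(int)
    np.fill_diagonal(adjacency, 0)
    n_comp, labels = connected_components(adjacency.T, directed=True, connection="strong")
    # recurrent classes = strongly connected components with no outgoing edge
    recurrent = set(range(n_comp))
    for j in range(n):
        for i in range(n):
            if i != j and A[i, j] > 0 and labels[i] != labels[j]:
                recurrent.discard(labels[j])
    if len(recurrent) != 1:
        raise ReducibleMatrixError(
            f"{len(recurrent)} recurrent classes; stationary weights not unique"
        )
    # replace one balance equation by the normalisation constraint; this
    # keeps componentwise accuracy on stiff generators where a plain SVD
    # null space would wash out the small weights
    B = A.copy()
    B[0, :] = 1.0
    rhs = np.zeros(n)
    rhs[0] = 1.0
    try:
        pi = np.linalg.solve(B, rhs)
        # one step of iterative refinement
        resid = rhs - B @ pi
        pi = pi + np.linalg.solve(B, resid)
    except np.linalg.LinAlgError:
        ns = null_space(A)
        if ns.shape[1] != 1:
            raise ReducibleMatrixError("null space of K is not one-dimensional")
        pi = ns[:, 0]
        pi = pi / pi.sum()
    if np.any(pi < -tol):
        raise ReducibleMatrixError("negative entries in the stationary vector")
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()
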