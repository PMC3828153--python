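"""Continuous-time pseudo-trajectory sampling on the frozen rate matrix.

Validates committors, mediation probabilities and channel decompositions by
direct counting: jump-chain sampling (next state proportional to the
off-diagonal rates, holding time exponential in the total exit rate) from
the source outflux distribution until absorption at a sink.  Each path draws
from its own counter-based Philox stream keyed by (seed, path index), so
individual paths are reproducible regardless of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tagged import RateMatrix

__all__ = ["PathSample", "sample_first_passage_paths", "estimate_decomposition"]


@dataclass
class PathSample:
    start: int
    states: list[int]
    holding_times: list[float]
    terminal: int | None  # None when truncated at the step cap
    visited_mask: int
    seed_key: tuple[int, int]

    @property
    def truncated(self) -> bool:
        return self.terminal is None


def sample_first_passage_paths(
    K: RateMatrix,
    source,
    sinks,
    n: int,
    seed: int,
    mediators: list | None = None,
    max_steps: int = 1_000_000,
) -> list[PathSample]:
    """Sample ``n`` first-passage paths from the source outflux to the sinks.

    ``mediators`` is an optional list of state sets; bit ``k`` of
    ``visited_mask`` records whether set ``k`` was entered along the path.
    Paths start from the first jump out of the source set (rate-weighted)
    and are absorbed on arrival at any sink (source states are sinks for the
    usual reactive-path conditioning when included in ``sinks``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    A = K.K
    nstates = A.shape[0]
    iS = K.indices(source)
    sink_set = set(K.indices(sinks))
    med_sets = [set(K.indices(m)) for m in (mediators or [])]
    med_of = np.zeros(nstates, dtype=np.int64)
    for k, m in enumerate(med_sets):
        for s in m:
            med_of[s] |= 1 << k

    # per-state jump distributions (cumulative) and exit rates
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    exit_rates = off.sum(axis=0)
    cum = np.cumsum(off, axis=0).T  # row j: cumulative over destinations
    jump_targets = [np.nonzero(off[:, j])[0] for j in range(nstates)]

    # source outflux distribution over first edges (s -> i), i outside S
    src_set = set(iS)
    start_edges = []
    start_w = []
    for s in iS:
        for i in np.nonzero(off[:, s])[0]:
            if int(i) not in src_set:
                start_edges.append((s, int(i)))
                start_w.append(off[i, s])
    if not start_edges or sum(start_w) <= 0:
        raise ValueError("source has no outgoing rate")
    start_cum = np.cumsum(np.asarray(start_w) / sum(start_w))

    paths = []
    for p in range(n):
        rng = np.random.Generator(np.random.Philox(key=(seed, p)))
        s0, state = start_edges[int(np.searchsorted(start_cum, rng.random(), side="right"))]
        states = [s0, state]
        holds: list[float] = []
        mask = int(med_of[state])
        terminal: int | None = None
        if state in sink_set:
            terminal = state
        else:
            for _ in range(max_steps):
                r = exit_rates[state]
                holds.append(rng.exponential(1.0 / r))
                u = rng.random() * r
                state = int(np.searchsorted(cum[state], u, side="right"))
                states.append(state)
                mask |= int(med_of[state])
                if state in sink_set:
                    terminal = state
                    break
        paths.append(PathSample(s0, states, holds, terminal, mask, (seed, p)))
    return paths


def estimate_decomposition(
    paths: list[PathSample],
    channels: dict[str, list],
    K: RateMatrix | None = None,
) -> dict[str, tuple[float, float]]:
    """Channel fractions with binomial standard errors from sampled paths.

    ``channels`` maps names to entry-edge lists ``(from, to)`` (labels or
    indices; ``K`` is needed to resolve labels).  A path is assigned to the
    channel of its final edge.  Truncated paths are excluded from the
    fractions and reported under ``"_truncated"``; paths whose final edge is
    in no channel (e.g. returns to the source) are counted under
    ``"_unclassified"``.
    """
    def resolve(x):
        return K.index(x) if K is not None and not isinstance(x, (int, np.integer)) else int(x)

    edge_map = {}
    for name, edges in channels.items():
        for u, t in edges:
            edge_map[(resolve(u), resolve(t))] = name
    counts = dict.fromkeys(channels, 0)
    truncated = unclassified = 0
    for p in paths:
        if p.truncated:
            truncated += 1
            continue
        if len(p.states) < 2:
            unclassified += 1
            continue
        edge = (p.states[-2], p.states[-1])
        name = edge_map.get(edge)
        if name is None:
            unclassified += 1
        else:
            counts[name] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero reactive (classified) paths")
    out = {}
    for name, c in counts.items():
        frac = c / total
        out[name] = (frac, float(np.sqrt(frac * (1.0 - frac) / total)))
    out["_truncated"] = (truncated, 0.0)
    out["_unclassified"] = (unclassified, 0.0)
    return out


def visited_fraction(paths: list[PathSample], bit: int = 0, reactive_terminal=None):
    """Fraction of (optionally terminal-filtered) paths with mediator bit set."""
    sel = [
        p for p in paths
        if not p.truncated and (reactive_terminal is None or p.terminal in reactive_terminal)
    ]
    if not sel:
        return 0.0, 0.0
    frac = sum(1 for p in sel if p.visited_mask >> bit & 1) / len(sel)
    return frac, float(np.sqrt(frac * (1 - frac) / len(sel)))
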