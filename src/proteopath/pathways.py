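"""Decomposition of source->target transition paths into pathway channels.

A reactive path starts with a jump out of the source set and is terminated
on first arrival at either the source (non-reactive, discarded) or the
target.  Channels classify reactive paths by the *entry edge* through which
they first reach the target:

* ``direct``       -- conformational conversion edges from bare client
  conformers (M->U, N->U, U->N, ...);
* ``KJE``          -- release edges from DnaK complexes;
* ``GroELS``       -- release edges from GroEL/GroES complexes;
* ``B+KJE``        -- ClpB extraction edges from prepared aggregates;
* ``degradation``  -- the re-synthesis edge from the Null state (degradation
  followed by re-synthesis);
* ``TriggerFactor``/``Lon_release`` -- release from holder/protease
  complexes; these complexes are entered only from the free states, so on
  the headline decompositions they carry zero probability.

The entry-edge convention yields an exact, exhaustive, mutually exclusive
decomposition; mediation probabilities computed from conditional committors
(fraction of reactive paths that *visit* a chaperone system) coincide with
the channel probabilities whenever the system's release edges are its only
exits toward the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .committor import (
    NonConvergenceError,
    TransitionMatrix,
    _square_to_absorption,
    conditional_committor,
)
from .kinetics import ConcentrationState
from .model import System
from .tagged import RateMatrix

__all__ = [
    "PathwayDecomposition",
    "ProportionalityFit",
    "classify_entry_channels",
    "pathway_probabilities",
    "pathway_flux",
    "mediation_probability",
    "entrance_rates",
    "fit_proportionality",
]


@dataclass
class PathwayDecomposition:
    """Per-channel probabilities (reactive-conditioned) and absorption data."""

    source: list[int]
    target: list[int]
    channels: dict[str, list[tuple[int, int]]]
    probabilities: dict[str, float]
    #: absorption probability in each channel from every non-source state
    absorption: dict[str, np.ndarray]
    #: per-source-state first-jump weights used for conditioning
    reactive_probability: float
    labels: list[str] = field(default_factory=list)

    def to_csv(self, path, fluxes: dict[str, float] | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("channel,probability" + (",flux_uM_per_s" if fluxes else "") + "\n")
            for ch, p in self.probabilities.items():
                row = f"{ch},{p:.17g}"
                if fluxes:
                    row += f",{fluxes.get(ch, 0.0):.17g}"
                fh.write(row + "\n")


@dataclass(frozen=True)
class ProportionalityFit:
    """Least-squares fit of y = c*x through the origin."""

    slope: float
    points: tuple[tuple[float, float], ...]
    rss: float

    @property
    def r_squared(self) -> float:
        tot = sum(y * y for _, y in self.points)
        return 1.0 - self.rss / tot if tot > 0 else 1.0


_BARE = {"U", "N", "M"}


def classify_entry_channels(K: RateMatrix, target) -> dict[str, list[tuple[int, int]]]:
    """Group every edge entering the target set by the origin state's system."""
    t_idx = set(K.indices(target))
    channels: dict[str, list[tuple[int, int]]] = {}
    for t in t_idx:
        for u in range(K.K.shape[0]):
            if u == t or u in t_idx or K.K[t, u] == 0.0:
                continue
            src = K.states[u]
            if src.label == "Null":
                name = "degradation"
            elif src.label.startswith("TF:"):
                name = "TriggerFactor"
            elif src.label.startswith("Lon:"):
                name = "Lon_release"
            elif src.system is System.KJE:
                name = "KJE"
            elif src.system is System.GROELS:
                name = "GroELS"
            elif src.system is System.BKJE:
                name = "B+KJE"
            elif src.label in _BARE:
                name = "direct"
            elif src.agg_size:
                # unprepared aggregates shed monomers spontaneously
                name = "direct"
            else:  # pragma: no cover - exhaustive by construction
                name = "other"
            channels.setdefault(name, []).append((u, t))
    return channels


def _source_weights(K_or_T, source_idx, conc_weights):
    if conc_weights is None:
        return {s: 1.0 for s in source_idx}
    return dict(zip(source_idx, conc_weights))


def pathway_probabilities(
    T: TransitionMatrix,
    source,
    target,
    channels: dict[str, list] | None = None,
    K: RateMatrix | None = None,
    source_concentrations=None,
    tol: float = 1e-12,
    max_squarings: int = 200,
) -> PathwayDecomposition:
    """Entry-channel decomposition of reactive source->target paths.

    The target sink is split into one absorbing copy per channel and the
    source made absorbing (non-reactive return); paths start from the
    source's normalised outflux distribution.  Channel probabilities are the
    absorbed masses renormalised over all target copies.
    """
    n = T.T.shape[0]
    iS = T.indices(source)
    iG = T.indices(target)
    if set(iS) & set(iG):
        raise ValueError("source and target must be disjoint")
    if channels is None:
        Kref = K if K is not None else RateMatrix(
            (T.T - np.eye(n)) / T.tau, list(T.states)
        )
        channels = classify_entry_channels(Kref, target)
    channels = {name: [(T.index(u), T.index(t)) for u, t in edges]
                for name, edges in channels.items()}
    edge_map = {}
    for name, edges in channels.items():
        for e in edges:
            if e in edge_map:
                raise ValueError(f"edge {e} assigned to two channels")
            edge_map[e] = name
    # channels must cover every edge into the target
    for t in iG:
        for u in range(n):
            if u not in iG and u != t and T.T[t, u] > 0 and (u, t) not in edge_map:
                raise ValueError(f"entry edge ({T.labels[u]}, {T.labels[t]}) not in any channel")

    names = list(channels.keys())
    nch = len(names)
    ch_of = {name: k for k, name in enumerate(names)}
    # modified chain: states + channel sinks; source absorbing; target
    # columns unreachable (their inbound mass is redirected to channels)
    m = n + nch
    Tm = np.zeros((m, m))
    sinkset = set(iS) | set(iG)
    for u in range(n):
        if u in sinkset:
            Tm[u, u] = 1.0
            continue
        col = T.T[:, u]
        for i in range(n):
            if col[i] == 0.0 or i == u:
                continue
            if i in iG:
                Tm[n + ch_of[edge_map[(u, i)]], u] += col[i]
            else:
                Tm[i, u] += col[i]
        Tm[u, u] = col[u]
    for k in range(nch):
        Tm[n + k, n + k] = 1.0
    nonsink = np.array([u for u in range(n) if u not in sinkset], dtype=int)
    M, _ = _square_to_absorption(Tm, nonsink, tol, max_squarings)

    # absorption probability per channel from every transient state
    absorption = {name: M[n + ch_of[name], :n] for name in names}

    # start from the source outflux: first jumps weighted by rate (and
    # optionally by source concentration for multi-state sources)
    w = _source_weights(T, iS, source_concentrations)
    raw = dict.fromkeys(names, 0.0)
    returned = 0.0
    for s in iS:
        col = T.T[:, s]
        for i in range(n):
            if i == s or col[i] == 0.0 or i in iS:
                continue
            wgt = w[s] * col[i]
            if i in iG:
                raw[edge_map[(s, i)]] += wgt
            else:
                for name in names:
                    raw[name] += wgt * absorption[name][i]
                returned += wgt * (1.0 - sum(absorption[name][i] for name in names))
    total = sum(raw.values())
    if total <= 0:
        raise NonConvergenceError("zero reactive probability: all paths return to the source")
    probabilities = {name: raw[name] / total for name in names}
    return PathwayDecomposition(
        source=iS,
        target=iG,
        channels=channels,
        probabilities=probabilities,
        absorption=absorption,
        reactive_probability=total / (total + returned),
        labels=T.labels,
    )


def pathway_flux(
    decomposition: PathwayDecomposition,
    K: RateMatrix,
    state_at_t: ConcentrationState | dict | None = None,
) -> dict[str, float]:
    """Reactive flux (uM/s) through each channel.

    flux_c = sum_s [s](t) * sum_i K(i, s) * P(absorb in channel c | first
    jump to i).  For the folding decomposition the direct channel reduces to
    k_fold * [U](t) exactly.
    """
    conc = np.ones(len(decomposition.labels))
    if state_at_t is not None:
        getter = state_at_t.get if hasattr(state_at_t, "get") else state_at_t.__getitem__
        for s in decomposition.source:
            conc[s] = getter(decomposition.labels[s])
    edge_map = {}
    for name, edges in decomposition.channels.items():
        for e in edges:
            edge_map[e] = name
    iS, iG = set(decomposition.source), set(decomposition.target)
    fluxes = dict.fromkeys(decomposition.channels, 0.0)
    n = K.K.shape[0]
    for s in decomposition.source:
        for i in range(n):
            if i == s or i in iS or K.K[i, s] == 0.0:
                continue
            w = conc[s] * K.K[i, s]
            if i in iG:
                fluxes[edge_map[(s, i)]] += w
            else:
                for name, absorb in decomposition.absorption.items():
                    fluxes[name] += w * absorb[i]
    return fluxes


def mediation_probability(
    T: TransitionMatrix,
    A,
    B,
    C,
    tol: float = 1e-12,
    max_squarings: int = 200,
) -> float:
    """Fraction of reactive A->B paths that visit the mediator set C.

    Uses conditional committors on the first-jump distribution out of A; a
    first jump landing inside C counts as a visit.
    """
    iA, iB, iC = T.indices(A), T.indices(B), T.indices(C)
    res = conditional_committor(T, iA, iB, iC, tol=tol, max_squarings=max_squarings)
    q_B, h = res.committor.q_B, res.h
    inC = set(iC)
    num = den = 0.0
    for a in iA:
        col = T.T[:, a]
        for j in range(T.T.shape[0]):
            if j == a or j in iA or col[j] == 0.0:
                continue
            hop = col[j]
            den += hop * q_B[j]
            num += hop * (q_B[j] if j in inC else h[j])
    if den <= 0:
        raise NonConvergenceError("zero reactive probability from A")
    return num / den


def entrance_rates(K: RateMatrix, from_state, to_states) -> dict[str, float]:
    """Tagged transition rates K(to, from) for the requested destinations."""
    j = K.index(from_state)
    out = {}
    for t in to_states:
        i = K.index(t)
        out[K.states[i].label] = float(K.K[i, j])
    return out


def fit_proportionality(points) -> ProportionalityFit:
    """Least squares through the origin: c = sum(x*y) / sum(x^2)."""
    pts = tuple((float(x), float(y)) for x, y in points)
    if not pts:
        raise ValueError("at least one point required")
    sxx = sum(x * x for x, _ in pts)
    if sxx == 0:
        raise ValueError("all x values are zero")
    c = sum(x * y for x, y in pts) / sxx
    rss = sum((y - c * x) ** 2 for x, y in pts)
    return ProportionalityFit(slope=c, points=pts, rss=rss)
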