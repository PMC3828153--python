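"""Single-tagged-molecule state space and time-frozen rate matrix.

The bulk model is nonlinear (aggregation) and couples the client to
time-varying chaperone concentrations.  Tracking one tagged client molecule
turns it into a linear master equation dp/dt = K p once the bulk
concentrations are frozen at the analysis time: every bimolecular step of
the tagged molecule with a partner species S becomes pseudo-first-order with
rate k*[S](t).

Multi-client complexes (the doubly occupied GroEL/GroES chaperonin) are
split into two tagged states, one per position, with the untagged partner's
conformation written in lowercase (``GrLd:{U,m}:GrS`` = tagged cis client
unfolded, untagged trans partner misfolded).  Monomers inside an aggregate
of size n are indistinguishable: when one monomer leaves, the tagged one is
the leaver with probability 1/n.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kinetics import AnalysisConfig, ConcentrationState, propagate
from .model import NetworkModel, System

__all__ = [
    "ClientState",
    "RateMatrix",
    "enumerate_client_states",
    "extract_rate_matrix",
    "frozen_matrix_check",
    "write_rate_matrix_csv",
    "read_rate_matrix_csv",
]


@dataclass(frozen=True)
class ClientState:
    """One state of the tagged client molecule."""

    id: int
    label: str
    system: System | None = None
    agg_size: int = 0
    position: str | None = None  # cis / trans for double GroEL complexes


def enumerate_client_states(model: NetworkModel) -> list[ClientState]:
    """Exhaustive, deterministically ordered tagged-state list.

    Includes ``Null``; every doubly-occupied GroEL complex contributes a
    cis-tagged and a trans-tagged state; each aggregate size contributes
    ``A_n`` and (with B+KJE) the prepared ``A_n*``.
    """
    opts = model.options
    systems = opts.enabled_systems
    labels: list[tuple[str, System | None, int, str | None]] = [
        ("Null", None, 0, None),
        ("U", None, 0, None),
        ("N", None, 0, None),
        ("M", None, 0, None),
    ]
    if System.TRIGGER_FACTOR in systems:
        labels.append(("TF:U", System.TRIGGER_FACTOR, 0, None))
    if System.DEGRADATION in systems:
        labels.append(("Lon:U", System.DEGRADATION, 0, None))
        if opts.lon_binds_misfolded:
            labels.append(("Lon:M", System.DEGRADATION, 0, None))
    if System.KJE in systems:
        for lab in ("K_T:U", "K_T:M", "U:J:K_T", "U:J:K_D", "K_D:U"):
            labels.append((lab, System.KJE, 0, None))
    if System.GROELS in systems:
        for lab in ("GrL_T:U", "GrL_T:M"):
            labels.append((lab, System.GROELS, 0, None))
        for x in ("U", "N", "M"):
            labels.append((f"GrLd:{{{x}}}:GrS", System.GROELS, 0, "cis"))
        if opts.double_occupancy:
            for x in ("U", "N", "M"):
                for y in ("u", "m"):
                    labels.append((f"GrLd:{{{x},{y}}}:GrS", System.GROELS, 0, "cis"))
            for x in ("u", "n", "m"):
                for y in ("U", "M"):
                    labels.append((f"GrLd:{{{x},{y}}}:GrS", System.GROELS, 0, "trans"))
    if opts.enable_aggregation:
        for n in range(2, opts.n_max + 1):
            labels.append((f"A{n}", None, n, None))
        if System.BKJE in systems:
            for n in range(2, opts.n_max + 1):
                labels.append((f"A{n}*", System.BKJE, n, None))
    return [
        ClientState(i, lab, system, size, pos)
        for i, (lab, system, size, pos) in enumerate(labels)
    ]


@dataclass
class RateMatrix:
    """Tagged-molecule generator K with column convention K[i, j] = rate j->i.

    Off-diagonal entries are nonnegative and every column sums to zero (the
    diagonal holds the negative total exit rate).  ``concentrations`` is the
    snapshot of bulk concentrations used to freeze bimolecular steps.
    """

    K: np.ndarray
    states: list[ClientState]
    time: float = 0.0
    concentrations: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = self.K.shape[0]
        if self.K.shape != (n, n) or n != len(self.states):
            raise ValueError("rate matrix / state list size mismatch")
        self._index = {s.label: s.id for s in self.states}

    @classmethod
    def from_array(cls, K, labels=None, **kw) -> "RateMatrix":
        K = np.asarray(K, dtype=float)
        labels = labels or [f"s{i}" for i in range(K.shape[0])]
        states = [ClientState(i, lab) for i, lab in enumerate(labels)]
        return cls(K, states, **kw)

    def index(self, label) -> int:
        if isinstance(label, ClientState):
            return label.id
        if isinstance(label, (int, np.integer)):
            return int(label)
        return self._index[label]

    def indices(self, labels) -> list[int]:
        return [self.index(l) for l in labels]

    @property
    def labels(self) -> list[str]:
        return [s.label for s in self.states]

    def column_sum_residual(self) -> float:
        """Max |column sum| relative to the largest rate in the column."""
        sums = np.abs(self.K.sum(axis=0))
        scale = np.maximum(np.max(np.abs(self.K), axis=0), 1e-300)
        return float(np.max(sums / scale))


def extract_rate_matrix(model: NetworkModel, state_at_t: ConcentrationState) -> RateMatrix:
    """Build K(t) from the bulk model and the concentrations at time t.

    Unimolecular client transitions carry their rate constants; bimolecular
    transitions carry ``k * [partner](t)``; the client-client aggregation
    steps are linearised with the bulk monomer / aggregate concentration;
    aggregate monomer-loss rates are apportioned by the 1/n rule (encoded in
    the model's tagged moves); the synthesis closure gives
    ``Null -> U`` at ``r_syn / max([Null](t), floor)``.
    """
    states = enumerate_client_states(model)
    idx = {s.label: s.id for s in states}
    n = len(states)
    K = np.zeros((n, n))
    floor = model.options.null_floor
    for r in model.reactions:
        for mv in r.moves:
            rate = r.value * mv.weight
            for sp, power in mv.factors:
                c = state_at_t[sp]
                if power == -1:
                    rate /= max(c, floor)
                else:
                    rate *= c**power
            if rate < 0:
                raise ValueError(f"negative tagged rate for move {mv}")
            K[idx[mv.dst], idx[mv.src]] += rate
    np.fill_diagonal(K, 0.0)
    np.fill_diagonal(K, -K.sum(axis=0))
    snapshot = {s.name: state_at_t[s.name] for s in model.species}
    return RateMatrix(K, states, time=state_at_t.time, concentrations=snapshot)


def frozen_matrix_check(
    model: NetworkModel,
    config: AnalysisConfig,
    source,
    target,
    channels=None,
) -> dict[str, float]:
    """Compare pathway probabilities from K(t_eval) and K(2*t_eval).

    Returns per-channel absolute probability differences plus ``"max"``.
    Reporting only -- large differences simply mean the constant-rate-matrix
    assumption is poor for this configuration (e.g. runaway aggregation).
    """
    from .pathways import pathway_probabilities
    from .committor import build_transition_matrix

    states = propagate(model, config, t_end=2 * config.t_eval)
    times = np.array([st.time for st in states])
    st1 = states[int(np.argmin(np.abs(times - config.t_eval)))]
    st2 = states[-1]
    out: dict[str, float] = {}
    decomps = []
    for st in (st1, st2):
        K = extract_rate_matrix(model, st)
        T = build_transition_matrix(K)
        decomps.append(pathway_probabilities(T, source, target, channels=channels))
    probs1, probs2 = decomps[0].probabilities, decomps[1].probabilities
    for ch in probs1:
        out[ch] = abs(probs1[ch] - probs2.get(ch, 0.0))
    out["max"] = max(out.values()) if out else 0.0
    return out


# --------------------------------------------------------------------------
# sparse triplet CSV export / import
# --------------------------------------------------------------------------


def write_rate_matrix_csv(K: RateMatrix, matrix_path, states_path) -> None:
    import csv

    # state labels contain commas (doubly occupied chaperonin complexes),
    # so both files are written with proper CSV quoting
    with open(states_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "label", "system", "agg_size", "position"])
        for s in K.states:
            w.writerow(
                [s.id, s.label, s.system.value if s.system else "", s.agg_size, s.position or ""]
            )
    with open(matrix_path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["from_state", "to_state", "rate"])
        for j, src in enumerate(K.states):
            for i, dst in enumerate(K.states):
                if i != j and K.K[i, j] != 0.0:
                    w.writerow([src.label, dst.label, f"{K.K[i, j]:.17g}"])


def read_rate_matrix_csv(matrix_path, states_path) -> RateMatrix:
    import csv

    states = []
    with open(states_path) as fh:
        for row in csv.DictReader(fh):
            states.append(
                ClientState(
                    int(row["id"]),
                    row["label"],
                    System(row["system"]) if row["system"] else None,
                    int(row["agg_size"]),
                    row["position"] or None,
                )
            )
    n = len(states)
    idx = {s.label: s.id for s in states}
    K = np.zeros((n, n))
    with open(matrix_path) as fh:
        for row in csv.DictReader(fh):
            K[idx[row["to_state"]], idx[row["from_state"]]] = float(row["rate"])
    np.fill_diagonal(K, -K.sum(axis=0))
    return RateMatrix(K, states)
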