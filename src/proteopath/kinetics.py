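"""Stiff mass-action ODE integration of the bulk network.

The simulation starts from zero client protein and fixed chaperone
concentrations and is integrated to an analysis time ``t_eval`` at which the
network is approximately stationary (for systems without runaway
aggregation).  Rate constants span many orders of magnitude, so the
integrator is BDF with an analytic Jacobian assembled from the mass-action
structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import NetworkModel

__all__ = [
    "AnalysisConfig",
    "ConcentrationState",
    "IntegrationError",
    "propagate",
    "species_summary",
    "conservation_check",
    "write_timeseries_csv",
]

#: tiny negative concentrations produced by the integrator are clamped to 0
#: when read through :class:`ConcentrationState`
TOL_NEG = 1e-9


class IntegrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class AnalysisConfig:
    """Integration protocol: analysis time, tolerances, output grid size."""

    t_eval: float = 1e4  # s
    rtol: float = 1e-8
    atol: float = 1e-12
    n_points: int = 50  # log-spaced output times; t_eval always included

    def __post_init__(self) -> None:
        if self.t_eval <= 0:
            raise ValueError("t_eval must be > 0")

    def output_grid(self, t_end: float | None = None) -> np.ndarray:
        t_end = t_end or self.t_eval
        grid = np.geomspace(t_end * 1e-6, t_end, self.n_points)
        grid[-1] = t_end
        return np.concatenate([[0.0], grid])


class ConcentrationState:
    """Concentrations (uM) of every species at one time point.

    Mapping-style access by species name; values within ``TOL_NEG`` of zero
    are clamped to 0 on read.
    """

    def __init__(self, time: float, names: list[str], values: np.ndarray):
        self.time = float(time)
        self.names = list(names)
        self.values = np.asarray(values, dtype=float)
        self._idx = {n: i for i, n in enumerate(self.names)}

    def __getitem__(self, name: str) -> float:
        v = self.values[self._idx[name]]
        if v < 0:
            if v < -TOL_NEG:
                raise ValueError(f"species {name} has concentration {v} < -{TOL_NEG}")
            return 0.0
        return float(v)

    def __contains__(self, name: str) -> bool:
        return name in self._idx

    def get(self, name: str, default: float = 0.0) -> float:
        return self[name] if name in self._idx else default

    def as_dict(self) -> dict[str, float]:
        return {n: self[n] for n in self.names}

    def __repr__(self) -> str:  # pragma: no cover
        return f"ConcentrationState(t={self.time:g}, {len(self.names)} species)"


class _CompiledRHS:
    """Vectorised mass-action right-hand side and Jacobian."""

    def __init__(self, model: NetworkModel):
        ns = len(model.species)
        nr = len(model.reactions)
        self.k = np.array([r.value for r in model.reactions])
        # net stoichiometry (species x reactions) and reactant exponents
        self.S = np.zeros((ns, nr))
        self.reactants: list[list[tuple[int, int]]] = []
        for j, r in enumerate(model.reactions):
            lst = []
            for sp, n in r.reactants:
                i = model.species_index(sp)
                self.S[i, j] -= n
                lst.append((i, n))
            for sp, n in r.products:
                self.S[model.species_index(sp), j] += n
            self.reactants.append(lst)
        self.ns, self.nr = ns, nr

    def fluxes(self, c: np.ndarray) -> np.ndarray:
        c = np.maximum(c, 0.0)
        f = self.k.copy()
        for j, lst in enumerate(self.reactants):
            for i, n in lst:
                f[j] *= c[i] ** n
        return f

    def rhs(self, t: float, c: np.ndarray) -> np.ndarray:
        return self.S @ self.fluxes(c)

    def jac(self, t: float, c: np.ndarray) -> np.ndarray:
        c = np.maximum(c, 0.0)
        dfdc = np.zeros((self.nr, self.ns))
        for j, lst in enumerate(self.reactants):
            for pos, (i, n) in enumerate(lst):
                d = self.k[j] * (n * c[i] ** (n - 1))
                for q, (i2, n2) in enumerate(lst):
                    if q != pos:
                        d *= c[i2] ** n2
                dfdc[j, i] += d
            # zeroth-order reactions contribute nothing to the Jacobian
        return self.S @ dfdc


def propagate(
    model: NetworkModel,
    config: AnalysisConfig | None = None,
    t_end: float | None = None,
) -> list[ConcentrationState]:
    """Integrate the bulk ODEs from zero client protein to ``t_eval``.

    Returns states on the output grid (the analysis time is always the last
    entry).  ``t_end`` extends the integration past ``config.t_eval``, e.g.
    for the frozen-matrix check at ``2 * t_eval``.
    """
    config = config or AnalysisConfig()
    compiled = _CompiledRHS(model)
    grid = config.output_grid(t_end)
    c0 = model.initial_concentrations()
    sol = solve_ivp(
        compiled.rhs,
        (0.0, grid[-1]),
        c0,
        method="BDF",
        jac=compiled.jac,
        t_eval=grid,
        rtol=config.rtol,
        atol=config.atol,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed at t={sol.t[-1]:g}: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError("non-finite concentrations in solution")
    names = [s.name for s in model.species]
    y = sol.y.copy()
    # species in a conservation group with zero total (e.g. a knocked-out
    # chaperone system) are identically zero; flush integrator noise there
    totals = model.conservation_totals()
    for group, weights in model.conservation_groups.items():
        if totals[group] == 0.0:
            for sp in weights:
                y[model.species_index(sp), :] = 0.0
    return [ConcentrationState(t, names, y[:, i]) for i, t in enumerate(sol.t)]


def species_summary(state: ConcentrationState, model: NetworkModel) -> dict[str, float]:
    """Conformational totals (uM) counting every client-containing species.

    ``native``/``unfolded``/``misfolded`` count complexed clients with their
    stoichiometry; ``aggregated_monomers`` is ``sum_n n*([A_n] + [A_n*])``;
    ``insoluble_fraction`` divides it by the total client monomers currently
    in existence (the degraded ``Null`` pool is excluded).
    """
    totals = {"native": 0.0, "unfolded": 0.0, "misfolded": 0.0, "aggregated_monomers": 0.0}
    key = {"N": "native", "U": "unfolded", "M": "misfolded"}
    for s in model.species:
        c = state[s.name]
        if s.agg_size:
            totals["aggregated_monomers"] += s.agg_size * c
        else:
            for conf in s.conformers:
                totals[key[conf]] += c
    client_total = sum(totals.values())
    totals["insoluble_fraction"] = (
        totals["aggregated_monomers"] / client_total if client_total > 0 else 0.0
    )
    return totals


def conservation_check(
    states: list[ConcentrationState], model: NetworkModel, tol: float = 1e-6
):
    """Max relative drift of every conservation group over a trajectory."""
    import pandas as pd

    if not states:
        raise ValueError("empty state list")
    rows = []
    for group, weights in model.conservation_groups.items():
        sums = np.array(
            [sum(w * st.values[st._idx[sp]] for sp, w in weights.items()) for st in states]
        )
        ref = sums[0]
        if ref == 0:
            drift = float(np.max(np.abs(sums)))
        else:
            drift = float(np.max(np.abs(sums - ref)) / abs(ref))
        rows.append({"group": group, "total": ref, "max_rel_drift": drift, "flagged": drift > tol})
    return pd.DataFrame(rows)


def write_timeseries_csv(states: list[ConcentrationState], path) -> None:
    """Long-format CSV (time, species, concentration)."""
    with open(path, "w") as fh:
        fh.write("time,species,concentration\n")
        for st in states:
            for name in st.names:
                fh.write(f"{st.time:.10g},{name},{st.values[st._idx[name]]:.10g}\n")
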