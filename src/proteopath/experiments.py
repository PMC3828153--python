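"""Scripted experiment designs: parameter sweeps, knockouts, classification.

Each experiment runs the full pipeline -- build the network, integrate the
bulk ODEs to the analysis time, freeze the tagged rate matrix, decompose the
requested transition into pathway channels -- at every grid point and stacks
the results into a tidy DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .committor import build_transition_matrix
from .kinetics import AnalysisConfig, propagate, species_summary
from .model import (
    BiophysicalProfile,
    ChaperoneLevels,
    ModelOptions,
    NetworkModel,
    PROFILES,
    System,
    build_model,
    knockout_system,
)
from .pathways import (
    ProportionalityFit,
    fit_proportionality,
    pathway_flux,
    pathway_probabilities,
)
from .tagged import extract_rate_matrix

__all__ = [
    "SweepSpec",
    "default_synthesis_grid",
    "run_point",
    "run_sweep",
    "knockout_compare",
    "classify_substrate",
    "groel_flux_ratio",
    "kje_bkje_proportionality",
]

SWEEPABLE = ("ribosome_activation_rate", "binding_factor", "capacity_factor")


def default_synthesis_grid(n: int = 5) -> np.ndarray:
    """Log-uniform ribosome activation rates spanning four decades (s^-1)."""
    return np.logspace(-7, -3, n)


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep over a set of protein profiles."""

    parameter: str
    grid: tuple[float, ...]
    profiles: tuple[str, ...] = ("default",)
    transition: tuple[str, str] = ("M", "U")
    levels: ChaperoneLevels = field(default_factory=ChaperoneLevels)
    options: ModelOptions = field(default_factory=ModelOptions)
    overrides: dict | None = None
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.parameter not in SWEEPABLE:
            raise ValueError(f"parameter must be one of {SWEEPABLE}")
        if len(self.grid) == 0:
            raise ValueError("grid must be nonempty")
        for name in self.profiles:
            if name not in PROFILES:
                raise KeyError(f"unknown profile {name!r}")


def _build_at(spec: SweepSpec, profile_name: str, value: float) -> NetworkModel:
    options = replace(spec.options, **{spec.parameter: value})
    return build_model(PROFILES[profile_name], spec.levels, options, spec.overrides)


def run_point(
    model: NetworkModel,
    analysis: AnalysisConfig,
    transition: tuple[str, str] = ("M", "U"),
):
    """Full pipeline at one configuration.

    Returns (decomposition, fluxes, summary, rate matrix, final state).
    """
    states = propagate(model, analysis)
    final = states[-1]
    K = extract_rate_matrix(model, final)
    T = build_transition_matrix(K)
    decomp = pathway_probabilities(T, [transition[0]], [transition[1]], K=K)
    fluxes = pathway_flux(decomp, K, final)
    summary = species_summary(final, model)
    return decomp, fluxes, summary, K, final


def run_sweep(spec: SweepSpec, analysis: AnalysisConfig | None = None) -> pd.DataFrame:
    """One row per (profile, grid value, channel); deterministic ordering.

    Failed integrations are flagged (``ok = False``) and the sweep
    continues.
    """
    analysis = analysis or spec.analysis
    rows = []
    for profile_name in spec.profiles:
        for value in spec.grid:
            model = _build_at(spec, profile_name, value)
            try:
                decomp, fluxes, summary, K, final = run_point(model, analysis, spec.transition)
            except Exception as exc:  # propagation / decomposition failure
                rows.append(
                    {
                        "profile": profile_name,
                        spec.parameter: value,
                        "channel": None,
                        "probability": np.nan,
                        "flux": np.nan,
                        "ok": False,
                        "error": str(exc),
                    }
                )
                continue
            free_groel = final.get("GrL_T", 0.0)
            for channel in sorted(decomp.probabilities):
                rows.append(
                    {
                        "profile": profile_name,
                        spec.parameter: value,
                        "channel": channel,
                        "probability": decomp.probabilities[channel],
                        "flux": fluxes.get(channel, 0.0),
                        "native": summary["native"],
                        "unfolded": summary["unfolded"],
                        "misfolded": summary["misfolded"],
                        "aggregated_monomers": summary["aggregated_monomers"],
                        "insoluble_fraction": summary["insoluble_fraction"],
                        "free_N": final.get("N", 0.0),
                        "free_U": final.get("U", 0.0),
                        "free_M": final.get("M", 0.0),
                        "free_GrL_T": free_groel,
                        "ok": True,
                        "error": "",
                    }
                )
    return pd.DataFrame(rows)


def knockout_compare(
    profile: BiophysicalProfile | str,
    system: System | str,
    levels: ChaperoneLevels | None = None,
    options: ModelOptions | None = None,
    analysis: AnalysisConfig | None = None,
    overrides: dict | None = None,
    transition: tuple[str, str] = ("M", "U"),
) -> dict:
    """Baseline vs knockout arms with compensation metrics.

    The knockout zeroes the system's chaperone concentrations; the reaction
    network is identical in both arms, so flux differences per channel
    quantify how the remaining systems compensate.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    levels = levels or ChaperoneLevels()
    options = options or ModelOptions()
    analysis = analysis or AnalysisConfig()
    base_model = build_model(profile, levels, options, overrides)
    ko_model = knockout_system(base_model, system)
    out = {}
    for arm, model in (("baseline", base_model), ("knockout", ko_model)):
        decomp, fluxes, summary, K, final = run_point(model, analysis, transition)
        out[arm] = {
            "probabilities": decomp.probabilities,
            "fluxes": fluxes,
            "summary": summary,
            "free_N": final.get("N", 0.0),
        }
    channels = set(out["baseline"]["fluxes"]) | set(out["knockout"]["fluxes"])
    out["delta_flux"] = {
        ch: out["knockout"]["fluxes"].get(ch, 0.0) - out["baseline"]["fluxes"].get(ch, 0.0)
        for ch in sorted(channels)
    }
    out["delta_native"] = out["knockout"]["free_N"] - out["baseline"]["free_N"]
    out["delta_insoluble_fraction"] = (
        out["knockout"]["summary"]["insoluble_fraction"]
        - out["baseline"]["summary"]["insoluble_fraction"]
    )
    return out


def classify_substrate(yield_curve: dict[float, float], theta: float = 0.5) -> str:
    """Kerner-style chaperonin dependence classes from a capacity curve.

    ``yield_curve`` maps capacity factor g to native yield.  A client is
    class III when depleting the chaperonin pool to the lowest capacity
    collapses the native yield below ``theta`` times the full-capacity
    yield; otherwise class I/II.
    """
    if 1.0 not in yield_curve:
        raise ValueError("yield curve must contain g = 1")
    g_min = min(yield_curve)
    full = yield_curve[1.0]
    if full <= 0:
        return "class-III" if yield_curve[g_min] < full else "class-I/II"
    return "class-III" if yield_curve[g_min] < theta * full else "class-I/II"


def groel_flux_ratio(sweep: pd.DataFrame) -> ProportionalityFit:
    """Fit (GroELS folding flux / direct folding flux) vs free [GrL_T].

    Expects a capacity-sweep table from :func:`run_sweep` with the U->N
    transition; points with zero direct flux are excluded.
    """
    pts = []
    ok = sweep[sweep["ok"] == True]  # noqa: E712
    for (profile, value), grp in ok.groupby(["profile", ok.columns[1]], sort=True):
        by = dict(zip(grp["channel"], grp["flux"]))
        direct = by.get("direct", 0.0)
        groels = by.get("GroELS", 0.0)
        if direct > 0:
            pts.append((grp["free_GrL_T"].iloc[0], groels / direct))
    if not pts:
        raise ValueError("no sweep points with nonzero direct flux")
    return fit_proportionality(pts)


def kje_bkje_proportionality(sweep: pd.DataFrame, min_ratio_prob: float = 1e-12):
    """KJE/B+KJE channel-probability ratio vs [M]/[aggregated monomers].

    Returns the proportionality fit across all sweep points where both the
    aggregate concentration and the B+KJE probability are nonzero.
    """
    pts = []
    ok = sweep[sweep["ok"] == True]  # noqa: E712
    for (profile, value), grp in ok.groupby(["profile", ok.columns[1]], sort=True):
        probs = dict(zip(grp["channel"], grp["probability"]))
        agg = grp["aggregated_monomers"].iloc[0]
        mis = grp["free_M"].iloc[0]
        p_kje = probs.get("KJE", 0.0)
        p_bkje = probs.get("B+KJE", 0.0)
        if agg > 0 and p_bkje > min_ratio_prob and mis > 0:
            pts.append((mis / agg, p_kje / p_bkje))
    if not pts:
        raise ValueError("no sweep points with nonzero aggregate population")
    return fit_proportionality(pts)
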