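"""Canonical reduced proteostasis reaction network for a single client protein.

The model tracks one client protein species through folding (U<->N),
misfolding (U<->M), aggregation (A_n), degradation (Lon) and three chaperone
systems of *E. coli*:

* **KJE** -- the Hsp70-like DnaK/DnaJ/GrpE cycle, which binds unfolded or
  misfolded client, actively unfolds misfolded client, and releases it
  unfolded after an ATP hydrolysis / nucleotide-exchange cycle.
* **GroELS** -- the Hsp60-like GroEL/GroES chaperonin, which encapsulates a
  client in the *cis* cavity where it folds at bulk rates and is released on a
  timer; a second client may occupy the *trans* ring.
* **B+KJE** -- ClpB cooperating with DnaK/DnaJ to extract monomers from
  aggregates.

Trigger factor is a pure holder (U + TF <-> TF:U) and Lon protease routes
client to a bookkeeping ``Null`` state that closes degradation to
re-synthesis, so a single tagged molecule has continuous dynamics.

Every reaction is elementary mass action.  ATP/ADP are assumed saturating:
nucleotide state is encoded in species identity (``K_T`` vs ``K_D``,
``GrL_T``).  Concentrations are in uM, rate constants in s^-1, uM^-1 s^-1 or
uM^-2 s^-1 according to molecularity.

Alongside the bulk reaction list, the builder records for each reaction the
*tagged-molecule moves*: the transitions available to one tracked client
molecule, with the bulk concentration factors that turn bimolecular steps
into pseudo-first-order rates.  Multi-client complexes contribute one move
per tagged position, and monomer removal from an aggregate of size n carries
the 1/n indistinguishability rule.
"""

from __future__ import annotations

import copy
import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "System",
    "BiophysicalProfile",
    "ChaperoneLevels",
    "ModelOptions",
    "Species",
    "Reaction",
    "TaggedMove",
    "NetworkModel",
    "build_model",
    "apply_binding_factor",
    "apply_capacity_factor",
    "knockout_system",
    "DEFAULT_RATE_CONSTANTS",
    "PROFILES",
    "ALL_SYSTEMS",
]


class System(str, enum.Enum):
    """Chaperone / auxiliary subsystems of the network."""

    KJE = "KJE"
    GROELS = "GroELS"
    BKJE = "B+KJE"
    TRIGGER_FACTOR = "TriggerFactor"
    DEGRADATION = "Degradation"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_SYSTEMS = frozenset(System)

#: Default values for every rate constant that is not derived from the
#: client's biophysical profile.  These are package defaults (the historical
#: FoldEco parameter table is an external resource): each value is picked
#: from the literature-plausible range for the step it describes and the set
#: is documented in docs/methods.md.  All are overridable via ``overrides``.
DEFAULT_RATE_CONSTANTS: dict[str, float] = {
    # trigger factor (holder)
    "k_tf_on": 0.1,      # uM^-1 s^-1
    "k_tf_off": 1.0,     # s^-1
    # Lon protease
    "k_lon_on": 0.1,     # uM^-1 s^-1
    "k_lon_off": 0.2,    # s^-1
    "k_lon_cat": 0.02,   # s^-1, commitment to degradation
    # KJE cycle (DnaK association is slow, ~1e5 M^-1 s^-1; misfolded
    # clients expose more hydrophobic surface and bind somewhat faster)
    "k_ku_on": 0.03,     # uM^-1 s^-1, DnaK(ATP) + U
    "k_ku_off": 0.3,     # s^-1
    "k_km_on": 0.1,      # uM^-1 s^-1, DnaK(ATP) + M
    "k_km_off": 0.3,     # s^-1
    "k_kje_unfold": 0.1, # s^-1, DnaK-mediated unfolding of bound M
    "k_j_on": 2.0,       # uM^-1 s^-1, DnaJ2 joins K_T:U
    "k_j_off": 0.5,      # s^-1
    "k_hyd": 1.0,        # s^-1, DnaJ-stimulated ATP hydrolysis
    "k_j_rel": 0.5,      # s^-1, DnaJ2 release from the ADP complex
    "k_exch": 0.4,       # uM^-1 s^-1, GrpE-catalysed exchange + release
    # GroELS cycle (misfolded clients present the strong hydrophobic
    # binding surface; nascent unfolded chains are bound more weakly)
    "k_gu_on": 0.03,     # uM^-1 s^-1, GroEL(ATP) + U
    "k_gu_off": 1.0,     # s^-1
    "k_gm_on": 0.4,      # uM^-1 s^-1, GroEL(ATP) + M
    "k_gm_off": 1.0,     # s^-1
    "k_es_on": 1.0,      # uM^-1 s^-1, GroES capping (cis encapsulation)
    "k_cycle": 0.3,      # s^-1, timed release of the cis cavity
    # B+KJE disaggregation
    "k_prep": 0.05,      # uM^-2 s^-1, aggregate preparation by DnaK+DnaJ
    "k_unprep": 0.02,    # s^-1
    "k_extract": 0.1,    # uM^-1 s^-1, ClpB monomer extraction
}

#: Steps that are deliberately one-way (no mass-action reverse reaction).
IRREVERSIBLE_STEPS = frozenset(
    {
        "k_kje_unfold",  # active unfolding
        "k_hyd",         # ATP hydrolysis
        "k_j_rel",       # DnaJ release after hydrolysis
        "k_exch",        # nucleotide exchange + client release
        "k_es_on",       # encapsulation (cap release is the timer step)
        "k_cycle",       # timed cavity release
        "k_lon_cat",     # commitment to degradation
        "k_extract",     # ClpB extraction
        "k_syn",         # synthesis
    }
)


# --------------------------------------------------------------------------
# configuration dataclasses
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BiophysicalProfile:
    """Six-parameter biophysical profile of the client protein.

    Parameters
    ----------
    k_fold : float
        Folding rate constant U->N (s^-1).
    K_fold : float
        Dimensionless folding equilibrium constant; the unfolding rate is
        ``k_unfold = k_fold / K_fold``.
    k_mis : float
        Misfolding rate constant U->M (s^-1).
    K_mis : float
        Dimensionless misfolding equilibrium constant;
        ``k_unmis = k_mis / K_mis``.
    k_ag : float
        Aggregation rate constant (uM^-1 s^-1).
    c_crit : float
        Critical aggregation concentration (uM); controls the disaggregation
        rate as ``k_dis = k_ag * c_crit``.
    """

    k_fold: float
    K_fold: float
    k_mis: float
    K_mis: float
    k_ag: float
    c_crit: float

    def __post_init__(self) -> None:
        for name in ("k_fold", "K_fold", "k_mis", "K_mis", "k_ag", "c_crit"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise ValueError(f"profile parameter {name} must be strictly positive, got {value!r}")

    @property
    def k_unfold(self) -> float:
        return self.k_fold / self.K_fold

    @property
    def k_unmis(self) -> float:
        return self.k_mis / self.K_mis

    @property
    def k_dis(self) -> float:
        return self.k_ag * self.c_crit


#: The four characteristic client proteins (k_mis, K_mis, k_fold, K_fold,
#: k_ag, c_crit).  "Slow Folder" folds slowly into a very stable native
#: state; "Bad Folder" misfolds into the most stable trap; "Aggregator"
#: misfolds quickly and aggregates at low critical concentration.
PROFILES: dict[str, BiophysicalProfile] = {
    "default": BiophysicalProfile(k_fold=0.1, K_fold=1e4, k_mis=1.0, K_mis=100.0, k_ag=0.1, c_crit=0.1),
    "slow_folder": BiophysicalProfile(k_fold=0.02, K_fold=3e5, k_mis=1.0, K_mis=0.1, k_ag=0.4, c_crit=1.0),
    "bad_folder": BiophysicalProfile(k_fold=0.1, K_fold=2e4, k_mis=1.0, K_mis=200.0, k_ag=1.0, c_crit=2.0),
    "aggregator": BiophysicalProfile(k_fold=0.1, K_fold=2e4, k_mis=10.0, K_mis=40.0, k_ag=10.0, c_crit=0.01),
}


@dataclass(frozen=True)
class ChaperoneLevels:
    """Total chaperone concentrations (uM).

    Defaults are the geometric-average literature values used for the
    wild-type *E. coli* cytosol.  ``dnaj`` is the total monomer
    concentration; the functional species is the dimer ``J2``.
    """

    ribosomes: float = 20.0
    trigger_factor: float = 20.0
    dnak: float = 30.0
    dnaj: float = 1.0
    grpe: float = 15.0
    groel: float = 42.0
    groes: float = 35.0
    lon: float = 0.3
    clpb: float = 1.8

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"chaperone level {name} must be nonnegative, got {value}")


@dataclass(frozen=True)
class ModelOptions:
    """Structural and experimental knobs of the network.

    ``binding_factor`` (lambda) multiplies GroEL on-rates and divides DnaK
    on-rates; ``capacity_factor`` (g) scales the total GroEL and GroES
    concentrations; ``ribosome_activation_rate`` controls synthesis through
    ``r_syn = ribosome_activation_rate * [Rib]``.
    """

    ribosome_activation_rate: float = 1e-4  # s^-1
    n_max: int = 20
    binding_factor: float = 1.0
    capacity_factor: float = 1.0
    enabled_systems: frozenset[System] = ALL_SYSTEMS
    double_occupancy: bool = True
    enable_aggregation: bool = True
    lon_binds_misfolded: bool = True
    null_floor: float = 1e-6  # uM, floor on [Null] in the tagged closure

    def __post_init__(self) -> None:
        if self.n_max < 2:
            raise ValueError(f"n_max must be >= 2, got {self.n_max}")
        if self.binding_factor <= 0:
            raise ValueError("binding_factor must be > 0")
        if self.capacity_factor < 0:
            raise ValueError("capacity_factor must be >= 0")
        if self.ribosome_activation_rate < 0:
            raise ValueError("ribosome_activation_rate must be >= 0")
        systems = frozenset(System(s) for s in self.enabled_systems)
        object.__setattr__(self, "enabled_systems", systems)
        if System.BKJE in systems:
            if System.KJE not in systems:
                raise ValueError("the B+KJE system requires the KJE system")
            if not self.enable_aggregation:
                raise ValueError("the B+KJE system requires aggregation to be enabled")


# --------------------------------------------------------------------------
# network data structures
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Species:
    """One chemical species of the bulk model.

    ``conformers`` lists the conformation (U/N/M) of each client molecule in
    the species (empty for chaperones, bookkeeping and aggregates);
    ``agg_size`` is the number of aggregated monomers (0 if not an
    aggregate).
    """

    name: str
    role: str  # client-state | chaperone | complex | bookkeeping
    initial: float
    conformers: tuple[str, ...] = ()
    agg_size: int = 0
    system: System | None = None

    @property
    def client_count(self) -> int:
        return self.agg_size if self.agg_size else len(self.conformers)


@dataclass(frozen=True)
class TaggedMove:
    """A transition of the tagged molecule contributed by one bulk reaction.

    The tagged rate is ``reaction.value * weight * prod(conc(s)**p)`` over
    ``factors``; a power of -1 divides by the concentration floored at the
    model's ``null_floor`` (used only by the synthesis closure).
    """

    src: str
    dst: str
    weight: float = 1.0
    factors: tuple[tuple[str, int], ...] = ()


@dataclass(frozen=True)
class Reaction:
    """An elementary mass-action reaction.

    ``constant`` names the rate constant (shared between reactions that use
    the same physical constant, e.g. aggregate growth at every size);
    ``name`` is unique.  ``reversible_partner`` points to the reaction
    realising the microscopic reverse step, if one exists.
    """

    name: str
    constant: str
    value: float
    reactants: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    moves: tuple[TaggedMove, ...] = ()
    system: System | None = None
    reversible_partner: str | None = None

    @property
    def order(self) -> int:
        return sum(n for _, n in self.reactants)


@dataclass
class NetworkModel:
    """A validated reaction network: species, reactions, conservation groups.

    Conservation groups map a chaperone name to ``{species: weight}``; the
    weighted concentration sum over each group is a linear invariant of the
    dynamics.
    """

    profile: BiophysicalProfile
    levels: ChaperoneLevels
    options: ModelOptions
    species: list[Species]
    reactions: list[Reaction]
    conservation_groups: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        self._index = {s.name: i for i, s in enumerate(self.species)}
        if len(self._index) != len(self.species):
            raise ValueError("duplicate species names")

    # -- lookups ---------------------------------------------------------
    def species_index(self, name: str) -> int:
        return self._index[name]

    def has_species(self, name: str) -> bool:
        return name in self._index

    def initial_concentrations(self):
        import numpy as np

        return np.array([s.initial for s in self.species], dtype=float)

    def rate(self, constant: str) -> float:
        for r in self.reactions:
            if r.constant == constant:
                return r.value
        raise KeyError(constant)

    def conservation_totals(self) -> dict[str, float]:
        totals = {}
        for group, weights in self.conservation_groups.items():
            totals[group] = sum(w * self.species[self._index[s]].initial for s, w in weights.items())
        return totals

    # -- transforms ------------------------------------------------------
    def _scaled_constants(self, scale: dict[str, float]) -> "NetworkModel":
        new = copy.deepcopy(self)
        new.reactions = [
            replace(r, value=r.value * scale.get(r.constant, 1.0)) for r in new.reactions
        ]
        return new

    def with_initials(self, updates: dict[str, float]) -> "NetworkModel":
        new = copy.deepcopy(self)
        new.species = [
            replace(s, initial=updates.get(s.name, s.initial)) for s in new.species
        ]
        return new

    # -- export ----------------------------------------------------------
    def to_tsv(self, species_path, reactions_path) -> None:
        """Write species and reaction listings as TSV."""
        with open(species_path, "w") as fh:
            fh.write("name\trole\tinitial_uM\tclient_count\tagg_size\tsystem\n")
            for s in self.species:
                fh.write(
                    f"{s.name}\t{s.role}\t{s.initial:.10g}\t{s.client_count}\t"
                    f"{s.agg_size}\t{s.system.value if s.system else ''}\n"
                )
        with open(reactions_path, "w") as fh:
            fh.write("name\tconstant\tvalue\treactants\tproducts\tsystem\n")
            for r in self.reactions:
                lhs = " + ".join(f"{n} {sp}" if n > 1 else sp for sp, n in r.reactants) or "0"
                rhs = " + ".join(f"{n} {sp}" if n > 1 else sp for sp, n in r.products) or "0"
                fh.write(
                    f"{r.name}\t{r.constant}\t{r.value:.10g}\t{lhs}\t{rhs}\t"
                    f"{r.system.value if r.system else ''}\n"
                )


# --------------------------------------------------------------------------
# builder
# --------------------------------------------------------------------------

_SYSTEM_CHAPERONES: dict[System, tuple[str, ...]] = {
    System.KJE: ("K_T", "J2", "GrpE"),
    System.GROELS: ("GrL_T", "GrS"),
    System.BKJE: ("ClpB",),
    System.TRIGGER_FACTOR: ("TF",),
    System.DEGRADATION: ("Lon",),
}


def build_model(
    profile: BiophysicalProfile,
    levels: ChaperoneLevels | None = None,
    options: ModelOptions | None = None,
    overrides: dict[str, float] | None = None,
) -> NetworkModel:
    """Instantiate the reaction network for one client protein.

    ``overrides`` maps rate-constant names (from
    :data:`DEFAULT_RATE_CONSTANTS` plus the profile-derived ``k_fold``,
    ``k_unfold``, ``k_mis``, ``k_unmis``, ``k_ag``, ``k_dis``) to replacement
    values.  The binding factor and capacity factor held in ``options`` are
    applied during the build.
    """
    levels = levels or ChaperoneLevels()
    options = options or ModelOptions()
    systems = options.enabled_systems

    constants = dict(DEFAULT_RATE_CONSTANTS)
    constants.update(
        {
            "k_fold": profile.k_fold,
            "k_unfold": profile.k_unfold,
            "k_mis": profile.k_mis,
            "k_unmis": profile.k_unmis,
            "k_ag": profile.k_ag,
            "k_dis": profile.k_dis,
        }
    )
    if overrides:
        unknown = set(overrides) - set(constants)
        if unknown:
            raise KeyError(f"unknown rate-constant override(s): {sorted(unknown)}")
        constants.update(overrides)

    lam = options.binding_factor
    constants["k_ku_on"] /= lam
    constants["k_km_on"] /= lam
    constants["k_gu_on"] *= lam
    constants["k_gm_on"] *= lam

    r_syn = options.ribosome_activation_rate * levels.ribosomes
    constants["k_syn"] = r_syn

    species: list[Species] = []
    reactions: list[Reaction] = []

    def add_species(name, role, initial, conformers=(), agg_size=0, system=None):
        species.append(Species(name, role, initial, tuple(conformers), agg_size, system))

    def add(name, constant, reactants, products, moves, system=None, partner=None):
        reactions.append(
            Reaction(
                name=name,
                constant=constant,
                value=constants[constant],
                reactants=tuple(sorted(reactants.items())),
                products=tuple(sorted(products.items())),
                moves=tuple(moves),
                system=system,
                reversible_partner=partner,
            )
        )

    # ---- species -------------------------------------------------------
    add_species("Null", "bookkeeping", 0.0)
    add_species("U", "client-state", 0.0, ("U",))
    add_species("N", "client-state", 0.0, ("N",))
    add_species("M", "client-state", 0.0, ("M",))
    if System.TRIGGER_FACTOR in systems:
        add_species("TF:U", "complex", 0.0, ("U",), system=System.TRIGGER_FACTOR)
    if System.DEGRADATION in systems:
        add_species("Lon:U", "complex", 0.0, ("U",), system=System.DEGRADATION)
        if options.lon_binds_misfolded:
            add_species("Lon:M", "complex", 0.0, ("M",), system=System.DEGRADATION)
    if System.KJE in systems:
        add_species("K_T:U", "complex", 0.0, ("U",), system=System.KJE)
        add_species("K_T:M", "complex", 0.0, ("M",), system=System.KJE)
        add_species("U:J:K_T", "complex", 0.0, ("U",), system=System.KJE)
        add_species("U:J:K_D", "complex", 0.0, ("U",), system=System.KJE)
        add_species("K_D:U", "complex", 0.0, ("U",), system=System.KJE)
    cis_confs = ("U", "N", "M")
    trans_confs = ("U", "M")
    if System.GROELS in systems:
        add_species("GrL_T:U", "complex", 0.0, ("U",), system=System.GROELS)
        add_species("GrL_T:M", "complex", 0.0, ("M",), system=System.GROELS)
        for x in cis_confs:
            add_species(f"GrLd:{{{x}}}:GrS", "complex", 0.0, (x,), system=System.GROELS)
        if options.double_occupancy:
            for x in cis_confs:
                for y in trans_confs:
                    add_species(
                        f"GrLd:{{{x},{y}}}:GrS", "complex", 0.0, (x, y), system=System.GROELS
                    )
    if options.enable_aggregation:
        for n in range(2, options.n_max + 1):
            add_species(f"A{n}", "client-state", 0.0, agg_size=n)
        if System.BKJE in systems:
            for n in range(2, options.n_max + 1):
                add_species(f"A{n}*", "client-state", 0.0, agg_size=n, system=System.BKJE)

    g = options.capacity_factor
    add_species("Rib", "chaperone", levels.ribosomes)
    if System.TRIGGER_FACTOR in systems:
        add_species("TF", "chaperone", levels.trigger_factor, system=System.TRIGGER_FACTOR)
    if System.DEGRADATION in systems:
        add_species("Lon", "chaperone", levels.lon, system=System.DEGRADATION)
    if System.KJE in systems:
        add_species("K_T", "chaperone", levels.dnak, system=System.KJE)
        add_species("J2", "chaperone", levels.dnaj / 2.0, system=System.KJE)
        add_species("GrpE", "chaperone", levels.grpe, system=System.KJE)
    if System.GROELS in systems:
        add_species("GrL_T", "chaperone", levels.groel * g, system=System.GROELS)
        add_species("GrS", "chaperone", levels.groes * g, system=System.GROELS)
    if System.BKJE in systems:
        add_species("ClpB", "chaperone", levels.clpb, system=System.BKJE)

    # ---- core conformational reactions ---------------------------------
    add("fold", "k_fold", {"U": 1}, {"N": 1}, [TaggedMove("U", "N")], partner="unfold")
    add("unfold", "k_unfold", {"N": 1}, {"U": 1}, [TaggedMove("N", "U")], partner="fold")
    add("misfold", "k_mis", {"U": 1}, {"M": 1}, [TaggedMove("U", "M")], partner="unmisfold")
    add("unmisfold", "k_unmis", {"M": 1}, {"U": 1}, [TaggedMove("M", "U")], partner="misfold")

    # ---- synthesis closure ---------------------------------------------
    # Bulk flux is zeroth order in client (r_syn = activation rate * [Rib]);
    # the tagged molecule leaves Null at r_syn / max([Null], floor).
    add("synthesis", "k_syn", {}, {"U": 1}, [TaggedMove("Null", "U", factors=(("Null", -1),))])

    # ---- degradation ----------------------------------------------------
    if System.DEGRADATION in systems:
        deg_clients = ["U"] + (["M"] if options.lon_binds_misfolded else [])
        for x in deg_clients:
            lx = x.lower()
            add(f"lon_on_{lx}", "k_lon_on", {x: 1, "Lon": 1}, {f"Lon:{x}": 1},
                [TaggedMove(x, f"Lon:{x}", factors=(("Lon", 1),))],
                System.DEGRADATION, partner=f"lon_off_{lx}")
            add(f"lon_off_{lx}", "k_lon_off", {f"Lon:{x}": 1}, {x: 1, "Lon": 1},
                [TaggedMove(f"Lon:{x}", x)], System.DEGRADATION, partner=f"lon_on_{lx}")
            add(f"lon_cat_{lx}", "k_lon_cat", {f"Lon:{x}": 1}, {"Lon": 1, "Null": 1},
                [TaggedMove(f"Lon:{x}", "Null")], System.DEGRADATION)

    # ---- trigger factor -------------------------------------------------
    if System.TRIGGER_FACTOR in systems:
        add("tf_on", "k_tf_on", {"U": 1, "TF": 1}, {"TF:U": 1},
            [TaggedMove("U", "TF:U", factors=(("TF", 1),))], System.TRIGGER_FACTOR,
            partner="tf_off")
        add("tf_off", "k_tf_off", {"TF:U": 1}, {"U": 1, "TF": 1},
            [TaggedMove("TF:U", "U")], System.TRIGGER_FACTOR, partner="tf_on")

    # ---- KJE cycle ------------------------------------------------------
    if System.KJE in systems:
        add("ku_on", "k_ku_on", {"U": 1, "K_T": 1}, {"K_T:U": 1},
            [TaggedMove("U", "K_T:U", factors=(("K_T", 1),))], System.KJE, partner="ku_off")
        add("ku_off", "k_ku_off", {"K_T:U": 1}, {"U": 1, "K_T": 1},
            [TaggedMove("K_T:U", "U")], System.KJE, partner="ku_on")
        add("km_on", "k_km_on", {"M": 1, "K_T": 1}, {"K_T:M": 1},
            [TaggedMove("M", "K_T:M", factors=(("K_T", 1),))], System.KJE, partner="km_off")
        add("km_off", "k_km_off", {"K_T:M": 1}, {"M": 1, "K_T": 1},
            [TaggedMove("K_T:M", "M")], System.KJE, partner="km_on")
        add("kje_unfold", "k_kje_unfold", {"K_T:M": 1}, {"K_T:U": 1},
            [TaggedMove("K_T:M", "K_T:U")], System.KJE)
        add("j_on", "k_j_on", {"K_T:U": 1, "J2": 1}, {"U:J:K_T": 1},
            [TaggedMove("K_T:U", "U:J:K_T", factors=(("J2", 1),))], System.KJE, partner="j_off")
        add("j_off", "k_j_off", {"U:J:K_T": 1}, {"K_T:U": 1, "J2": 1},
            [TaggedMove("U:J:K_T", "K_T:U")], System.KJE, partner="j_on")
        add("hyd", "k_hyd", {"U:J:K_T": 1}, {"U:J:K_D": 1},
            [TaggedMove("U:J:K_T", "U:J:K_D")], System.KJE)
        add("j_rel", "k_j_rel", {"U:J:K_D": 1}, {"K_D:U": 1, "J2": 1},
            [TaggedMove("U:J:K_D", "K_D:U")], System.KJE)
        add("exch", "k_exch", {"K_D:U": 1, "GrpE": 1}, {"U": 1, "K_T": 1, "GrpE": 1},
            [TaggedMove("K_D:U", "U", factors=(("GrpE", 1),))], System.KJE)

    # ---- GroELS cycle ---------------------------------------------------
    if System.GROELS in systems:
        for x, kon, koff in (("U", "k_gu_on", "k_gu_off"), ("M", "k_gm_on", "k_gm_off")):
            lx = x.lower()
            add(f"g{lx}_on", kon, {x: 1, "GrL_T": 1}, {f"GrL_T:{x}": 1},
                [TaggedMove(x, f"GrL_T:{x}", factors=(("GrL_T", 1),))], System.GROELS,
                partner=f"g{lx}_off")
            add(f"g{lx}_off", koff, {f"GrL_T:{x}": 1}, {x: 1, "GrL_T": 1},
                [TaggedMove(f"GrL_T:{x}", x)], System.GROELS, partner=f"g{lx}_on")
            add(f"encaps_{lx}", "k_es_on", {f"GrL_T:{x}": 1, "GrS": 1},
                {f"GrLd:{{{x}}}:GrS": 1},
                [TaggedMove(f"GrL_T:{x}", f"GrLd:{{{x}}}:GrS", factors=(("GrS", 1),))],
                System.GROELS)
        # in-cavity conversions at bulk rates
        cavity = [("U", "N", "k_fold", "k_unfold"), ("U", "M", "k_mis", "k_unmis")]
        for a, b, kf, kr in cavity:
            add(f"cav_{a}{b}".lower(), kf, {f"GrLd:{{{a}}}:GrS": 1}, {f"GrLd:{{{b}}}:GrS": 1},
                [TaggedMove(f"GrLd:{{{a}}}:GrS", f"GrLd:{{{b}}}:GrS")], System.GROELS,
                partner=f"cav_{b}{a}".lower())
            add(f"cav_{b}{a}".lower(), kr, {f"GrLd:{{{b}}}:GrS": 1}, {f"GrLd:{{{a}}}:GrS": 1},
                [TaggedMove(f"GrLd:{{{b}}}:GrS", f"GrLd:{{{a}}}:GrS")], System.GROELS,
                partner=f"cav_{a}{b}".lower())
        for x in cis_confs:
            add(f"release_{x.lower()}", "k_cycle", {f"GrLd:{{{x}}}:GrS": 1},
                {x: 1, "GrL_T": 1, "GrS": 1},
                [TaggedMove(f"GrLd:{{{x}}}:GrS", x)], System.GROELS)
        if options.double_occupancy:
            # trans-ring binding to a capped single-occupancy complex
            for x in cis_confs:
                for y, kon in (("U", "k_gu_on"), ("M", "k_gm_on")):
                    single = f"GrLd:{{{x}}}:GrS"
                    double = f"GrLd:{{{x},{y}}}:GrS"
                    add(f"trans_{y.lower()}_{x.lower()}", kon, {single: 1, y: 1}, {double: 1},
                        [
                            # tagged molecule binds into the trans ring
                            TaggedMove(y, f"GrLd:{{{x.lower()},{y}}}:GrS",
                                       factors=((single, 1),)),
                            # tagged molecule already in cis gains a partner
                            TaggedMove(single, f"GrLd:{{{x},{y.lower()}}}:GrS",
                                       factors=((y, 1),)),
                        ],
                        System.GROELS)
            # cis conversions with a trans partner
            for y in trans_confs:
                for a, b, kf, kr in cavity:
                    for (c, d, kk) in ((a, b, kf), (b, a, kr)):
                        add(f"cavd_{c}{d}_{y}".lower(), kk,
                            {f"GrLd:{{{c},{y}}}:GrS": 1}, {f"GrLd:{{{d},{y}}}:GrS": 1},
                            [
                                TaggedMove(f"GrLd:{{{c},{y.lower()}}}:GrS",
                                           f"GrLd:{{{d},{y.lower()}}}:GrS"),
                                TaggedMove(f"GrLd:{{{c.lower()},{y}}}:GrS",
                                           f"GrLd:{{{d.lower()},{y}}}:GrS"),
                            ],
                            System.GROELS, partner=f"cavd_{d}{c}_{y}".lower())
            # timed release of the cis client; the trans client becomes the
            # new cis-bound client of the re-opened complex
            for x in cis_confs:
                for y in trans_confs:
                    add(f"release_{x.lower()}_{y.lower()}", "k_cycle",
                        {f"GrLd:{{{x},{y}}}:GrS": 1}, {x: 1, "GrS": 1, f"GrL_T:{y}": 1},
                        [
                            TaggedMove(f"GrLd:{{{x},{y.lower()}}}:GrS", x),
                            TaggedMove(f"GrLd:{{{x.lower()},{y}}}:GrS", f"GrL_T:{y}"),
                        ],
                        System.GROELS)

    # ---- aggregation ----------------------------------------------------
    if options.enable_aggregation:
        n_max = options.n_max
        add("nucleation", "k_ag", {"M": 2}, {"A2": 1},
            [TaggedMove("M", "A2", factors=(("M", 1),))], partner="dissolve_2")
        add("dissolve_2", "k_dis", {"A2": 1}, {"M": 2},
            [TaggedMove("A2", "M")], partner="nucleation")
        for n in range(2, n_max):
            add(f"growth_{n}", "k_ag", {f"A{n}": 1, "M": 1}, {f"A{n + 1}": 1},
                [
                    TaggedMove("M", f"A{n + 1}", factors=((f"A{n}", 1),)),
                    TaggedMove(f"A{n}", f"A{n + 1}", factors=(("M", 1),)),
                ],
                partner=f"shrink_{n + 1}")
            add(f"shrink_{n + 1}", "k_dis", {f"A{n + 1}": 1}, {f"A{n}": 1, "M": 1},
                [
                    TaggedMove(f"A{n + 1}", "M", weight=1.0 / (n + 1)),
                    TaggedMove(f"A{n + 1}", f"A{n}", weight=n / (n + 1)),
                ],
                partner=f"growth_{n}")

    # ---- B+KJE disaggregation ------------------------------------------
    if System.BKJE in systems:
        for n in range(2, options.n_max + 1):
            add(f"prep_{n}", "k_prep", {f"A{n}": 1, "K_T": 1, "J2": 1}, {f"A{n}*": 1},
                [TaggedMove(f"A{n}", f"A{n}*", factors=(("K_T", 1), ("J2", 1)))],
                System.BKJE, partner=f"unprep_{n}")
            add(f"unprep_{n}", "k_unprep", {f"A{n}*": 1}, {f"A{n}": 1, "K_T": 1, "J2": 1},
                [TaggedMove(f"A{n}*", f"A{n}")], System.BKJE, partner=f"prep_{n}")
        for n in range(3, options.n_max + 1):
            add(f"extract_{n}", "k_extract", {f"A{n}*": 1, "ClpB": 1},
                {f"A{n - 1}": 1, "U": 1, "ClpB": 1, "K_T": 1, "J2": 1},
                [
                    TaggedMove(f"A{n}*", "U", weight=1.0 / n, factors=(("ClpB", 1),)),
                    TaggedMove(f"A{n}*", f"A{n - 1}", weight=(n - 1.0) / n,
                               factors=(("ClpB", 1),)),
                ],
                System.BKJE)
        # dimer extraction: tagged molecule leaves as U or stays behind as M
        add("extract_2", "k_extract", {"A2*": 1, "ClpB": 1},
            {"U": 1, "M": 1, "ClpB": 1, "K_T": 1, "J2": 1},
            [
                TaggedMove("A2*", "U", weight=0.5, factors=(("ClpB", 1),)),
                TaggedMove("A2*", "M", weight=0.5, factors=(("ClpB", 1),)),
            ],
            System.BKJE)

    # ---- conservation groups -------------------------------------------
    groups: dict[str, dict[str, float]] = {"Ribosomes": {"Rib": 1.0}}
    if System.TRIGGER_FACTOR in systems:
        groups["TF"] = {"TF": 1.0, "TF:U": 1.0}
    if System.DEGRADATION in systems:
        lon = {"Lon": 1.0, "Lon:U": 1.0}
        if options.lon_binds_misfolded:
            lon["Lon:M"] = 1.0
        groups["Lon"] = lon
    if System.KJE in systems:
        dnak = {"K_T": 1.0, "K_T:U": 1.0, "K_T:M": 1.0, "U:J:K_T": 1.0,
                "U:J:K_D": 1.0, "K_D:U": 1.0}
        dnaj = {"J2": 2.0, "U:J:K_T": 2.0, "U:J:K_D": 2.0}
        if System.BKJE in systems:
            for n in range(2, options.n_max + 1):
                dnak[f"A{n}*"] = 1.0
                dnaj[f"A{n}*"] = 2.0
        groups["DnaK"] = dnak
        groups["DnaJ"] = dnaj
        groups["GrpE"] = {"GrpE": 1.0}
    if System.GROELS in systems:
        groel = {"GrL_T": 1.0, "GrL_T:U": 1.0, "GrL_T:M": 1.0}
        groes = {"GrS": 1.0}
        for s in species:
            if s.name.startswith("GrLd:"):
                groel[s.name] = 1.0
                groes[s.name] = 1.0
        groups["GroEL"] = groel
        groups["GroES"] = groes
    if System.BKJE in systems:
        groups["ClpB"] = {"ClpB": 1.0}

    model = NetworkModel(profile, levels, options, species, reactions, groups)
    _validate(model)
    return model


def _validate(model: NetworkModel) -> None:
    names = {s.name for s in model.species}
    for r in model.reactions:
        for sp, _ in r.reactants + r.products:
            if sp not in names:
                raise ValueError(f"reaction {r.name} references unknown species {sp}")
    for group, weights in model.conservation_groups.items():
        for sp in weights:
            if sp not in names:
                raise ValueError(f"conservation group {group} references unknown species {sp}")
    # the tagged-move graph over client states must be connected
    import itertools

    labels = set()
    edges = []
    for r in model.reactions:
        for mv in r.moves:
            labels.add(mv.src)
            labels.add(mv.dst)
            edges.append((mv.src, mv.dst))
    parent = {lab: lab for lab in labels}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        parent[find(a)] = find(b)
    roots = {find(lab) for lab in labels}
    if len(roots) > 1:
        raise ValueError(f"client-state graph is disconnected: {len(roots)} components")


# --------------------------------------------------------------------------
# configuration transforms
# --------------------------------------------------------------------------


def apply_binding_factor(model: NetworkModel, binding_factor: float) -> NetworkModel:
    """Scale GroEL on-rates by lambda and DnaK on-rates by 1/lambda."""
    if binding_factor <= 0:
        raise ValueError("binding factor must be > 0")
    lam = binding_factor
    new = model._scaled_constants(
        {"k_gu_on": lam, "k_gm_on": lam, "k_ku_on": 1.0 / lam, "k_km_on": 1.0 / lam}
    )
    new.options = replace(model.options, binding_factor=model.options.binding_factor * lam)
    return new


def apply_capacity_factor(model: NetworkModel, capacity_factor: float) -> NetworkModel:
    """Scale the initial total GroEL and GroES concentrations by ``g``."""
    if capacity_factor < 0:
        raise ValueError("capacity factor must be >= 0")
    updates = {}
    for name in ("GrL_T", "GrS"):
        if model.has_species(name):
            updates[name] = model.species[model.species_index(name)].initial * capacity_factor
    new = model.with_initials(updates)
    new.options = replace(
        model.options, capacity_factor=model.options.capacity_factor * capacity_factor
    )
    return new


def knockout_system(model: NetworkModel, system: System | str) -> NetworkModel:
    """Zero the initial concentrations of a system's chaperones.

    The reaction list is unchanged: fluxes through the system vanish
    dynamically, mirroring a genetic knockout of the chaperone.
    """
    system = System(system)
    if system not in model.options.enabled_systems:
        raise ValueError(f"system {system.value} is not enabled in this model")
    updates = {name: 0.0 for name in _SYSTEM_CHAPERONES[system] if model.has_species(name)}
    return model.with_initials(updates)
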