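"""Multi-compartment reaction network for one cyclic nucleotide.

The cell is modelled as a small set of well-mixed compartments (bulk cytosol
``CYT``, plasmalemma ``PM``, outer mitochondrial membrane ``OMM``).  Within
each compartment a cyclic nucleotide (cAMP or cGMP) is produced by cyclase
sources at a zero-order, treatment-scaled rate, degraded by phosphodiesterases
(PDEs) with Michaelis–Menten kinetics, and exchanged with neighbouring
compartments by first-order fluxes.  For compartment *i* holding
concentration :math:`S_i` (μM),

.. math::

    \\frac{dS_i}{dt} = \\sum_c J_c \\; - \\sum_p a_p (1-\\phi_p)
        \\frac{V_{max,p} S_i}{K_{M,p} + S_i} \\; + \\sum_j k_{ij}(S_j - S_i)

where :math:`J_c` are cyclase rates (μM·s⁻¹), :math:`a_p` dimensionless
activity scalars, :math:`\\phi_p` pharmacological inhibition fractions and
:math:`k_{ij}` exchange rate constants (s⁻¹).  Exchange terms are
volume-corrected so total mass is conserved.

Units throughout: concentrations in μM, time in s.  PDE maximal rates are
carried as intrinsic specific activities (μmol·min⁻¹·mg⁻¹, as usually
tabulated) together with a dimensionless density factor that converts them to
a compartment-local ``vmax`` in μM·s⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .errors import (
    ConvergenceError,
    InvalidInputError,
    InvalidProtocolError,
    NoSteadyStateError,
    StructuralError,
)

NUCLEOTIDES = ("cAMP", "cGMP")
COMPARTMENT_NAMES = ("CYT", "PM", "OMM")
PDE_FAMILIES = ("PDE1", "PDE2A", "PDE3", "PDE4", "PDE5", "PDE8", "PDE9")

#: Michaelis constants (μM) and specific activities (μmol·min⁻¹·mg⁻¹) per
#: family.  PDE8 (0.06/0.15) and PDE4 (5/0.03) carry the tabulated cAMP
#: constants for the high-affinity/fast and low-affinity/slow enzymes; PDE2A
#: carries its low-affinity constants for cGMP (10 μM) and cAMP (30 μM).  The
#: remaining Km and all other Vmax values are literature-typical defaults.
PDE_KINETICS: Mapping[str, dict] = {
    "PDE1": {"substrate": "dual", "km_uM": {"cGMP": 3.0, "cAMP": 30.0}, "vmax_specific": 0.10},
    "PDE2A": {"substrate": "dual", "km_uM": {"cGMP": 10.0, "cAMP": 30.0}, "vmax_specific": 0.12},
    "PDE3": {"substrate": "dual", "km_uM": {"cAMP": 0.15, "cGMP": 0.30}, "vmax_specific": 0.01},
    "PDE4": {"substrate": "cAMP", "km_uM": {"cAMP": 5.0}, "vmax_specific": 0.03},
    "PDE5": {"substrate": "cGMP", "km_uM": {"cGMP": 1.5}, "vmax_specific": 0.04},
    "PDE8": {"substrate": "cAMP", "km_uM": {"cAMP": 0.06}, "vmax_specific": 0.15},
    "PDE9": {"substrate": "cGMP", "km_uM": {"cGMP": 0.17}, "vmax_specific": 0.03},
}


@dataclass(frozen=True)
class PDEIsoform:
    """A phosphodiesterase family with its substrate specificity and kinetics.

    ``vmax_local = vmax_specific * density_factor`` is the compartment-local
    maximal hydrolysis rate in μM·s⁻¹; the density factor absorbs the
    (unknown) enzyme amount per compartment.
    """

    name: str
    substrate: str  # "cAMP", "cGMP" or "dual"
    km_uM: Mapping[str, float]
    vmax_specific: float
    density_factor: float = 1.0

    def __post_init__(self):
        if self.substrate not in ("cAMP", "cGMP", "dual"):
            raise InvalidInputError(f"unknown substrate {self.substrate!r}")
        expected = NUCLEOTIDES if self.substrate == "dual" else (self.substrate,)
        for nuc in expected:
            km = self.km_uM.get(nuc)
            if km is None or km <= 0:
                raise InvalidInputError(f"{self.name}: Km for {nuc} must be positive")
        if self.vmax_specific < 0 or self.density_factor < 0:
            raise InvalidInputError(f"{self.name}: vmax and density factor must be >= 0")

    @property
    def vmax_local(self) -> float:
        """Compartment-local maximal rate, μM·s⁻¹."""
        return self.vmax_specific * self.density_factor

    def km(self, nucleotide: str) -> float:
        try:
            return self.km_uM[nucleotide]
        except KeyError:
            raise InvalidInputError(f"{self.name} does not hydrolyse {nucleotide}") from None

    def hydrolyses(self, nucleotide: str) -> bool:
        return self.substrate == "dual" or self.substrate == nucleotide


def pde_isoform(name: str, density_factor: float = 1.0) -> PDEIsoform:
    """Build a :class:`PDEIsoform` from the built-in kinetics table."""
    try:
        entry = PDE_KINETICS[name]
    except KeyError:
        raise InvalidInputError(f"unknown PDE family {name!r}") from None
    return PDEIsoform(name=name, substrate=entry["substrate"], km_uM=dict(entry["km_uM"]),
                      vmax_specific=entry["vmax_specific"], density_factor=density_factor)


@dataclass(frozen=True)
class TreatmentEffects:
    """Resolved pharmacological state applied to a model.

    ``inhibition`` maps PDE family name to an occupancy fraction in [0, 1].
    ``ac_drive`` is the fraction of the adenylyl-cyclase stimulation reserve
    engaged (0 untreated, 1 full/forskolin).  ``reduced_sgc_drive`` adds to the
    NO input of the reduced (heme-intact) sGC branch; ``oxidised_sgc_drive``
    drives the oxidised branch (cinaciguat-sensitive, NO-insensitive).
    """

    inhibition: Mapping[str, float] = field(default_factory=dict)
    ac_drive: float = 0.0
    reduced_sgc_drive: float = 0.0
    oxidised_sgc_drive: float = 0.0

    def __post_init__(self):
        for name, frac in self.inhibition.items():
            if not 0.0 <= frac <= 1.0:
                raise InvalidInputError(f"inhibition fraction for {name} outside [0, 1]")
        if self.ac_drive < 0 or self.reduced_sgc_drive < 0 or self.oxidised_sgc_drive < 0:
            raise InvalidInputError("treatment drives must be >= 0")

    def inhibition_of(self, pde_name: str) -> float:
        return self.inhibition.get(pde_name, 0.0)


UNTREATED = TreatmentEffects()


@dataclass(frozen=True)
class CyclaseSource:
    """A cyclase population local to one compartment.

    cAMP sources behave as adenylyl cyclases (AC): rate ``J_basal * stim``
    with ``stim`` between 1 and ``max_stim_factor``.  cGMP sources behave as
    soluble guanylyl cyclase (sGC) split into a reduced branch, activated by
    NO (endogenous ``no_input`` plus NO donors / NO-independent stimulators),
    and an ``oxidised_fraction`` that ignores NO but responds to oxidised-sGC
    activators such as cinaciguat.
    """

    nucleotide: str
    j_basal: float  # μM·s⁻¹
    max_stim_factor: float = 1.0
    stim_factor: float = 1.0
    oxidised_fraction: float = 0.0
    no_input: float = 0.0

    def __post_init__(self):
        if self.nucleotide not in NUCLEOTIDES:
            raise InvalidInputError(f"unknown nucleotide {self.nucleotide!r}")
        if self.j_basal < 0:
            raise InvalidInputError("J_basal must be >= 0")
        if not 1.0 <= self.stim_factor <= self.max_stim_factor + 1e-12:
            raise InvalidInputError("stim_factor must satisfy 1 <= stim_factor <= max_stim_factor")
        if not 0.0 <= self.oxidised_fraction <= 1.0:
            raise InvalidInputError("oxidised_fraction must lie in [0, 1]")
        if self.no_input < 0:
            raise InvalidInputError("no_input must be >= 0")


def synthesis_rate(source: CyclaseSource, effects: TreatmentEffects = UNTREATED) -> float:
    """Current synthesis rate of a cyclase source (μM·s⁻¹)."""
    if source.nucleotide == "cAMP":
        stim = max(source.stim_factor, 1.0 + effects.ac_drive * (source.max_stim_factor - 1.0))
        stim = min(stim, source.max_stim_factor)
        return source.j_basal * stim
    # sGC: reduced branch follows NO-type drives, oxidised branch only
    # cinaciguat-type drives; both saturate at the fold-activation ceiling.
    f = min(1.0 + source.no_input + effects.reduced_sgc_drive, source.max_stim_factor)
    g = min(1.0 + effects.oxidised_sgc_drive, source.max_stim_factor)
    f = max(f, 1.0)
    g = max(g, 1.0)
    ox = source.oxidised_fraction
    return source.j_basal * ((1.0 - ox) * f + ox * g)


def michaelis_menten_rate(isoform: PDEIsoform, substrate_conc: float,
                          activity_scalar: float = 1.0, inhibition_fraction: float = 0.0,
                          nucleotide: str | None = None) -> float:
    """Michaelis–Menten hydrolysis rate (μM·s⁻¹).

    ``activity_scalar`` is the dimensionless compartment-local activity
    multiplier; ``inhibition_fraction`` the pharmacological occupancy.  For a
    dual-specificity isoform pass ``nucleotide`` to select the Km.
    """
    if substrate_conc < 0:
        raise InvalidInputError("substrate concentration must be >= 0")
    if activity_scalar < 0:
        raise InvalidInputError("activity scalar must be >= 0")
    if not 0.0 <= inhibition_fraction <= 1.0:
        raise InvalidInputError("inhibition fraction must lie in [0, 1]")
    if nucleotide is None:
        if isoform.substrate == "dual":
            raise InvalidInputError(f"{isoform.name} is dual-specificity; specify the nucleotide")
        nucleotide = isoform.substrate
    km = isoform.km(nucleotide)
    return (activity_scalar * (1.0 - inhibition_fraction) * isoform.vmax_local
            * substrate_conc / (km + substrate_conc))


def exchange_flux(conc_a: float, conc_b: float, k_ex: float) -> float:
    """First-order exchange rate into compartment *b* (μM·s⁻¹ in b's volume)."""
    if k_ex < 0:
        raise InvalidInputError("k_ex must be >= 0")
    return k_ex * (conc_a - conc_b)


@dataclass(frozen=True)
class Compartment:
    """One well-mixed compartment: PDE complement, sources and exchanges.

    ``pdes`` pairs each isoform with its dimensionless activity scalar.
    ``exchanges`` maps a partner compartment name to the exchange rate
    constant ``k_ex`` (s⁻¹) expressed in *this* compartment's volume; each
    exchange coupling must be declared on exactly one side of the pair (the
    opposite flux is derived by volume scaling so mass is conserved).
    """

    name: str
    volume_fraction: float
    pdes: tuple = ()  # tuple[(PDEIsoform, activity scalar), ...]
    cyclases: tuple = ()  # tuple[CyclaseSource, ...]
    exchanges: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.volume_fraction <= 1.0:
            raise InvalidInputError(f"{self.name}: volume fraction must lie in (0, 1]")
        for _, activity in self.pdes:
            if activity < 0:
                raise InvalidInputError(f"{self.name}: PDE activity scalar must be >= 0")
        for k in self.exchanges.values():
            if k < 0:
                raise InvalidInputError(f"{self.name}: k_ex must be >= 0")


@dataclass(frozen=True)
class CellModel:
    """A genotype-specific compartmental model for one nucleotide."""

    genotype: str
    nucleotide: str
    compartments: tuple  # tuple[Compartment, ...]
    initial_uM: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.nucleotide not in NUCLEOTIDES:
            raise InvalidInputError(f"unknown nucleotide {self.nucleotide!r}")
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise StructuralError("duplicate compartment names")
        if sum(c.volume_fraction for c in self.compartments) > 1.0 + 1e-9:
            raise InvalidInputError("compartment volume fractions must sum to <= 1")
        for comp in self.compartments:
            for partner in comp.exchanges:
                if partner not in names:
                    raise StructuralError(f"{comp.name} exchanges with unknown compartment {partner}")
                other = self.compartment(partner)
                if comp.name in other.exchanges:
                    raise StructuralError(
                        f"exchange {comp.name}<->{partner} declared on both sides")
            for source in comp.cyclases:
                if source.nucleotide != self.nucleotide:
                    raise StructuralError(
                        f"{comp.name}: cyclase nucleotide {source.nucleotide} != model {self.nucleotide}")
            for iso, _ in comp.pdes:
                if not iso.hydrolyses(self.nucleotide):
                    raise StructuralError(f"{comp.name}: {iso.name} does not hydrolyse {self.nucleotide}")
        if len(self.compartments) > 1 and not self._connected():
            raise StructuralError("compartment graph is not connected")

    def _connected(self) -> bool:
        names = [c.name for c in self.compartments]
        adj = {n: set() for n in names}
        for comp in self.compartments:
            for partner in comp.exchanges:
                adj[comp.name].add(partner)
                adj[partner].add(comp.name)
        seen = {names[0]}
        stack = [names[0]]
        while stack:
            for nxt in adj[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return len(seen) == len(names)

    @property
    def compartment_names(self) -> tuple:
        return tuple(c.name for c in self.compartments)

    def compartment(self, name: str) -> Compartment:
        for comp in self.compartments:
            if comp.name == name:
                return comp
        raise StructuralError(f"no compartment named {name!r}")

    def index(self, name: str) -> int:
        return self.compartment_names.index(name)

    def initial_state(self) -> np.ndarray:
        return np.array([self.initial_uM.get(c.name, 0.0) for c in self.compartments], float)


def _compartment_rate(model: CellModel, comp: Compartment, s: float,
                      effects: TreatmentEffects) -> float:
    """Local (non-exchange) net rate: synthesis minus hydrolysis."""
    rate = 0.0
    for source in comp.cyclases:
        rate += synthesis_rate(source, effects)
    for iso, activity in comp.pdes:
        rate -= michaelis_menten_rate(iso, s, activity, effects.inhibition_of(iso.name),
                                      nucleotide=model.nucleotide)
    return rate


def assemble_rhs(model: CellModel, state: Sequence[float],
                 effects: TreatmentEffects = UNTREATED) -> np.ndarray:
    """Time derivatives dS/dt (μM·s⁻¹) per compartment, in model order."""
    state = np.asarray(state, float)
    if state.shape != (len(model.compartments),):
        raise StructuralError(
            f"state has shape {state.shape}, expected ({len(model.compartments)},)")
    if np.any(state < 0):
        raise InvalidInputError("state concentrations must be >= 0")
    deriv = np.zeros_like(state)
    for i, comp in enumerate(model.compartments):
        deriv[i] += _compartment_rate(model, comp, state[i], effects)
        for partner, k_ex in comp.exchanges.items():
            j = model.index(partner)
            flux = exchange_flux(state[j], state[i], k_ex)  # into comp i
            deriv[i] += flux
            # partner loses the same mass: scale by the volume ratio
            deriv[j] -= flux * comp.volume_fraction / model.compartments[j].volume_fraction
    return deriv


def _capacity_check(model: CellModel, effects: TreatmentEffects) -> None:
    """Raise NoSteadyStateError if synthesis can outrun total hydrolysis."""
    synth_mass = 0.0
    vmax_mass = 0.0
    for comp in model.compartments:
        v = comp.volume_fraction
        synth_mass += v * sum(synthesis_rate(src, effects) for src in comp.cyclases)
        vmax_mass += v * sum(
            act * (1.0 - effects.inhibition_of(iso.name)) * iso.vmax_local
            for iso, act in comp.pdes)
        # an isolated compartment must balance locally
        if not comp.exchanges and not any(comp.name in c.exchanges for c in model.compartments):
            local_j = sum(synthesis_rate(src, effects) for src in comp.cyclases)
            local_v = sum(act * (1.0 - effects.inhibition_of(iso.name)) * iso.vmax_local
                          for iso, act in comp.pdes)
            if local_j > 0 and local_j >= local_v * (1.0 - 1e-12):
                raise NoSteadyStateError(
                    f"{comp.name}: synthesis {local_j:g} >= hydrolysis capacity {local_v:g}")
    if synth_mass > 0 and synth_mass >= vmax_mass * (1.0 - 1e-12):
        raise NoSteadyStateError(
            f"total synthesis {synth_mass:g} >= total hydrolysis capacity {vmax_mass:g}")


def solve_steady_state(model: CellModel, effects: TreatmentEffects = UNTREATED,
                       s0: Sequence[float] | None = None, tol: float = 1e-10) -> np.ndarray:
    """Steady-state concentrations (μM) per compartment.

    Solved by root-finding on the RHS in log-concentration space (which
    enforces positivity), with a long-horizon integration fallback.  Raises
    :class:`NoSteadyStateError` when synthesis exceeds hydrolysis capacity and
    :class:`ConvergenceError` when the residual cannot be driven below ``tol``.
    """
    _capacity_check(model, effects)
    n = len(model.compartments)
    total_j = sum(synthesis_rate(src, effects)
                  for comp in model.compartments for src in comp.cyclases)
    if total_j == 0.0:
        return np.zeros(n)

    if s0 is None:
        guess = np.full(n, 0.1)
    else:
        guess = np.maximum(np.asarray(s0, float), 1e-9)

    def log_rhs(x):
        # clip to keep exp finite while the root-finder explores
        return assemble_rhs(model, np.exp(np.clip(x, -500.0, 500.0)), effects)

    scale = max(total_j, 1e-12)
    for attempt in range(2):
        sol = root(log_rhs, np.log(guess), method="hybr", tol=1e-14)
        s_star = np.exp(sol.x)
        resid = np.max(np.abs(assemble_rhs(model, s_star, effects)))
        if resid < tol * max(1.0, scale / 1e-3):
            return s_star
        if attempt == 0:
            # relax toward the attractor, then re-polish
            ivp = solve_ivp(lambda t, y: assemble_rhs(model, np.maximum(y, 0.0), effects),
                            (0.0, 1e5), guess, method="LSODA", rtol=1e-10, atol=1e-12)
            guess = np.maximum(ivp.y[:, -1], 1e-12)
    raise ConvergenceError(f"steady-state residual {resid:g} above tolerance")


def simulate_schedule(model: CellModel, schedule: Sequence[tuple], t_grid: Sequence[float],
                      s0: Sequence[float] | None = None, rtol: float = 1e-8,
                      atol: float = 1e-10) -> np.ndarray:
    """Integrate over a piecewise-constant treatment schedule.

    ``schedule`` is a sequence of ``(t_start, t_end, TreatmentEffects)``
    segments covering the simulation window; integration restarts at each
    boundary so drug additions are handled as instantaneous steps.  Returns an
    array of shape ``(len(t_grid), n_compartments)``.  When ``s0`` is omitted
    the trajectory starts at the steady state of the first segment.
    """
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise InvalidInputError("output grid must be strictly increasing with >= 2 points")
    if not schedule:
        raise InvalidProtocolError("empty treatment schedule")
    if t_grid[0] < schedule[0][0] - 1e-9 or t_grid[-1] > schedule[-1][1] + 1e-9:
        raise InvalidProtocolError("output grid extends beyond the schedule")

    if s0 is None:
        state = solve_steady_state(model, schedule[0][2])
    else:
        state = np.asarray(s0, float).copy()
    out = np.empty((len(t_grid), len(model.compartments)))
    filled = 0
    for t0, t1, effects in schedule:
        remaining = t_grid[filled:]
        grid_pts = remaining[(remaining >= t0 - 1e-9) & (remaining <= t1 + 1e-9)].tolist()
        eval_pts = list(grid_pts)
        if not eval_pts or abs(eval_pts[-1] - t1) > 1e-9:
            eval_pts.append(t1)  # always land exactly on the event time
        sol = solve_ivp(lambda t, y: assemble_rhs(model, np.maximum(y, 0.0), effects),
                        (t0, t1), state, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=eval_pts)
        if not sol.success:
            raise ConvergenceError(f"integration failed on [{t0}, {t1}]: {sol.message}")
        y = sol.y.T
        out[filled:filled + len(grid_pts)] = y[:len(grid_pts)]
        filled += len(grid_pts)
        state = y[-1].copy()
    if filled != len(t_grid):
        raise StructuralError("schedule did not cover every grid point")
    return np.maximum(out, 0.0)


def simulate_protocol(model: CellModel, protocol, t_grid: Sequence[float] | None = None,
                      s0: Sequence[float] | None = None, rtol: float = 1e-8,
                      atol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a timed drug-addition protocol on the acquisition grid.

    Returns ``(t_grid, concentrations)`` with concentrations of shape
    ``(n_frames, n_compartments)``.  The default grid spans the protocol
    duration at its frame interval, mirroring image acquisition every 10 s.
    """
    from .pharmacology import resolve_protocol  # late import; pharmacology depends on kinetics

    schedule = resolve_protocol(protocol, model)
    if t_grid is None:
        t_grid = np.arange(0.0, protocol.duration + 1e-9, protocol.frame_interval)
    t_grid = np.asarray(t_grid, float)
    conc = simulate_schedule(model, schedule, t_grid, s0=s0, rtol=rtol, atol=atol)
    return t_grid, conc
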