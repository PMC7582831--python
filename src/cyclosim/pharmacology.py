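"""Virtual pharmacology: drugs, doses, treatments and timed protocols.

Named drugs at their experimental working doses are translated into
parameter transformations of a :class:`~cyclosim.kinetics.CellModel`:

* family-selective PDE inhibitors produce complete block (occupancy 1) of
  their primary family at the working dose, plus IC50-based occupancy of
  documented off-targets (sildenafil inhibits PDE1 with IC50 = 0.1 μM);
* IBMX blocks every PDE family;
* isoproterenol (β-adrenergic, sub-maximal) and forskolin (direct, maximal)
  engage the adenylyl-cyclase stimulation reserve;
* SNAP (NO donor) and Bay 41-2272 (NO-independent stimulator) drive the
  reduced branch of sGC; cinaciguat drives both branches and is the only
  drug the oxidised fraction responds to.

Drug effects are instantaneous steps — with frames every 10 s, sub-frame
binding kinetics are not identifiable and are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .errors import IncompatibleTreatmentError, InvalidInputError, InvalidProtocolError
from .kinetics import PDE_FAMILIES, CellModel, TreatmentEffects

CAMP_PDES = tuple(n for n in PDE_FAMILIES if n in ("PDE1", "PDE2A", "PDE3", "PDE4", "PDE8"))
CGMP_PDES = tuple(n for n in PDE_FAMILIES if n in ("PDE1", "PDE2A", "PDE3", "PDE5", "PDE9"))


def inhibition_fraction(dose_uM: float, ic50_uM: float) -> float:
    """Single-site occupancy ``dose / (dose + IC50)``; monotone in dose."""
    if dose_uM < 0:
        raise InvalidInputError("dose must be >= 0")
    if ic50_uM <= 0:
        raise InvalidInputError("IC50 must be > 0")
    return dose_uM / (dose_uM + ic50_uM)


@dataclass(frozen=True)
class DrugAction:
    """One mechanism of a drug: what it touches and how strongly."""

    mechanism: str  # pde_inhibition | sgc_no_donor | sgc_stimulator |
    #                 sgc_oxidised_activator | ac_receptor_stimulation | ac_direct_activation
    target: str | None = None  # PDE family for pde_inhibition
    ic50_uM: float | None = None  # None => complete block at the working dose
    drive: float = 0.0  # dimensionless drive for cyclase mechanisms


@dataclass(frozen=True)
class DrugSpec:
    name: str
    dose_uM: float  # working dose used throughout the experiments
    actions: tuple  # tuple[DrugAction, ...]
    nucleotide: str | None = None  # restrict to cAMP/cGMP models; None = both


def _pde_block(*families: str) -> tuple:
    return tuple(DrugAction("pde_inhibition", target=f) for f in families)


#: The drug panel with working doses.  Cyclase drive magnitudes are the
#: fold-activation each stimulus contributes at its working dose; they are
#: model defaults (dose–response curves for the cyclases are not part of the
#: kinetic scheme).  ``reduced_sgc_drive`` values add on top of the
#: endogenous NO input; cinaciguat carries a strong oxidised-branch drive and
#: a weak reduced-branch one.
DRUG_LIBRARY: Mapping[str, DrugSpec] = {
    "Bay60_7550": DrugSpec("Bay60_7550", 1.0, _pde_block("PDE2A")),
    "sildenafil": DrugSpec("sildenafil", 10.0,
                           _pde_block("PDE5")
                           + (DrugAction("pde_inhibition", target="PDE1", ic50_uM=0.1),)),
    "cilostamide": DrugSpec("cilostamide", 10.0, _pde_block("PDE3")),
    "rolipram": DrugSpec("rolipram", 10.0, _pde_block("PDE4"), nucleotide="cAMP"),
    "PF04449743": DrugSpec("PF04449743", 5.0, _pde_block("PDE9"), nucleotide="cGMP"),
    "PF04957325": DrugSpec("PF04957325", 0.3, _pde_block("PDE8"), nucleotide="cAMP"),
    "IBMX": DrugSpec("IBMX", 100.0, _pde_block(*PDE_FAMILIES)),
    "SNAP": DrugSpec("SNAP", 50.0, (DrugAction("sgc_no_donor", drive=4.0),),
                     nucleotide="cGMP"),
    "Bay41_2272": DrugSpec("Bay41_2272", 5.0, (DrugAction("sgc_stimulator", drive=3.0),),
                           nucleotide="cGMP"),
    "cinaciguat": DrugSpec("cinaciguat", 10.0,
                           (DrugAction("sgc_oxidised_activator", drive=8.0),
                            DrugAction("sgc_stimulator", drive=1.0)),
                           nucleotide="cGMP"),
    "isoproterenol": DrugSpec("isoproterenol", 0.001, (DrugAction("ac_receptor_stimulation", drive=0.5),),
                              nucleotide="cAMP"),
    "forskolin": DrugSpec("forskolin", 25.0, (DrugAction("ac_direct_activation", drive=0.9),),
                          nucleotide="cAMP"),
}


@dataclass(frozen=True)
class Treatment:
    """One or more drugs added simultaneously (e.g. SNAP + Bay 41)."""

    drugs: tuple  # tuple[str, ...] of DRUG_LIBRARY keys
    label: str | None = None

    def __post_init__(self):
        if not self.drugs:
            raise InvalidInputError("a treatment needs at least one drug")
        for name in self.drugs:
            if name not in DRUG_LIBRARY:
                raise InvalidInputError(f"unknown drug {name!r}")
        if self.label is None:
            object.__setattr__(self, "label", "+".join(self.drugs))


def treatment(*drugs: str, label: str | None = None) -> Treatment:
    return Treatment(tuple(drugs), label=label)


@dataclass(frozen=True)
class ProtocolEvent:
    time_s: float
    treatment: Treatment
    label: str | None = None

    def __post_init__(self):
        if self.label is None:
            object.__setattr__(self, "label", self.treatment.label)


@dataclass(frozen=True)
class Protocol:
    """Timed drug additions plus the terminal saturation event.

    ``stim_label`` names the event that anchors the R/R0 baseline (the 8
    frames preceding it); ``saturation_label`` marks the terminal IBMX or
    IBMX+forskolin addition used for the non-saturation control.
    """

    duration: float
    events: tuple  # tuple[ProtocolEvent, ...]
    frame_interval: float = 10.0
    stim_label: str | None = None
    saturation_label: str | None = None

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise InvalidProtocolError("frame_interval must be > 0")
        times = [e.time_s for e in self.events]
        if any(t < 0 for t in times):
            raise InvalidProtocolError("event before t = 0")
        if any(t > self.duration for t in times):
            raise InvalidProtocolError("event after protocol end")
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            if len(set(times)) != len(times):
                raise InvalidProtocolError(
                    "duplicate event times; encode simultaneous additions as one combined treatment")
            raise InvalidProtocolError("events must be in strictly increasing time order")
        labels = [e.label for e in self.events]
        if len(set(labels)) != len(labels):
            raise InvalidProtocolError("event labels must be unique")
        for name in (self.stim_label, self.saturation_label):
            if name is not None and name not in labels:
                raise InvalidProtocolError(f"no event labelled {name!r}")

    def event(self, label: str) -> ProtocolEvent:
        for e in self.events:
            if e.label == label:
                return e
        raise InvalidProtocolError(f"no event labelled {label!r}")

    def frame_of(self, label: str) -> int:
        """0-based index of the first frame acquired after the addition."""
        import math
        t = self.event(label).time_s
        return int(math.floor(t / self.frame_interval)) + 1

    @property
    def n_frames(self) -> int:
        return int(self.duration / self.frame_interval) + 1


def _merge_effects(effects: TreatmentEffects, drug: DrugSpec,
                   model: CellModel) -> TreatmentEffects:
    if drug.nucleotide is not None and drug.nucleotide != model.nucleotide:
        raise IncompatibleTreatmentError(
            f"{drug.name} acts on {drug.nucleotide} models, not {model.nucleotide}")
    inhibition = dict(effects.inhibition)
    ac = dict(getattr(effects, "_ac_drives", {}) or {})
    red = dict(getattr(effects, "_red_drives", {}) or {})
    oxi = dict(getattr(effects, "_oxi_drives", {}) or {})
    for action in drug.actions:
        if action.mechanism == "pde_inhibition":
            frac = 1.0 if action.ic50_uM is None else inhibition_fraction(drug.dose_uM, action.ic50_uM)
            # same-site occupancy: a saturating inhibitor dominates
            inhibition[action.target] = max(inhibition.get(action.target, 0.0), frac)
        elif action.mechanism in ("ac_receptor_stimulation", "ac_direct_activation"):
            ac[drug.name] = max(ac.get(drug.name, 0.0), action.drive)
        elif action.mechanism in ("sgc_no_donor", "sgc_stimulator"):
            # distinct drugs add their drives; re-applying a drug overwrites its own key
            red[drug.name] = max(red.get(drug.name, 0.0), action.drive)
        elif action.mechanism == "sgc_oxidised_activator":
            oxi[drug.name] = max(oxi.get(drug.name, 0.0), action.drive)
        else:
            raise InvalidInputError(f"unknown mechanism {action.mechanism!r}")
    merged = TreatmentEffects(
        inhibition=inhibition,
        ac_drive=max([0.0, *ac.values()]),
        reduced_sgc_drive=sum(red.values()),
        oxidised_sgc_drive=max([0.0, *oxi.values()]),
    )
    object.__setattr__(merged, "_ac_drives", ac)
    object.__setattr__(merged, "_red_drives", red)
    object.__setattr__(merged, "_oxi_drives", oxi)
    return merged


def apply_treatment(model: CellModel, trt: Treatment,
                    base: TreatmentEffects | None = None) -> TreatmentEffects:
    """Resolve a treatment into :class:`TreatmentEffects` on top of ``base``.

    The input model is never modified.  Composition is per-drug and keyed by
    drug name, so applying the same treatment twice is idempotent and the
    order of application never matters.
    """
    effects = base if base is not None else TreatmentEffects()
    for name in trt.drugs:
        effects = _merge_effects(effects, DRUG_LIBRARY[name], model)
    return effects


def resolve_protocol(protocol: Protocol, model: CellModel) -> list:
    """Piecewise-constant schedule ``[(t0, t1, TreatmentEffects), ...]``.

    Effects are cumulative: each event composes with everything added
    earlier.  Segment boundaries align exactly with event times.
    """
    segments = []
    effects = TreatmentEffects()
    t_prev = 0.0
    for event in protocol.events:
        if event.time_s > t_prev:
            segments.append((t_prev, event.time_s, effects))
            t_prev = event.time_s
        elif event.time_s < t_prev:
            raise InvalidProtocolError("events out of order")
        effects = apply_treatment(model, event.treatment, base=effects)
    if protocol.duration > t_prev:
        segments.append((t_prev, protocol.duration, effects))
    if not segments:
        segments.append((0.0, protocol.duration, effects))
    return segments
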