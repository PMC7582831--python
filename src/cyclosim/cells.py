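"""Default cell models, genotype factor tables and the experiment library.

The control neonatal ventricular myocyte (NVM) is described by one cAMP and
one cGMP model with three compartments: bulk cytosol (CYT, 70% of cell
volume), plasmalemma shell (PM, 5%) and outer mitochondrial membrane shell
(OMM, 5%).  Adenylyl cyclases sit at the plasmalemma; soluble guanylyl
cyclase is present in all three compartments, with a small NO-supplied pool
near the mitochondria.  PM and OMM exchange nucleotide with the cytosol by
first-order fluxes; there is no direct PM↔OMM coupling.

The dystrophic (mdx) cell is the control model transformed by a genotype
factor table.  The factors are calibration defaults chosen so that the model
reproduces the qualitative control-vs-mdx differences observed with targeted
FRET reporters (lower basal cGMP in cytosol and PM, unchanged at the OMM;
higher basal cAMP in the cytosol but lower at the OMM; blunted responses to
isoproterenol and forskolin; unchanged PM cAMP responses) — they are model
calibration values, not measurements.  Key ingredients: a reduced endogenous
NO drive, a larger and more oxidised sGC pool at the plasmalemma, less PDE4
in the cytosol, redistribution of PDE8 toward the OMM, a weaker adenylyl
cyclase stimulation reserve, and slower PM→cytosol cAMP exchange (the
disordered cortical cytoskeleton trapping sub-membrane cAMP).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ConfigError
from .kinetics import CellModel, Compartment, CyclaseSource, pde_isoform
from .pharmacology import Protocol, ProtocolEvent, Treatment, treatment

GENOTYPES = ("control", "mdx")

VOLUME_FRACTIONS = {"CYT": 0.70, "PM": 0.05, "OMM": 0.05}


def _pde(name: str, vmax_local: float):
    """(isoform, activity=1) pair with the density factor set so that the
    compartment-local vmax equals ``vmax_local`` μM·s⁻¹."""
    from .kinetics import PDE_KINETICS
    density = vmax_local / PDE_KINETICS[name]["vmax_specific"]
    return (pde_isoform(name, density_factor=density), 1.0)


# ---------------------------------------------------------------------------
# Control models

def control_cgmp_model() -> CellModel:
    """Control cGMP model: sGC in all compartments, cGMP-PDE complement.

    The endogenous NO drive (``no_input = 2``) roughly triples basal sGC
    output over its NO-free rate; the OMM carries its own small NO-supplied
    sGC pool, which is what keeps mitochondrial cGMP insensitive to the
    cytosolic NO deficit of the dystrophic cell.
    """
    cyt = Compartment(
        name="CYT", volume_fraction=VOLUME_FRACTIONS["CYT"],
        pdes=(_pde("PDE2A", 0.32), _pde("PDE5", 0.055), _pde("PDE1", 0.023),
              _pde("PDE9", 0.0047), _pde("PDE3", 0.003)),
        cyclases=(CyclaseSource("cGMP", j_basal=0.0094, max_stim_factor=6.0,
                                no_input=2.0, oxidised_fraction=0.0),),
    )
    pm = Compartment(
        name="PM", volume_fraction=VOLUME_FRACTIONS["PM"],
        pdes=(_pde("PDE5", 0.0174), _pde("PDE2A", 0.0254), _pde("PDE1", 0.009),
              _pde("PDE9", 0.0025), _pde("PDE3", 0.002)),
        cyclases=(CyclaseSource("cGMP", j_basal=0.0053, max_stim_factor=6.0,
                                no_input=2.0, oxidised_fraction=0.1),),
        exchanges={"CYT": 0.02},
    )
    omm = Compartment(
        name="OMM", volume_fraction=VOLUME_FRACTIONS["OMM"],
        pdes=(_pde("PDE2A", 0.0337), _pde("PDE5", 0.01), _pde("PDE9", 0.002)),
        cyclases=(CyclaseSource("cGMP", j_basal=0.001, max_stim_factor=6.0,
                                no_input=2.0, oxidised_fraction=0.0),),
        exchanges={"CYT": 0.001},
    )
    return CellModel(genotype="control", nucleotide="cGMP", compartments=(cyt, pm, omm))


def control_camp_model() -> CellModel:
    """Control cAMP model: adenylyl-cyclase input split between a
    bulk-accessible pool (read by the cytosolic reporter) and a sub-membrane
    pool feeding the weakly coupled plasmalemmal shell; PDE4 carries most of
    the regulated cytosolic hydrolysis, PDE2A provides a large low-affinity
    reservoir, and the OMM is a passive shell whose high-affinity PDE8
    complement sets its standing cAMP below the bulk level.
    """
    cyt = Compartment(
        name="CYT", volume_fraction=VOLUME_FRACTIONS["CYT"],
        pdes=(_pde("PDE4", 0.060), _pde("PDE8", 0.0008), _pde("PDE3", 0.0003),
              _pde("PDE2A", 0.244)),
        cyclases=(CyclaseSource("cAMP", j_basal=0.0447, max_stim_factor=4.0),),
    )
    pm = Compartment(
        name="PM", volume_fraction=VOLUME_FRACTIONS["PM"],
        pdes=(_pde("PDE4", 0.0408), _pde("PDE8", 0.0027), _pde("PDE2A", 0.0829)),
        cyclases=(CyclaseSource("cAMP", j_basal=0.030, max_stim_factor=4.0),),
        exchanges={"CYT": 0.002},
    )
    omm = Compartment(
        name="OMM", volume_fraction=VOLUME_FRACTIONS["OMM"],
        pdes=(_pde("PDE8", 0.0214), _pde("PDE4", 0.0027)),
        exchanges={"CYT": 0.0153},
    )
    return CellModel(genotype="control", nucleotide="cAMP", compartments=(cyt, pm, omm))


def inversion_benchmark_model() -> CellModel:
    """Single-compartment cytosolic template for estimator validation.

    All four cAMP-hydrolysing families carry comparable local capacity so
    that each family-selective inhibitor produces a measurable ΔR/R0 — the
    design assumption of the inhibitor-panel assay itself.
    """
    cyt = Compartment(
        name="CYT", volume_fraction=1.0,
        pdes=(_pde("PDE4", 0.05), _pde("PDE8", 0.012), _pde("PDE3", 0.008),
              _pde("PDE2A", 0.15)),
        cyclases=(CyclaseSource("cAMP", j_basal=0.02, max_stim_factor=4.0),),
    )
    return CellModel(genotype="control", nucleotide="cAMP", compartments=(cyt,))


# ---------------------------------------------------------------------------
# Genotype factor tables

@dataclass(frozen=True)
class GenotypeFactors:
    """Multiplicative (and a few absolute) transformations control → mdx."""

    pde_activity: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    exchange: Mapping[tuple, float] = field(default_factory=dict)  # (comp, partner) -> factor
    cyclase_scale: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    cyclase_override: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


#: mdx cGMP table: endogenous NO drive reduced to 40% in cytosol and PM (the
#: mitochondria-proximal NO source is spared), 1.3× total sGC with the excess
#: oxidised (cytosolic oxidised fraction 1 − 1/1.3 keeps the functional
#: reduced-branch pool unchanged; at the PM half the pool is oxidised vs 10%
#: in control), and an increased PM cGMP-PDE complement.
MDX_CGMP_FACTORS = GenotypeFactors(
    pde_activity={"PM": {"PDE5": 2.25, "PDE2A": 1.65, "PDE1": 1.8, "PDE9": 1.2, "PDE3": 1.2}},
    cyclase_scale={"CYT": {"j_basal": 1.3, "no_input": 0.4},
                   "PM": {"j_basal": 1.3, "no_input": 0.4}},
    cyclase_override={"CYT": {"oxidised_fraction": 1.0 - 1.0 / 1.3},
                      "PM": {"oxidised_fraction": 0.5}},
)

#: mdx cAMP table: markedly less PDE4 and PDE8 but more PDE3 in the cytosol,
#: PDE8 redistributed toward the OMM (3×), a mildly rebalanced PM complement
#: (PDE4 up, PDE8 down) and a weaker stimulation reserve of the
#: bulk-accessible AC pool.  The PM-local pool couples normally — together
#: with the shell's weak exchange this is what preserves the plasmalemmal
#: isoprenaline response while the bulk response is blunted.
MDX_CAMP_FACTORS = GenotypeFactors(
    pde_activity={"CYT": {"PDE4": 0.43, "PDE8": 0.5, "PDE3": 1.5},
                  "PM": {"PDE4": 1.05, "PDE8": 0.85},
                  "OMM": {"PDE8": 3.0}},
    cyclase_scale={"CYT": {"max_stim_factor": 0.6}},
)


def apply_genotype(model: CellModel, factors: GenotypeFactors,
                   genotype: str = "mdx") -> CellModel:
    """Transform a control model by a genotype factor table."""
    new_comps = []
    for comp in model.compartments:
        pde_f = factors.pde_activity.get(comp.name, {})
        pdes = tuple((iso, act * pde_f.get(iso.name, 1.0)) for iso, act in comp.pdes)
        scale = factors.cyclase_scale.get(comp.name, {})
        override = factors.cyclase_override.get(comp.name, {})
        cyclases = []
        for src in comp.cyclases:
            kwargs = {}
            for fld in ("j_basal", "no_input", "max_stim_factor"):
                if fld in scale:
                    kwargs[fld] = getattr(src, fld) * scale[fld]
            for fld, value in override.items():
                kwargs[fld] = value
            cyclases.append(replace(src, **kwargs) if kwargs else src)
        exchanges = {partner: k * factors.exchange.get((comp.name, partner), 1.0)
                     for partner, k in comp.exchanges.items()}
        new_comps.append(replace(comp, pdes=pdes, cyclases=tuple(cyclases),
                                 exchanges=exchanges))
    return replace(model, genotype=genotype, compartments=tuple(new_comps))


def build_model(nucleotide: str, genotype: str) -> CellModel:
    """Default model for a (nucleotide, genotype) pair."""
    if nucleotide == "cGMP":
        base, factors = control_cgmp_model(), MDX_CGMP_FACTORS
    elif nucleotide == "cAMP":
        base, factors = control_camp_model(), MDX_CAMP_FACTORS
    else:
        raise ConfigError(f"unknown nucleotide {nucleotide!r}")
    if genotype == "control":
        return base
    if genotype == "mdx":
        return apply_genotype(base, factors)
    raise ConfigError(f"unknown genotype {genotype!r}")


# ---------------------------------------------------------------------------
# Protocol and scenario library

SATURATION_LABEL = "saturation"

#: Family-selective inhibitors per nucleotide, in panel order.
CGMP_INHIBITORS = {"bay60": "Bay60_7550", "sildenafil": "sildenafil",
                   "cilostamide": "cilostamide", "pf9": "PF04449743"}
CAMP_INHIBITORS = {"bay60": "Bay60_7550", "cilostamide": "cilostamide",
                   "rolipram": "rolipram", "pf8": "PF04957325"}

STIM_TREATMENTS = {
    "snapbay41": treatment("SNAP", "Bay41_2272", label="SNAP+Bay41"),
    "cinaciguat": treatment("cinaciguat"),
    "iso": treatment("isoproterenol", label="ISO"),
    "forskolin": treatment("forskolin"),
}


def _saturation(nucleotide: str) -> Treatment:
    if nucleotide == "cGMP":
        return treatment("IBMX", label=SATURATION_LABEL)
    return treatment("IBMX", "forskolin", label=SATURATION_LABEL)


def single_addition_protocol(nucleotide: str, trt: Treatment, t_add: float = 300.0,
                             t_sat: float | None = None, duration: float | None = None) -> Protocol:
    """Baseline, one addition (inhibitor or stimulus), terminal saturation."""
    if t_sat is None:
        # cAMP responses settle more slowly (near-saturated PDE8 dynamics)
        t_sat = 800.0 if nucleotide == "cGMP" else 1000.0
    if duration is None:
        duration = t_sat + (500.0 if nucleotide == "cGMP" else 700.0)
    return Protocol(
        duration=duration,
        events=(ProtocolEvent(t_add, trt),
                ProtocolEvent(t_sat, _saturation(nucleotide), label=SATURATION_LABEL)),
        stim_label=trt.label, saturation_label=SATURATION_LABEL)


def chained_protocol(nucleotide: str, stim: Treatment, inhibitor: Treatment,
                     t_stim: float = 300.0, t_inh: float = 700.0,
                     t_sat: float = 1200.0, duration: float | None = None) -> Protocol:
    """Stimulus, then an inhibitor on the stimulated background, then saturation."""
    if duration is None:
        duration = t_sat + (500.0 if nucleotide == "cGMP" else 700.0)
    return Protocol(
        duration=duration,
        events=(ProtocolEvent(t_stim, stim),
                ProtocolEvent(t_inh, inhibitor),
                ProtocolEvent(t_sat, _saturation(nucleotide), label=SATURATION_LABEL)),
        stim_label=stim.label, saturation_label=SATURATION_LABEL)


@dataclass(frozen=True)
class Scenario:
    """One experiment type: which sensor compartment sees which protocol."""

    id: str
    nucleotide: str
    compartment: str
    protocol: Protocol


def _scenario_library() -> dict:
    lib = {}

    def add(sid, nuc, comp, protocol):
        lib[sid] = Scenario(sid, nuc, comp, protocol)

    for comp in ("CYT", "PM", "OMM"):
        tag = comp.lower()
        for key, drug in CGMP_INHIBITORS.items():
            add(f"cgmp_{tag}_{key}", "cGMP", comp,
                single_addition_protocol("cGMP", treatment(drug)))
            add(f"cgmp_{tag}_snapbay41_{key}", "cGMP", comp,
                chained_protocol("cGMP", STIM_TREATMENTS["snapbay41"], treatment(drug)))
        add(f"cgmp_{tag}_snapbay41", "cGMP", comp,
            single_addition_protocol("cGMP", STIM_TREATMENTS["snapbay41"]))
        for key, drug in CAMP_INHIBITORS.items():
            add(f"camp_{tag}_{key}", "cAMP", comp,
                single_addition_protocol("cAMP", treatment(drug)))
            add(f"camp_{tag}_iso_{key}", "cAMP", comp,
                chained_protocol("cAMP", STIM_TREATMENTS["iso"], treatment(drug)))
        add(f"camp_{tag}_iso", "cAMP", comp,
            single_addition_protocol("cAMP", STIM_TREATMENTS["iso"]))
    add("cgmp_pm_cinaciguat", "cGMP", "PM",
        single_addition_protocol("cGMP", STIM_TREATMENTS["cinaciguat"]))
    add("camp_cyt_forskolin", "cAMP", "CYT",
        single_addition_protocol("cAMP", STIM_TREATMENTS["forskolin"]))
    return lib


SCENARIO_LIBRARY: Mapping[str, Scenario] = _scenario_library()

#: Scenarios generated by the default cohort: the basal-state inhibitor
#: panels, the stimulus responses and the PM cinaciguat experiment — the set
#: the genotype-comparison report needs.
DEFAULT_COHORT_SCENARIOS = tuple(
    sid for sid in SCENARIO_LIBRARY
    if ("_iso_" not in sid and "_snapbay41_" not in sid)
)
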