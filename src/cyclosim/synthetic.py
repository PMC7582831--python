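"""Virtual cohorts: parameter sampling, trace synthesis, dataset layout.

Each virtual cell is the genotype's default model with every PDE activity
scalar, cyclase basal rate and exchange constant multiplied by independent
mean-one lognormal noise (``sigma`` on the log scale), standing in for
biological replicates.  A cell's two-channel fluorescence trace is produced
by simulating its treatment protocol, mapping the sensor compartment's
concentration through the Hill transfer function, splitting the ratio into
donor/acceptor channels of constant summed intensity, applying per-channel
exponential bleaching, Gaussian read noise and a background offset.

Randomness is counter-based: every cell derives its generator from
``(seed, scenario name, genotype, cell index)``, so cohorts are
reproducible and independent of generation order and cohort composition.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cells import DEFAULT_COHORT_SCENARIOS, SCENARIO_LIBRARY, GENOTYPES, Scenario, build_model
from .errors import ConfigError, InvalidInputError
from .kinetics import CellModel, Compartment, CyclaseSource, simulate_protocol
from .pharmacology import Protocol
from .sensors import DEFAULT_SENSORS, SensorSpec, ratio_from_concentration, sensor_for
from .traces import RawTrace, write_trace

MANIFEST_SCHEMA = "cyclosim-cohort-1"


@dataclass(frozen=True)
class CohortConfig:
    """Generation plan for one synthetic cohort."""

    n_cells: int = 8
    seed: int = 1
    cell_sigma: float = 0.2        # lognormal sigma on activities / rates
    noise_sigma: float = 0.01      # Gaussian channel noise, fraction of signal
    bleach_rate: float = 2e-4      # fractional intensity loss per frame
    bleach_differential: float = 0.0  # extra donor-channel bleach (exercises detrending)
    background_480: float = 100.0
    background_545: float = 100.0
    channel_total: float = 2000.0  # summed above-background intensity per frame
    scenarios: tuple = DEFAULT_COHORT_SCENARIOS
    genotypes: tuple = GENOTYPES

    def __post_init__(self):
        if self.n_cells < 2:
            raise ConfigError("n_cells must be >= 2")
        if min(self.cell_sigma, self.noise_sigma, self.bleach_rate) < 0:
            raise ConfigError("sigmas and bleach rate must be >= 0")
        unknown = [s for s in self.scenarios if s not in SCENARIO_LIBRARY]
        if unknown:
            raise ConfigError(f"unknown scenarios: {unknown}")
        if any(g not in GENOTYPES for g in self.genotypes):
            raise ConfigError(f"genotypes must be among {GENOTYPES}")


def _cell_rng(config: CohortConfig, scenario_id: str, genotype: str, cell_idx: int):
    # streams keyed by (seed, scenario name, genotype, cell): reproducible and
    # independent of which other scenarios a cohort happens to contain
    sid_key = zlib.crc32(scenario_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(
        [config.seed, sid_key, GENOTYPES.index(genotype), cell_idx])


def sample_cell_params(genotype: str, base: CellModel, config: CohortConfig,
                       rng: np.random.Generator) -> CellModel:
    """One virtual cell: mean-one lognormal noise on the base model.

    With ``cell_sigma = 0`` the genotype-scaled base model is returned
    unchanged.  Deterministic given the generator state.
    """
    if genotype not in GENOTYPES:
        raise ConfigError(f"unknown genotype {genotype!r}")
    sigma = config.cell_sigma
    if sigma == 0:
        return base

    def jitter():
        # mean-one lognormal so cohort averages stay on the base model
        return rng.lognormal(-sigma ** 2 / 2.0, sigma)

    comps = []
    for comp in base.compartments:
        pdes = tuple((iso, act * jitter()) for iso, act in comp.pdes)
        cyclases = tuple(replace(src, j_basal=src.j_basal * jitter())
                         for src in comp.cyclases)
        exchanges = {partner: k * jitter() for partner, k in comp.exchanges.items()}
        comps.append(replace(comp, pdes=pdes, cyclases=cyclases, exchanges=exchanges))
    return replace(base, compartments=tuple(comps))


def generate_trace(cell: CellModel, sensor: SensorSpec, protocol: Protocol,
                   config: CohortConfig, rng: np.random.Generator,
                   meta: Mapping[str, object] | None = None) -> RawTrace:
    """Simulate one protocol on one cell and synthesise its raw trace."""
    if sensor.compartment not in cell.compartment_names:
        raise InvalidInputError(
            f"sensor compartment {sensor.compartment} absent from the cell model")
    t_grid, conc = simulate_protocol(cell, protocol)
    local = conc[:, cell.index(sensor.compartment)]
    ratio = np.asarray(ratio_from_concentration(sensor, local), float)

    n = len(t_grid)
    frames = np.arange(n)
    total = config.channel_total
    donor = total * ratio / (1.0 + ratio)
    acceptor = total / (1.0 + ratio)
    donor = donor * (1.0 - config.bleach_rate - config.bleach_differential) ** frames
    acceptor = acceptor * (1.0 - config.bleach_rate) ** frames
    if config.noise_sigma > 0:
        donor = donor + rng.normal(0.0, config.noise_sigma * donor)
        acceptor = acceptor + rng.normal(0.0, config.noise_sigma * acceptor)
    donor = donor + config.background_480
    acceptor = acceptor + config.background_545

    events = {e.label: protocol.frame_of(e.label) for e in protocol.events}
    meta = dict(meta or {})
    meta.setdefault("genotype", cell.genotype)
    meta.setdefault("nucleotide", cell.nucleotide)
    meta.setdefault("compartment", sensor.compartment)
    meta.setdefault("sensor", sensor.name)
    meta.setdefault("stim_label", protocol.stim_label)
    meta.setdefault("saturation_label", protocol.saturation_label)
    return RawTrace(time_s=t_grid, donor_480=donor, acceptor_545=acceptor,
                    background_480=config.background_480,
                    background_545=config.background_545,
                    events=events, meta=meta)


def generate_cohort(config: CohortConfig, out_dir: str | Path,
                    overwrite: bool = False,
                    registry: Mapping[str, SensorSpec] = DEFAULT_SENSORS) -> Path:
    """Write one trace CSV + JSON sidecar per cell, plus a manifest.

    Refuses to write into an existing non-empty directory unless
    ``overwrite`` is set.  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not overwrite:
        raise ConfigError(f"{out_dir} exists and is not empty (pass overwrite=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    entries = []
    for sid in config.scenarios:
        scenario: Scenario = SCENARIO_LIBRARY[sid]
        sensor = sensor_for(scenario.nucleotide, scenario.compartment, registry)
        for genotype in config.genotypes:
            base = build_model(scenario.nucleotide, genotype)
            for cell_idx in range(config.n_cells):
                rng = _cell_rng(config, sid, genotype, cell_idx)
                cell = sample_cell_params(genotype, base, config, rng)
                cell_id = f"{sid}__{genotype}__c{cell_idx:03d}"
                trace = generate_trace(cell, sensor, scenario.protocol, config, rng,
                                       meta={"cell_id": cell_id, "scenario": sid})
                path = out_dir / f"{cell_id}.csv"
                write_trace(trace, path)
                entries.append({"file": path.name, "scenario": sid,
                                "nucleotide": scenario.nucleotide,
                                "compartment": scenario.compartment,
                                "genotype": genotype, "cell_id": cell_id})
    manifest = {
        "schema": MANIFEST_SCHEMA,
        "seed": config.seed,
        "n_cells": config.n_cells,
        "cell_sigma": config.cell_sigma,
        "noise_sigma": config.noise_sigma,
        "scenarios": list(config.scenarios),
        "genotypes": list(config.genotypes),
        "traces": entries,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest_path


def read_manifest(dataset_dir: str | Path) -> dict:
    path = Path(dataset_dir) / "manifest.json"
    if not path.exists():
        from .errors import MissingDataError
        raise MissingDataError(f"no manifest.json under {dataset_dir}")
    manifest = json.loads(path.read_text())
    if manifest.get("schema") != MANIFEST_SCHEMA:
        raise ConfigError(f"unknown manifest schema {manifest.get('schema')!r}")
    return manifest
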