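"""Structured-text (YAML/JSON) configuration for models, protocols, sensors.

Every document carries a versioned ``schema`` id and round-trips exactly:
``load(save(x)) == x``.  Simulated time courses are written as tidy CSV with
columns ``t_s, compartment, conc_uM, genotype, scenario_id``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .kinetics import CellModel, Compartment, CyclaseSource, PDEIsoform
from .pharmacology import Protocol, ProtocolEvent, Treatment
from .sensors import SensorSpec

MODEL_SCHEMA = "cyclosim-model-1"
PROTOCOL_SCHEMA = "cyclosim-protocol-1"
SENSOR_SCHEMA = "cyclosim-sensors-1"


def model_to_dict(model: CellModel) -> dict:
    return {
        "schema": MODEL_SCHEMA,
        "genotype": model.genotype,
        "nucleotide": model.nucleotide,
        "initial_uM": dict(model.initial_uM),
        "compartments": [
            {
                "name": c.name,
                "volume_fraction": c.volume_fraction,
                "pdes": [
                    {"name": iso.name, "substrate": iso.substrate,
                     "km_uM": dict(iso.km_uM), "vmax_specific": iso.vmax_specific,
                     "density_factor": iso.density_factor, "activity": act}
                    for iso, act in c.pdes],
                "cyclases": [
                    {"nucleotide": s.nucleotide, "j_basal": s.j_basal,
                     "max_stim_factor": s.max_stim_factor, "stim_factor": s.stim_factor,
                     "oxidised_fraction": s.oxidised_fraction, "no_input": s.no_input}
                    for s in c.cyclases],
                "exchanges": dict(c.exchanges),
            }
            for c in model.compartments],
    }


def model_from_dict(doc: Mapping) -> CellModel:
    if doc.get("schema") != MODEL_SCHEMA:
        raise ConfigError(f"expected schema {MODEL_SCHEMA}, got {doc.get('schema')!r}")
    comps = []
    for c in doc["compartments"]:
        pdes = tuple(
            (PDEIsoform(name=p["name"], substrate=p["substrate"], km_uM=dict(p["km_uM"]),
                        vmax_specific=p["vmax_specific"],
                        density_factor=p.get("density_factor", 1.0)),
             p.get("activity", 1.0))
            for p in c.get("pdes", []))
        cyclases = tuple(CyclaseSource(**s) for s in c.get("cyclases", []))
        comps.append(Compartment(name=c["name"], volume_fraction=c["volume_fraction"],
                                 pdes=pdes, cyclases=cyclases,
                                 exchanges=dict(c.get("exchanges", {}))))
    return CellModel(genotype=doc["genotype"], nucleotide=doc["nucleotide"],
                     compartments=tuple(comps),
                     initial_uM=dict(doc.get("initial_uM", {})))


def protocol_to_dict(protocol: Protocol) -> dict:
    return {
        "schema": PROTOCOL_SCHEMA,
        "duration": protocol.duration,
        "frame_interval": protocol.frame_interval,
        "stim_label": protocol.stim_label,
        "saturation_label": protocol.saturation_label,
        "events": [{"t_s": e.time_s, "drugs": list(e.treatment.drugs),
                    "label": e.label} for e in protocol.events],
    }


def protocol_from_dict(doc: Mapping) -> Protocol:
    if doc.get("schema") != PROTOCOL_SCHEMA:
        raise ConfigError(f"expected schema {PROTOCOL_SCHEMA}, got {doc.get('schema')!r}")
    events = tuple(
        ProtocolEvent(e["t_s"], Treatment(tuple(e["drugs"]),
                                          label=e.get("label")), label=e.get("label"))
        for e in doc.get("events", []))
    return Protocol(duration=doc["duration"], events=events,
                    frame_interval=doc.get("frame_interval", 10.0),
                    stim_label=doc.get("stim_label"),
                    saturation_label=doc.get("saturation_label"))


def sensors_to_dict(registry: Mapping[str, SensorSpec]) -> dict:
    return {"schema": SENSOR_SCHEMA,
            "sensors": {name: {"nucleotide": s.nucleotide, "compartment": s.compartment,
                               "ec50_uM": s.ec50_uM, "hill_n": s.hill_n,
                               "r_min": s.r_min, "r_max": s.r_max}
                        for name, s in registry.items()}}


def sensors_from_dict(doc: Mapping) -> dict:
    if doc.get("schema") != SENSOR_SCHEMA:
        raise ConfigError(f"expected schema {SENSOR_SCHEMA}, got {doc.get('schema')!r}")
    return {name: SensorSpec(name=name, **spec)
            for name, spec in doc.get("sensors", {}).items()}


def save_yaml(doc: Mapping, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dict(doc), sort_keys=True))


def load_yaml(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return doc


def write_timecourse_csv(path: str | Path, t_s, conc, model: CellModel,
                         scenario_id: str) -> None:
    """Tidy CSV of a simulated time course, one row per (frame, compartment)."""
    t_s = np.asarray(t_s, float)
    conc = np.asarray(conc, float)
    frames = []
    for i, name in enumerate(model.compartment_names):
        frames.append(pd.DataFrame({
            "t_s": t_s, "compartment": name, "conc_uM": conc[:, i],
            "genotype": model.genotype, "scenario_id": scenario_id}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")
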