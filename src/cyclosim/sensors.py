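"""FRET biosensor model: concentration → CFP/YFP emission ratio.

Each sensor variant (cytosolic, plasmalemma- or OMM-targeted cGi500 for
cGMP; EPAC-S H187 for cAMP) is described by a Hill transfer function

.. math:: R(c) = r_{min} + (r_{max} - r_{min}) \\frac{c^n}{c^n + EC_{50}^n}

mapping the local nucleotide concentration (μM) to the background-subtracted
480/545 nm emission ratio.  Targeted variants carry a reduced dynamic range,
reflecting the common observation that fusing a targeting sequence compresses
a reporter's span.  EC50, Hill coefficient and dynamic-range defaults are
literature-typical placeholders exposed in the registry, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import CalibrationError, InvalidInputError, OutOfRangeError

SENSOR_NAMES = ("cGi500", "PM-cGi500", "OMM-cGi500", "H187", "PM-H187", "OMM-H187")


@dataclass(frozen=True)
class SensorSpec:
    """Hill-type transfer function of one FRET reporter variant."""

    name: str
    nucleotide: str
    compartment: str
    ec50_uM: float
    hill_n: float = 1.0
    r_min: float = 1.0
    r_max: float = 1.5

    def __post_init__(self):
        if self.ec50_uM <= 0:
            raise InvalidInputError(f"{self.name}: EC50 must be > 0")
        if self.hill_n <= 0:
            raise InvalidInputError(f"{self.name}: Hill coefficient must be > 0")
        if not 0 < self.r_min < self.r_max:
            raise InvalidInputError(f"{self.name}: need 0 < r_min < r_max")


def _targeted(base: str) -> float:
    """Dynamic-range span ratio r_max/r_min: 1.5 cytosolic, 1.3 targeted."""
    return 1.3 if base.startswith(("PM-", "OMM-")) else 1.5


def _default(name: str, nucleotide: str, compartment: str, ec50: float) -> SensorSpec:
    return SensorSpec(name=name, nucleotide=nucleotide, compartment=compartment,
                      ec50_uM=ec50, hill_n=1.0, r_min=1.0, r_max=_targeted(name))


#: Default registry: cGi500 family EC50 0.5 μM, H187 family EC50 4 μM.
DEFAULT_SENSORS: Mapping[str, SensorSpec] = {
    "cGi500": _default("cGi500", "cGMP", "CYT", 0.5),
    "PM-cGi500": _default("PM-cGi500", "cGMP", "PM", 0.5),
    "OMM-cGi500": _default("OMM-cGi500", "cGMP", "OMM", 0.5),
    "H187": _default("H187", "cAMP", "CYT", 4.0),
    "PM-H187": _default("PM-H187", "cAMP", "PM", 4.0),
    "OMM-H187": _default("OMM-H187", "cAMP", "OMM", 4.0),
}


def sensor_for(nucleotide: str, compartment: str,
               registry: Mapping[str, SensorSpec] = DEFAULT_SENSORS) -> SensorSpec:
    """The registry sensor reporting ``nucleotide`` in ``compartment``."""
    for spec in registry.values():
        if spec.nucleotide == nucleotide and spec.compartment == compartment:
            return spec
    raise InvalidInputError(f"no sensor for {nucleotide} in {compartment}")


def ratio_from_concentration(sensor: SensorSpec, conc_uM):
    """480/545 emission ratio at the given concentration(s).

    Strictly increasing in concentration and bounded in ``[r_min, r_max)``.
    """
    conc = np.asarray(conc_uM, float)
    if np.any(conc < 0):
        raise InvalidInputError("concentration must be >= 0")
    cn = conc ** sensor.hill_n
    out = sensor.r_min + (sensor.r_max - sensor.r_min) * cn / (cn + sensor.ec50_uM ** sensor.hill_n)
    return out if out.ndim else float(out)


def concentration_from_ratio(sensor: SensorSpec, ratio):
    """Exact inverse of :func:`ratio_from_concentration`.

    Raises :class:`OutOfRangeError` for readings at or beyond the sensor's
    open range ``(r_min, r_max)`` — a saturated or sub-basal measurement
    carries no concentration information.
    """
    r = np.asarray(ratio, float)
    if np.any(r <= sensor.r_min) or np.any(r >= sensor.r_max):
        raise OutOfRangeError(
            f"ratio outside ({sensor.r_min}, {sensor.r_max}): saturated or sub-basal reading")
    frac = (r - sensor.r_min) / (sensor.r_max - r)
    out = sensor.ec50_uM * frac ** (1.0 / sensor.hill_n)
    return out if out.ndim else float(out)


def calibrate_dynamic_range(zero_trace, saturating_trace, plateau_len: int = 6,
                            slope_tol: float = 1e-3) -> tuple[float, float]:
    """Recover ``(r_min, r_max)`` from zero / saturating calibration traces.

    Mirrors the whole-cell calibration in which the reporter equilibrates
    with either 0 or 1 mM cyclic nucleotide: each trace must reach a plateau,
    and the plateau means give the two ends of the dynamic range.
    """
    from .traces import find_plateau  # shared plateau rule

    r_min = float(np.mean(find_plateau(np.asarray(zero_trace.ratio, float),
                                       0, len(zero_trace.ratio), plateau_len, slope_tol)))
    r_max = float(np.mean(find_plateau(np.asarray(saturating_trace.ratio, float),
                                       0, len(saturating_trace.ratio), plateau_len, slope_tol)))
    if r_max <= r_min:
        raise CalibrationError(f"r_max {r_max:g} <= r_min {r_min:g}")
    return r_min, r_max
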