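"""FRET trace quantification: ratio, R/R0 normalisation and plateau deltas.

The measured quantity is the background-subtracted 480/545 nm emission ratio
R.  Responses are expressed as R/R0, with R0 the average ratio over the 8
frames preceding the stimulus addition, and each response is summarised as
ΔR/R0: the mean of the latest flat (plateau) window after the event minus the
pre-event reference level.  Frame indexing is 0-based and the event frame is
the first frame acquired after the addition.

A window of ``plateau_len`` consecutive frames counts as a plateau when the
magnitude of its fitted slope is below ``max(slope_tol, 2·SE(slope))``; the
standard-error term keeps the rule meaningful on noisy traces (a noiseless
ramp is still rejected by the strict ``slope_tol``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    CorruptFrameError,
    InsufficientBaselineError,
    InvalidInputError,
    MissingEventError,
    NoPlateauError,
)

BASELINE_FRAMES = 8  # R0 window: the 8 frames preceding the stimulus

TRACE_SCHEMA = "cyclosim-trace-1"


@dataclass(frozen=True)
class RawTrace:
    """Two-channel fluorescence time series with background and events."""

    time_s: np.ndarray
    donor_480: np.ndarray
    acceptor_545: np.ndarray
    background_480: float = 0.0
    background_545: float = 0.0
    events: Mapping[str, int] = field(default_factory=dict)  # label -> frame index
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.time_s, float)
        d = np.asarray(self.donor_480, float)
        a = np.asarray(self.acceptor_545, float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "donor_480", d)
        object.__setattr__(self, "acceptor_545", a)
        if not (len(t) == len(d) == len(a)):
            raise InvalidInputError("channels and time axis must have equal length")
        if len(t) < BASELINE_FRAMES + 1:
            raise InvalidInputError(f"a trace needs at least {BASELINE_FRAMES + 1} frames")
        for label, frame in self.events.items():
            if not 0 <= frame < len(t):
                raise InvalidInputError(f"event {label!r} frame {frame} out of range")
        if np.mean(d) <= self.background_480 or np.mean(a) <= self.background_545:
            raise InvalidInputError("mean intensity must exceed the background")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)


@dataclass(frozen=True)
class RatioSeries:
    """Ratio trace, optionally normalised to its pre-stimulus baseline."""

    time_s: np.ndarray
    ratio: np.ndarray
    events: Mapping[str, int] = field(default_factory=dict)
    r0: float | None = None
    normalized: np.ndarray | None = None
    stim_frame: int | None = None
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "time_s", np.asarray(self.time_s, float))
        object.__setattr__(self, "ratio", np.asarray(self.ratio, float))
        if self.normalized is not None:
            object.__setattr__(self, "normalized", np.asarray(self.normalized, float))
        if self.r0 is not None and self.r0 <= 0:
            raise InvalidInputError("R0 must be > 0")


def background_subtract_and_ratio(trace: RawTrace) -> RatioSeries:
    """R_t = (donor − background) / (acceptor − background), per frame."""
    donor = trace.donor_480 - trace.background_480
    acceptor = trace.acceptor_545 - trace.background_545
    bad = np.flatnonzero((donor <= 0) | (acceptor <= 0))
    if bad.size:
        raise CorruptFrameError(int(bad[0]))
    return RatioSeries(time_s=trace.time_s, ratio=donor / acceptor,
                       events=dict(trace.events), meta=dict(trace.meta))


def normalize_to_baseline(series: RatioSeries, stim_frame: int) -> RatioSeries:
    """Normalise to R0, the mean ratio over the 8 frames before the stimulus."""
    if stim_frame < BASELINE_FRAMES:
        raise InsufficientBaselineError(
            f"stimulus at frame {stim_frame}: need >= {BASELINE_FRAMES} baseline frames")
    r0 = float(np.mean(series.ratio[stim_frame - BASELINE_FRAMES:stim_frame]))
    if r0 <= 0:
        raise InvalidInputError("baseline mean must be positive")
    return replace(series, r0=r0, normalized=series.ratio / r0, stim_frame=stim_frame)


def detrend_baseline(series: RatioSeries, mode: str = "linear",
                     stim_frame: int | None = None) -> RatioSeries:
    """Divide out a straight-line drift fitted to the baseline window.

    The correction is scale-preserving: frame *t* is multiplied by
    ``line(baseline mean) / line(t)``, so a drift-free series is returned
    unchanged.  ``mode="none"`` is the identity.
    """
    if mode == "none":
        return series
    if mode != "linear":
        raise InvalidInputError(f"unknown detrend mode {mode!r}")
    stim = stim_frame if stim_frame is not None else series.stim_frame
    if stim is None or stim < BASELINE_FRAMES:
        raise InsufficientBaselineError("detrending needs >= 8 baseline frames")
    idx = np.arange(len(series.ratio), dtype=float)
    win = slice(stim - BASELINE_FRAMES, stim)
    slope, intercept = np.polyfit(idx[win], series.ratio[win], 1)
    line = intercept + slope * idx
    ref = float(np.mean(line[win]))
    corrected = series.ratio * (ref / line)
    out = replace(series, ratio=corrected)
    if series.r0 is not None:
        out = normalize_to_baseline(out, stim)
    return out


def _window_slope(values: np.ndarray) -> tuple[float, float]:
    """Fitted slope per frame and its standard error."""
    n = len(values)
    x = np.arange(n, dtype=float)
    x -= x.mean()
    sxx = float(np.dot(x, x))
    slope = float(np.dot(x, values - values.mean()) / sxx)
    resid = values - values.mean() - slope * x
    dof = max(n - 2, 1)
    se = float(np.sqrt(np.dot(resid, resid) / dof / sxx))
    return slope, se


def find_plateau(values: np.ndarray, start: int, stop: int, plateau_len: int = 6,
                 slope_tol: float = 1e-3) -> np.ndarray:
    """Latest run of ``plateau_len`` frames in ``[start, stop)`` that is flat.

    Flatness: ``|slope| <= max(slope_tol, 2 SE(slope))`` per frame.  Returns
    the window's values; raises :class:`NoPlateauError` if no window passes.
    """
    values = np.asarray(values, float)
    stop = min(stop, len(values))
    if stop - start < plateau_len:
        raise NoPlateauError(f"fewer than {plateau_len} frames available after the event")
    for i in range(stop - plateau_len, start - 1, -1):
        window = values[i:i + plateau_len]
        slope, se = _window_slope(window)
        if abs(slope) <= max(slope_tol, 2.0 * se):
            return window
    raise NoPlateauError("no flat window found")


def _event_bounds(series: RatioSeries, label: str) -> tuple[int, int]:
    if label not in series.events:
        raise MissingEventError(f"no event labelled {label!r}")
    start = series.events[label]
    later = [f for f in series.events.values() if f > start]
    stop = min(later) if later else len(series.ratio)
    return start, stop


def plateau_level(series: RatioSeries, label: str, plateau_len: int = 6,
                  slope_tol: float = 1e-3) -> float:
    """Plateau mean of R/R0 after the labelled event."""
    if series.normalized is None:
        raise InvalidInputError("series must be normalised first")
    start, stop = _event_bounds(series, label)
    return float(np.mean(find_plateau(series.normalized, start, stop, plateau_len, slope_tol)))


def _reference_level(series: RatioSeries, label: str, plateau_len: int,
                     slope_tol: float) -> float:
    """1.0 for the stimulus event, previous plateau for chained events."""
    frame = series.events[label]
    earlier = [(f, lab) for lab, f in series.events.items() if f < frame]
    if not earlier or frame == series.stim_frame:
        return 1.0
    _, prev = max(earlier)
    return plateau_level(series, prev, plateau_len, slope_tol)


def extract_plateau_delta(series: RatioSeries, event_label: str, plateau_len: int = 6,
                          slope_tol: float = 1e-3) -> float:
    """ΔR/R0 of one event: plateau mean minus the pre-event reference level."""
    level = plateau_level(series, event_label, plateau_len, slope_tol)
    return level - _reference_level(series, event_label, plateau_len, slope_tol)


def saturation_headroom(series: RatioSeries, saturation_label: str, plateau_len: int = 6,
                        slope_tol: float = 1e-3) -> float:
    """Rise of R/R0 caused by the terminal saturating addition.

    Positive headroom means the preceding responses had not saturated the
    reporter; a cell passes the non-saturation control when headroom > 0.
    """
    if saturation_label not in series.events:
        raise MissingEventError(f"no saturation event labelled {saturation_label!r}")
    post = plateau_level(series, saturation_label, plateau_len, slope_tol)
    pre = _reference_level(series, saturation_label, plateau_len, slope_tol)
    return post - pre


# ---------------------------------------------------------------------------
# Trace file format: one CSV per cell plus a JSON sidecar.

def write_trace(trace: RawTrace, csv_path: str | Path) -> None:
    """Write ``t_s, donor_480, acceptor_545`` CSV and its JSON sidecar."""
    csv_path = Path(csv_path)
    frame = pd.DataFrame({"t_s": trace.time_s, "donor_480": trace.donor_480,
                          "acceptor_545": trace.acceptor_545})
    frame.to_csv(csv_path, index=False, float_format="%.6f")
    sidecar = {
        "schema": TRACE_SCHEMA,
        "background_480": trace.background_480,
        "background_545": trace.background_545,
        "events": {k: int(v) for k, v in trace.events.items()},
        "meta": dict(trace.meta),
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def read_trace(csv_path: str | Path) -> RawTrace:
    csv_path = Path(csv_path)
    frame = pd.read_csv(csv_path)
    missing = {"t_s", "donor_480", "acceptor_545"} - set(frame.columns)
    if missing:
        raise InvalidInputError(f"{csv_path}: missing columns {sorted(missing)}")
    sidecar = json.loads(csv_path.with_suffix(".json").read_text())
    if sidecar.get("schema") != TRACE_SCHEMA:
        raise InvalidInputError(f"{csv_path}: unknown sidecar schema {sidecar.get('schema')!r}")
    return RawTrace(time_s=frame["t_s"].to_numpy(), donor_480=frame["donor_480"].to_numpy(),
                    acceptor_545=frame["acceptor_545"].to_numpy(),
                    background_480=float(sidecar["background_480"]),
                    background_545=float(sidecar["background_545"]),
                    events={k: int(v) for k, v in sidecar["events"].items()},
                    meta=sidecar.get("meta", {}))
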