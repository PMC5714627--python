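"""Reading and writing respiratory surrogate trace files.

Two text dialects are supported, mirroring the exports of the two external
surrogate systems commonly paired with 4D CT:

* an RPM-style VXP dialect -- infrared marker-block tracking at a nominal
  30 Hz, exported with amplitude (mm), phase, millisecond timestamps, a
  validity flag, the beam-active (X-RAY ON / TTL-in) indicator and a mark
  column;
* a bellows-style CSV export -- pneumatic-belt pressure in arbitrary units
  at roughly 38 Hz, with time in seconds and the X-RAY ON flag.

Both are mapped onto a single in-memory representation, :class:`SurrogateTrace`,
with times in seconds so downstream analysis never has to care which system
produced the samples.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "SurrogateLabel",
    "TraceDialect",
    "SurrogateTrace",
    "TraceFormatError",
    "TraceParseError",
    "EmptyTraceError",
    "TraceOrderingError",
    "read_rpm_vxp",
    "read_bellows_export",
    "write_trace",
]


class SurrogateLabel(str, enum.Enum):
    """Which physical system a trace came from."""

    RPM = "rpm"
    BELLOWS = "bellows"
    OTHER = "other"


class TraceDialect(str, enum.Enum):
    """On-disk trace file dialects."""

    RPM_VXP = "rpm_vxp"
    BELLOWS_CSV = "bellows_csv"


class TraceFormatError(ValueError):
    """File structure (header/layout) is not the expected dialect."""


class TraceParseError(ValueError):
    """A data line could not be parsed; message carries the line number."""


class EmptyTraceError(ValueError):
    """File contained no data lines."""


class TraceOrderingError(ValueError):
    """Timestamps are not strictly increasing."""


# Nominal sampling rate of the marker-block system; the bellows rate is
# estimated from the timestamps when absent from the header.
RPM_NOMINAL_RATE_HZ = 30.0


@dataclass
class SurrogateTrace:
    """One respiratory surrogate channel.

    Attributes
    ----------
    label
        Source system (rpm / bellows / other).
    times
        Sample times in seconds, strictly increasing.
    amplitudes
        Signal amplitude (mm for rpm-like, arbitrary pressure units for
        bellows-like traces).
    beam_on
        Per-sample X-RAY ON flag: true while the scanner is acquiring.
    phase
        Optional per-sample phase carried over from the file.  It is
        advisory only -- phase sorting in this package always derives its
        own end-inhale tags -- but is preserved for round-tripping.
    nominal_rate
        Sampling rate in Hz.
    """

    label: SurrogateLabel
    times: np.ndarray
    amplitudes: np.ndarray
    beam_on: np.ndarray
    nominal_rate: float
    phase: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label = SurrogateLabel(self.label)
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.beam_on = np.asarray(self.beam_on, dtype=bool)
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.times)
        if n < 1:
            raise EmptyTraceError("trace must contain at least one sample")
        arrays = [self.amplitudes, self.beam_on]
        if self.phase is not None:
            arrays.append(self.phase)
        if any(len(a) != n for a in arrays):
            raise ValueError("times, amplitudes, beam_on (and phase) must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise TraceOrderingError("times must be strictly increasing")
        if not self.nominal_rate > 0:
            raise ValueError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Span of the time axis in seconds."""
        return float(self.times[-1] - self.times[0])

    def copy_with(self, **changes) -> "SurrogateTrace":
        """Return a copy with the given fields replaced (arrays are copied)."""
        base = dict(
            label=self.label,
            times=self.times.copy(),
            amplitudes=self.amplitudes.copy(),
            beam_on=self.beam_on.copy(),
            nominal_rate=self.nominal_rate,
            phase=None if self.phase is None else self.phase.copy(),
            meta=dict(self.meta),
        )
        base.update(changes)
        return SurrogateTrace(**base)


def _parse_float(token: str, lineno: int, path: Union[str, Path]) -> float:
    try:
        return float(token)
    except ValueError:
        raise TraceParseError(
            f"{path}: line {lineno}: non-numeric field {token!r}"
        ) from None


def read_rpm_vxp(path: Union[str, Path]) -> SurrogateTrace:
    """Read an RPM-style VXP text file.

    The dialect is minimal: ``key=value`` header lines up to a literal
    ``[Data]`` line, then one CSV record per sample with the columns
    ``amplitude,phase,timestamp_ms,valid,ttlin,mark``.  Unknown header keys
    are preserved in ``meta`` but otherwise ignored.  Timestamps are integer
    (or decimal) milliseconds and are converted to seconds.
    """
    path = Path(path)
    header: dict = {}
    amplitudes, phases, times, beam_on = [], [], [], []
    in_data = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if not in_data:
                if line == "[Data]":
                    in_data = True
                    continue
                if "=" not in line:
                    raise TraceFormatError(
                        f"{path}: line {lineno}: expected 'key=value' header or '[Data]', got {line!r}"
                    )
                key, _, value = line.partition("=")
                header[key.strip()] = value.strip()
                continue
            fields = line.split(",")
            if len(fields) != 6:
                raise TraceParseError(
                    f"{path}: line {lineno}: expected 6 comma-separated fields, got {len(fields)}"
                )
            amp, ph, t_ms, _valid, ttlin, _mark = (
                _parse_float(f, lineno, path) for f in fields
            )
            amplitudes.append(amp)
            phases.append(ph)
            times.append(t_ms / 1000.0)
            beam_on.append(ttlin != 0)
    if not in_data:
        raise TraceFormatError(f"{path}: no '[Data]' section found")
    if not times:
        raise EmptyTraceError(f"{path}: no data lines")
    rate = float(header.get("Samples_per_second", RPM_NOMINAL_RATE_HZ))
    return SurrogateTrace(
        label=SurrogateLabel.RPM,
        times=np.array(times),
        amplitudes=np.array(amplitudes),
        beam_on=np.array(beam_on),
        phase=np.array(phases),
        nominal_rate=rate,
        meta=header,
    )


def read_bellows_export(path: Union[str, Path]) -> SurrogateTrace:
    """Read a bellows-style CSV export.

    Expected layout: a header line ``time_s,displacement,xray_on`` followed
    by one row per sample.  The sampling rate is estimated from the time
    axis as ``(n - 1) / (t_last - t_first)``.
    """
    path = Path(path)
    times, amplitudes, beam_on = [], [], []
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().strip()
        if first.replace(" ", "") != "time_s,displacement,xray_on":
            raise TraceFormatError(
                f"{path}: line 1: expected header 'time_s,displacement,xray_on', got {first!r}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            fields = line.split(",")
            if len(fields) != 3:
                raise TraceParseError(
                    f"{path}: line {lineno}: expected 3 comma-separated fields, got {len(fields)}"
                )
            t, amp, xr = (_parse_float(f, lineno, path) for f in fields)
            times.append(t)
            amplitudes.append(amp)
            beam_on.append(xr != 0)
    if not times:
        raise EmptyTraceError(f"{path}: no data lines")
    times_arr = np.array(times)
    if len(times_arr) > 1:
        if not np.all(np.diff(times_arr) > 0):
            bad = int(np.argmin(np.diff(times_arr) > 0)) + 2
            raise TraceOrderingError(f"{path}: non-increasing timestamp near line {bad + 1}")
        rate = (len(times_arr) - 1) / (times_arr[-1] - times_arr[0])
    else:
        rate = 38.0
    return SurrogateTrace(
        label=SurrogateLabel.BELLOWS,
        times=times_arr,
        amplitudes=np.array(amplitudes),
        beam_on=np.array(beam_on),
        nominal_rate=float(rate),
    )


def write_trace(
    trace: SurrogateTrace, path: Union[str, Path], dialect: Union[TraceDialect, str]
) -> None:
    """Write *trace* to *path* in the requested dialect.

    The written file is re-readable by the matching reader; numeric values
    are formatted with enough digits (``%.9g``) that the round trip is
    lossless well beyond the stated 1e-6 tolerance.
    """
    dialect = TraceDialect(dialect)
    path = Path(path)
    trace.validate()
    if dialect is TraceDialect.RPM_VXP:
        phase = trace.phase if trace.phase is not None else np.zeros(len(trace))
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"Samples_per_second={trace.nominal_rate:.9g}\n")
            fh.write("[Data]\n")
            for a, p, t, b in zip(trace.amplitudes, phase, trace.times, trace.beam_on):
                fh.write(f"{a:.9g},{p:.9g},{t * 1000.0:.9g},1,{int(b)},0\n")
    elif dialect is TraceDialect.BELLOWS_CSV:
        with path.open("w", encoding="utf-8") as fh:
            fh.write("time_s,displacement,xray_on\n")
            for t, a, b in zip(trace.times, trace.amplitudes, trace.beam_on):
                fh.write(f"{t:.9g},{a:.9g},{int(b)}\n")
    else:  # pragma: no cover - TraceDialect() above already rejects unknowns
        raise ValueError(f"unknown dialect {dialect!r}")
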