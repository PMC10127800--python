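"""File formats: recording/trace CSV dialects and YAML configuration.

Recording CSV (version 1)::

    # dakinetics-recording v1
    # key=value          (one line per metadata entry)
    time_s,da_um
    0,0
    0.1,0.0123456789

Trace CSV::

    time_s,da_s_um,da_e_um,gamma_um

Floats are written with 12 significant digits so a write→read round trip
preserves values well below the 1 nM level.  Metadata lines are optional
on read (a missing header is logged, not fatal); structural problems —
malformed header, non-monotone time, NaN — are parse errors naming the
offending row.

Configuration files are flat YAML with a ``protocol`` block
(``n_pulses``, ``frequency_hz``, ``current_ma``, ``onset_s``) and a
``parameters`` block (the ten kinetic fields plus a ``free`` list).
Unknown keys are rejected: units are fixed package-wide (s, μM, mA, Hz)
and nothing is converted silently.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from .model import (
    FSCVRecording,
    ConcentrationTrace,
    KineticParameters,
    StimulusProtocol,
    ValidationError,
)

__all__ = [
    "ParseError",
    "read_recording",
    "write_recording",
    "write_trace",
    "read_trace",
    "load_model_config",
    "protocol_from_dict",
    "parameters_from_dict",
]

logger = logging.getLogger("dakinetics")

_FLOAT_FMT = "%.12g"
_RECORDING_MAGIC = "dakinetics-recording v1"

_PROTOCOL_KEYS = {
    "n_pulses": "n_pulses",
    "frequency_hz": "frequency",
    "current_ma": "current",
    "onset_s": "onset",
    "n_bursts": "n_bursts",
    "inter_burst_interval_s": "inter_burst_interval",
}
_PARAMETER_KEYS = {
    "dap", "vm", "km", "L", "ks", "ke", "kgamma", "k1ads", "k2ads", "k3ads",
}


class ParseError(ValueError):
    """A file does not conform to the documented dialect."""


def _format_meta_value(v):
    if isinstance(v, float):
        return _FLOAT_FMT % v
    return str(v)


def write_recording(rec: FSCVRecording, path) -> None:
    """Write a recording in the versioned CSV dialect."""
    path = Path(path)
    lines = [f"# {_RECORDING_MAGIC}"]
    for key in sorted(rec.metadata):
        lines.append(f"# {key}={_format_meta_value(rec.metadata[key])}")
    lines.append("time_s,da_um")
    for t, y in zip(rec.time, rec.signal):
        lines.append(f"{_FLOAT_FMT % t},{_FLOAT_FMT % y}")
    path.write_text("\n".join(lines) + "\n")


def _parse_meta_token(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            continue
    return raw


def read_recording(path) -> FSCVRecording:
    """Read a recording CSV, validating structure row by row."""
    path = Path(path)
    metadata: dict = {}
    times: list[float] = []
    values: list[float] = []
    saw_header = False
    saw_magic = False
    for row_no, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body == _RECORDING_MAGIC:
                saw_magic = True
            elif "=" in body:
                key, _, raw = body.partition("=")
                metadata[key.strip()] = _parse_meta_token(raw.strip())
            continue
        if not saw_header:
            if line != "time_s,da_um":
                raise ParseError(
                    f"{path}:{row_no}: expected header 'time_s,da_um', got {line!r}"
                )
            saw_header = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"{path}:{row_no}: expected 2 columns, got {len(parts)}")
        try:
            t, y = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{row_no}: non-numeric value ({exc})") from exc
        if np.isnan(t) or np.isnan(y):
            raise ParseError(f"{path}:{row_no}: NaN value")
        if times and t <= times[-1]:
            raise ParseError(
                f"{path}:{row_no}: time must be strictly increasing "
                f"({t} after {times[-1]})"
            )
        times.append(t)
        values.append(y)
    if not saw_header:
        raise ParseError(f"{path}: missing 'time_s,da_um' header")
    if not saw_magic and not metadata:
        logger.warning("%s: no metadata header; recording loads with empty metadata", path)
    return FSCVRecording(
        time=np.array(times), signal=np.array(values), metadata=metadata
    )


def write_trace(trace: ConcentrationTrace, path) -> None:
    """Write full simulator state trajectories as CSV."""
    path = Path(path)
    lines = ["time_s,da_s_um,da_e_um,gamma_um"]
    for t, a, e, g in zip(trace.time, trace.da_s, trace.da_e, trace.gamma):
        lines.append(
            ",".join(_FLOAT_FMT % v for v in (t, a, e, g))
        )
    path.write_text("\n".join(lines) + "\n")


def read_trace(path) -> ConcentrationTrace:
    """Read a state-trajectory CSV written by :func:`write_trace`."""
    path = Path(path)
    rows = path.read_text().splitlines()
    if not rows or rows[0] != "time_s,da_s_um,da_e_um,gamma_um":
        raise ParseError(f"{path}: missing trace header")
    data = np.array(
        [[float(x) for x in row.split(",")] for row in rows[1:] if row.strip()]
    )
    if data.ndim != 2 or data.shape[1] != 4:
        raise ParseError(f"{path}: expected 4 columns")
    dt = float(np.median(np.diff(data[:, 0]))) if len(data) > 1 else 1.0
    return ConcentrationTrace(
        time=data[:, 0], da_s=data[:, 1], da_e=data[:, 2], gamma=data[:, 3], dt=dt
    )


def protocol_from_dict(block: dict) -> StimulusProtocol:
    """Build a protocol from a config block, rejecting unknown keys."""
    unknown = set(block) - set(_PROTOCOL_KEYS)
    if unknown:
        raise ParseError(f"unknown protocol key(s): {sorted(unknown)}")
    return StimulusProtocol(**{_PROTOCOL_KEYS[k]: v for k, v in block.items()})


def parameters_from_dict(block: dict) -> KineticParameters:
    """Build kinetic parameters from a config block, rejecting unknown keys."""
    block = dict(block)
    free = block.pop("free", None)
    unknown = set(block) - _PARAMETER_KEYS
    if unknown:
        raise ParseError(f"unknown parameter key(s): {sorted(unknown)}")
    kwargs = dict(block)
    if free is not None:
        kwargs["free"] = frozenset(free)
    return KineticParameters(**kwargs)


def load_model_config(path) -> tuple[StimulusProtocol, KineticParameters]:
    """Load the flat protocol + parameters YAML config."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: config must be a mapping")
    unknown = set(raw) - {"protocol", "parameters"}
    if unknown:
        raise ParseError(f"{path}: unknown top-level key(s): {sorted(unknown)}")
    protocol = protocol_from_dict(raw.get("protocol", {}))
    params = parameters_from_dict(raw.get("parameters", {}))
    return protocol, params
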