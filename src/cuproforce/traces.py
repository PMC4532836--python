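"""Trace containers and the plain-text trace format.

Traces are stored as TSV with '#' comment header lines carrying key=value
metadata (velocity_nm_s, spring_constant_pN_nm, seed, ...), followed by a
column header and the sampled channels::

    # format=cuproforce-trace-v1
    # mode=constant_velocity
    # velocity_nm_s=400.0
    time_s	extension_nm	force_pN
    0.0	0.0	0.0

Floats are rendered with repr (shortest round-tripping decimal), so writing
and re-reading a trace is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ForceExtensionTrace", "ForceClampTrace", "write_trace", "read_trace"]

FORMAT_TAG = "cuproforce-trace-v1"


@dataclass
class ForceExtensionTrace:
    """Constant-velocity pulling trace: force and extension channels vs time."""

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.extension) == len(self.force)):
            raise ValueError("time/extension/force channels must have equal length")
        if np.any(np.diff(self.extension) < -1e-9):
            raise ValueError("extension must be non-decreasing in constant-velocity mode")

    def __len__(self) -> int:
        return len(self.time)


@dataclass
class ForceClampTrace:
    """Force-clamp trace: extension staircase vs time at constant set force."""

    time: np.ndarray
    extension: np.ndarray
    force: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if not (len(self.time) == len(self.extension) == len(self.force)):
            raise ValueError("time/extension/force channels must have equal length")

    def __len__(self) -> int:
        return len(self.time)


def _render_value(v) -> str:
    if isinstance(v, (float, np.floating)):
        return repr(float(v))
    return str(v)


def write_trace(trace, path) -> None:
    """Write a trace in the TSV trace format (bit-exact floats)."""
    mode = "constant_velocity" if isinstance(trace, ForceExtensionTrace) else "force_clamp"
    lines = [f"# format={FORMAT_TAG}", f"# mode={mode}"]
    for k in sorted(trace.metadata):
        lines.append(f"# {k}={_render_value(trace.metadata[k])}")
    lines.append("time_s\textension_nm\tforce_pN")
    for t, x, f in zip(trace.time, trace.extension, trace.force):
        lines.append(f"{float(t)!r}\t{float(x)!r}\t{float(f)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_meta_value(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    return s


def read_trace(path):
    """Read a TSV trace; returns ForceExtensionTrace or ForceClampTrace."""
    meta: dict = {}
    rows = []
    mode = "constant_velocity"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    if k.strip() == "mode":
                        mode = v.strip()
                    elif k.strip() != "format":
                        meta[k.strip()] = _parse_meta_value(v.strip())
                continue
            if line.startswith("time_s"):
                continue
            rows.append([float(c) for c in line.split("\t")])
    if not rows:
        raise ValueError(f"no samples in trace file {path}")
    arr = np.array(rows)
    cls = ForceExtensionTrace if mode == "constant_velocity" else ForceClampTrace
    return cls(time=arr[:, 0], extension=arr[:, 1], force=arr[:, 2], metadata=meta)
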