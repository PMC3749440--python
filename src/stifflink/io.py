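"""Trace container and tab-separated file formats.

A :class:`Trace` is the sampled record of one dual-trap run: trap separation,
the two bead deflections, force, extension and (optionally) the hidden
hairpin state, all at a constant sampling rate.  On disk a trace is a TSV
table with '#'-prefixed ``key=value`` metadata lines before the header.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Trace", "read_trace", "write_trace", "read_config", "write_config"]

TRACE_COLUMNS = [
    "time_s",
    "trap_sep_nm",
    "defl1_nm",
    "defl2_nm",
    "force_pN",
    "extension_nm",
    "state",
]


class TraceFormatError(ValueError):
    """Raised when a trace file violates the format contract."""


@dataclass
class Trace:
    """Sampled time series of a dual-trap assay.

    ``state`` uses 0 = folded, 1 = unfolded, NaN = undefined/mixed sample.
    """

    time: np.ndarray
    trap_sep: np.ndarray
    defl1: np.ndarray
    defl2: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    state: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("trap_sep", "defl1", "defl2", "force", "extension"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if self.state is not None and len(self.state) != n:
            raise ValueError("state length mismatch")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def sample_rate(self) -> float:
        if "sample_rate" in self.meta:
            return float(self.meta["sample_rate"])
        return 1.0 / float(np.median(np.diff(self.time)))

    def to_frame(self) -> pd.DataFrame:
        state = self.state if self.state is not None else np.full(len(self), np.nan)
        return pd.DataFrame(
            {
                "time_s": self.time,
                "trap_sep_nm": self.trap_sep,
                "defl1_nm": self.defl1,
                "defl2_nm": self.defl2,
                "force_pN": self.force,
                "extension_nm": self.extension,
                "state": state,
            }
        )


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as TSV with '#' metadata lines (9 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in trace.meta.items():
            fh.write(f"# {key}={val}\n")
        df = trace.to_frame()
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g", na_rep="NA")


def read_trace(path: str | Path) -> Trace:
    """Read a TSV trace written by :func:`write_trace`.

    Raises :class:`TraceFormatError` naming the first missing column, or on a
    non-monotone / non-uniform time axis.
    """
    path = Path(path)
    meta: dict = {}
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                stripped = line[1:].strip()
                if "=" in stripped:
                    key, val = stripped.split("=", 1)
                    meta[key.strip()] = val.strip()
            else:
                body.append(line)
    df = pd.read_csv(_io.StringIO("".join(body)), sep="\t", na_values=["NA"])
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise TraceFormatError(f"trace file {path} is missing column {col!r}")
    t = df["time_s"].to_numpy(float)
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TraceFormatError(f"trace file {path} has non-monotone time")
        if np.ptp(dt) > 1e-9 * max(abs(dt).max(), 1e-30) + 1e-12 * abs(dt[0]):
            raise TraceFormatError(f"trace file {path} has non-constant sampling")
    state = df["state"].to_numpy(float)
    return Trace(
        time=t,
        trap_sep=df["trap_sep_nm"].to_numpy(float),
        defl1=df["defl1_nm"].to_numpy(float),
        defl2=df["defl2_nm"].to_numpy(float),
        force=df["force_pN"].to_numpy(float),
        extension=df["extension_nm"].to_numpy(float),
        state=state,
        meta=meta,
    )


def write_config(cfg: dict, path: str | Path) -> None:
    """Write a flat key=value configuration file."""
    with open(path, "w") as fh:
        for key, val in cfg.items():
            fh.write(f"{key}={val}\n")


def read_config(path: str | Path, known_keys: set[str] | None = None) -> dict:
    """Read a flat key=value configuration file into a dict of strings.

    Blank lines and '#' comments are ignored.  If ``known_keys`` is given,
    unknown keys raise ValueError.
    """
    out: dict = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key=value, got {line!r}")
            key, val = line.split("=", 1)
            key = key.strip()
            if known_keys is not None and key not in known_keys:
                raise ValueError(
                    f"{path}:{ln}: unknown key {key!r}; known: {sorted(known_keys)}"
                )
            out[key] = val.strip()
    return out
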