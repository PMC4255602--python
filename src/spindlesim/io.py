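"""Plain-text readers/writers for waveforms, rate traces, and spike rasters.

All formats are two-column tab-separated text with a header line, preceded by
``#``-prefixed metadata lines where needed; they are small, diff-able, and
round-trip exactly for times on the 1 ms grid. Parse failures raise
:class:`~spindlesim.errors.ParseError` carrying the offending line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParseError
from .neurons import SpikeRaster
from .stimuli import GRID_DT_MS, Waveform

__all__ = [
    "write_waveform", "read_waveform",
    "write_rates", "read_rates",
    "write_raster", "read_raster",
]


def _read_lines(path):
    try:
        return Path(path).read_text().splitlines()
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc


def _parse_meta(lines):
    meta = {}
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
            body_start = i + 1
        else:
            break
    return meta, body_start


def _parse_table(lines, start, header, path):
    if start >= len(lines) or lines[start].strip() != header:
        raise ParseError(f"expected header '{header}' in {path}", line=start + 1)
    col1, col2 = [], []
    for i, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"expected 2 tab-separated columns, got {len(parts)}", line=i)
        try:
            col1.append(float(parts[0]))
            col2.append(float(parts[1]))
        except ValueError as exc:
            raise ParseError(f"non-numeric value: {exc}", line=i) from exc
    return np.asarray(col1), np.asarray(col2)


def write_waveform(wf: Waveform, path) -> None:
    lines = [f"# label={wf.label}", f"# dt_ms={wf.dt_ms:g}", "time_ms\tlength_l0"]
    lines += [f"{t:.6g}\t{x:.9g}" for t, x in zip(wf.times_ms, wf.samples)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_waveform(path) -> Waveform:
    lines = _read_lines(path)
    meta, start = _parse_meta(lines)
    times, samples = _parse_table(lines, start, "time_ms\tlength_l0", path)
    if times.size == 0:
        raise ParseError(f"waveform file {path} has no samples")
    dt = float(meta.get("dt_ms", GRID_DT_MS))
    if times.size > 1 and not np.allclose(np.diff(times), dt):
        raise ParseError(f"waveform times are not uniform at dt={dt} ms")
    return Waveform(samples, dt_ms=dt, label=meta.get("label", ""))


def write_rates(time_ms: np.ndarray, rate_hz: np.ndarray, path, group: str = "") -> None:
    """Write one afferent group's rate trace as (time_ms, rate_hz) columns."""
    if len(time_ms) != len(rate_hz):
        raise ValueError("time and rate arrays must have equal length")
    lines = [f"# group={group}", "time_ms\trate_hz"]
    lines += [f"{t:.6g}\t{r:.9g}" for t, r in zip(time_ms, rate_hz)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_rates(path) -> tuple[np.ndarray, np.ndarray, str]:
    """Read a rate trace; returns (time_ms, rate_hz, group)."""
    lines = _read_lines(path)
    meta, start = _parse_meta(lines)
    times, rates = _parse_table(lines, start, "time_ms\trate_hz", path)
    if np.any(rates < 0):
        raise ParseError(f"negative rate in {path}")
    return times, rates, meta.get("group", "")


def write_raster(raster: SpikeRaster, path) -> None:
    lines = [f"# group={raster.group}", f"# n_neurons={raster.n_neurons}",
             "time_ms\tneuron_id"]
    lines += [f"{t:.6g}\t{int(n)}" for t, n in zip(raster.times_ms, raster.neuron_ids)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_raster(path) -> SpikeRaster:
    lines = _read_lines(path)
    meta, start = _parse_meta(lines)
    if "n_neurons" not in meta:
        raise ParseError(f"raster file {path} is missing the '# n_neurons=' line")
    times, ids = _parse_table(lines, start, "time_ms\tneuron_id", path)
    try:
        return SpikeRaster(times_ms=times, neuron_ids=ids.astype(np.int64),
                           n_neurons=int(meta["n_neurons"]),
                           group=meta.get("group", ""))
    except ValueError as exc:
        raise ParseError(f"invalid raster in {path}: {exc}") from exc
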