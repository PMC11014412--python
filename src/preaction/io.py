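"""Trace and reference-set I/O.

Defines the two containers every other module consumes — :class:`AccelTrace`
(a single 3-axis acceleration recording) and :class:`ReferenceSet` (expert
punch templates anchored at their striking samples) — plus CSV/YAML
persistence for both.

Conventions used throughout the package:

* indices are 0-based; intervals are half-open ``[start, end)``;
* acceleration values stay in whatever unit the sensor produced — the unit
  is carried as a metadata string and never converted;
* trace files are CSV with header ``time_s,ax,ay,az``; the time column is
  only used to validate uniform sampling.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "AccelTrace",
    "ReferenceSet",
    "TraceError",
    "load_trace",
    "save_trace",
    "load_reference_set",
    "save_reference_set",
]

#: Relative tolerance on inter-sample spacing (fraction of the nominal period).
TIME_SPACING_RTOL = 0.01

#: Default unit label for traces whose physical scale is unknown
#: (raw sensor counts).
NATIVE_UNIT = "raw"


class TraceError(ValueError):
    """Raised when a trace or manifest violates the format contract."""


@dataclass(frozen=True)
class AccelTrace:
    """A uniformly sampled 3-axis acceleration time series.

    Parameters
    ----------
    samples
        Array of shape ``(n, 3)`` holding the X, Y, Z acceleration of each
        sample, ``n >= 2``, all values finite.
    sample_rate_hz
        Sampling frequency, strictly positive.
    source_id
        Free-text provenance label (file stem, simulator tag, ...).
    unit
        Unit string for the acceleration values, e.g. ``"m/s^2"`` or
        ``"raw"`` for uncalibrated sensor counts.
    """

    samples: np.ndarray
    sample_rate_hz: float
    source_id: str = ""
    unit: str = NATIVE_UNIT

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise TraceError(
                f"samples must have shape (n, 3), got {arr.shape}"
            )
        if arr.shape[0] < 2:
            raise TraceError("trace too short: need at least 2 samples")
        if not np.all(np.isfinite(arr)):
            bad = int(np.argwhere(~np.isfinite(arr))[0, 0])
            raise TraceError(f"non-finite acceleration value at row {bad}")
        if not (self.sample_rate_hz > 0):
            raise TraceError("sample_rate_hz must be > 0")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return int(self.samples.shape[0])

    @property
    def x(self) -> np.ndarray:
        return self.samples[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.samples[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.samples[:, 2]

    @property
    def duration_s(self) -> float:
        return (len(self) - 1) / self.sample_rate_hz

    def times(self) -> np.ndarray:
        """Sample timestamps in seconds, starting at 0."""
        return np.arange(len(self)) / self.sample_rate_hz

    def scaled(self, factor: float) -> "AccelTrace":
        """Return a copy with every acceleration value multiplied by ``factor``."""
        return replace(self, samples=self.samples * float(factor))


@dataclass(frozen=True)
class Template:
    """One pre-action-free reference punch with its striking sample."""

    trace: AccelTrace
    striking_index: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.striking_index < len(self.trace)):
            raise TraceError(
                f"striking index {self.striking_index} out of range for "
                f"trace of length {len(self.trace)}"
            )


@dataclass(frozen=True)
class ReferenceSet:
    """An ordered collection of pre-action-free punch templates.

    All templates share one acceleration unit; ``len(refset)`` is the number
    of templates J.
    """

    templates: tuple[Template, ...]
    unit: str = NATIVE_UNIT

    def __post_init__(self) -> None:
        if len(self.templates) < 1:
            raise TraceError("reference set needs at least one template")
        object.__setattr__(self, "templates", tuple(self.templates))
        for t in self.templates:
            if t.trace.unit != self.unit:
                raise TraceError(
                    f"unit mismatch: template {t.label!r} has unit "
                    f"{t.trace.unit!r}, reference set declares {self.unit!r}"
                )

    def __len__(self) -> int:
        return len(self.templates)

    def __iter__(self):
        return iter(self.templates)

    def scaled(self, factor: float) -> "ReferenceSet":
        return ReferenceSet(
            tuple(
                Template(t.trace.scaled(factor), t.striking_index, t.label)
                for t in self.templates
            ),
            unit=self.unit,
        )


# ---------------------------------------------------------------------------
# CSV traces
# ---------------------------------------------------------------------------

_HEADER = ["time_s", "ax", "ay", "az"]


def load_trace(
    path: str | Path,
    sample_rate_hz: float,
    *,
    unit: str = NATIVE_UNIT,
) -> AccelTrace:
    """Read a single-punch trace from a ``time_s,ax,ay,az`` CSV file.

    The time column is validated against uniform spacing at the nominal
    period ``1/sample_rate_hz`` (tolerance :data:`TIME_SPACING_RTOL` of the
    period) and then discarded; sample order is file order.
    """
    path = Path(path)
    if not path.exists():
        raise TraceError(f"trace file not found: {path}")
    rows: list[tuple[float, float, float, float]] = []
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != _HEADER:
            raise TraceError(
                f"{path}: expected header {','.join(_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise TraceError(
                    f"{path}: row {lineno}: expected 4 columns, got {len(row)}"
                )
            try:
                rows.append(tuple(float(c) for c in row))  # type: ignore[arg-type]
            except ValueError as exc:
                raise TraceError(f"{path}: row {lineno}: non-numeric cell ({exc})")
    if len(rows) < 2:
        raise TraceError(f"{path}: trace too short ({len(rows)} data rows, need >= 2)")

    arr = np.asarray(rows, dtype=np.float64)
    period = 1.0 / sample_rate_hz
    dt = np.diff(arr[:, 0])
    bad = np.nonzero(np.abs(dt - period) > TIME_SPACING_RTOL * period)[0]
    if bad.size:
        # +2: skip header line, and dt[k] is the gap ending at data row k+1
        raise TraceError(
            f"{path}: non-uniform sample spacing at row {int(bad[0]) + 3}: "
            f"dt={dt[bad[0]]:.6g}s vs nominal {period:.6g}s"
        )
    return AccelTrace(
        samples=arr[:, 1:4],
        sample_rate_hz=sample_rate_hz,
        source_id=path.stem,
        unit=unit,
    )


def save_trace(trace: AccelTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,ax,ay,az`` CSV (full float precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    times = trace.times()
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for t, (ax, ay, az) in zip(times, trace.samples):
            writer.writerow([repr(float(t)), repr(float(ax)),
                             repr(float(ay)), repr(float(az))])


# ---------------------------------------------------------------------------
# Reference-set manifests
# ---------------------------------------------------------------------------


def load_reference_set(manifest_path: str | Path) -> ReferenceSet:
    """Load a reference set from a YAML manifest.

    Manifest schema::

        unit: raw
        sample_rate_hz: 100.0
        templates:
          - {file: expert0.csv, striking_index: 72, label: expert0}
          - ...

    Template file paths are resolved relative to the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise TraceError(f"manifest not found: {manifest_path}")
    doc = yaml.safe_load(manifest_path.read_text())
    if not isinstance(doc, dict):
        raise TraceError(f"{manifest_path}: manifest must be a mapping")
    try:
        unit = str(doc["unit"])
        rate = float(doc["sample_rate_hz"])
        entries = doc["templates"]
    except KeyError as exc:
        raise TraceError(f"{manifest_path}: missing manifest key {exc}")
    if not isinstance(entries, list) or not entries:
        raise TraceError(f"{manifest_path}: 'templates' must be a non-empty list")

    templates = []
    for entry in entries:
        tpath = manifest_path.parent / entry["file"]
        trace = load_trace(tpath, sample_rate_hz=rate, unit=unit)
        templates.append(
            Template(
                trace=trace,
                striking_index=int(entry["striking_index"]),
                label=str(entry.get("label", tpath.stem)),
            )
        )
    return ReferenceSet(tuple(templates), unit=unit)


def save_reference_set(refset: ReferenceSet, manifest_path: str | Path,
                       sample_rate_hz: float | None = None) -> None:
    """Write templates as CSVs next to a YAML manifest at ``manifest_path``."""
    manifest_path = Path(manifest_path)
    manifest_path.parent.mkdir(parents=True, exist_ok=True)
    if sample_rate_hz is None:
        sample_rate_hz = refset.templates[0].trace.sample_rate_hz
    entries = []
    for k, t in enumerate(refset.templates):
        label = t.label or f"template{k}"
        fname = f"{label}.csv"
        save_trace(t.trace, manifest_path.parent / fname)
        entries.append(
            {"file": fname, "striking_index": int(t.striking_index), "label": label}
        )
    doc = {
        "unit": refset.unit,
        "sample_rate_hz": float(sample_rate_hz),
        "templates": entries,
    }
    manifest_path.write_text(yaml.safe_dump(doc, sort_keys=False))
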