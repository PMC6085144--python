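"""Containers and CSV round-trip for longitudinal pain-intensity records.

A record holds one subject's pain (or proxy) values at ordered time marks in
months.  A cohort is a set of records sharing a time grid; records missing
some marks are retained but flagged incomplete, and cohort-level analyses
filter on completeness.

Two CSV layouts are supported:

* ``long`` — columns ``subject_id,time_months,value[,scale]``, one row per
  observation;
* ``wide`` — columns ``subject_id,t0,t1,t6,t12,...`` (``t<mark>``), one row
  per subject; empty cells denote missing marks.

All times are months; values are serialized with 6 decimals so that a
write/read round trip is bit-stable at that precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParseError, ValidationError

#: Recognized value scales.
SCALES = frozenset({"nrs", "geometric", "dose_proxy", "strength_gap"})

#: Valid range of the numerical rating scale.
NRS_BOUNDS = (0.0, 10.0)

_CSV_DECIMALS = 6


def _fmt_mark(t: float) -> str:
    """Column name for a time mark: ``t6`` for 6.0, ``t1.5`` for 1.5."""
    return f"t{int(t)}" if float(t).is_integer() else f"t{t:g}"


@dataclass(frozen=True)
class TimeSeriesRecord:
    """One subject's pain trajectory.

    Parameters
    ----------
    subject_id
        Opaque identifier.
    times
        Strictly increasing time marks in months, all non-negative.
    values
        Pain intensities aligned with ``times``.  Finite; on the ``nrs``
        scale every value must lie in [0, 10].
    scale
        One of :data:`SCALES`.
    """

    subject_id: str
    times: tuple[float, ...]
    values: tuple[float, ...]
    scale: str = "nrs"

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if self.scale not in SCALES:
            raise ValidationError(f"unknown scale {self.scale!r}; expected one of {sorted(SCALES)}")
        if len(self.times) != len(self.values):
            raise ValidationError(
                f"record {self.subject_id!r}: {len(self.times)} times but {len(self.values)} values"
            )
        if len(self.times) < 2:
            raise ValidationError(f"record {self.subject_id!r}: needs at least 2 marks")
        if any(t < 0 for t in self.times):
            raise ValidationError(f"record {self.subject_id!r}: negative time mark")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValidationError(f"record {self.subject_id!r}: times not strictly increasing")
        if not all(math.isfinite(v) for v in self.values):
            raise ValidationError(f"record {self.subject_id!r}: non-finite value")
        if self.scale == "nrs":
            lo, hi = NRS_BOUNDS
            if any(not (lo <= v <= hi) for v in self.values):
                raise ValidationError(f"record {self.subject_id!r}: NRS value outside [{lo}, {hi}]")

    def value_at(self, t: float) -> float:
        """Value at mark ``t``; raises :class:`KeyError` if absent."""
        t = float(t)
        for tk, vk in zip(self.times, self.values):
            if tk == t:
                return vk
        raise KeyError(f"record {self.subject_id!r} has no mark t={t:g}")

    def has_marks(self, marks: Iterable[float]) -> bool:
        present = set(self.times)
        return all(float(m) in present for m in marks)

    def is_complete_on(self, grid: Sequence[float]) -> bool:
        return self.has_marks(grid)

    def subset(self, marks: Iterable[float]) -> "TimeSeriesRecord":
        """Restrict the record to the given marks (all must be present)."""
        marks = sorted(float(m) for m in marks)
        vals = [self.value_at(m) for m in marks]
        return replace(self, times=tuple(marks), values=tuple(vals))

    def with_scale(self, scale: str, values: Sequence[float] | None = None) -> "TimeSeriesRecord":
        vals = self.values if values is None else tuple(values)
        return TimeSeriesRecord(self.subject_id, self.times, vals, scale)


@dataclass
class Cohort:
    """A collection of records on a shared time-mark grid.

    Each record's times must be a subset of ``time_grid``.  Records covering
    every grid mark are *complete*; analyses that need a full grid call
    :meth:`complete`.
    """

    records: list[TimeSeriesRecord]
    time_grid: tuple[float, ...]
    rejection_report: list[tuple[str, str]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.time_grid = tuple(float(t) for t in self.time_grid)
        if not self.records:
            raise ValidationError("cohort is empty")
        if any(b <= a for a, b in zip(self.time_grid, self.time_grid[1:])):
            raise ValidationError("time grid not strictly increasing")
        grid = set(self.time_grid)
        for rec in self.records:
            extra = set(rec.times) - grid
            if extra:
                raise ValidationError(
                    f"record {rec.subject_id!r} has marks {sorted(extra)} outside the grid {self.time_grid}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    def complete_records(self) -> list[TimeSeriesRecord]:
        return [r for r in self.records if r.is_complete_on(self.time_grid)]

    def complete(self) -> "Cohort":
        """Sub-cohort of records observed at every grid mark."""
        recs = self.complete_records()
        if not recs:
            raise ValidationError("no complete records in cohort")
        return Cohort(recs, self.time_grid)

    @property
    def n_incomplete(self) -> int:
        return self.n - len(self.complete_records())

    def values_at(self, t: float) -> np.ndarray:
        """Values of all complete records at mark ``t`` (cohort order)."""
        return np.array([r.value_at(t) for r in self.complete_records()])

    def value_matrix(self) -> np.ndarray:
        """(n_complete, n_marks) matrix of values over the grid."""
        return np.array([[r.value_at(t) for t in self.time_grid] for r in self.complete_records()])


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_value(raw, row: int) -> float:
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise ParseError(f"cannot parse value {raw!r}", row=row) from None
    return v


def read_cohort(path: str | Path, format: str = "wide", errors: str = "raise") -> Cohort:
    """Read a cohort from CSV.

    Parameters
    ----------
    path
        CSV file with header.
    format
        ``"long"`` or ``"wide"`` (see module docstring).
    errors
        ``"raise"`` aborts on the first record violating an invariant;
        ``"drop"`` drops offending records and collects a per-record report
        in ``Cohort.rejection_report``.
    """
    if format not in ("long", "wide"):
        raise FormatError(f"unknown format {format!r}; expected 'long' or 'wide'")
    if errors not in ("raise", "drop"):
        raise ValueError("errors must be 'raise' or 'drop'")
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if format == "long":
        return _cohort_from_long(df, errors)
    return _cohort_from_wide(df, errors)


def _cohort_from_long(df: pd.DataFrame, errors: str) -> Cohort:
    required = {"subject_id", "time_months", "value"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"long CSV is missing columns: {sorted(missing)}")
    has_scale = "scale" in df.columns
    per_subject: dict[str, list[tuple[float, float]]] = {}
    scales: dict[str, str] = {}
    for row, rec in enumerate(df.itertuples(index=False)):
        sid = str(rec.subject_id)
        t = _parse_value(rec.time_months, row)
        v = _parse_value(rec.value, row)
        per_subject.setdefault(sid, []).append((t, v))
        if has_scale and isinstance(rec.scale, str):
            scales[sid] = rec.scale
    return _assemble(per_subject, scales, errors)


def _cohort_from_wide(df: pd.DataFrame, errors: str) -> Cohort:
    if "subject_id" not in df.columns:
        raise FormatError("wide CSV is missing the subject_id column")
    mark_cols = [c for c in df.columns if c.startswith("t") and c != "subject_id"]
    if not mark_cols:
        raise FormatError("wide CSV has no time-mark columns (expected t0, t1, ...)")
    try:
        marks = [(c, float(c[1:])) for c in mark_cols]
    except ValueError as exc:
        raise FormatError(f"unparseable time-mark column: {exc}") from None
    marks.sort(key=lambda m: m[1])
    scale_col = "scale" if "scale" in df.columns else None
    per_subject: dict[str, list[tuple[float, float]]] = {}
    scales: dict[str, str] = {}
    for row, rec in df.iterrows():
        sid = str(rec["subject_id"])
        obs = []
        for col, t in marks:
            raw = rec[col]
            if pd.isna(raw) or (isinstance(raw, str) and not raw.strip()):
                continue  # missing mark -> incomplete record
            obs.append((t, _parse_value(raw, int(row))))
        per_subject[sid] = obs
        if scale_col and isinstance(rec[scale_col], str):
            scales[sid] = rec[scale_col]
    return _assemble(per_subject, scales, errors, grid=tuple(t for _, t in marks))


def _assemble(
    per_subject: dict[str, list[tuple[float, float]]],
    scales: dict[str, str],
    errors: str,
    grid: tuple[float, ...] | None = None,
) -> Cohort:
    records: list[TimeSeriesRecord] = []
    rejected: list[tuple[str, str]] = []
    all_marks: set[float] = set()
    for sid, obs in per_subject.items():
        obs = sorted(obs)
        try:
            rec = TimeSeriesRecord(
                sid,
                tuple(t for t, _ in obs),
                tuple(v for _, v in obs),
                scales.get(sid, "nrs"),
            )
        except ValidationError as exc:
            if errors == "raise":
                raise
            rejected.append((sid, str(exc)))
            continue
        records.append(rec)
        all_marks.update(rec.times)
    if grid is None:
        grid = tuple(sorted(all_marks))
    if not records:
        raise ValidationError("no valid records in file")
    cohort = Cohort(records, grid)
    cohort.rejection_report = rejected
    return cohort


def write_cohort(cohort: Cohort, path: str | Path, format: str = "wide") -> None:
    """Write a cohort to CSV (6-decimal values; lossless round trip)."""
    if format not in ("long", "wide"):
        raise FormatError(f"unknown format {format!r}")
    path = Path(path)
    if format == "long":
        rows = [
            {"subject_id": r.subject_id, "time_months": f"{t:g}", "value": f"{v:.{_CSV_DECIMALS}f}", "scale": r.scale}
            for r in cohort.records
            for t, v in zip(r.times, r.values)
        ]
        pd.DataFrame(rows, columns=["subject_id", "time_months", "value", "scale"]).to_csv(path, index=False)
        return
    cols = [_fmt_mark(t) for t in cohort.time_grid]
    rows = []
    for r in cohort.records:
        row: dict[str, str] = {"subject_id": r.subject_id}
        for t, c in zip(cohort.time_grid, cols):
            try:
                row[c] = f"{r.value_at(t):.{_CSV_DECIMALS}f}"
            except KeyError:
                row[c] = ""
        row["scale"] = r.scale
        rows.append(row)
    pd.DataFrame(rows, columns=["subject_id", *cols, "scale"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summary helpers


def average_nrs(current: float, best: float, worst: float) -> float:
    """Arithmetic mean of current/best/worst NRS ratings.

    Each input must lie in [0, 10].
    """
    lo, hi = NRS_BOUNDS
    for name, v in (("current", current), ("best", best), ("worst", worst)):
        if not (lo <= v <= hi):
            raise ValidationError(f"{name} rating {v} outside [{lo}, {hi}]")
    return (current + best + worst) / 3.0


def cumulative_distribution(samples: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF of ``samples``.

    Returns ``(values, fractions)``: sorted unique values and the cumulative
    fraction of samples ≤ each value.  Fractions lie in (0, 1] and end at
    exactly 1.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValidationError("cumulative_distribution: empty input")
    if not np.all(np.isfinite(samples)):
        raise ValidationError("cumulative_distribution: non-finite sample")
    values, counts = np.unique(samples, return_counts=True)
    fractions = np.cumsum(counts) / samples.size
    fractions[-1] = 1.0  # exact despite fp accumulation
    return values, fractions
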