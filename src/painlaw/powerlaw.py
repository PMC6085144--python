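"""The shifted power-law decay model and its closed-form companions.

The model is ``F(t) = F0 * (1 + t/t0)**(-P)`` with prefactor ``F0 > 0``,
dimensionless exponent ``P`` (positive for recovery, negative for worsening)
and a time offset ``t0 > 0`` (default 1 month) that keeps the curve finite at
t = 0.  In log–log coordinates ``log F`` is linear in ``log(1 + t/t0)`` with
slope ``-P``, so fitting reduces to ordinary least squares.

Two fit routes are provided: a 2-parameter fit (prefactor and exponent, by
log–log regression) and a 1-parameter fit (prefactor only, exponent fixed)
that averages the per-mark prefactors ``A_k = Y_k * (1 + t_k/t0)**P``.

Also here: the halving ratio ``M = 2**(1/P)`` — the factor by which
offset-shifted time must grow for a pure power law to drop by half — and the
geometric pain-scale mapping ``N -> step_ratio**N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort_io import TimeSeriesRecord
from .exceptions import DomainError, FitError

#: Default time offset, months.
DEFAULT_T0 = 1.0

#: Values below this are floored before any log transform (0 occurs in 0-10
#: NRS data and has no logarithm).
DEFAULT_FLOOR = 0.1

#: Default geometric-scale step ratio (one NRS step = factor 2 in pain).
DEFAULT_STEP_RATIO = 2.0


@dataclass(frozen=True)
class PowerLawParams:
    """Parameters of the shifted power law ``F(t) = prefactor*(1+t/offset)**(-exponent)``."""

    prefactor: float
    exponent: float
    offset: float = DEFAULT_T0

    def __post_init__(self) -> None:
        if not self.prefactor > 0:
            raise DomainError(f"prefactor must be > 0, got {self.prefactor}")
        if not self.offset > 0:
            raise DomainError(f"offset must be > 0, got {self.offset}")

    def __call__(self, t):
        return evaluate(self, t)


@dataclass(frozen=True)
class ExpDecayParams:
    """Parameters of the alternative model ``amplitude * exp(-t/tau)``.

    ``tau = inf`` is the flat-trajectory sentinel.
    """

    amplitude: float
    tau: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise DomainError(f"amplitude must be > 0, got {self.amplitude}")
        if not self.tau > 0:
            raise DomainError(f"tau must be > 0, got {self.tau}")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = self.amplitude * np.exp(-t / self.tau)
        return float(out) if out.ndim == 0 else out


def evaluate(params: PowerLawParams, t):
    """Evaluate the power law at time(s) ``t`` (months, >= 0)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("evaluate: t must be >= 0")
    out = params.prefactor * (1.0 + t / params.offset) ** (-params.exponent)
    return float(out) if out.ndim == 0 else out


def floor_values(values, floor: float = DEFAULT_FLOOR) -> np.ndarray:
    """Clip values from below so log transforms are defined."""
    return np.maximum(np.asarray(values, dtype=float), floor)


def _select_marks(record: TimeSeriesRecord, marks: Sequence[float] | None):
    if marks is None:
        marks = record.times
    marks = sorted(float(m) for m in marks)
    values = np.array([record.value_at(m) for m in marks])
    return np.asarray(marks, dtype=float), values


def fit_two_param(
    record: TimeSeriesRecord,
    marks: Sequence[float] | None = None,
    *,
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
) -> PowerLawParams:
    """Fit prefactor and exponent by OLS of log(value) on log(1 + t/t0).

    The slope is ``-P`` and the intercept ``log(prefactor)``.  Exact (to
    rounding) when the record lies on a power law with the same offset.
    """
    times, values = _select_marks(record, marks)
    if times.size < 2:
        raise FitError(f"record {record.subject_id!r}: need >= 2 marks to fit, got {times.size}")
    x = np.log1p(times / t0)
    y = np.log(floor_values(values, floor))
    slope, intercept = np.polyfit(x, y, 1)
    return PowerLawParams(prefactor=float(np.exp(intercept)), exponent=float(-slope), offset=t0)


def fit_prefactor_fixed_exponent(
    record: TimeSeriesRecord,
    exponent: float,
    marks: Sequence[float] | None = None,
    *,
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """1-parameter fit: mean over marks of ``A_k = Y_k * (1 + t_k/t0)**P``."""
    times, values = _select_marks(record, marks)
    if times.size == 0:
        raise FitError("fit_prefactor_fixed_exponent: no marks given")
    a_k = floor_values(values, floor) * (1.0 + times / t0) ** exponent
    return float(np.mean(a_k))


def halving_ratio(exponent: float) -> float:
    """``M = 2**(1/P)``: the time-stretch factor that halves a pure power law."""
    if exponent <= 0:
        raise DomainError(f"halving requires a decreasing trajectory (P > 0), got P={exponent}")
    return 2.0 ** (1.0 / exponent)


def half_reduction_time(t_now: float, exponent: float) -> float:
    """Projected time at which pain is half its level at ``t_now``.

    Pure power-law convention: ``t_half = t_now * M``.  Units follow
    ``t_now`` (days in, days out).  For the offset-shifted model the identity
    is exact in ``u = t0 + t`` and approximate in ``t`` when ``t >> t0``.
    """
    if t_now <= 0:
        raise DomainError(f"t_now must be > 0, got {t_now}")
    return t_now * halving_ratio(exponent)


def geometric_from_nrs(n, step_ratio: float = DEFAULT_STEP_RATIO):
    """Map an NRS level to the geometric pain scale: ``step_ratio**N``."""
    if step_ratio <= 0:
        raise DomainError(f"step_ratio must be > 0, got {step_ratio}")
    out = np.asarray(step_ratio, dtype=float) ** np.asarray(n, dtype=float)
    return float(out) if out.ndim == 0 else out


def nrs_from_geometric(value, step_ratio: float = DEFAULT_STEP_RATIO):
    """Inverse of :func:`geometric_from_nrs`: ``log(value)/log(step_ratio)``."""
    if step_ratio <= 0:
        raise DomainError(f"step_ratio must be > 0, got {step_ratio}")
    value = np.asarray(value, dtype=float)
    if np.any(value <= 0):
        raise DomainError("nrs_from_geometric: value must be > 0")
    out = np.log(value) / np.log(step_ratio)
    return float(out) if out.ndim == 0 else out


def step_ratio_from_endpoints(pain_ratio: float, n_steps: int) -> float:
    """Per-step ratio implied by a total pain ratio over ``n_steps`` scale steps."""
    if pain_ratio <= 0:
        raise DomainError(f"pain_ratio must be > 0, got {pain_ratio}")
    if n_steps < 1:
        raise DomainError(f"n_steps must be >= 1, got {n_steps}")
    return pain_ratio ** (1.0 / n_steps)
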