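"""Outcome projection from early time marks and its accuracy diagnostics.

Four standard schemes predict pain at a future time T from a subset of the
early marks:

========  ===========  =================
label     fit marks    exponent
========  ===========  =================
I         0, 6         fixed
II        0, 1, 6      fixed
III       0, 1         fixed
IV        0, 1, 6      fitted per record
========  ===========  =================

Fixed-exponent schemes estimate only the prefactor (per-mark prefactors
averaged); scheme IV fits both parameters by log–log regression.  Custom
schemes (other mark subsets) can be built directly.

Accuracy is summarized by the distribution of observed-minus-predicted
deviations at T and by tolerance-band accuracies: the percentage of records
whose absolute deviation is within ±1, ±1.5, ±2 pain units (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .cohort_io import Cohort, TimeSeriesRecord
from .exceptions import FitError, ValidationError
from .powerlaw import (
    DEFAULT_FLOOR,
    DEFAULT_T0,
    PowerLawParams,
    evaluate,
    fit_prefactor_fixed_exponent,
    fit_two_param,
    floor_values,
)

#: Exponent used by the fixed-exponent schemes (cohort-level estimate from
#: the per-record fitted exponents of scheme IV).
DEFAULT_FIXED_EXPONENT = 0.3

#: Tolerance bands, pain units.
DEFAULT_BANDS = (1.0, 1.5, 2.0)

_STANDARD = {
    "I": ((0.0, 6.0), "fixed"),
    "II": ((0.0, 1.0, 6.0), "fixed"),
    "III": ((0.0, 1.0), "fixed"),
    "IV": ((0.0, 1.0, 6.0), "fitted"),
}


@dataclass(frozen=True)
class ProjectionScheme:
    """Which marks feed the fit and whether the exponent is fixed or fitted."""

    label: str
    fit_marks: tuple[float, ...]
    exponent_mode: str  # "fixed" | "fitted"
    fixed_P: float | None = DEFAULT_FIXED_EXPONENT

    def __post_init__(self) -> None:
        if self.exponent_mode not in ("fixed", "fitted"):
            raise ValidationError(f"exponent_mode must be 'fixed' or 'fitted', got {self.exponent_mode!r}")
        if self.exponent_mode == "fixed" and self.fixed_P is None:
            raise ValidationError("fixed-exponent scheme needs fixed_P")
        if len(self.fit_marks) < 1:
            raise ValidationError("scheme needs at least one fit mark")
        if self.exponent_mode == "fitted" and len(self.fit_marks) < 2:
            raise ValidationError("fitted-exponent scheme needs >= 2 fit marks")
        std = _STANDARD.get(self.label)
        if std is not None and (tuple(self.fit_marks), self.exponent_mode) != std:
            raise ValidationError(
                f"scheme {self.label}: marks/mode must be {std}, got ({self.fit_marks}, {self.exponent_mode})"
            )

    @classmethod
    def standard(cls, label: str, fixed_P: float = DEFAULT_FIXED_EXPONENT) -> "ProjectionScheme":
        """One of the four standard schemes by label."""
        try:
            marks, mode = _STANDARD[label]
        except KeyError:
            raise ValidationError(f"unknown scheme label {label!r}; expected I, II, III or IV") from None
        return cls(label, marks, mode, fixed_P if mode == "fixed" else None)


def standard_schemes(fixed_P: float = DEFAULT_FIXED_EXPONENT) -> dict[str, ProjectionScheme]:
    return {lbl: ProjectionScheme.standard(lbl, fixed_P) for lbl in _STANDARD}


@dataclass
class DeviationSummary:
    """Distribution of observed − predicted values at the target time."""

    deviations: np.ndarray
    accuracies: dict[float, float]  # band -> percent within ±band
    mean_bias: float
    spread: float  # SD of deviations
    n: int
    target_time: float
    scheme_label: str

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme_label,
            "target_time": self.target_time,
            "n": self.n,
            "mean_bias": self.mean_bias,
            "spread": self.spread,
            "accuracies": {f"{band:g}": round(pct, 1) for band, pct in self.accuracies.items()},
        }


def project_record(
    record: TimeSeriesRecord,
    scheme: ProjectionScheme,
    T: float,
    *,
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
) -> float:
    """Predicted pain at time ``T`` for one record under ``scheme``."""
    for m in scheme.fit_marks:
        if not record.has_marks([m]):
            raise ValidationError(f"record {record.subject_id!r} is missing fit mark t={m:g}")
    if scheme.exponent_mode == "fixed":
        prefactor = fit_prefactor_fixed_exponent(record, scheme.fixed_P, scheme.fit_marks, t0=t0, floor=floor)
        params = PowerLawParams(prefactor, scheme.fixed_P, t0)
    else:
        params = fit_two_param(record, scheme.fit_marks, t0=t0, floor=floor)
    return float(evaluate(params, T))


def tolerance_band_accuracies(deviations: np.ndarray, bands: Sequence[float]) -> dict[float, float]:
    """Percent of |deviation| <= band (inclusive), per band."""
    deviations = np.abs(np.asarray(deviations, dtype=float))
    return {float(b): float(100.0 * np.mean(deviations <= b)) for b in bands}


def cohort_deviations(
    cohort: Cohort,
    scheme: ProjectionScheme,
    T: float,
    *,
    bands: Sequence[float] = DEFAULT_BANDS,
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
) -> DeviationSummary:
    """Observed − predicted at ``T`` across all complete records."""
    records = cohort.complete_records()
    if not records:
        raise ValidationError("no complete records to project")
    devs = np.array(
        [r.value_at(T) - project_record(r, scheme, T, t0=t0, floor=floor) for r in records]
    )
    return DeviationSummary(
        deviations=devs,
        accuracies=tolerance_band_accuracies(devs, bands),
        mean_bias=float(np.mean(devs)),
        spread=float(np.std(devs, ddof=1)) if devs.size > 1 else 0.0,
        n=devs.size,
        target_time=float(T),
        scheme_label=scheme.label,
    )


@dataclass
class ExponentDistribution:
    """Per-record fitted exponents with summary statistics."""

    exponents: np.ndarray
    mean: float
    sd: float
    n: int
    n_failed: int
    failures: list[tuple[str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "n": self.n,
            "n_failed": self.n_failed,
        }


def exponent_distribution(
    cohort: Cohort,
    fit_marks: Sequence[float] | None = None,
    *,
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
) -> ExponentDistribution:
    """Fit every complete record (2 free parameters) and collect the exponents."""
    records = cohort.complete_records()
    if not records:
        raise ValidationError("no complete records")
    exps: list[float] = []
    failures: list[tuple[str, str]] = []
    for rec in records:
        try:
            exps.append(fit_two_param(rec, fit_marks, t0=t0, floor=floor).exponent)
        except FitError as exc:
            failures.append((rec.subject_id, str(exc)))
    arr = np.asarray(exps)
    if arr.size == 0:
        raise FitError("every record failed to fit")
    return ExponentDistribution(
        exponents=arr,
        mean=float(np.mean(arr)),
        sd=float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0,
        n=arr.size,
        n_failed=len(failures),
        failures=failures,
    )


@dataclass
class SlopeScatter:
    """Per-transition log–log slopes and their spreads.

    ``transitions[i]`` is the consecutive mark pair, ``slopes[i]`` the
    per-record slopes for that pair, ``spreads[i]`` the scatter (IQR by
    default) and ``spread_ratios[i]`` the spread relative to the median
    spread of the other transitions.
    """

    transitions: list[tuple[float, float]]
    slopes: list[np.ndarray]
    spreads: np.ndarray
    spread_ratios: np.ndarray
    spread_measure: str

    def to_dict(self) -> dict:
        return {
            "transitions": [list(t) for t in self.transitions],
            "spreads": self.spreads.tolist(),
            "spread_ratios": self.spread_ratios.tolist(),
            "spread_measure": self.spread_measure,
        }


def transition_slope_scatter(
    cohort: Cohort,
    *,
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
    spread: str = "iqr",
) -> SlopeScatter:
    """Scatter of per-record slopes for each consecutive mark transition.

    The slope between marks (t_k, t_{k+1}) is Δlog(value)/Δlog(1 + t/t0),
    i.e. the two-point exponent estimate (negated).  A broad first-transition
    scatter relative to the rest flags extra noise at baseline.
    """
    if spread not in ("iqr", "sd"):
        raise ValueError("spread must be 'iqr' or 'sd'")
    records = cohort.complete_records()
    if not records:
        raise ValidationError("no complete records")
    grid = cohort.time_grid
    if len(grid) < 2:
        raise ValidationError("need at least 2 marks for transitions")
    matrix = floor_values(cohort.value_matrix(), floor)
    x = np.log1p(np.asarray(grid) / t0)
    logv = np.log(matrix)
    transitions = list(zip(grid, grid[1:]))
    slopes = [
        (logv[:, k + 1] - logv[:, k]) / (x[k + 1] - x[k]) for k in range(len(grid) - 1)
    ]
    if spread == "iqr":
        spreads = np.array([float(stats.iqr(s)) for s in slopes])
    else:
        spreads = np.array([float(np.std(s, ddof=1)) if s.size > 1 else 0.0 for s in slopes])
    ratios = np.empty_like(spreads)
    for i in range(spreads.size):
        others = np.delete(spreads, i)
        med = float(np.median(others)) if others.size else np.nan
        ratios[i] = spreads[i] / med if med > 0 else np.inf if spreads[i] > 0 else 1.0
    return SlopeScatter(transitions, slopes, spreads, ratios, spread)
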