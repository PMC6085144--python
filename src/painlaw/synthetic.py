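"""Seeded generators for cohorts, single-subject cases and decay ensembles.

Everything downstream is testable without external data: the cohort
generator draws per-subject power-law parameters and adds per-mark Gaussian
noise; the ensemble generator averages exponential decays with gamma-drawn
rates, whose exact mixture ``(1 + b*t)**(-a)`` serves as a closed-form
oracle; the case generator emits a dose/strength history whose implied proxy
follows a known power law.

All generators are bit-reproducible under a fixed seed and return the truth
parameters alongside the data for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .case_study import DEFAULT_EQUIVALENCE, DoseRecord, StrengthRecord
from .cohort_io import Cohort, TimeSeriesRecord
from .exceptions import DomainError, ValidationError
from .powerlaw import PowerLawParams, evaluate

_MAX_REDRAWS = 1000


@dataclass
class CohortSimConfig:
    """Configuration of the cohort generator.

    Defaults emulate the reference data structure: 243 complete records on
    the 0/1/6/12-month grid, baseline pain ~5.5 NRS, a narrow exponent
    distribution centered on 0.3, and approximately constant per-mark noise
    SD of 1.9 NRS units.  ``noise_sd`` may be a scalar or a per-mark
    sequence (e.g. to inflate baseline noise only).  ``value_bounds=None``
    disables clamping (useful when recovering the injected noise SD).
    """

    n_subjects: int = 243
    time_grid: tuple[float, ...] = (0.0, 1.0, 6.0, 12.0)
    prefactor_mean: float = 5.5
    prefactor_sd: float = 1.5
    exponent_mean: float = 0.3
    exponent_sd: float = 0.1
    exponent_floor: float = 0.0
    worsener_fraction: float = 0.05
    noise_sd: float | tuple[float, ...] = 1.9
    t0: float = 1.0
    value_bounds: tuple[float, float] | None = (0.0, 10.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.time_grid = tuple(float(t) for t in self.time_grid)
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if any(b <= a for a, b in zip(self.time_grid, self.time_grid[1:])):
            raise ValidationError("time_grid must be strictly increasing")
        if not 0 <= self.worsener_fraction <= 1:
            raise ValidationError("worsener_fraction must be in [0, 1]")
        if self.t0 <= 0:
            raise ValidationError("t0 must be > 0")
        if np.any(np.asarray(self.noise_sd, dtype=float) < 0):
            raise ValidationError("noise_sd must be >= 0")

    def noise_sd_per_mark(self) -> np.ndarray:
        sd = np.asarray(self.noise_sd, dtype=float)
        if sd.ndim == 0:
            return np.full(len(self.time_grid), float(sd))
        if sd.size != len(self.time_grid):
            raise ValidationError("per-mark noise_sd length must match time_grid")
        return sd


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lower: float, size: int) -> np.ndarray:
    """Draw Normal(mean, sd) truncated below at ``lower`` by redrawing."""
    out = rng.normal(mean, sd, size)
    for _ in range(_MAX_REDRAWS):
        bad = out < lower
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
    raise ValidationError(f"truncation bound {lower} is too far into the tail of N({mean}, {sd})")


def generate_cohort(config: CohortSimConfig) -> tuple[Cohort, pd.DataFrame]:
    """Draw a noisy power-law cohort; returns (cohort, truth table).

    Per subject: prefactor ~ N(prefactor_mean, prefactor_sd) truncated > 0,
    exponent ~ N(exponent_mean, exponent_sd) truncated at exponent_floor; a
    ``worsener_fraction`` of subjects get their exponent sign flipped
    (worsening pain).  Values are the mean curve plus independent Gaussian
    noise, clamped to ``value_bounds``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    grid = np.asarray(config.time_grid)
    prefactors = _truncated_normal(rng, config.prefactor_mean, config.prefactor_sd, 1e-6, n)
    exponents = _truncated_normal(rng, config.exponent_mean, config.exponent_sd, config.exponent_floor, n)
    worsener = rng.random(n) < config.worsener_fraction
    exponents = np.where(worsener, -np.abs(exponents), exponents)
    noise = rng.normal(0.0, 1.0, (n, grid.size)) * config.noise_sd_per_mark()
    curves = prefactors[:, None] * (1.0 + grid[None, :] / config.t0) ** (-exponents[:, None])
    values = curves + noise
    if config.value_bounds is not None:
        lo, hi = config.value_bounds
        values = np.clip(values, lo, hi)
    scale = "nrs" if config.value_bounds == (0.0, 10.0) else "geometric"
    records = [
        TimeSeriesRecord(f"s{i + 1:04d}", tuple(grid), tuple(values[i]), scale)
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "prefactor": prefactors,
            "exponent": exponents,
            "worsener": worsener,
        }
    )
    return Cohort(records, tuple(grid)), truth


@dataclass
class EnsembleSimConfig:
    """Configuration of the exponential-decay ensemble generator."""

    n_elements: int
    rate_shape: float  # gamma shape a (also lognormal sigma)
    rate_scale: float  # gamma scale b, per month
    time_grid: tuple[float, ...]
    seed: int | None = None
    rate_dist: str = "gamma"  # "gamma" | "lognormal" | "uniform"

    def __post_init__(self) -> None:
        self.time_grid = tuple(float(t) for t in self.time_grid)
        if self.n_elements < 1:
            raise ValidationError("n_elements must be >= 1")
        if self.rate_shape <= 0 or self.rate_scale <= 0:
            raise ValidationError("rate_shape and rate_scale must be > 0")
        if any(t < 0 for t in self.time_grid):
            raise ValidationError("time_grid must be non-negative")
        if self.rate_dist not in ("gamma", "lognormal", "uniform"):
            raise ValidationError(f"unknown rate_dist {self.rate_dist!r}")


def aggregate_exponentials(config: EnsembleSimConfig) -> np.ndarray:
    """Mean over ensemble elements of exp(−λ t), on the configured grid.

    With gamma-distributed rates this converges to
    :func:`closed_form_aggregate` at the Monte-Carlo rate O(1/sqrt(n)).
    """
    rng = np.random.default_rng(config.seed)
    if config.rate_dist == "gamma":
        rates = rng.gamma(config.rate_shape, config.rate_scale, config.n_elements)
    elif config.rate_dist == "lognormal":
        rates = rng.lognormal(np.log(config.rate_scale), config.rate_shape, config.n_elements)
    else:
        rates = rng.uniform(0.0, config.rate_scale, config.n_elements)
    t = np.asarray(config.time_grid)
    return np.exp(-np.outer(t, rates)).mean(axis=1)


def closed_form_aggregate(a: float, b: float, t):
    """Exact gamma mixture of exponentials: ``(1 + b*t)**(-a)``.

    The asymptotic log–log slope is −a, i.e. the ensemble behaves as a power
    law with exponent equal to the rate-distribution shape.
    """
    if a <= 0 or b <= 0:
        raise DomainError("shape and scale must be > 0")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    out = (1.0 + b * t) ** (-a)
    return float(out) if out.ndim == 0 else out


@dataclass
class CrpsCaseTruth:
    """Ground truth returned by :func:`generate_crps_case`."""

    proxy_params: PowerLawParams
    strength_params: PowerLawParams
    calibration: float
    step_ratio: float


@dataclass
class CrpsCaseConfig:
    """Single-subject case generator: medication phases then a no-medication tail.

    The implied pain proxy follows ``proxy_prefactor*(1+t/t0)**(-true_P)``;
    doses are that curve times the medication's equivalence factor, with
    optional log-normal noise.  Residual NRS ratings (no-medication tail and
    the calibration anchor) come from the geometric mapping of the same
    curve.  The strength gap follows its own power law.
    """

    true_P: float = 1.7
    months: float = 30.0
    proxy_prefactor: float = 450.0
    oxycodone_end: float = 3.0
    gabapentin_end: float = 9.0
    strength_q0: float = 0.9
    strength_exponent: float = 0.8
    noise_sd: float = 0.0  # sd of log-normal multiplicative noise
    step_ratio: float = 2.0
    t0: float = 1.0
    anchor_nrs: float = 8.0  # NRS judged at the first medicated point
    equivalence: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EQUIVALENCE))
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.true_P <= 0:
            raise ValidationError("true_P must be > 0")
        if not 0 < self.oxycodone_end < self.gabapentin_end < self.months:
            raise ValidationError("phase boundaries must satisfy 0 < oxy_end < gab_end < months")


def generate_crps_case(
    config: CrpsCaseConfig | None = None,
    **overrides,
) -> tuple[list[DoseRecord], list[StrengthRecord], CrpsCaseTruth]:
    """Generate a dose history plus strength series with known power laws."""
    if config is None:
        config = CrpsCaseConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(config.seed)
    proxy = PowerLawParams(config.proxy_prefactor, config.true_P, config.t0)
    # geometric calibration: the curve at t=0 corresponds to anchor_nrs
    calibration = evaluate(proxy, 0.0) / config.step_ratio**config.anchor_nrs

    times = np.arange(0.0, config.months + 0.5)
    doses: list[DoseRecord] = []
    last_medicated_idx = None
    for t in times:
        noise = float(np.exp(rng.normal(0.0, config.noise_sd))) if config.noise_sd > 0 else 1.0
        level = evaluate(proxy, float(t)) * noise
        if t < config.oxycodone_end:
            med = "oxycodone"
        elif t < config.gabapentin_end:
            med = "gabapentin"
        else:
            med = "none"
        if med == "none":
            doses.append(DoseRecord(float(t), "none", 0.0, residual_nrs=float(np.log(level / calibration) / np.log(config.step_ratio))))
        else:
            doses.append(DoseRecord(float(t), med, level * config.equivalence[med]))
            last_medicated_idx = len(doses) - 1
    # anchor: give the last medicated point a residual NRS consistent with its dose
    if last_medicated_idx is not None:
        d = doses[last_medicated_idx]
        implied = d.daily_dose / config.equivalence[d.medication]
        doses[last_medicated_idx] = DoseRecord(
            d.time, d.medication, d.daily_dose,
            residual_nrs=float(np.log(implied / calibration) / np.log(config.step_ratio)),
        )

    strength_params = PowerLawParams(config.strength_q0, config.strength_exponent, config.t0)
    strengths: list[StrengthRecord] = []
    for t in times:
        noise = float(np.exp(rng.normal(0.0, config.noise_sd))) if config.noise_sd > 0 else 1.0
        gap = evaluate(strength_params, float(t)) * noise
        strengths.append(StrengthRecord(float(t), 1.0 - gap))

    truth = CrpsCaseTruth(proxy, strength_params, calibration, config.step_ratio)
    return doses, strengths, truth
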