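"""Power-law vs. exponential fits to the cohort mean trajectory.

The mean trajectory (per-mark mean, SD and n over complete records) is
fitted by both model families using the same log-space regressions as the
per-record fits, and goodness of fit is gauged by

    chi2 = sum_k ((mean_k - model_k) / (sd_k / sqrt(n_k)))**2

i.e. misfit weighted by the standard error of each mark's mean.  The
comparison is run in parallel on the raw NRS scale and on the geometric
scale (each value mapped through step_ratio**N before averaging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort_io import Cohort
from .exceptions import FitError, ValidationError
from .powerlaw import (
    DEFAULT_FLOOR,
    DEFAULT_STEP_RATIO,
    DEFAULT_T0,
    ExpDecayParams,
    PowerLawParams,
    floor_values,
    geometric_from_nrs,
)


@dataclass
class MeanTrajectory:
    """Per-mark summary of a cohort: mean, SD and n.

    SDs are population SDs (ddof=0) so that duplicating every record leaves
    the per-mark SD unchanged and chi-square scales exactly by 2.
    """

    time_grid: tuple[float, ...]
    means: np.ndarray
    sds: np.ndarray
    n: np.ndarray
    scale: str

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if not (self.means.size == self.sds.size == self.n.size == len(self.time_grid)):
            raise ValidationError("mean trajectory arrays misaligned with time grid")
        if np.any(self.sds < 0):
            raise ValidationError("negative SD")
        if np.any(self.n < 2):
            raise ValidationError("need n >= 2 subjects per mark (SD undefined otherwise)")

    @property
    def standard_errors(self) -> np.ndarray:
        return self.sds / np.sqrt(self.n)


def mean_trajectory(
    cohort: Cohort,
    scale: str = "nrs",
    *,
    step_ratio: float = DEFAULT_STEP_RATIO,
) -> MeanTrajectory:
    """Mean trajectory of the complete records, on the requested scale.

    ``scale="geometric"`` transforms each value record-wise by
    ``step_ratio**N`` before averaging.
    """
    if scale not in ("nrs", "geometric"):
        raise ValidationError(f"scale must be 'nrs' or 'geometric', got {scale!r}")
    matrix = cohort.complete().value_matrix()
    if scale == "geometric":
        matrix = geometric_from_nrs(matrix, step_ratio)
    if matrix.shape[0] < 2:
        raise ValidationError("need >= 2 complete records for a mean trajectory")
    return MeanTrajectory(
        time_grid=cohort.time_grid,
        means=matrix.mean(axis=0),
        sds=matrix.std(axis=0, ddof=0),
        n=np.full(matrix.shape[1], matrix.shape[0]),
        scale=scale,
    )


def fit_powerlaw_mean(
    traj: MeanTrajectory,
    *,
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
) -> PowerLawParams:
    """Log–log OLS fit of the mean trajectory (same regression as per-record fits)."""
    if len(traj.time_grid) < 2:
        raise FitError("need >= 2 marks")
    x = np.log1p(np.asarray(traj.time_grid) / t0)
    y = np.log(floor_values(traj.means, floor))
    slope, intercept = np.polyfit(x, y, 1)
    return PowerLawParams(float(np.exp(intercept)), float(-slope), t0)


def fit_exponential(traj: MeanTrajectory, *, floor: float = DEFAULT_FLOOR) -> ExpDecayParams:
    """Semi-log OLS fit: amplitude = exp(intercept), tau = −1/slope.

    A non-decreasing trajectory (slope >= 0) yields the ``tau = inf``
    sentinel.
    """
    if len(traj.time_grid) < 2:
        raise FitError("need >= 2 marks")
    t = np.asarray(traj.time_grid, dtype=float)
    y = np.log(floor_values(traj.means, floor))
    slope, intercept = np.polyfit(t, y, 1)
    tau = math.inf if slope >= 0 else -1.0 / slope
    return ExpDecayParams(float(np.exp(intercept)), float(tau))


def chi_square(traj: MeanTrajectory, model_values) -> float:
    """Standard-error-weighted chi-square of model predictions vs. the means."""
    model_values = np.asarray(model_values, dtype=float)
    if model_values.size != len(traj.time_grid):
        raise ValidationError("model values misaligned with time grid")
    se = traj.standard_errors
    if np.any(se == 0):
        raise ValidationError("zero SD at a mark: chi-square weight undefined")
    return float(np.sum(((traj.means - model_values) / se) ** 2))


@dataclass
class ModelComparisonReport:
    """Fits and chi-square values for both models on both scales."""

    per_scale: dict  # scale -> {powerlaw: {params, chi2}, exponential: {...}, ratio}

    def to_dict(self) -> dict:
        out = {}
        for scale, entry in self.per_scale.items():
            pl, ex = entry["powerlaw"], entry["exponential"]
            out[scale] = {
                "powerlaw": {
                    "prefactor": pl["params"].prefactor,
                    "exponent": pl["params"].exponent,
                    "offset": pl["params"].offset,
                    "chi2": pl["chi2"],
                },
                "exponential": {
                    "amplitude": ex["params"].amplitude,
                    "tau": ex["params"].tau,
                    "chi2": ex["chi2"],
                },
                "chi2_ratio_exp_over_powerlaw": entry["ratio"],
            }
        return out


def compare_models(
    cohort: Cohort,
    *,
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
    step_ratio: float = DEFAULT_STEP_RATIO,
    scales: tuple[str, ...] = ("nrs", "geometric"),
) -> ModelComparisonReport:
    """Fit both models on each scale and report the four chi-square values."""
    per_scale: dict = {}
    t = np.asarray(cohort.time_grid, dtype=float)
    for scale in scales:
        traj = mean_trajectory(cohort, scale, step_ratio=step_ratio)
        pl = fit_powerlaw_mean(traj, t0=t0, floor=floor)
        ex = fit_exponential(traj, floor=floor)
        chi_pl = chi_square(traj, pl(t))
        chi_ex = chi_square(traj, ex(t))
        per_scale[scale] = {
            "powerlaw": {"params": pl, "chi2": chi_pl},
            "exponential": {"params": ex, "chi2": chi_ex},
            "ratio": chi_ex / chi_pl if chi_pl > 0 else math.inf,
        }
    return ModelComparisonReport(per_scale)
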