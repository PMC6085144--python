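"""Single-subject reconstruction: dose-derived pain proxy and strength gap.

When pain is masked by titrated medication, the daily dose tracks the
underlying no-medication pain, so dose converted to a common
oxycodone-mg-equivalent serves as a pain proxy.  After medication stops,
residual NRS ratings are mapped onto the same proxy axis through the
geometric scale (``step_ratio**N``), calibrated so the series is continuous
at the medication-stop boundary.  The strength gap Q(t) = 1 − S(t), with
S(t) the affected/unaffected strength ratio, gives an independent physical
recovery trajectory.  Both series are fit-ready for the power-law core.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .cohort_io import TimeSeriesRecord
from .exceptions import ValidationError
from .powerlaw import (
    DEFAULT_FLOOR,
    DEFAULT_STEP_RATIO,
    DEFAULT_T0,
    PowerLawParams,
    fit_two_param,
    half_reduction_time,
    halving_ratio,
)

#: mg of each medication equivalent to 1 mg oxycodone.
DEFAULT_EQUIVALENCE: dict[str, float] = {"oxycodone": 1.0, "gabapentin": 300.0}


@dataclass(frozen=True)
class DoseRecord:
    """One point of a medication-dose history."""

    time: float  # months since injury
    medication: str  # "oxycodone", "gabapentin", ... or "none"
    daily_dose: float  # mg/day
    residual_nrs: float | None = None  # NRS under (or without) medication

    def __post_init__(self) -> None:
        if self.daily_dose < 0:
            raise ValidationError(f"daily_dose must be >= 0, got {self.daily_dose}")
        if self.medication == "none" and self.daily_dose != 0:
            raise ValidationError("medication 'none' implies daily_dose 0")


@dataclass(frozen=True)
class StrengthRecord:
    """Affected/unaffected strength ratio at one time."""

    time: float
    strength_ratio: float  # S(t), typically in [0, 1]

    @property
    def gap(self) -> float:
        """Q(t) = 1 − S(t)."""
        return 1.0 - self.strength_ratio


def dose_to_pain_proxy(
    doses: Sequence[DoseRecord],
    equivalence: Mapping[str, float] | None = None,
    *,
    step_ratio: float = DEFAULT_STEP_RATIO,
) -> TimeSeriesRecord:
    """Convert a dose history to a pain-proxy time series.

    Medicated points: proxy = daily_dose / equivalence[medication]
    (oxycodone-mg-equivalents).  Unmedicated points: proxy =
    C * step_ratio**residual_nrs, with C calibrated from the last medicated
    point — against its own residual NRS when recorded, otherwise against
    the first unmedicated rating — so the series has no jump at the
    medication-stop boundary.
    """
    if not doses:
        raise ValidationError("empty dose history")
    equivalence = dict(DEFAULT_EQUIVALENCE if equivalence is None else equivalence)
    doses = sorted(doses, key=lambda d: d.time)
    medicated = [d for d in doses if d.medication != "none"]
    unmedicated = [d for d in doses if d.medication == "none"]
    for d in medicated:
        if d.medication not in equivalence:
            raise ValidationError(f"unknown medication {d.medication!r}: no equivalence entry")

    def proxy_of(d: DoseRecord) -> float:
        return d.daily_dose / equivalence[d.medication]

    calibration = 1.0
    if medicated and unmedicated:
        anchor = medicated[-1]
        if anchor.residual_nrs is not None:
            ref_nrs = anchor.residual_nrs
        else:
            first = unmedicated[0]
            if first.residual_nrs is None:
                raise ValidationError(
                    "cannot calibrate unmedicated proxy: no residual NRS at the stop boundary"
                )
            ref_nrs = first.residual_nrs
        calibration = proxy_of(anchor) / step_ratio**ref_nrs

    times, values = [], []
    for d in doses:
        if d.medication != "none":
            v = proxy_of(d)
        else:
            if d.residual_nrs is None:
                raise ValidationError(f"unmedicated record at t={d.time:g} has no residual NRS")
            v = calibration * step_ratio**d.residual_nrs
        times.append(d.time)
        values.append(v)
    return TimeSeriesRecord("case", tuple(times), tuple(values), scale="dose_proxy")


def strength_gap_series(records: Sequence[StrengthRecord]) -> TimeSeriesRecord:
    """Strength-gap series Q(t), ordered by time, fit-ready."""
    if not records:
        raise ValidationError("empty strength history")
    records = sorted(records, key=lambda r: r.time)
    return TimeSeriesRecord(
        "case",
        tuple(r.time for r in records),
        tuple(r.gap for r in records),
        scale="strength_gap",
    )


@dataclass
class CaseReport:
    """Fitted trajectories for one subject plus half-reduction forecasts."""

    pain_fit: PowerLawParams
    strength_fit: PowerLawParams
    halving_ratio: float
    forecasts: dict[float, float]  # now-time -> projected half-reduction time

    def to_dict(self) -> dict:
        return {
            "pain_fit": {
                "prefactor": self.pain_fit.prefactor,
                "exponent": self.pain_fit.exponent,
                "offset": self.pain_fit.offset,
            },
            "strength_fit": {
                "prefactor": self.strength_fit.prefactor,
                "exponent": self.strength_fit.exponent,
                "offset": self.strength_fit.offset,
            },
            "halving_ratio": self.halving_ratio,
            "forecasts": {f"{t:g}": v for t, v in self.forecasts.items()},
        }


def case_report(
    pain_proxy: TimeSeriesRecord,
    strength: TimeSeriesRecord,
    *,
    now_times: Sequence[float] = (),
    t0: float = DEFAULT_T0,
    floor: float = DEFAULT_FLOOR,
    strength_floor: float = 1e-3,
) -> CaseReport:
    """Fit both series and project half-reduction times at the given "now" marks.

    The strength gap lives in [0, 1], so it gets its own (much smaller) log
    floor; the default NRS floor would flatten its tail.
    """
    pain_fit = fit_two_param(pain_proxy, t0=t0, floor=floor)
    strength_fit = fit_two_param(strength, t0=t0, floor=strength_floor)
    ratio = halving_ratio(pain_fit.exponent)
    forecasts = {float(t): half_reduction_time(t, pain_fit.exponent) for t in now_times}
    return CaseReport(pain_fit, strength_fit, ratio, forecasts)
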