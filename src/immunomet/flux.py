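"""Supernatant glucose/lactate fluxes and ELISPOT response calls.

Culture supernatant glucose falls as cells consume it and lactate rises as
glycolysis exports it; a media change (day 3 in the standard DC protocol)
resets both to the fresh-medium values, so interval fluxes must account for
the reset rather than reading a spurious negative consumption. The fraction
of consumed glucose recovered as lactate uses the glycolytic stoichiometry
of 2 lactate per glucose.

ELISPOT positivity follows the trial's rule: after subtracting the AdVLacZ
background (floored at zero), a response is positive when the
post-vaccination net count exceeds 10 spots/well and is at least twofold
over baseline (with a baseline floor of 1 net spot so the fold criterion is
defined at zero baselines).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GLUCOSE_MG_DL_PER_MM",
    "LACTATE_MG_DL_PER_MM",
    "glucose_mgdl_to_mm",
    "lactate_mgdl_to_mm",
    "SupernatantSeries",
    "interval_fluxes",
    "FluxFraction",
    "glucose_to_lactate_fraction",
    "ElispotRecord",
    "ElispotCall",
    "elispot_call",
]

# molar masses: glucose 180.16 g/mol, lactate 90.08 g/mol
GLUCOSE_MG_DL_PER_MM = 18.016
LACTATE_MG_DL_PER_MM = 9.008


def glucose_mgdl_to_mm(value: float) -> float:
    """Clinical glucose-meter units (mg/dL) to mM."""
    return value / GLUCOSE_MG_DL_PER_MM


def lactate_mgdl_to_mm(value: float) -> float:
    """Clinical lactate-meter units (mg/dL) to mM."""
    return value / LACTATE_MG_DL_PER_MM


@dataclass
class SupernatantSeries:
    """Glucose/lactate concentrations over culture days with media changes.

    ``media_changes`` lists ``(day, fresh_glucose_mM, fresh_lactate_mM)``;
    a change between two observations resets the interval's starting
    concentrations to the fresh-medium values (the observation that opens
    the interval is read before the change).
    """

    sample_id: str
    days: np.ndarray
    glucose: np.ndarray  # mM
    lactate: np.ndarray  # mM
    media_changes: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.glucose = np.asarray(self.glucose, dtype=float)
        self.lactate = np.asarray(self.lactate, dtype=float)
        if not (self.days.size == self.glucose.size == self.lactate.size):
            raise ValueError("days, glucose and lactate must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.glucose < 0) or np.any(self.lactate < 0):
            raise ValueError("concentrations must be non-negative")
        changes = []
        for entry in self.media_changes:
            if len(entry) != 3:
                raise ValueError(
                    "media change must be (day, fresh_glucose_mM, fresh_lactate_mM); "
                    "a change with unspecified fresh glucose cannot be interpreted"
                )
            day, fg, fl = (float(v) for v in entry)
            if not np.isfinite(fg):
                raise ValueError(f"media change at day {day}: fresh glucose unspecified")
            if not (self.days[0] <= day < self.days[-1]):
                raise ValueError(
                    f"media change at day {day} outside the observation span"
                )
            changes.append((day, fg, fl))
        self.media_changes = tuple(sorted(changes))


def interval_fluxes(series: SupernatantSeries) -> pd.DataFrame:
    """Per-interval glucose consumption and lactate production (mM).

    For the interval between consecutive observations i → i+1,
    ``glucose_consumed = start − end`` where *start* is the observed
    concentration at day i unless a media change falls in [day_i, day_{i+1})
    — then the fresh-medium concentration. Lactate production is the sign-
    reversed analogue. Totals are the column sums; fluxes are additive when
    adjacent change-free intervals are merged.
    """
    rows = []
    for i in range(series.days.size - 1):
        d0, d1 = series.days[i], series.days[i + 1]
        g_start, l_start = series.glucose[i], series.lactate[i]
        reset = False
        for day, fg, fl in series.media_changes:
            if d0 <= day < d1:
                g_start, l_start = fg, fl
                reset = True
        rows.append(
            {
                "sample_id": series.sample_id,
                "day_start": d0,
                "day_end": d1,
                "media_change": reset,
                "glucose_consumed": g_start - series.glucose[i + 1],
                "lactate_produced": series.lactate[i + 1] - l_start,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class FluxFraction:
    """Glucose→lactate conversion under 2:1 stoichiometry, plus the raw ratio."""

    fraction_stoich: float  # lactate / (2 * glucose), glycolytic yield
    ratio_raw: float  # lactate / glucose, convention-free export
    qc_flag: str = ""

    @property
    def computable(self) -> bool:
        return np.isfinite(self.fraction_stoich)


def glucose_to_lactate_fraction(
    glucose_consumed: float, lactate_produced: float
) -> FluxFraction:
    """Fraction of consumed glucose recovered as secreted lactate.

    Glycolysis yields 2 lactate per glucose, so full conversion gives
    fraction 1. Values above 1 indicate an exogenous lactate source or
    measurement error and are returned with a QC flag, not clipped.
    Non-positive consumption makes the fraction not-computable (NaN).
    """
    if glucose_consumed <= 0:
        return FluxFraction(float("nan"), float("nan"), "non-positive glucose consumption")
    frac = lactate_produced / (2.0 * glucose_consumed)
    flag = "" if frac <= 1 else "stoichiometric excess (fraction > 1)"
    return FluxFraction(frac, lactate_produced / glucose_consumed, flag)


@dataclass(frozen=True)
class ElispotRecord:
    """Spot counts for one patient, antigen, timepoint and T-cell compartment."""

    patient: str
    antigen: str  # Tyrosinase | MART-1 | MAGE-A6
    timepoint: str  # baseline | post
    spots_antigen: int
    spots_advlacz: int
    compartment: str = "CD8"  # CD8 | CD4

    def __post_init__(self) -> None:
        if self.spots_antigen < 0 or self.spots_advlacz < 0:
            raise ValueError("spot counts must be non-negative")

    @property
    def net(self) -> int:
        """Background-subtracted response, floored at zero."""
        return max(self.spots_antigen - self.spots_advlacz, 0)


@dataclass
class ElispotCall:
    patient: str
    antigen: str
    compartment: str
    net_baseline: int
    net_post: int
    positive: bool


def elispot_call(
    baseline: ElispotRecord,
    post: ElispotRecord,
    min_spots: int = 10,
    min_fold: float = 2.0,
) -> ElispotCall:
    """Positive-response call for a matched baseline/post ELISPOT pair.

    Positive iff net post > ``min_spots`` AND
    net post ≥ ``min_fold`` × max(net baseline, 1). The baseline floor of 1
    net spot keeps the fold criterion defined when the baseline is zero.
    The call is monotone in the post net count with all else fixed.
    """
    if (baseline.patient, baseline.antigen, baseline.compartment) != (
        post.patient,
        post.antigen,
        post.compartment,
    ):
        raise ValueError(
            "baseline and post records must match on patient, antigen and compartment"
        )
    if baseline.timepoint != "baseline" or post.timepoint != "post":
        raise ValueError("records must be a (baseline, post) pair in that order")
    net_base, net_post = baseline.net, post.net
    positive = net_post > min_spots and net_post >= min_fold * max(net_base, 1)
    return ElispotCall(
        baseline.patient, baseline.antigen, baseline.compartment, net_base, net_post, positive
    )
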