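"""Seeded synthetic cohorts with the statistical structure of a DC-vaccine study.

The generator emulates, per patient sample: per-cell log-normal puromycin
intensities whose condition medians follow the inhibitor-suppression model
``median_i = C · (1 − d_i · (1 − b))`` (``d_i`` the ground-truth dependence
for inhibitor *i*, ``d_DGO = 1``, ``b`` a residual background fraction);
immune-marker intensities coupled to a per-cell latent glycolytic score that
also modulates translation under oligomycin; Seahorse plateau segments with
Gaussian noise; piecewise supernatant glucose decline / lactate rise with a
day-3 media change; and exponential proportional-hazards survival with
independent censoring. Group defaults mirror the study conditions: 13
good-outcome and 17 bad-outcome patients, mitochondrial dependence ≈ 84.4%
(good) vs 76.4% (bad), glutaminolysis ~7 points lower in the bad group,
25 mM glucose medium.

Every output is a pure function of (config, seed): the master seed is split
into named sub-streams (cells / traces / flux / survival) so adding one
generator never shifts another's stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cytometry import CONDITIONS, PUROMYCIN, EventTable
from .scenith import InhibitorPanelSummary
from .seahorse import SeahorseTrace

__all__ = [
    "MarkerSpec",
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_cell_events",
    "panel_from_events",
    "generate_seahorse_trace",
    "generate_supernatant_table",
    "generate_survival_cohort",
    "generate_cohort",
    "simulate_ph_data",
]

_STREAMS = {"cells": 1, "traces": 2, "flux": 3, "survival": 4}


def _rng(seed: int, stream: str, key: str = "") -> np.random.Generator:
    """Deterministic named sub-stream: pure function of (seed, stream, key)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], zlib.crc32(key.encode())])
    )


@dataclass(frozen=True)
class MarkerSpec:
    """Log-normal marker model: log-mean ``log(base) + coupling · z`` with the
    per-cell latent glycolytic score z ~ N(0, 1)."""

    base: float
    coupling: float
    sigma: float = 0.3


def _default_markers() -> dict[str, MarkerSpec]:
    # couplings chosen so glycolytic cells over-express activation/checkpoint
    # markers (the pattern the mDC quantile analysis probes); one marker is
    # anti-coupled as a negative control
    return {
        "HLA-DR": MarkerSpec(800.0, 0.45),
        "CD86": MarkerSpec(600.0, 0.35),
        "CD40": MarkerSpec(300.0, 0.25),
        "ILT3": MarkerSpec(200.0, 0.30),
        "pAMPK": MarkerSpec(400.0, -0.30),
    }


def _default_dependence() -> dict[str, dict[str, float]]:
    return {
        "good": {"glucose": 0.38, "mito": 0.844, "fao": 0.30, "glut": 0.32},
        "bad": {"glucose": 0.46, "mito": 0.764, "fao": 0.26, "glut": 0.25},
    }


def _default_seahorse() -> dict[str, dict[str, float]]:
    # plateau means, pmol O2/min (OCR) and mpH/min (ECAR); bad group shows
    # lower maximal OCR, higher proton leak and higher glycolysis
    return {
        "good": {
            "ocr_pre": 100.0, "ocr_post_oligo": 30.0, "ocr_post_fccp": 160.0,
            "ocr_post_ra": 10.0, "ecar_pre": 30.0, "ecar_post_oligo": 45.0,
            "ecar_post_fccp": 45.0, "ecar_post_ra": 5.0,
        },
        "bad": {
            "ocr_pre": 95.0, "ocr_post_oligo": 42.0, "ocr_post_fccp": 125.0,
            "ocr_post_ra": 10.0, "ecar_pre": 42.0, "ecar_post_oligo": 62.0,
            "ecar_post_fccp": 62.0, "ecar_post_ra": 5.0,
        },
    }


def _default_supernatant() -> dict[str, dict[str, float]]:
    # mM/day; bad group consumes glucose and exports lactate faster
    return {
        "good": {"glucose_per_day": 1.6, "lactate_per_day": 2.4},
        "bad": {"glucose_per_day": 2.4, "lactate_per_day": 3.8},
    }


@dataclass
class SyntheticCohortConfig:
    """Ground truth and noise model for one synthetic cohort."""

    seed: int
    n_patients: dict[str, int] = field(default_factory=lambda: {"good": 13, "bad": 17})
    cells_per_condition: int = 1000
    dependence: dict[str, dict[str, float]] = field(default_factory=_default_dependence)
    control_mean: float = 1000.0  # control-condition puromycin median (MFI)
    noise_sigma: float = 0.35  # log-normal sigma of per-cell puromycin
    background_fraction: float = 0.05  # DGO residual translation fraction b
    sample_sigma: float = 0.02  # between-sample jitter of dependence values
    latent_effect: float = 0.6  # latent-score effect on oligomycin translation
    markers: dict[str, MarkerSpec] = field(default_factory=_default_markers)
    include_harringtonine: bool = True
    seahorse_means: dict[str, dict[str, float]] = field(default_factory=_default_seahorse)
    seahorse_noise_sd: float = 5.0
    seahorse_points_per_segment: int = 3
    seahorse_interval_min: float = 30.0
    seahorse_fao_delta: float = 40.0  # control-minus-palm/eto post-FCCP OCR
    supernatant_rates: dict[str, dict[str, float]] = field(default_factory=_default_supernatant)
    supernatant_days: tuple[float, ...] = (0.0, 3.0, 5.0, 6.0)
    media_change_day: float = 3.0
    fresh_glucose: float = 25.0  # mM, the culture medium's glucose
    supernatant_noise_sd: float = 0.15  # mM meter noise
    baseline_hazard: float = 1.0 / 18.0  # events/month for the reference group
    hr_high_mito: float = 0.45  # hazard ratio, high vs low mitochondrial dependence
    mito_threshold: float = 80.0  # percent; "high" group above this
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory (no implicit entropy)")
        for group, deps in self.dependence.items():
            for name, d in deps.items():
                if not 0.0 <= d <= 1.0:
                    raise ValueError(f"dependence {group}/{name}={d} outside [0, 1]")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background fraction must lie in [0, 1)")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring rate must lie in [0, 1]")
        if self.hr_high_mito <= 0:
            raise ValueError("hazard ratio must be positive")
        if self.noise_sigma < 0 or self.seahorse_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.cells_per_condition < 1:
            raise ValueError("cells_per_condition must be >= 1")

    def sample_ids(self, group: str) -> list[str]:
        return [f"{group}_{i + 1:02d}" for i in range(self.n_patients[group])]


# ----------------------------------------------------------------- cell events


_CONDITION_DEPENDENCE = {"C": None, "2DG": "glucose", "O": "mito", "Eto": "fao",
                         "Tele": "glut", "DGO": None, "H": None}


def generate_cell_events(
    config: SyntheticCohortConfig, group: str, sample_id: str
) -> EventTable:
    """Per-cell events for one sample across every inhibitor condition.

    Condition medians follow ``C · (1 − d_i (1 − b))``; per-cell puromycin is
    log-normal around the condition median. Under oligomycin the per-cell
    latent glycolytic score shifts the log-intensity (median-preserving), so
    glycolytic cells retain translation; marker intensities couple to the
    same score.
    """
    if group not in config.dependence:
        raise ValueError(f"unknown group {group!r}")
    rng = _rng(config.seed, "cells", f"{group}/{sample_id}")
    deps = dict(config.dependence[group])
    if config.sample_sigma > 0:
        for name in deps:
            deps[name] = float(
                np.clip(deps[name] + rng.normal(0.0, config.sample_sigma), 0.0, 1.0)
            )
    b = config.background_fraction
    c0 = config.control_mean
    n = config.cells_per_condition
    conditions = [c for c in CONDITIONS if config.include_harringtonine or c != "H"]
    frames = []
    for cond in conditions:
        dep_name = _CONDITION_DEPENDENCE[cond]
        if cond == "C":
            median = c0
        elif cond == "DGO":
            median = c0 * b
        elif cond == "H":
            median = c0 * b * 0.8  # arrest floor sits below every inhibitor
        else:
            median = c0 * (1.0 - deps[dep_name] * (1.0 - b))
        median = max(median, 1e-6)
        z = rng.normal(0.0, 1.0, size=n)
        log_mu = np.log(median) * np.ones(n)
        if cond == "O":
            log_mu = log_mu + config.latent_effect * z
        puro = np.exp(log_mu + rng.normal(0.0, config.noise_sigma, size=n))
        cols: dict[str, np.ndarray | str | bool] = {PUROMYCIN: puro}
        for marker, spec in config.markers.items():
            cols[marker] = np.exp(
                np.log(spec.base) + spec.coupling * z + rng.normal(0.0, spec.sigma, size=n)
            )
        frame = pd.DataFrame(cols)
        frame["sample_id"] = sample_id
        frame["population"] = "mDC"
        frame["condition"] = cond
        frame["viability_pass"] = True
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    channels = (PUROMYCIN, *config.markers.keys())
    return EventTable(data, channels)


def panel_from_events(events: EventTable) -> InhibitorPanelSummary:
    """Reduce one sample's events to the per-condition median puromycin panel."""
    grouped = events.data.groupby("condition", observed=True)[PUROMYCIN]
    mfi = {str(c): float(v) for c, v in grouped.median().items()}
    n_cells = {str(c): int(v) for c, v in grouped.size().items()}
    sample_id = str(events.data["sample_id"].iloc[0])
    population = str(events.data["population"].iloc[0])
    return InhibitorPanelSummary(sample_id, population, mfi, n_cells)


# -------------------------------------------------------------- Seahorse traces


def generate_seahorse_trace(
    config: SyntheticCohortConfig,
    group: str,
    well: str = "A1",
    condition: str = "control",
    noise_sd: float | None = None,
) -> SeahorseTrace:
    """One mito-stress-test trace: four plateau segments plus Gaussian noise.

    ``condition="palmitate+etomoxir"`` lowers the post-FCCP OCR plateau by
    the configured exogenous-FAO delta. With ``noise_sd=0`` the segment
    plateaus are exact, so the index computation closes the loop on the
    configured values.
    """
    if group not in config.seahorse_means:
        raise ValueError(f"unknown group {group!r}")
    means = dict(config.seahorse_means[group])
    if condition == "palmitate+etomoxir":
        means["ocr_post_fccp"] = means["ocr_post_fccp"] - config.seahorse_fao_delta
    elif condition not in ("control", "palmitate", "BSA-control"):
        raise ValueError(f"unknown trace condition {condition!r}")
    sd = config.seahorse_noise_sd if noise_sd is None else noise_sd
    rng = _rng(config.seed, "traces", f"{group}/{well}/{condition}")
    k = config.seahorse_points_per_segment
    dt = config.seahorse_interval_min
    times = np.arange(4 * k) * dt
    # injections half an interval after the last point of each segment
    injections = (
        ("oligomycin", times[k - 1] + dt / 2),
        ("FCCP", times[2 * k - 1] + dt / 2),
        ("rotenone/antimycinA", times[3 * k - 1] + dt / 2),
    )
    ocr_means = np.repeat(
        [means["ocr_pre"], means["ocr_post_oligo"], means["ocr_post_fccp"], means["ocr_post_ra"]], k
    )
    ecar_means = np.repeat(
        [means["ecar_pre"], means["ecar_post_oligo"], means["ecar_post_fccp"], means["ecar_post_ra"]], k
    )
    ocr = ocr_means + (rng.normal(0.0, sd, size=times.size) if sd > 0 else 0.0)
    ecar = ecar_means + (rng.normal(0.0, sd / 2, size=times.size) if sd > 0 else 0.0)
    return SeahorseTrace(well, condition, times, ocr, ecar, injections)


# ------------------------------------------------------------------ supernatant


def generate_supernatant_table(
    config: SyntheticCohortConfig, group: str, sample_id: str
) -> pd.DataFrame:
    """Supernatant glucose/lactate readings over the culture days.

    Glucose declines and lactate rises linearly at the group's rates; the
    day-``media_change_day`` reading is taken before fresh medium is added,
    after which glucose resets to the fresh concentration and lactate to 0.
    """
    rates = config.supernatant_rates[group]
    rng = _rng(config.seed, "flux", f"{group}/{sample_id}")
    days = np.asarray(config.supernatant_days, dtype=float)
    glucose = np.empty(days.size)
    lactate = np.empty(days.size)
    g, l = config.fresh_glucose, 0.0
    prev_day = days[0]
    changed = False
    for i, day in enumerate(days):
        span = day - prev_day
        g = g - rates["glucose_per_day"] * span
        l = l + rates["lactate_per_day"] * span
        glucose[i], lactate[i] = g, l
        if not changed and day >= config.media_change_day:
            # reading precedes the change; state resets afterwards
            g, l = config.fresh_glucose, 0.0
            changed = True
        prev_day = day
    if config.supernatant_noise_sd > 0:
        glucose = glucose + rng.normal(0.0, config.supernatant_noise_sd, size=days.size)
        lactate = lactate + rng.normal(0.0, config.supernatant_noise_sd, size=days.size)
    glucose = np.clip(glucose, 0.0, None)
    lactate = np.clip(lactate, 0.0, None)
    return pd.DataFrame(
        {"sample_id": sample_id, "day": days, "glucose_mM": glucose, "lactate_mM": lactate}
    )


# --------------------------------------------------------------------- survival


def generate_survival_cohort(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Per-patient survival records under an exponential proportional-hazards model.

    Each patient's mitochondrial dependence (percent) is drawn around the
    group truth; patients above ``mito_threshold`` have their hazard
    multiplied by ``hr_high_mito`` (< 1: protective, matching higher
    mitochondrial dependence → longer survival). Censoring is independent
    exponential tuned to the target rate; ``censoring_rate=1`` censors
    everyone.
    """
    rng = _rng(config.seed, "survival", "cohort")
    rows = []
    for group in config.n_patients:
        m_truth = 100.0 * config.dependence[group]["mito"]
        for sample_id in config.sample_ids(group):
            mito = float(np.clip(rng.normal(m_truth, 5.0), 0.0, 100.0))
            lam = config.baseline_hazard * (
                config.hr_high_mito if mito > config.mito_threshold else 1.0
            )
            t_event = rng.exponential(1.0 / lam)
            t_pfs_event = min(rng.exponential(1.0 / (1.5 * lam)), t_event)
            if config.censoring_rate >= 1.0:
                t_cens = rng.exponential(1.0 / lam)
                os_months, os_event = t_cens, 0
                pfs_months, pfs_event = t_cens, 0
            elif config.censoring_rate <= 0.0:
                os_months, os_event = t_event, 1
                pfs_months, pfs_event = t_pfs_event, 1
            else:
                mu = lam * config.censoring_rate / (1.0 - config.censoring_rate)
                t_cens = rng.exponential(1.0 / mu)
                os_months, os_event = min(t_event, t_cens), int(t_event <= t_cens)
                pfs_months, pfs_event = min(t_pfs_event, t_cens), int(t_pfs_event <= t_cens)
            lactate = float(
                max(
                    rng.normal(
                        config.supernatant_rates[group]["lactate_per_day"] * 3.0, 1.0
                    ),
                    0.0,
                )
            )
            rows.append(
                {
                    "patient": sample_id,
                    "os_months": os_months,
                    "os_event": os_event,
                    "pfs_months": pfs_months,
                    "pfs_event": pfs_event,
                    "outcome_group": group,
                    "mitochondrial_dependence": mito,
                    "idc_lactate": lactate,
                }
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- full cohort


@dataclass
class SyntheticCohort:
    config: SyntheticCohortConfig
    events: dict[str, EventTable]  # sample_id → events (all conditions)
    panels: list[InhibitorPanelSummary]
    seahorse: dict[str, tuple[SeahorseTrace, SeahorseTrace]]  # control, palm+eto
    supernatant: dict[str, pd.DataFrame]
    survival: pd.DataFrame
    sample_groups: dict[str, str]


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate every data kind for the full cohort (pure in config + seed)."""
    events: dict[str, EventTable] = {}
    panels: list[InhibitorPanelSummary] = []
    traces: dict[str, tuple[SeahorseTrace, SeahorseTrace]] = {}
    supernatant: dict[str, pd.DataFrame] = {}
    sample_groups: dict[str, str] = {}
    for group in config.n_patients:
        for sample_id in config.sample_ids(group):
            table = generate_cell_events(config, group, sample_id)
            events[sample_id] = table
            panels.append(panel_from_events(table))
            traces[sample_id] = (
                generate_seahorse_trace(config, group, well=sample_id, condition="control"),
                generate_seahorse_trace(
                    config, group, well=sample_id, condition="palmitate+etomoxir"
                ),
            )
            supernatant[sample_id] = generate_supernatant_table(config, group, sample_id)
            sample_groups[sample_id] = group
    survival = generate_survival_cohort(config)
    return SyntheticCohort(config, events, panels, traces, supernatant, survival, sample_groups)


# ----------------------------------------------------- standalone PH simulator


def simulate_ph_data(
    n: int,
    hazard_ratio: float,
    censoring_rate: float = 0.2,
    baseline_hazard: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Exponential proportional-hazards data with a balanced binary covariate.

    Used for parameter-recovery checks: subjects with ``x = 1`` have hazard
    ``baseline_hazard × hazard_ratio``; censoring is independent exponential
    tuned so roughly ``censoring_rate`` of subjects are censored.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 97]))
    x = rng.integers(0, 2, size=n)
    lam = baseline_hazard * np.power(hazard_ratio, x)
    t_event = rng.exponential(1.0 / lam)
    if censoring_rate <= 0:
        return pd.DataFrame({"time": t_event, "event": 1, "x": x})
    mu = lam * censoring_rate / max(1.0 - censoring_rate, 1e-12)
    t_cens = rng.exponential(1.0 / mu)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event, "x": x})
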