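"""SCENITH metabolic-dependence parameters from inhibitor-panel puromycin MFIs.

SCENITH infers which fuel pathways a cell population relies on by measuring
how much protein synthesis (puromycin incorporation) survives a short
treatment with pathway inhibitors. With median puromycin MFIs per condition
— C (control/DMSO), 2DG (2-deoxy-glucose), O (oligomycin), Eto (etomoxir),
Tele (CB-839), DGO (2DG + oligomycin) — the percent-scale parameters are

    glucose dependence        = 100 (C − 2DG)  / (C − DGO)
    mitochondrial dependence  = 100 (C − O)    / (C − DGO)
    FAO dependence            = 100 (C − Eto)  / (C − DGO)
    glutaminolysis dependence = 100 (C − Tele) / (C − DGO)
    glycolytic capacity       = 100 − mitochondrial dependence
    FAAO capacity             = 100 − glucose dependence

The DGO condition anchors full suppression, so C − DGO is the assay's
dynamic range and must be positive. Harringtonine (H) arrests translation
outright; it enters no formula and serves only as a QC anchor (its MFI
should not exceed any other condition's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ScenithError",
    "InhibitorPanelSummary",
    "QCReport",
    "MetabolicProfile",
    "validate_panel",
    "compute_scenith_profile",
    "profile_cohort",
    "panels_from_table",
    "DEPENDENCE_CONDITIONS",
]

logger = logging.getLogger(__name__)

#: condition → name of the dependence parameter it determines
DEPENDENCE_CONDITIONS = {
    "2DG": "glucose_dependence",
    "O": "mitochondrial_dependence",
    "Eto": "fao_dependence",
    "Tele": "glutaminolysis_dependence",
}

_MANDATORY = ("C", "2DG", "O", "DGO")


class ScenithError(ValueError):
    """Raised when a panel cannot support the percent parameters."""


@dataclass(frozen=True)
class InhibitorPanelSummary:
    """Median puromycin MFI per inhibitor condition for one (sample, population)."""

    sample_id: str
    population: str
    mfi: Mapping[str, float]
    n_cells: Mapping[str, int] | None = None

    def __post_init__(self) -> None:
        for cond, value in self.mfi.items():
            if value < 0 or not np.isfinite(value):
                raise ScenithError(
                    f"{self.sample_id}/{self.population}: MFI for {cond} is {value}; "
                    "must be finite and non-negative"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.population)


@dataclass
class QCReport:
    flags: set[str] = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return not self.flags


@dataclass
class MetabolicProfile:
    """Percent-scale SCENITH parameters, clamped to [0, 100], with raw values kept."""

    sample_id: str
    population: str
    values: dict[str, float]
    raw: dict[str, float]
    qc_flags: set[str] = field(default_factory=set)

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {"sample_id": self.sample_id, "population": self.population}
        row.update(self.values)
        row.update({f"raw_{k}": v for k, v in self.raw.items()})
        row["qc_flags"] = ";".join(sorted(self.qc_flags))
        return row


def validate_panel(panel: InhibitorPanelSummary, min_dynamic_range: float = 0.2) -> QCReport:
    """Guard the shared denominator C − DGO and note missing optional inhibitors.

    Flags ``low_dynamic_range`` when the suppressible fraction (C − DGO)/C
    falls below ``min_dynamic_range`` and ``missing_inhibitor`` when Eto or
    Tele is absent (their parameters are then reported missing, not zero).
    Raises :class:`ScenithError` when C ≤ DGO: with no translation dynamic
    range every parameter's denominator is non-positive.
    """
    missing = [c for c in _MANDATORY if c not in panel.mfi]
    if missing:
        raise ScenithError(
            f"{panel.sample_id}/{panel.population}: mandatory conditions missing: {missing}"
        )
    c, dgo = panel.mfi["C"], panel.mfi["DGO"]
    if c <= dgo:
        raise ScenithError(
            f"{panel.sample_id}/{panel.population}: no translation dynamic range "
            f"(C={c} <= DGO={dgo})"
        )
    report = QCReport()
    if (c - dgo) / c < min_dynamic_range:
        report.flags.add("low_dynamic_range")
    if "Eto" not in panel.mfi or "Tele" not in panel.mfi:
        report.flags.add("missing_inhibitor")
    if "H" in panel.mfi:
        others = [v for k, v in panel.mfi.items() if k != "H"]
        if panel.mfi["H"] > min(others):
            logger.warning(
                "%s/%s: harringtonine MFI %.3g exceeds another condition's MFI; "
                "translation-arrest anchor looks unreliable",
                panel.sample_id,
                panel.population,
                panel.mfi["H"],
            )
            report.flags.add("harringtonine_above_floor")
    return report


def compute_scenith_profile(
    panel: InhibitorPanelSummary,
    clamp: bool = True,
    min_dynamic_range: float = 0.2,
) -> MetabolicProfile:
    """Compute the six percent parameters for one panel.

    Raw (unclamped) dependencies are always retained; when ``clamp`` is on,
    dependencies are truncated to [0, 100] (with ``clamped_low`` /
    ``clamped_high`` flags) and the two capacities recomputed from the
    clamped dependencies so the complement identities hold exactly.
    """
    qc = validate_panel(panel, min_dynamic_range=min_dynamic_range)
    c, dgo = panel.mfi["C"], panel.mfi["DGO"]
    denom = c - dgo

    raw: dict[str, float] = {}
    for cond, name in DEPENDENCE_CONDITIONS.items():
        if cond in panel.mfi:
            raw[name] = 100.0 * (c - panel.mfi[cond]) / denom
        else:
            raw[name] = float("nan")
    raw["glycolytic_capacity"] = 100.0 - raw["mitochondrial_dependence"]
    raw["faao_capacity"] = 100.0 - raw["glucose_dependence"]

    flags = set(qc.flags)
    values: dict[str, float] = {}
    for name in DEPENDENCE_CONDITIONS.values():
        v = raw[name]
        if np.isnan(v):
            values[name] = v
            continue
        if clamp and v < 0:
            flags.add("clamped_low")
            v = 0.0
        elif clamp and v > 100:
            flags.add("clamped_high")
            v = 100.0
        values[name] = v
    values["glycolytic_capacity"] = 100.0 - values["mitochondrial_dependence"]
    values["faao_capacity"] = 100.0 - values["glucose_dependence"]
    return MetabolicProfile(panel.sample_id, panel.population, values, raw, flags)


def profile_cohort(
    panels: Iterable[InhibitorPanelSummary],
    clamp: bool = True,
    min_dynamic_range: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Profile a batch of panels; per-key failures are recorded, not fatal.

    Returns ``(profiles, failures)`` — one profile row per valid
    (sample, population) key and one failure row per panel that raised.
    """
    rows: list[dict[str, object]] = []
    failures: list[dict[str, str]] = []
    flag_counts: dict[str, int] = {}
    for panel in panels:
        try:
            profile = compute_scenith_profile(
                panel, clamp=clamp, min_dynamic_range=min_dynamic_range
            )
        except ScenithError as exc:
            failures.append(
                {"sample_id": panel.sample_id, "population": panel.population, "error": str(exc)}
            )
            continue
        for flag in profile.qc_flags:
            flag_counts[flag] = flag_counts.get(flag, 0) + 1
        rows.append(profile.as_row())
    if not rows and not failures:
        logger.warning("profile_cohort called with no panels")
    if flag_counts:
        logger.info("QC flag summary: %s", flag_counts)
    profiles = pd.DataFrame(rows)
    return profiles, pd.DataFrame(failures, columns=["sample_id", "population", "error"])


def panels_from_table(medians: pd.DataFrame) -> list[InhibitorPanelSummary]:
    """Build panels from a tidy median table.

    Expects columns ``sample_id, population, condition, median_puromycin``
    and optionally ``n_cells`` — the layout :func:`population_median` emits
    (rename its statistic column) and the interchange CSV uses.
    """
    required = {"sample_id", "population", "condition", "median_puromycin"}
    missing = required - set(medians.columns)
    if missing:
        raise ScenithError(f"median table missing columns {sorted(missing)}")
    panels = []
    for (sample_id, population), grp in medians.groupby(
        ["sample_id", "population"], observed=True, sort=True
    ):
        mfi = dict(zip(grp["condition"], grp["median_puromycin"].astype(float)))
        n_cells = (
            dict(zip(grp["condition"], grp["n_cells"].astype(int)))
            if "n_cells" in grp.columns
            else None
        )
        panels.append(InhibitorPanelSummary(str(sample_id), str(population), mfi, n_cells))
    return panels
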