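"""Single-cell cytometry ingestion, transforms, gating and summaries.

Event data arrive either as FCS files (one acquisition per file) or as tidy
CSV tables with one row per cell. Channels are addressed through a
``channel_map`` from panel names (e.g. ``"puromycin"``) to the names used in
the file, so panel renames between batches never touch analysis code.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fcs import read_fcs, write_fcs

__all__ = [
    "CONDITIONS",
    "PUROMYCIN",
    "EventTable",
    "GateSpec",
    "read_events",
    "write_events_fcs",
    "arcsinh_transform",
    "inverse_arcsinh_transform",
    "apply_gates",
    "population_median",
]

#: Closed vocabulary of SCENITH inhibitor conditions: control (DMSO),
#: 2-deoxy-glucose, oligomycin, etomoxir, CB-839 (telaglenastat), the
#: 2DG+oligomycin combination, and harringtonine (translation-arrest anchor).
CONDITIONS = ("C", "2DG", "O", "Eto", "Tele", "DGO", "H")

#: Canonical panel name of the anti-puromycin channel (translation readout).
PUROMYCIN = "puromycin"

_META_COLUMNS = ("sample_id", "population", "condition", "viability_pass")


@dataclass
class EventTable:
    """Per-cell intensities plus acquisition annotations.

    ``data`` holds one row per cell with the metadata columns
    ``sample_id``, ``population``, ``condition``, ``viability_pass`` and one
    column per channel; ``channels`` lists the channel columns in panel
    naming.
    """

    data: pd.DataFrame
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicated channel names in EventTable")
        missing = [c for c in self.channels if c not in self.data.columns]
        if missing:
            raise ValueError(f"channels absent from data: {missing}")
        for col, default in zip(_META_COLUMNS, ("sample", "all", "C", True)):
            if col not in self.data.columns:
                self.data[col] = default
        bad = set(self.data["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(
                f"unknown inhibitor condition labels {sorted(bad)}; "
                f"allowed: {CONDITIONS}"
            )
        if PUROMYCIN in self.channels:
            puro = self.data[PUROMYCIN].to_numpy(dtype=float)
            if not np.all(np.isfinite(puro)):
                raise ValueError("non-finite puromycin intensities in EventTable")

    def __len__(self) -> int:
        return len(self.data)

    def intensities(self, channel: str) -> np.ndarray:
        if channel not in self.channels:
            raise KeyError(f"channel {channel!r} not in table (has {self.channels})")
        return self.data[channel].to_numpy(dtype=float)

    def subset(self, mask: np.ndarray) -> "EventTable":
        return EventTable(self.data.loc[mask].reset_index(drop=True), self.channels)

    def restrict_condition(self, condition: str) -> "EventTable":
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        mask = (self.data["condition"] == condition).to_numpy()
        return self.subset(mask)


@dataclass
class GateSpec:
    """Ordered conjunction of rectangular threshold gates.

    Each gate is ``(channel, lower, upper)`` with open bounds expressed as
    ``-inf`` / ``+inf``; a cell passes when it lies inside every rectangle
    (bounds inclusive) and passed viability. Mirrors manual polarity gating
    such as CD14− HLA-DR+ CD86+ for mature monocyte-derived DC.
    """

    gates: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self) -> None:
        norm = []
        for channel, lo, hi in self.gates:
            lo = float(lo) if lo is not None else -np.inf
            hi = float(hi) if hi is not None else np.inf
            if not lo < hi:
                raise ValueError(f"gate on {channel!r}: lower {lo} !< upper {hi}")
            norm.append((str(channel), lo, hi))
        self.gates = tuple(norm)

    @classmethod
    def from_dict(cls, spec: Mapping[str, Mapping[str, float]]) -> "GateSpec":
        """Build from ``{channel: {"lower": x, "upper": y}}`` (either bound optional)."""
        gates = []
        for channel, bounds in spec.items():
            gates.append(
                (channel, bounds.get("lower", -np.inf), bounds.get("upper", np.inf))
            )
        return cls(tuple(gates))


def read_events(
    path: str | Path,
    format: str = "tabular",
    channel_map: Mapping[str, str] | None = None,
    sample_id: str | None = None,
) -> EventTable:
    """Read one acquisition into an :class:`EventTable`.

    ``channel_map`` maps panel names to the channel/column names in the file
    and must cover the puromycin channel; file channels not in the map are
    preserved verbatim. ``format`` is ``"tabular"`` (CSV, one row per cell,
    header row) or ``"fcs"``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    channel_map = dict(channel_map or {PUROMYCIN: PUROMYCIN})
    if PUROMYCIN not in channel_map:
        raise ValueError(
            f"channel_map must map the {PUROMYCIN!r} panel channel to a file channel"
        )
    if format == "tabular":
        raw = pd.read_csv(path)
    elif format == "fcs":
        _, raw = read_fcs(path)
    else:
        raise ValueError(f"unknown format {format!r}; use 'tabular' or 'fcs'")

    missing_src = channel_map[PUROMYCIN]
    if missing_src not in raw.columns:
        raise ValueError(
            f"puromycin channel {missing_src!r} not present in {path.name}; "
            f"available: {list(raw.columns)}"
        )
    rename = {src: panel for panel, src in channel_map.items() if src in raw.columns}
    raw = raw.rename(columns=rename)
    channels = [c for c in raw.columns if c not in _META_COLUMNS]
    if sample_id is not None:
        raw["sample_id"] = sample_id
    elif "sample_id" not in raw.columns:
        raw["sample_id"] = path.stem
    return EventTable(raw.reset_index(drop=True), tuple(channels))


def write_events_fcs(path: str | Path, events: EventTable) -> None:
    """Write the channel intensities of a (single-condition) table as FCS."""
    write_fcs(path, events.data[list(events.channels)])


def arcsinh_transform(values: Sequence[float] | np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    """Elementwise ``asinh(x / cofactor)``, the standard mass-cytometry
    variance-stabilizing transform (cofactor 5). Strictly monotone, so
    rank-based downstream steps are unaffected."""
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.arcsinh(np.asarray(values, dtype=float) / cofactor)


def inverse_arcsinh_transform(values: Sequence[float] | np.ndarray, cofactor: float = 5.0) -> np.ndarray:
    if cofactor <= 0:
        raise ValueError(f"cofactor must be positive, got {cofactor}")
    return np.sinh(np.asarray(values, dtype=float)) * cofactor


def apply_gates(events: EventTable, spec: GateSpec) -> EventTable:
    """Keep cells inside every gate rectangle with ``viability_pass`` true.

    Idempotent; the empty gate list keeps viable cells only (and is the
    identity on a table whose cells all passed viability).
    """
    mask = events.data["viability_pass"].to_numpy(dtype=bool).copy()
    for channel, lo, hi in spec.gates:
        if channel not in events.channels:
            raise KeyError(f"gate references absent channel {channel!r}")
        x = events.intensities(channel)
        mask &= (x >= lo) & (x <= hi)
    return events.subset(mask)


def population_median(
    events: EventTable,
    channel: str,
    group_by: Iterable[str] = ("sample_id", "population", "condition"),
    statistic: str = "median",
) -> pd.DataFrame:
    """Per-group summary intensity (median MFI by default; mean on request).

    Empty groups never appear (pandas drops them); groups whose values are
    all-NaN are flagged in the ``missing`` column rather than reported as 0.
    """
    if channel not in events.channels:
        raise KeyError(f"channel {channel!r} not in table")
    if statistic not in ("median", "mean"):
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    group_by = list(group_by)
    grouped = events.data.groupby(group_by, observed=True, sort=True)
    agg = grouped[channel].median() if statistic == "median" else grouped[channel].mean()
    out = agg.rename(statistic).reset_index()
    out["n_cells"] = grouped[channel].size().to_numpy()
    out["missing"] = ~np.isfinite(out[statistic].to_numpy(dtype=float))
    return out
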