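"""Single-cell metabolic-state binning from oligomycin-treated cells.

Cells that sustain protein synthesis after ATP-synthase inhibition
(oligomycin) are running on glycolysis; cells that shut translation down are
mitochondrial-dependent. Binning the oligomycin-condition puromycin
distribution into four quantiles therefore orders cells from
mitochondrial-dependent (bin 1, lowest puromycin) to glycolytic (bin 4,
highest), and bin occupancy can be compared across clinical groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cytometry import PUROMYCIN, EventTable
from .stats import adjust_pvalues, two_group_test

__all__ = [
    "QuantileBinAssignment",
    "assign_oligomycin_quantiles",
    "bin_proportions_by_group",
    "per_bin_marker_comparison",
]

logger = logging.getLogger(__name__)

N_BINS = 4


@dataclass
class QuantileBinAssignment:
    """Bin label per oligomycin-condition cell.

    ``table`` columns: ``cell_index`` (row in the restricted event table),
    ``sample_id``, ``bin`` (1 = mitochondrial-dependent … 4 = glycolytic).
    ``boundaries`` maps the pooling scope key ("cohort" or a sample id) to
    its (25, 50, 75)-percentile triple.
    """

    table: pd.DataFrame
    scope: str
    boundaries: dict[str, np.ndarray]


def _bin_with_boundaries(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    # strict > sends boundary ties to the lower bin; deterministic and
    # independent of cell order
    return 1 + (x > q[0]).astype(int) + (x > q[1]).astype(int) + (x > q[2]).astype(int)


def assign_oligomycin_quantiles(
    events: EventTable,
    scope: str = "cohort",
    channel: str = PUROMYCIN,
) -> QuantileBinAssignment:
    """Assign each oligomycin-condition cell to one of four puromycin quantile bins.

    Boundaries are the empirical 25/50/75 percentiles (linear interpolation)
    of the pooled distribution — pooled across all samples under
    ``scope="cohort"`` (the default: cross-group occupancy comparisons need
    shared boundaries) or per sample under ``scope="sample"``. Bin membership
    is rank-based, hence invariant to any strictly monotone intensity
    transform.
    """
    if scope not in ("cohort", "sample"):
        raise ValueError(f"scope must be 'cohort' or 'sample', got {scope!r}")
    oligo = events if (events.data["condition"] == "O").all() else events.restrict_condition("O")
    x = oligo.intensities(channel)
    if x.size < 2 * N_BINS:
        raise ValueError(
            f"need >= {2 * N_BINS} oligomycin-condition cells for 4 quantile bins, got {x.size}"
        )
    samples = oligo.data["sample_id"].to_numpy()
    boundaries: dict[str, np.ndarray] = {}
    bins = np.empty(x.size, dtype=int)
    if scope == "cohort":
        q = np.percentile(x, [25, 50, 75])
        boundaries["cohort"] = q
        bins[:] = _bin_with_boundaries(x, q)
    else:
        for s in np.unique(samples):
            mask = samples == s
            if mask.sum() < 2 * N_BINS:
                raise ValueError(f"sample {s!r} has < {2 * N_BINS} oligomycin cells")
            q = np.percentile(x[mask], [25, 50, 75])
            boundaries[str(s)] = q
            bins[mask] = _bin_with_boundaries(x[mask], q)
    if np.ptp(x) == 0:
        logger.warning("degenerate puromycin distribution: all cells tied into bin 1")
    table = pd.DataFrame(
        {"cell_index": np.arange(x.size), "sample_id": samples, "bin": bins}
    )
    return QuantileBinAssignment(table, scope, boundaries)


def bin_proportions_by_group(
    assignment: QuantileBinAssignment, sample_groups: dict[str, str]
) -> pd.DataFrame:
    """Proportion of each group's cells falling in each bin (rows sum to 1)."""
    table = assignment.table
    unmapped = sorted(set(table["sample_id"].astype(str)) - set(map(str, sample_groups)))
    if unmapped:
        raise KeyError(f"samples without a group label: {unmapped}")
    groups = table["sample_id"].astype(str).map({str(k): v for k, v in sample_groups.items()})
    counts = (
        pd.crosstab(groups, table["bin"])
        .reindex(columns=range(1, N_BINS + 1), fill_value=0)
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    props.index.name = "group"
    props.columns.name = "bin"
    return props


def per_bin_marker_comparison(
    events: EventTable,
    assignment: QuantileBinAssignment,
    markers: list[str],
    sample_groups: dict[str, str],
    reference_group: str,
    min_cells: int = 2,
) -> pd.DataFrame:
    """Compare marker expression against a reference group within each bin.

    For every (bin, marker, group≠reference) the groups' per-cell marker
    values are compared through the normality-routed two-group test; p-values
    are Holm-adjusted across the comparisons belonging to the same marker.
    Contrasts with fewer than ``min_cells`` cells on either side, or zero
    variance overall, are flagged not-computable rather than dropped.
    """
    oligo = events if (events.data["condition"] == "O").all() else events.restrict_condition("O")
    if len(oligo) != len(assignment.table):
        raise ValueError("assignment does not match the oligomycin-condition table")
    for m in markers:
        if m not in oligo.channels:
            raise KeyError(f"marker {m!r} not in event table")
    groups = (
        oligo.data["sample_id"].astype(str).map({str(k): v for k, v in sample_groups.items()})
    ).to_numpy()
    if reference_group not in set(groups):
        raise ValueError(f"reference group {reference_group!r} has no cells")
    bins = assignment.table["bin"].to_numpy()
    rows = []
    for marker in markers:
        x = oligo.intensities(marker)
        for b in range(1, N_BINS + 1):
            in_bin = bins == b
            ref = x[in_bin & (groups == reference_group)]
            for g in sorted(set(groups) - {reference_group}):
                other = x[in_bin & (groups == g)]
                base = {
                    "bin": b,
                    "marker": marker,
                    "group": g,
                    "reference": reference_group,
                    "median_ref": float(np.median(ref)) if ref.size else float("nan"),
                    "median_group": float(np.median(other)) if other.size else float("nan"),
                    "n_ref": ref.size,
                    "n_group": other.size,
                }
                if ref.size < max(min_cells, 3) or other.size < max(min_cells, 3):
                    rows.append({**base, "test": "not-computable", "statistic": np.nan,
                                 "p_value": np.nan, "flag": "insufficient cells"})
                    continue
                res = two_group_test(ref, other)
                rows.append({**base, "test": res.test, "statistic": res.statistic,
                             "p_value": res.p_value,
                             "flag": res.note or ("" if res.test != "not-computable" else "zero variance")})
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    for marker in markers:
        mask = (out["marker"] == marker) & out["p_value"].notna()
        if mask.any():
            out.loc[mask, "p_holm"] = adjust_pvalues(out.loc[mask, "p_value"].to_numpy(), "holm")
    return out
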