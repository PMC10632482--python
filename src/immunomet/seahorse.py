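"""Extracellular-flux (Seahorse) trace segmentation and bioenergetic indices.

A mito-stress-test trace records OCR (pmol O2/min) and ECAR (mpH/min) at
fixed intervals while oligomycin, FCCP and rotenone/antimycin A (and in the
glycolysis arm 2-deoxy-glucose) are injected in sequence. The injections
split the trace into plateau segments, and the bioenergetic indices are
differences of segment summaries:

    basal respiration    = OCR(pre-Oligo)  − OCR(post-RA)
    maximal consumption  = OCR(post-FCCP)  − OCR(post-RA)
    spare capacity       = maximal − basal         (= post-FCCP − pre-Oligo)
    proton leak          = OCR(post-Oligo) − OCR(post-RA)
    ATP-linked           = basal − proton leak
    basal glycolysis     = ECAR(pre-Oligo) − ECAR(post-RA)
    glycolytic capacity  = ECAR(post-Oligo) − ECAR(post-RA)

Exogenous fatty-acid oxidation capacity is the post-FCCP OCR contrast
between a control well and a paired palmitate + etomoxir well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "INJECTION_LABELS",
    "SeahorseTrace",
    "SeahorseIndices",
    "DEFAULT_AGGREGATORS",
    "segment_trace",
    "compute_indices",
    "exogenous_fao_max",
    "scale_indices",
    "average_replicate_indices",
]

logger = logging.getLogger(__name__)

INJECTION_LABELS = ("oligomycin", "FCCP", "2DG", "rotenone/antimycinA")

#: Segment summary conventions (configurable): the basal plateau is averaged;
#: the FCCP response is taken at its peak; post-oligomycin and the
#: non-mitochondrial floor at their minima. Mirrors common instrument-report
#: conventions.
DEFAULT_AGGREGATORS = {
    "pre-Oligo": "mean",
    "post-oligomycin": "min",
    "post-FCCP": "max",
    "post-rotenone/antimycinA": "min",
}

_AGG_FUNCS = {"mean": np.mean, "min": np.min, "max": np.max, "median": np.median}


@dataclass
class SeahorseTrace:
    well: str
    condition: str  # control | palmitate | palmitate+etomoxir | BSA-control
    times: np.ndarray  # minutes, strictly increasing
    ocr: np.ndarray
    ecar: np.ndarray
    injections: tuple[tuple[str, float], ...]  # (label, time), ordered

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.ocr = np.asarray(self.ocr, dtype=float)
        self.ecar = np.asarray(self.ecar, dtype=float)
        if not (self.times.size == self.ocr.size == self.ecar.size):
            raise ValueError("times, OCR and ECAR must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not (np.all(np.isfinite(self.ocr)) and np.all(np.isfinite(self.ecar))):
            raise ValueError("OCR/ECAR values must be finite")
        self.injections = tuple((str(l), float(t)) for l, t in self.injections)
        inj_times = [t for _, t in self.injections]
        if any(np.diff(inj_times) <= 0):
            raise ValueError("injection times must be strictly increasing")
        for label, t in self.injections:
            if label not in INJECTION_LABELS:
                raise ValueError(f"unknown injection label {label!r}")
            if not (self.times[0] < t < self.times[-1]):
                raise ValueError(
                    f"injection {label!r} at t={t} lies outside the trace span "
                    f"[{self.times[0]}, {self.times[-1]}]"
                )


@dataclass
class SeahorseIndices:
    basal_respiration: float = float("nan")
    maximal_oxygen_consumption: float = float("nan")
    spare_respiratory_capacity: float = float("nan")
    proton_leak: float = float("nan")
    atp_linked_respiration: float = float("nan")
    basal_glycolysis: float = float("nan")
    glycolytic_capacity: float = float("nan")
    exogenous_fao_max: float = float("nan")
    aggregators: dict[str, str] = field(default_factory=dict)
    warnings: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            k: getattr(self, k)
            for k in (
                "basal_respiration",
                "maximal_oxygen_consumption",
                "spare_respiratory_capacity",
                "proton_leak",
                "atp_linked_respiration",
                "basal_glycolysis",
                "glycolytic_capacity",
                "exogenous_fao_max",
            )
        }


def segment_trace(trace: SeahorseTrace) -> dict[str, np.ndarray]:
    """Partition measurement indices by injection.

    ``pre-Oligo`` holds everything before the first injection; each
    ``post-<label>`` segment runs from its injection to the next (or the
    trace end). A measurement at exactly an injection time belongs to the
    following segment. Every measurement lands in exactly one segment; an
    empty segment is an error naming the injection.
    """
    edges = [t for _, t in trace.injections]
    labels = ["pre-Oligo"] + [f"post-{label}" for label, _ in trace.injections]
    bounds = [-np.inf] + edges + [np.inf]
    segments: dict[str, np.ndarray] = {}
    for i, label in enumerate(labels):
        mask = (trace.times >= bounds[i]) & (trace.times < bounds[i + 1])
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise ValueError(
                f"segment {label!r} is empty (injection schedule leaves no "
                "measurements in it)"
            )
        segments[label] = idx
    return segments


def _segment_value(trace_values: np.ndarray, idx: np.ndarray, how: str) -> float:
    try:
        fn = _AGG_FUNCS[how]
    except KeyError:
        raise ValueError(f"unknown aggregator {how!r}; choose from {sorted(_AGG_FUNCS)}")
    return float(fn(trace_values[idx]))


def compute_indices(
    trace: SeahorseTrace, aggregators: dict[str, str] | None = None
) -> SeahorseIndices:
    """Compute the OXPHOS and glycolytic indices for one trace.

    Requires oligomycin, FCCP and rotenone/antimycin A injections. Negative
    indices are returned as-is with a QC warning (clipping would hide failed
    wells). The aggregator configuration actually used is recorded on the
    result.
    """
    agg = dict(DEFAULT_AGGREGATORS)
    if aggregators:
        agg.update(aggregators)
    segments = segment_trace(trace)
    needed = ("pre-Oligo", "post-oligomycin", "post-FCCP", "post-rotenone/antimycinA")
    missing = [s for s in needed if s not in segments]
    if missing:
        raise ValueError(f"trace lacks required segments: {missing}")

    def ocr(seg: str) -> float:
        return _segment_value(trace.ocr, segments[seg], agg[seg])

    def ecar(seg: str) -> float:
        return _segment_value(trace.ecar, segments[seg], agg[seg])

    floor_ocr = ocr("post-rotenone/antimycinA")
    floor_ecar = ecar("post-rotenone/antimycinA")
    basal = ocr("pre-Oligo") - floor_ocr
    maximal = ocr("post-FCCP") - floor_ocr
    leak = ocr("post-oligomycin") - floor_ocr
    out = SeahorseIndices(
        basal_respiration=basal,
        maximal_oxygen_consumption=maximal,
        spare_respiratory_capacity=maximal - basal,
        proton_leak=leak,
        atp_linked_respiration=basal - leak,
        basal_glycolysis=ecar("pre-Oligo") - floor_ecar,
        glycolytic_capacity=ecar("post-oligomycin") - floor_ecar,
        aggregators=agg,
    )
    warns = tuple(
        f"negative index {name} = {value:.4g} in well {trace.well}"
        for name, value in out.as_dict().items()
        if np.isfinite(value) and value < 0
    )
    if warns:
        for w in warns:
            logger.warning(w)
        out.warnings = warns
    return out


def exogenous_fao_max(
    control: SeahorseTrace,
    palmitate_etomoxir: SeahorseTrace,
    aggregators: dict[str, str] | None = None,
) -> float:
    """Maximal respiration attributable to exogenous fatty-acid oxidation.

    Post-FCCP OCR of the control well minus that of the explicitly paired
    palmitate + etomoxir well (sign convention: positive when blocking FAO
    lowers the FCCP response). Pairing is explicit — never inferred from
    well position.
    """
    agg = dict(DEFAULT_AGGREGATORS)
    if aggregators:
        agg.update(aggregators)
    vals = []
    for trace in (control, palmitate_etomoxir):
        segments = segment_trace(trace)
        if "post-FCCP" not in segments:
            raise ValueError(f"trace {trace.well!r} lacks a post-FCCP segment")
        vals.append(_segment_value(trace.ocr, segments["post-FCCP"], agg["post-FCCP"]))
    return vals[0] - vals[1]


def scale_indices(values: pd.DataFrame, method: str = "zscore") -> pd.DataFrame:
    """Scale each index column across samples (for cross-index display).

    ``zscore`` centers to mean 0 and scales to sample SD 1 (ddof=1, the R
    ``scale()`` convention); ``minmax`` maps to [0, 1]. Zero-variance
    columns are returned unscaled with a log warning.
    """
    if len(values) < 2:
        raise ValueError("scaling needs >= 2 samples")
    out = values.copy().astype(float)
    for col in out.columns:
        x = out[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            logger.warning("index %r has zero variance; left unscaled", col)
            continue
        if method == "zscore":
            out[col] = (x - x.mean()) / x.std(ddof=1)
        elif method == "minmax":
            out[col] = (x - x.min()) / (x.max() - x.min())
        else:
            raise ValueError(f"unknown scaling method {method!r}")
    return out


def average_replicate_indices(indices: list[SeahorseIndices]) -> SeahorseIndices:
    """Mean of per-well indices across replicate wells (triplicates by default
    upstream). Because every index is a linear segment contrast, averaging at
    the index level commutes with averaging wells first when aggregators are
    linear (means)."""
    if not indices:
        raise ValueError("no replicate indices")
    mean: dict[str, float] = {}
    for k in indices[0].as_dict():
        vals = [v for ix in indices if np.isfinite(v := ix.as_dict()[k])]
        mean[k] = float(np.mean(vals)) if vals else float("nan")
    return SeahorseIndices(**mean, aggregators=dict(indices[0].aggregators))
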