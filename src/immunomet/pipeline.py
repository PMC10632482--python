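"""Config-driven orchestration of the analysis stages.

A run is described by a YAML config naming the input tables, the options of
each stage and an output directory; ``run()`` executes any subset of stages
in dependency order, writes tidy CSV result tables (no binary
intermediates) and a JSON manifest recording the package version, the
config hash, the seed and per-stage row counts — enough to reproduce every
number in every output table.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml

from . import __version__
from .binning import assign_oligomycin_quantiles, bin_proportions_by_group, per_bin_marker_comparison
from .cytometry import EventTable, GateSpec, PUROMYCIN, apply_gates, population_median
from .flux import SupernatantSeries, glucose_to_lactate_fraction, interval_fluxes
from .scenith import panels_from_table, profile_cohort
from .seahorse import SeahorseTrace, compute_indices, exogenous_fao_max
from .simulate import SyntheticCohortConfig, generate_cohort
from .stats import cox_univariate, km_estimate, logrank_test, maxstat_cutpoint

__all__ = ["ConfigError", "StageError", "RunConfig", "run", "simulate_inputs", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("scenith", "binning", "seahorse", "flux", "survival")

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Config fails validation (CLI exit code 2)."""


class StageError(RuntimeError):
    """A stage failed during execution (CLI exit code 3)."""


@dataclass
class RunConfig:
    """Validated run configuration.

    ``inputs`` maps data kinds to file paths: ``events`` (cohort event CSV),
    ``seahorse`` (long trace CSV), ``injections`` (schedule YAML),
    ``supernatant`` (CSV), ``media_changes`` (YAML), ``survival`` (CSV),
    ``sample_groups`` (CSV with sample_id, group).
    """

    seed: int
    output_dir: Path
    inputs: dict[str, Path] = field(default_factory=dict)
    gates: dict[str, dict[str, float]] = field(default_factory=dict)
    scenith: dict[str, Any] = field(default_factory=dict)
    binning: dict[str, Any] = field(default_factory=dict)
    seahorse: dict[str, Any] = field(default_factory=dict)
    survival: dict[str, Any] = field(default_factory=dict)
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc, base=path.parent)

    @classmethod
    def from_dict(cls, doc: dict[str, Any], base: Path = Path(".")) -> "RunConfig":
        if "seed" not in doc:
            raise ConfigError("config must set an integer 'seed'")
        if "output_dir" not in doc:
            raise ConfigError("config must set 'output_dir'")
        inputs = {}
        for kind, rel in (doc.get("inputs") or {}).items():
            p = Path(rel)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise ConfigError(f"input {kind!r}: path does not exist: {p}")
            inputs[kind] = p
        out = Path(doc["output_dir"])
        if not out.is_absolute():
            out = base / out
        return cls(
            seed=int(doc["seed"]),
            output_dir=out,
            inputs=inputs,
            gates=doc.get("gates") or {},
            scenith=doc.get("scenith") or {},
            binning=doc.get("binning") or {},
            seahorse=doc.get("seahorse") or {},
            survival=doc.get("survival") or {},
            raw=doc,
        )

    def config_hash(self) -> str:
        canonical = yaml.safe_dump(self.raw, sort_keys=True).encode()
        return hashlib.sha256(canonical).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return len(df)


def _load_events(config: RunConfig) -> EventTable:
    if "events" not in config.inputs:
        raise StageError("stage needs the 'events' input, which the config does not provide")
    raw = pd.read_csv(config.inputs["events"])
    meta = {"sample_id", "population", "condition", "viability_pass"}
    channels = tuple(c for c in raw.columns if c not in meta)
    table = EventTable(raw, channels)
    if config.gates:
        table = apply_gates(table, GateSpec.from_dict(config.gates))
    return table


def _load_sample_groups(config: RunConfig) -> dict[str, str]:
    if "sample_groups" not in config.inputs:
        raise StageError("stage needs the 'sample_groups' input (CSV: sample_id, group)")
    df = pd.read_csv(config.inputs["sample_groups"])
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


# ------------------------------------------------------------------- stages


def _stage_scenith(config: RunConfig, outdir: Path) -> dict[str, int]:
    events = _load_events(config)
    medians = population_median(events, PUROMYCIN)
    medians = medians.rename(columns={"median": "median_puromycin"})
    panels = panels_from_table(medians)
    profiles, failures = profile_cohort(
        panels,
        clamp=bool(config.scenith.get("clamp", True)),
        min_dynamic_range=float(config.scenith.get("min_dynamic_range", 0.2)),
    )
    counts = {"profiles": _write(profiles, outdir / "scenith_profiles.csv")}
    counts["failures"] = _write(failures, outdir / "scenith_failures.csv")
    return counts


def _stage_binning(config: RunConfig, outdir: Path) -> dict[str, int]:
    events = _load_events(config)
    groups = _load_sample_groups(config)
    scope = config.binning.get("scope", "cohort")
    assignment = assign_oligomycin_quantiles(events, scope=scope)
    counts = {"assignment": _write(assignment.table, outdir / "bin_assignment.csv")}
    props = bin_proportions_by_group(assignment, groups).reset_index()
    counts["proportions"] = _write(props, outdir / "bin_proportions.csv")
    markers = config.binning.get("markers")
    reference = config.binning.get("reference_group")
    if markers and reference:
        table = per_bin_marker_comparison(events, assignment, list(markers), groups, reference)
        counts["marker_comparison"] = _write(table, outdir / "bin_marker_comparison.csv")
    return counts


def _stage_seahorse(config: RunConfig, outdir: Path) -> dict[str, int]:
    if "seahorse" not in config.inputs:
        raise StageError("stage needs the 'seahorse' input (long CSV: well, condition, time_min, OCR, ECAR)")
    if "injections" not in config.inputs:
        raise StageError("stage needs the 'injections' input (YAML schedule)")
    long = pd.read_csv(config.inputs["seahorse"])
    with open(config.inputs["injections"]) as fh:
        schedule = yaml.safe_load(fh)
    injections = tuple((str(e["label"]), float(e["time"])) for e in schedule)
    aggregators = config.seahorse.get("aggregators") or None
    traces: dict[str, SeahorseTrace] = {}
    rows = []
    for (well, condition), grp in long.groupby(["well", "condition"], sort=True):
        grp = grp.sort_values("time_min")
        trace = SeahorseTrace(
            str(well), str(condition),
            grp["time_min"].to_numpy(), grp["OCR"].to_numpy(), grp["ECAR"].to_numpy(),
            injections,
        )
        traces[f"{well}/{condition}"] = trace
        idx = compute_indices(trace, aggregators)
        rows.append({"well": well, "condition": condition, **idx.as_dict(),
                     "warnings": ";".join(idx.warnings)})
    indices = pd.DataFrame(rows)
    # explicit control ↔ palmitate+etomoxir pairing from config, never by position
    for pair in config.seahorse.get("fao_pairs", []):
        ctrl, palm = traces.get(pair["control"]), traces.get(pair["palmitate_etomoxir"])
        if ctrl is None or palm is None:
            raise StageError(f"exogenous-FAO pair references unknown trace: {pair}")
        fao = exogenous_fao_max(ctrl, palm, aggregators)
        indices.loc[
            (indices["well"] == ctrl.well) & (indices["condition"] == ctrl.condition),
            "exogenous_fao_max",
        ] = fao
    indices["aggregators"] = json.dumps(
        aggregators or {}, sort_keys=True
    )
    return {"indices": _write(indices, outdir / "seahorse_indices.csv")}


def _stage_flux(config: RunConfig, outdir: Path) -> dict[str, int]:
    if "supernatant" not in config.inputs:
        raise StageError("stage needs the 'supernatant' input (CSV: sample_id, day, glucose_mM, lactate_mM)")
    sup = pd.read_csv(config.inputs["supernatant"])
    changes: tuple = ()
    if "media_changes" in config.inputs:
        with open(config.inputs["media_changes"]) as fh:
            doc = yaml.safe_load(fh) or []
        changes = tuple(
            (float(e["day"]), float(e["fresh_glucose"]), float(e.get("fresh_lactate", 0.0)))
            for e in doc
        )
    flux_frames, summary_rows = [], []
    for sample_id, grp in sup.groupby("sample_id", sort=True):
        grp = grp.sort_values("day")
        series = SupernatantSeries(
            str(sample_id), grp["day"].to_numpy(), grp["glucose_mM"].to_numpy(),
            grp["lactate_mM"].to_numpy(), changes,
        )
        fluxes = interval_fluxes(series)
        flux_frames.append(fluxes)
        consumed = float(fluxes["glucose_consumed"].sum())
        produced = float(fluxes["lactate_produced"].sum())
        frac = glucose_to_lactate_fraction(consumed, produced)
        summary_rows.append({
            "sample_id": sample_id,
            "glucose_consumed_total": consumed,
            "lactate_produced_total": produced,
            "fraction_stoich": frac.fraction_stoich,
            "ratio_raw": frac.ratio_raw,
            "qc_flag": frac.qc_flag,
        })
    counts = {"interval_fluxes": _write(pd.concat(flux_frames, ignore_index=True),
                                        outdir / "supernatant_fluxes.csv")}
    counts["flux_summary"] = _write(pd.DataFrame(summary_rows), outdir / "flux_summary.csv")
    return counts


def _stage_survival(config: RunConfig, outdir: Path) -> dict[str, int]:
    if "survival" not in config.inputs:
        raise StageError("stage needs the 'survival' input (CSV with times, events, covariates)")
    df = pd.read_csv(config.inputs["survival"])
    endpoint = config.survival.get("endpoint", "OS").upper()
    if endpoint not in ("OS", "PFS"):
        raise StageError(f"survival endpoint must be OS or PFS, got {endpoint!r}")
    tcol, ecol = ("os_months", "os_event") if endpoint == "OS" else ("pfs_months", "pfs_event")
    bounds = tuple(config.survival.get("maxstat_bounds", (0.1, 0.9)))
    permutations = int(config.survival.get("permutations", 0))
    covariates = config.survival.get("covariates")
    if not covariates:
        reserved = {"patient", "os_months", "os_event", "pfs_months", "pfs_event", "outcome_group"}
        covariates = [c for c in df.columns if c not in reserved and pd.api.types.is_numeric_dtype(df[c])]
    times = df[tcol].to_numpy(dtype=float)
    events = df[ecol].to_numpy(dtype=int)
    cut_rows, cox_rows, km_frames = [], [], []
    for cov in covariates:
        x = df[cov].to_numpy(dtype=float)
        cut = maxstat_cutpoint(
            x, times, events, bounds=bounds, covariate=cov,
            permutations=permutations, seed=config.seed,
        )
        cut_rows.append({
            "covariate": cov, "endpoint": endpoint, "cutpoint": cut.cutpoint,
            "statistic": cut.statistic, "p_uncorrected": cut.p_uncorrected,
            "p_permutation": cut.p_permutation, "n_low": cut.n_low, "n_high": cut.n_high,
        })
        high = (x > cut.cutpoint).astype(int)
        cox = cox_univariate(times, events, high)
        lr = logrank_test(times, events, high)
        cox_rows.append({
            "covariate": cov, "endpoint": endpoint, "hazard_ratio": cox.hazard_ratio,
            "ci_low": cox.ci_low, "ci_high": cox.ci_high, "p_wald": cox.p_value,
            "p_logrank": lr.p_value, "converged": cox.converged, "estimable": cox.estimable,
        })
        for label, mask in (("high", high == 1), ("low", high == 0)):
            km = km_estimate(times[mask], events[mask])
            km_frames.append(pd.DataFrame({
                "covariate": cov, "endpoint": endpoint, "stratum": label,
                "time": km.event_times, "n_risk": km.n_risk,
                "n_events": km.n_events, "survival": km.survival,
            }))
    counts = {"cutpoints": _write(pd.DataFrame(cut_rows), outdir / "maxstat_cutpoints.csv")}
    counts["cox"] = _write(pd.DataFrame(cox_rows), outdir / "cox_univariate.csv")
    km_table = (pd.concat(km_frames, ignore_index=True) if km_frames
                else pd.DataFrame(columns=["covariate", "endpoint", "stratum", "time",
                                           "n_risk", "n_events", "survival"]))
    counts["km"] = _write(km_table, outdir / "km_curves.csv")
    return counts


_STAGE_FUNCS = {
    "scenith": _stage_scenith,
    "binning": _stage_binning,
    "seahorse": _stage_seahorse,
    "flux": _stage_flux,
    "survival": _stage_survival,
}


def run(config: RunConfig, stages: Iterable[str] | None = None) -> dict[str, Any]:
    """Execute the requested stages and write the run manifest.

    Stages are independent once their inputs exist; a missing input raises
    :class:`StageError` naming it, and a stage failure is isolated (recorded
    in the manifest; remaining stages still run, and the error is re-raised
    at the end).
    """
    selected = list(stages) if stages else list(STAGES)
    unknown = set(selected) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}; available: {STAGES}")
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    first_error: StageError | None = None
    for stage in STAGES:
        if stage not in selected:
            continue
        t0 = time.perf_counter()
        try:
            counts = _STAGE_FUNCS[stage](config, outdir)
            manifest["stages"][stage] = {
                "status": "ok",
                "row_counts": counts,
                "wall_time_s": round(time.perf_counter() - t0, 3),
            }
        except (StageError, ValueError, KeyError) as exc:
            logger.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            if first_error is None:
                first_error = exc if isinstance(exc, StageError) else StageError(str(exc))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if first_error is not None:
        raise first_error
    return manifest


# ------------------------------------------------------------------- simulate


def simulate_inputs(sim_config: dict[str, Any] | SyntheticCohortConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate a synthetic cohort and write it in the formats ``run`` reads.

    Returns the mapping of input kinds to the files written (events CSV,
    Seahorse long CSV + injection YAML, supernatant CSV + media-change YAML,
    survival CSV, sample-group CSV).
    """
    if isinstance(sim_config, dict):
        markers = sim_config.pop("markers", None)
        cfg = SyntheticCohortConfig(**sim_config)
        if markers:
            from .simulate import MarkerSpec

            cfg.markers = {k: MarkerSpec(**v) for k, v in markers.items()}
    else:
        cfg = sim_config
    cohort = generate_cohort(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    events = pd.concat([t.data for t in cohort.events.values()], ignore_index=True)
    paths["events"] = outdir / "events.csv"
    events.to_csv(paths["events"], index=False, float_format=_FLOAT_FMT)

    long_rows = []
    injections = None
    for sample_id, (ctrl, palm) in cohort.seahorse.items():
        for trace in (ctrl, palm):
            if injections is None:
                injections = [{"label": l, "time": t} for l, t in trace.injections]
            for t, o, e in zip(trace.times, trace.ocr, trace.ecar):
                long_rows.append({"well": trace.well, "condition": trace.condition,
                                  "time_min": t, "OCR": o, "ECAR": e})
    paths["seahorse"] = outdir / "seahorse.csv"
    pd.DataFrame(long_rows).to_csv(paths["seahorse"], index=False, float_format=_FLOAT_FMT)
    paths["injections"] = outdir / "injections.yaml"
    with open(paths["injections"], "w") as fh:
        yaml.safe_dump(injections, fh, sort_keys=False)

    sup = pd.concat(cohort.supernatant.values(), ignore_index=True)
    paths["supernatant"] = outdir / "supernatant.csv"
    sup.to_csv(paths["supernatant"], index=False, float_format=_FLOAT_FMT)
    paths["media_changes"] = outdir / "media_changes.yaml"
    with open(paths["media_changes"], "w") as fh:
        yaml.safe_dump(
            [{"day": cfg.media_change_day, "fresh_glucose": cfg.fresh_glucose,
              "fresh_lactate": 0.0}],
            fh, sort_keys=False,
        )

    paths["survival"] = outdir / "survival.csv"
    cohort.survival.to_csv(paths["survival"], index=False, float_format=_FLOAT_FMT)

    paths["sample_groups"] = outdir / "sample_groups.csv"
    pd.DataFrame(
        {"sample_id": list(cohort.sample_groups), "group": list(cohort.sample_groups.values())}
    ).to_csv(paths["sample_groups"], index=False)
    return paths
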