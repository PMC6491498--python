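"""End-to-end orchestration: simulate -> QC -> connectivity -> graphs -> inference.

A run is configured by a single :class:`RunConfig` (constructible from a YAML
file), executes the full workflow on one synthetic cohort, and leaves behind
a self-contained output directory:

    subjects.tsv            cohort metadata (one row per subject)
    ground_truth.tsv        generator internals per subject
    timeseries/<id>.tsv     parcellated region x time signals
    subjects_qc.tsv         subjects with retained/excluded flags
    connectivity/<id>.tsv   wavelet correlation matrices (retained subjects)
    metrics.tsv             whole-network metrics per subject
    nodal_metrics.tsv       per subject x region metrics with hub flags
    contrasts.tsv           mixed-model group contrasts
    breakpoints.tsv         piecewise (breakpoint) regressions at expected onset
    associations.tsv        per-group correlations and interaction tests
    run_report.json         stage counts, manifest, seeds, software stamp
    run.log                 full config echo and per-stage log

Stages can be re-run individually from the cached intermediates with
identical results; everything is deterministic given the config seed.  No
multiple-comparison correction is applied to the inference tables (network
measures are not independent); this is stamped into the run report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, generate_cohort
from .connectivity import (
    exclude_by_spike_pct,
    select_wavelet_scale,
    wavelet_correlation_matrix,
)
from .graphs import (
    NullEnsembleSpec,
    build_graph,
    compute_global_metrics,
    compute_nodal_metrics,
    generate_null_ensemble,
    identify_hubs,
)
from .inference import (
    association_by_group,
    fit_breakpoint_model,
    fit_group_contrast,
    hub_gap_interaction,
)
from . import io as fio

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigError",
    "StageError",
    "RunConfig",
    "RunReport",
    "run_pipeline",
    "stage_simulate",
    "stage_connect",
    "stage_metrics",
    "stage_analyze",
]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    spike_threshold_pct: float = 10.0
    target_band: tuple = (0.0675, 0.125)
    wavelet_family: str = "db4"
    negative_policy: str = "zero"
    target_density: float = 0.10
    n_nulls: int = 500
    swaps_per_edge: int = 5
    contrasts: tuple = (("carrier", "ftd"), ("carrier", "gene_negative"))
    breakpoint_knot: float = 0.0
    alpha: float = 0.05
    output_dir: str = "ftdnet_run"
    log_level: str = "INFO"

    def validate(self) -> None:
        if not isinstance(self.cohort, CohortConfig):
            raise ConfigError("cohort must be a CohortConfig")
        if self.cohort.tr_seconds is None or self.cohort.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be a positive number of seconds")
        if not (0 <= self.spike_threshold_pct <= 100):
            raise ConfigError("spike_threshold_pct must lie in [0, 100]")
        if not (0 < self.target_density <= 1):
            raise ConfigError("target_density must lie in (0, 1]")
        if self.negative_policy not in ("zero", "absolute"):
            raise ConfigError("negative_policy must be 'zero' or 'absolute'")
        if self.n_nulls < 1:
            raise ConfigError("n_nulls must be >= 1")
        if len(self.target_band) != 2 or not (0 < self.target_band[0] < self.target_band[1]):
            raise ConfigError("target_band must be (f_low, f_high) with 0 < f_low < f_high")
        for pair in self.contrasts:
            if len(pair) != 2:
                raise ConfigError(f"contrasts entries must be pairs, got {pair!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        cohort_kwargs = d.pop("cohort", {})
        try:
            cohort = CohortConfig(**cohort_kwargs)
        except TypeError as exc:
            raise ConfigError(f"invalid cohort config: {exc}") from exc
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "target_band" in d:
            d["target_band"] = tuple(d["target_band"])
        if "contrasts" in d:
            d["contrasts"] = tuple(tuple(c) for c in d["contrasts"])
        cfg = cls(cohort=cohort, **d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        return d


@dataclass
class RunReport:
    n_generated: int
    n_excluded: int
    n_retained: int
    n_hubs: int
    seeds: dict
    manifest: list
    config: dict
    version: str = __version__
    multiple_comparison_correction: str = "none"

    def __post_init__(self) -> None:
        assert self.n_retained + self.n_excluded == self.n_generated

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path


def _null_seed(config: RunConfig, subject_index: int) -> int:
    return int((config.cohort.seed * 1000003 + 7919 * subject_index + 13) % (2**31 - 1))


def stage_simulate(config: RunConfig) -> Path:
    """Generate the cohort and write subjects, ground truth, and time series."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects, series, truth = generate_cohort(config.cohort)
    fio.write_subjects(subjects, out / "subjects.tsv")
    truth_rows = []
    for g in truth:
        truth_rows.append(
            {
                "subject_id": g.subject_id,
                "true_covariance_summary": g.true_covariance_summary,
                "true_hub_set": ",".join(map(str, g.true_hub_set)),
                **{f"effect_{k}": v for k, v in g.imposed_group_effect.items()},
                **{f"slope_{k}": v for k, v in g.imposed_breakpoint_slopes.items()},
            }
        )
    fio.write_table(pd.DataFrame(truth_rows), out / "ground_truth.tsv")
    for ts in series:
        fio.write_timeseries(ts, out / "timeseries")
    logger.info("simulate: %d subjects, %d regions, %d timepoints",
                len(subjects), config.cohort.n_regions, config.cohort.n_timepoints)
    return out


def stage_connect(config: RunConfig) -> Path:
    """Exclude high-motion subjects and estimate connectivity for the rest."""
    out = Path(config.output_dir)
    subjects = fio.read_subjects(out / "subjects.tsv")
    retained, excluded = exclude_by_spike_pct(subjects, config.spike_threshold_pct)
    qc = fio.subjects_to_frame(subjects)
    retained_ids = {s.subject_id for s in retained}
    qc["retained"] = qc["subject_id"].isin(retained_ids)
    fio.write_table(qc, out / "subjects_qc.tsv")

    band = select_wavelet_scale(
        config.cohort.tr_seconds, tuple(config.target_band), config.wavelet_family
    )
    for s in retained:
        ts = fio.read_timeseries(out / "timeseries" / f"{s.subject_id}.tsv")
        conn = wavelet_correlation_matrix(ts, band)
        fio.write_connectivity(conn, out / "connectivity")
    logger.info(
        "connect: retained %d / excluded %d at spike threshold %.1f%%; "
        "wavelet scale %d (%.4f-%.4f Hz)",
        len(retained), len(excluded), config.spike_threshold_pct,
        band.scale_index, band.f_low, band.f_high,
    )
    return out


def stage_metrics(config: RunConfig) -> Path:
    """Graphs, null-normalized metrics, and hub identification."""
    out = Path(config.output_dir)
    qc = fio.read_table(out / "subjects_qc.tsv")
    retained = qc[qc["retained"]].reset_index(drop=True)

    global_rows, nodal_frames = [], []
    for idx, row in retained.iterrows():
        sid = row["subject_id"]
        conn = fio.read_connectivity(out / "connectivity" / f"{sid}.tsv")
        graph = build_graph(conn, config.negative_policy, config.target_density)
        nulls = generate_null_ensemble(
            graph,
            NullEnsembleSpec(config.n_nulls, config.swaps_per_edge, _null_seed(config, idx)),
        )
        gm = compute_global_metrics(graph, nulls)
        nm = compute_nodal_metrics(graph)
        global_rows.append(
            {
                "subject_id": sid,
                "connection_strength_total": gm.connection_strength_total,
                "global_efficiency_raw": gm.global_efficiency_raw,
                "global_efficiency_normalized": gm.global_efficiency_normalized,
                "edge_density": graph.edge_density,
            }
        )
        nodal_frames.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "region": np.arange(graph.n_nodes),
                    "strength": nm.strength,
                    "farness": nm.farness,
                    "nodal_efficiency": nm.nodal_efficiency,
                    "farness_normalized": gm.farness_normalized,
                    "nodal_efficiency_normalized": gm.nodal_efficiency_normalized,
                }
            )
        )
    metrics = pd.DataFrame(global_rows)
    nodal = pd.concat(nodal_frames, ignore_index=True)

    # hubs: defined from mean nodal strengths in the gene-negative group only
    neg_ids = set(retained.loc[retained["group"] == "gene_negative", "subject_id"])
    ref = (
        nodal[nodal["subject_id"].isin(neg_ids)]
        .groupby("region")["strength"].mean()
        .sort_index()
        .to_numpy()
    )
    hub_flags = identify_hubs(ref)
    nodal["hub_flag"] = hub_flags[nodal["region"].to_numpy()]

    fio.write_table(metrics, out / "metrics.tsv")
    fio.write_table(nodal, out / "nodal_metrics.tsv")
    logger.info("metrics: %d subjects, %d hub regions", len(metrics), int(hub_flags.sum()))
    return out


def _analysis_table(out: Path) -> pd.DataFrame:
    qc = fio.read_table(out / "subjects_qc.tsv")
    metrics = fio.read_table(out / "metrics.tsv")
    return qc[qc["retained"]].merge(metrics, on="subject_id", validate="1:1")


def stage_analyze(config: RunConfig) -> Path:
    """Group contrasts, breakpoint regressions, hub-gap and association tests."""
    out = Path(config.output_dir)
    table = _analysis_table(out)
    nodal = fio.read_table(out / "nodal_metrics.tsv")

    outcomes = ("connection_strength_total", "global_efficiency_normalized")

    contrast_rows = []
    for outcome in outcomes:
        for pair in config.contrasts:
            r = fit_group_contrast(table, outcome, tuple(pair))
            contrast_rows.append(
                {
                    "analysis": "group_contrast",
                    "outcome": outcome,
                    "term": r.contrast,
                    "estimate": r.estimate,
                    "se": r.se,
                    "df": r.satterthwaite_df,
                    "stat": r.t,
                    "p": r.p,
                    "model": r.model,
                }
            )

    breakpoint_rows = []
    for outcome in outcomes:
        r = fit_breakpoint_model(table, outcome, config.breakpoint_knot)
        breakpoint_rows.append(
            {
                "analysis": "breakpoint",
                "outcome": outcome,
                "knot": r.knot,
                "pre_slope": r.pre_slope,
                "post_slope": r.post_slope,
                "slope_change": r.slope_change,
                "level_change": r.level_change,
                "p_breakpoint": r.p_breakpoint,
                "p_slope_change": r.term_p["slope_change"],
                "p_level_change": r.term_p["level_change"],
                "model": r.model,
            }
        )

    regional = nodal.merge(
        table[["subject_id", "group", "age", "site", "gene"]], on="subject_id", validate="m:1"
    )
    hub_rows = []
    for outcome in ("strength", "farness"):
        reg = regional.rename(columns={outcome: "outcome"})
        r = hub_gap_interaction(reg[["subject_id", "group", "age", "site", "gene",
                                     "hub_flag", "outcome"]])
        hub_rows.append(
            {
                "analysis": "hub_gap_interaction",
                "outcome": outcome,
                "term": r.contrast,
                "estimate": r.estimate,
                "se": r.se,
                "df": r.satterthwaite_df,
                "stat": r.t,
                "p": r.p,
                "model": r.model,
            }
        )

    association_rows = []
    assoc_specs = [
        ("brain_volume_pct", "connection_strength_total"),
        ("brain_volume_pct", "global_efficiency_normalized"),
        ("connection_strength_total", "cog_mmse"),
        ("connection_strength_total", "cog_trails_a"),
        ("global_efficiency_normalized", "cog_mmse"),
    ]
    for x, y in assoc_specs:
        if y not in table.columns:
            continue
        r = association_by_group(table, x, y, ("carrier", "ftd"))
        for g, (rr, pp, nn) in r.per_group.items():
            association_rows.append(
                {"analysis": "association", "x": x, "y": y, "term": f"r_{g}",
                 "estimate": rr, "p": pp, "n": nn}
            )
        association_rows.append(
            {"analysis": "association", "x": x, "y": y, "term": "interaction",
             "estimate": r.interaction_estimate, "p": r.interaction_p, "n": len(table)}
        )

    fio.write_table(pd.DataFrame(contrast_rows + hub_rows), out / "contrasts.tsv")
    fio.write_table(pd.DataFrame(breakpoint_rows), out / "breakpoints.tsv")
    fio.write_table(pd.DataFrame(association_rows), out / "associations.tsv")
    logger.info("analyze: %d contrasts, %d breakpoints, %d associations",
                len(contrast_rows) + len(hub_rows), len(breakpoint_rows), len(association_rows))
    return out


_STAGES = (
    ("simulate", stage_simulate),
    ("connect", stage_connect),
    ("metrics", stage_metrics),
    ("analyze", stage_analyze),
)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and write the run report; deterministic given seed."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ftdnet")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        logger.info("run config: %s", json.dumps(config.to_dict(), sort_keys=True))
        for name, fn in _STAGES:
            try:
                fn(config)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        qc = fio.read_table(out / "subjects_qc.tsv")
        nodal = fio.read_table(out / "nodal_metrics.tsv")
        n_hubs = int(nodal.groupby("region")["hub_flag"].first().sum())
        manifest = sorted(
            str(p.relative_to(out))
            for p in out.rglob("*")
            if p.is_file() and p.suffix in (".tsv", ".json", ".log")
        )
        report = RunReport(
            n_generated=len(qc),
            n_excluded=int((~qc["retained"]).sum()),
            n_retained=int(qc["retained"].sum()),
            n_hubs=n_hubs,
            seeds={"cohort": config.cohort.seed},
            manifest=manifest,
            config=config.to_dict(),
        )
        report.to_json(out / "run_report.json")
        logger.info("run complete: %d retained of %d generated", report.n_retained,
                    report.n_generated)
        return report
    finally:
        root.removeHandler(handler)
        handler.close()
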