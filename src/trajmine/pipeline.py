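"""End-to-end orchestration: configuration, staged execution, result writing.

Stages run in order — preprocess -> pairs -> risk -> trajectories ->
cluster — each consuming the previous stage's artifact from the output
directory, so they are independently invokable.  Every table is written
with a one-line metadata header (stage, config hash, master seed) and no
timestamps, making rerun output byte-identical under a fixed config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import event_model, pair_screening, synthetic_cohort
from .embedding_cluster import HashingEmbedder, cluster_trajectories, embed_codes
from .event_model import (DEFAULT_OUTCOME_CODES, Cohort, CodeVocabulary,
                          build_timelines, read_demographics, read_events)
from .matched_risk import (_StratumIndex, bonferroni_filter, child_seed,
                           relative_risk)
from .trajectory_assembly import (Trajectory, build_pair_graph,
                                  enumerate_trajectories,
                                  restrict_to_outcome_ancestors,
                                  trajectories_to_frame)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """All knobs of the pipeline; every published constant is a default here."""

    outdir: str = "results/run"
    events_path: Optional[str] = None
    demographics_path: Optional[str] = None
    descriptions_path: Optional[str] = None
    mapping_path: Optional[str] = None
    study_window_start: str = "2013-01-01"
    study_window_end: str = "2022-12-31"
    min_age: float = 18.0
    alpha_pair: float = 0.05
    alpha_dir: float = 0.05
    alpha_rr: float = 0.05
    min_pair_patients: int = 10
    k_controls: int = 10000
    min_support: int = 500
    max_gap_days: int = 1826          # five years
    max_len: int = 5
    control_outcome: str = "anywhere"
    embedding_dim: int = 256
    cluster_k: Optional[int] = 2
    cluster_threshold: Optional[float] = None
    outcome_codes: list[str] = field(
        default_factory=lambda: sorted(DEFAULT_OUTCOME_CODES))
    master_seed: int = 0
    # simulate-stage parameters (used only by the simulate subcommand)
    sim_n_patients: int = 20000
    sim_planted: bool = True

    def __post_init__(self):
        for name in ("alpha_pair", "alpha_dir", "alpha_rr"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in ("k_controls", "min_support", "max_gap_days", "max_len",
                     "embedding_dim", "min_pair_patients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.outcome_codes:
            raise ValueError("outcome code set must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (file locations excluded)."""
        d = dataclasses.asdict(self)
        for key in ("outdir", "events_path", "demographics_path",
                    "descriptions_path", "mapping_path"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @property
    def window(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return (pd.Timestamp(self.study_window_start),
                pd.Timestamp(self.study_window_end))


@dataclass
class RunReport:
    config_hash: str = ""
    master_seed: int = 0
    counts: dict = field(default_factory=dict)
    family_sizes: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    wall_clock: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                         sort_keys=True) + "\n")


def _header(cfg: RunConfig, stage: str) -> str:
    return (f"# trajmine stage={stage} config={cfg.config_hash()} "
            f"seed={cfg.master_seed}\n")


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig,
                 stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(cfg, stage))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise StageError(f"missing upstream artifact: {path}")
    return pd.read_csv(path, sep="\t", comment="#")


def _vocabulary(cfg: RunConfig) -> CodeVocabulary:
    if cfg.descriptions_path:
        df = pd.read_csv(cfg.descriptions_path)
        return CodeVocabulary.from_table(df, outcome_codes=cfg.outcome_codes)
    return CodeVocabulary.from_codes([], outcome_codes=cfg.outcome_codes)


def stage_simulate(cfg: RunConfig) -> RunConfig:
    """Generate a synthetic cohort and point the config at its files."""
    outdir = Path(cfg.outdir) / "input"
    gen = synthetic_cohort.default_config(
        n_patients=cfg.sim_n_patients, master_seed=cfg.master_seed,
        planted=cfg.sim_planted)
    events_path, demo_path, _ = synthetic_cohort.write_cohort_files(gen, outdir)
    cfg = dataclasses.replace(cfg, events_path=str(events_path),
                              demographics_path=str(demo_path),
                              outcome_codes=sorted(gen.outcome_codes))
    return cfg


def stage_preprocess(cfg: RunConfig) -> tuple[Cohort, dict]:
    if not cfg.events_path or not Path(cfg.events_path).exists():
        raise StageError(f"preprocess: events file not found: {cfg.events_path}")
    if not cfg.demographics_path or not Path(cfg.demographics_path).exists():
        raise StageError(
            f"preprocess: demographics file not found: {cfg.demographics_path}")
    events, load_report = read_events(cfg.events_path)
    demographics = read_demographics(cfg.demographics_path)
    mapping = {}
    if cfg.mapping_path:
        mdf = pd.read_csv(cfg.mapping_path)
        mapping = dict(zip(mdf["code"].astype(str), mdf["group"].astype(str)))
    cohort, exclusions = build_timelines(
        events, demographics, cfg.window, min_age=cfg.min_age,
        outcome_codes=cfg.outcome_codes, code_mapping=mapping,
        vocabulary=_vocabulary(cfg))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_table(cohort.events.assign(
        date=cohort.events["date"].dt.strftime("%Y-%m-%d")),
        outdir / "timelines.tsv", cfg, "preprocess")
    demo = cohort.demographics.reset_index()
    demo["birth_date"] = demo["birth_date"].dt.strftime("%Y-%m-%d")
    _write_table(demo, outdir / "demographics_included.tsv", cfg, "preprocess")
    (outdir / "load_report.json").write_text(
        json.dumps(load_report.to_dict(), indent=2) + "\n")
    exclusions.to_json(outdir / "exclusions.json")
    return cohort, {"n_included": exclusions.n_included,
                    "n_events": len(cohort.events),
                    "load": load_report.to_dict(),
                    "exclusions": exclusions.to_dict()}


def load_cohort(cfg: RunConfig) -> Cohort:
    """Rebuild the cohort from the preprocess stage's artifacts."""
    outdir = Path(cfg.outdir)
    ev = _read_table(outdir / "timelines.tsv")
    ev["date"] = pd.to_datetime(ev["date"])
    demo = _read_table(outdir / "demographics_included.tsv")
    demo["birth_date"] = pd.to_datetime(demo["birth_date"])
    demo = demo.set_index("patient_id")
    demo.index = demo.index.astype(str)
    ev["patient_id"] = ev["patient_id"].astype(str)
    vocab = _vocabulary(cfg)
    vocab.ensure(ev["code"].unique(), domains=dict(zip(ev["code"], ev["domain"])))
    for c in cfg.outcome_codes:
        if c in vocab.entries:
            vocab.entries[c]["is_outcome"] = True
    return Cohort(events=ev, demographics=demo, window=cfg.window,
                  vocabulary=vocab)


def stage_pairs(cfg: RunConfig, cohort: Cohort) -> tuple[pd.DataFrame, dict]:
    candidates = pair_screening.screen_pairs(
        cohort, alpha_pair=cfg.alpha_pair,
        min_pair_patients=cfg.min_pair_patients)
    directed = pair_screening.orient_pairs(cohort, candidates,
                                           alpha_dir=cfg.alpha_dir)
    outdir = Path(cfg.outdir)
    _write_table(candidates, outdir / "candidate_pairs.tsv", cfg, "pairs")
    _write_table(directed.assign(direction="forward"),
                 outdir / "directed_pairs.tsv", cfg, "pairs")
    return directed, {"n_candidate_pairs": len(candidates),
                      "n_directed_pairs": len(directed)}


def stage_risk(cfg: RunConfig, cohort: Cohort, directed: pd.DataFrame,
               ) -> tuple[pd.DataFrame, dict]:
    sidx = _StratumIndex(cohort)
    rows = []
    estimates = []
    for row in directed.itertuples(index=False):
        seed = child_seed(cfg.master_seed, "pair", row.c1, row.c2)
        est = relative_risk(cohort, [row.c1], row.c2, k=cfg.k_controls,
                            max_gap_days=cfg.max_gap_days, seed=seed,
                            control_outcome=cfg.control_outcome,
                            stratum_index=sidx)
        estimates.append(((row.c1, row.c2), est))
        rows.append({"c1": row.c1, "c2": row.c2, "a": row.a,
                     **est.to_dict()})
    kept, m = bonferroni_filter(estimates, alpha=cfg.alpha_rr)
    all_df = pd.DataFrame(rows).drop(columns=["flags"], errors="ignore")
    kept_keys = {key for key, _ in kept}
    vocab = cohort.vocabulary
    sig_rows = []
    for key, est in kept:
        c1, c2 = key
        sig_rows.append({
            "source_code": c1, "source_name": vocab.description(c1),
            "target_code": c2, "target_name": vocab.description(c2),
            "relative_risk": est.rr, "ci_low": est.ci_low,
            "ci_high": est.ci_high, "p_value": est.p_value,
            "patients_in_pair": est.n_exposed_outcome,
            "n_exposed": est.n_exposed,
            "n_control": est.n_control,
            "n_control_outcome": est.n_control_outcome,
        })
    sig_df = pd.DataFrame(sig_rows, columns=[
        "source_code", "source_name", "target_code", "target_name",
        "relative_risk", "ci_low", "ci_high", "p_value", "patients_in_pair",
        "n_exposed", "n_control", "n_control_outcome"])
    outdir = Path(cfg.outdir)
    _write_table(all_df, outdir / "pair_risk.tsv", cfg, "risk")
    _write_table(sig_df, outdir / "significant_pairs.tsv", cfg, "risk")
    sig_edges = all_df[[f"{a}" for a in ("c1", "c2", "rr", "p_value")]]
    sig_edges = sig_edges[[(r.c1, r.c2) in kept_keys
                           for r in sig_edges.itertuples(index=False)]]
    return sig_edges.reset_index(drop=True), {
        "bonferroni_family_size": m,
        "n_significant_pairs": len(sig_df)}


def _write_graph(graph: nx.DiGraph, outdir: Path, cfg: RunConfig) -> None:
    nx.write_graphml(graph, outdir / "pair_graph.graphml")
    lines = ["digraph pairs {"]
    for u, v, data in sorted(graph.edges(data=True)):
        lines.append(f'  "{u}" -> "{v}" [label="RR={data["rr"]:.2f}"];')
    lines.append("}")
    (outdir / "pair_graph.dot").write_text("\n".join(lines) + "\n")


def stage_trajectories(cfg: RunConfig, cohort: Cohort,
                       sig_edges: pd.DataFrame,
                       ) -> tuple[list[Trajectory], dict]:
    graph, removed = build_pair_graph(sig_edges)
    outcomes = [c for c in cfg.outcome_codes]
    restricted = restrict_to_outcome_ancestors(graph, outcomes)
    warnings = []
    if restricted.number_of_nodes() == 0:
        warnings.append("no outcome code present in the pair graph")
    trajectories = enumerate_trajectories(
        restricted, cohort, outcomes, min_support=cfg.min_support,
        max_len=cfg.max_len, max_gap_days=cfg.max_gap_days,
        k_controls=cfg.k_controls, master_seed=cfg.master_seed)
    outdir = Path(cfg.outdir)
    _write_graph(restricted, outdir, cfg)
    with open(outdir / "trajectories.jsonl", "w") as fh:
        fh.write(_header(cfg, "trajectories"))
        for t in trajectories:
            fh.write(json.dumps(t.to_dict(cohort.vocabulary),
                                sort_keys=True) + "\n")
    _write_table(trajectories_to_frame(trajectories, cohort.vocabulary),
                 outdir / "trajectories.tsv", cfg, "trajectories")
    return trajectories, {
        "n_cycle_edges_removed": len(removed),
        "n_graph_nodes": restricted.number_of_nodes(),
        "n_graph_edges": restricted.number_of_edges(),
        "n_trajectories": len(trajectories),
        "trajectory_family_size": len(trajectories),
        "warnings": warnings}


def stage_cluster(cfg: RunConfig, cohort: Cohort,
                  trajectories: list[Trajectory]) -> dict:
    if not trajectories:
        raise StageError("cluster: no trajectories to cluster")
    if cfg.cluster_k is not None and cfg.cluster_k > len(trajectories):
        raise StageError(
            f"cluster: k={cfg.cluster_k} exceeds {len(trajectories)} trajectories")
    embeddings = embed_codes(cohort.vocabulary,
                             HashingEmbedder(dim=cfg.embedding_dim),
                             dim=cfg.embedding_dim)
    clusters, dist = cluster_trajectories(
        cohort, trajectories, embeddings, k=cfg.cluster_k,
        threshold=cfg.cluster_threshold, k_controls=cfg.k_controls,
        max_gap_days=cfg.max_gap_days, master_seed=cfg.master_seed)
    outdir = Path(cfg.outdir)
    labels = [" -> ".join(t.codes) for t in trajectories]
    dist_df = pd.DataFrame(dist, columns=labels)
    dist_df.insert(0, "trajectory", labels)
    _write_table(dist_df, outdir / "distance_matrix.tsv", cfg, "cluster")
    payload = {"provider": f"hashing-ngram-d{cfg.embedding_dim}",
               "clusters": [c.to_dict(cohort.vocabulary) for c in clusters]}
    with open(outdir / "clusters.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"n_clusters": len(clusters)}


def run_pipeline(cfg: RunConfig, simulate: bool = False) -> RunReport:
    """Execute every stage in order; returns the run report (also written
    to <outdir>/report.json)."""
    report = RunReport(config_hash=cfg.config_hash(),
                       master_seed=cfg.master_seed)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def timed(stage, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except StageError:
            raise
        except Exception as exc:  # label the failing stage
            raise StageError(f"{stage}: {exc}") from exc
        report.wall_clock[stage] = round(time.perf_counter() - t0, 3)
        return result

    if simulate:
        cfg = timed("simulate", stage_simulate, cfg)
    cohort, info = timed("preprocess", stage_preprocess, cfg)
    report.counts.update({k: v for k, v in info.items()
                          if isinstance(v, int)})
    directed, info = timed("pairs", stage_pairs, cfg, cohort)
    report.counts.update(info)
    sig_edges, info = timed("risk", stage_risk, cfg, cohort, directed)
    report.family_sizes["pairs"] = info.pop("bonferroni_family_size")
    report.counts.update(info)
    trajectories, info = timed("trajectories", stage_trajectories, cfg,
                               cohort, sig_edges)
    report.warnings.extend(info.pop("warnings"))
    report.family_sizes["trajectories"] = info.pop("trajectory_family_size")
    report.counts.update(info)
    if trajectories and (cfg.cluster_k is None
                         or cfg.cluster_k <= len(trajectories)):
        info = timed("cluster", stage_cluster, cfg, cohort, trajectories)
        report.counts.update(info)
    else:
        report.warnings.append("cluster stage skipped: too few trajectories")
    report.seeds = {"master": cfg.master_seed}
    report.to_json(outdir / "report.json")
    cfg.to_yaml(outdir / "config_used.yaml")
    return report
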