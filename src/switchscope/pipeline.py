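"""End-to-end orchestration: simulate -> cohort -> extract -> evaluate ->
topics -> enrich, with per-stage artifacts and a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    apply_filters,
    build_timelines,
    demographic_comparison,
    detect_switches,
    events_frame,
    find_switches,
    switch_matrix,
)
from .enrichment import enrichment_scores, stratify
from .evaluation import auto_annotations, cohens_kappa, human_eval_report, micro_f1
from .extraction import RuleBasedExtractor, derive_silver_labels, extract_all, results_frame, silver_frame
from .patterns import PatternTable, load_default_table
from .synthetic import NoiseRates, SimConfig, generate_cohort
from .topics import topic_model

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "switchscope_run"
    seed: int = 0
    data_dir: str | None = None  # pre-existing inputs; None -> simulate
    simulate: dict = field(default_factory=dict)  # SimConfig overrides
    patterns_path: str | None = None
    followup_anchor: str = "last"
    note_token_threshold: int = 50
    extractor: str = "rules"
    topics: dict = field(default_factory=lambda: {"min_cluster_size": 10, "backend": "tfidf"})
    enrichment_axes: tuple = ("race", "age")
    include_noise_topic: bool = False
    stages: tuple = ("simulate", "cohort", "extract", "evaluate", "topics", "enrich")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("enrichment_axes", "stages"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["enrichment_axes"] = list(self.enrichment_axes)
        d["stages"] = list(self.stages)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sim_config(cfg: RunConfig) -> SimConfig:
    kwargs = dict(cfg.simulate)
    if "noise_rates" in kwargs and isinstance(kwargs["noise_rates"], dict):
        kwargs["noise_rates"] = NoiseRates(**kwargs["noise_rates"])
    kwargs.setdefault("seed", cfg.seed)
    return SimConfig(**kwargs)


def _load_inputs(data_dir: Path):
    orders = pd.read_csv(data_dir / "orders.csv")
    demographics = pd.read_csv(data_dir / "demographics.csv")
    notes = pd.read_json(data_dir / "notes.jsonl", lines=True)
    gold_path = data_dir / "gold.csv"
    gold = pd.read_csv(gold_path).fillna("") if gold_path.exists() else None
    return orders, demographics, notes, gold


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; returns the report bundle as a dict.

    Artifacts are written under ``cfg.out_dir``. Any stage failure aborts
    with the stage name, leaving earlier artifacts on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    table = PatternTable.from_yaml(cfg.patterns_path) if cfg.patterns_path else load_default_table()
    stage = "init"
    t0 = time.time()

    def tick(name):
        nonlocal stage, t0
        log.info("stage %-9s done in %.2fs", stage, time.time() - t0)
        stage, t0 = name, time.time()

    try:
        tick("simulate")
        if cfg.data_dir is None:
            sim = generate_cohort(_sim_config(cfg))
            sim.write(out / "synthetic")
            orders, demographics, notes = sim.orders, sim.demographics, sim.notes
            gold = sim.gold_frame()
        else:
            orders, demographics, notes, gold = _load_inputs(Path(cfg.data_dir))

        tick("cohort")
        filtered, attrition = apply_filters(
            orders,
            notes,
            table=table,
            followup_anchor=cfg.followup_anchor,
            token_threshold=cfg.note_token_threshold,
        )
        with open(out / "attrition.json", "w") as fh:
            json.dump(attrition.to_records(), fh, indent=2)
        bundle["attrition"] = attrition.to_records()

        timelines = build_timelines(filtered)
        events = [ev for pid, tl in timelines.items() for ev in detect_switches(tl, pid)]
        events_frame(events).to_csv(out / "switches.csv", index=False)
        mat = switch_matrix(events)
        mat.to_csv(out / "switch_matrix.csv")
        bundle["n_switch_events"] = len(events)
        bundle["switch_matrix"] = mat

        switch_pids = {ev.patient_id for ev in events}
        cohort_pids = set(filtered["patient_id"])
        demo = demographics[demographics["patient_id"].isin(cohort_pids)]
        sw = demo[demo["patient_id"].isin(switch_pids)]
        nsw = demo[~demo["patient_id"].isin(switch_pids)]
        if len(sw) and len(nsw):
            comparison = demographic_comparison(sw, nsw)
        else:
            comparison = {"note": "one of the cohorts is empty; comparison skipped"}
        with open(out / "demographics_comparison.json", "w") as fh:
            json.dump(comparison, fh, indent=2)
        bundle["demographics_comparison"] = comparison

        tick("extract")
        extractor = RuleBasedExtractor(table)
        event_by_note = {ev.note_id: ev for ev in events if ev.note_id}
        results = extract_all(notes, extractor, note_ids=event_by_note)
        results_frame(results).to_csv(out / "extractions.csv", index=False)
        silver = [
            derive_silver_labels(timelines[ev.patient_id], ev) for ev in events if ev.note_id
        ]
        silver_frame(silver).to_csv(out / "silver_labels.csv", index=False)

        tick("evaluate")
        pred = results_frame(results)
        silver_df = silver_frame(silver)
        eval_report: dict = {"n_switch_notes": len(pred)}
        if gold is not None and len(pred):
            gold_cols = auto_annotations(pred, gold, notes)
            rep = human_eval_report(pred, gold_cols)
            eval_report["vs_gold"] = rep.to_dict()
            merged = silver_df.merge(gold_cols, on="note_id", how="inner")
            eval_report["silver_vs_gold_kappa"] = {
                "started": cohens_kappa(merged["gold_started"], merged["started"]),
                "stopped": cohens_kappa(merged["gold_stopped"], merged["stopped"]),
                "started_restricted": cohens_kappa(
                    merged["gold_started"], merged["started"], restrict_to_relevant=True
                ),
                "stopped_restricted": cohens_kappa(
                    merged["gold_stopped"], merged["stopped"], restrict_to_relevant=True
                ),
            }
        if len(pred):
            ms = pred.merge(silver_df, on="note_id", suffixes=("_pred", "_silver"))
            eval_report["vs_silver"] = {
                "started_micro_f1": micro_f1(ms["started_pred"], ms["started_silver"])[2],
                "stopped_micro_f1": micro_f1(ms["stopped_pred"], ms["stopped_silver"])[2],
            }
        with open(out / "eval_report.json", "w") as fh:
            json.dump(eval_report, fh, indent=2)
        bundle["eval_report"] = eval_report

        tick("topics")
        reasons = pred.set_index("note_id")["reason"]
        n_reasons = int((reasons.fillna("").str.strip() != "").sum())
        if "topics" not in cfg.stages or n_reasons < 10:
            if n_reasons < 10:
                log.warning("only %d extracted reasons; topic stages skipped", n_reasons)
            bundle["topics"] = {"n_topics": 0, "skipped": True}
            return _finish(cfg, out, bundle)
        tm = topic_model(
            reasons.tolist(),
            backend=cfg.topics.get("backend", "tfidf"),
            min_cluster_size=int(cfg.topics.get("min_cluster_size", 10)),
            seed=cfg.seed,
            index=reasons.index,
        )
        tm.q.to_csv(out / "topic_q.csv")
        tm.assignments.to_frame().to_csv(out / "topic_assignments.csv")
        with open(out / "topic_terms.json", "w") as fh:
            json.dump({str(k): v for k, v in tm.topic_terms.items()}, fh, indent=2)
        bundle["topics"] = {"n_topics": tm.n_topics}

        tick("enrich")
        if "enrich" in cfg.stages and tm.n_topics > 0:
            note_patients = notes.set_index("note_id")["patient_id"].reindex(tm.q.index)
            q = tm.q if cfg.include_noise_topic else tm.q.drop(columns=[0])
            q = q.loc[q.sum(axis=1) > 0]
            q = q.div(q.sum(axis=1), axis=0)
            enrich_out = {}
            for axis in cfg.enrichment_axes:
                y = stratify(demographics, axis, note_patients.loc[q.index])
                em = enrichment_scores(q, y)
                em.theta_log.to_csv(out / f"enrichment_{axis}.csv")
                em.to_long().to_csv(out / f"enrichment_{axis}_long.csv", index=False)
                enrich_out[axis] = em
            bundle["enrichment"] = enrich_out

        return _finish(cfg, out, bundle)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc


def _finish(cfg: RunConfig, out: Path, bundle: dict) -> dict:
    manifest = {
        "switchscope_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    bundle["manifest"] = manifest
    return bundle
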