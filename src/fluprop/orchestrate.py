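"""End-to-end pipeline: corpus -> features -> stats -> classifier -> correlations.

One YAML config (plus CLI overrides) drives the full analysis graph on an
input directory; all randomness flows from a single root seed split per
stage, so a rerun with the same config and seed is byte-identical.  Each
stage writes tidy TSV/JSON outputs, and a run manifest records the config
hash, seed, and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import fluprop
from fluprop.classify import ClassifierConfig, feature_set_battery
from fluprop.correlate import correlation_battery, results_frame
from fluprop.featurize import build_feature_matrix
from fluprop.fluency_corpus import ValidityRules, flag_validity, load_transcripts
from fluprop.group_stats import ancova_results_frame, mixed_ancova, tukey_posthoc
from fluprop.lexicon import load_lexicon, load_taxonomy

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    transcripts: str
    metadata: str
    lexicon: str
    taxonomy_edges: str
    taxonomy_senses: str | None = None
    invalid_words: str | None = None
    out_dir: str = "fluprop_out"
    seed: int = 0
    group_pairs: list = field(default_factory=lambda: [["AD", "HC"], ["bvFTD", "HC"]])
    feature_mode: str = "all_responses"
    classifier_iterations: int = 1000
    classifier_folds: int = 5
    knn_k: int = 5
    correlation_target: str = "ifs"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid pipeline config {path}: {exc}") from exc

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the analysis graph and write the report bundle.

    Stages: load + validity flagging -> featurization (pooled 42-feature
    matrix for classification, per-task matrix for the mixed ANCOVAs) ->
    group statistics per group pair -> feature-set classifier battery ->
    IFS correlation battery per pooled patient+control sample.  Any stage
    error aborts with a stage-labeled message.  Returns a summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    name = stage("load")
    try:
        lexicon = load_lexicon(config.lexicon)
        taxonomy = load_taxonomy(config.taxonomy_edges, config.taxonomy_senses)
        responses, meta = load_transcripts(config.transcripts, config.metadata)
        invalid = frozenset()
        if config.invalid_words:
            invalid = frozenset(
                w.strip() for w in Path(config.invalid_words).read_text().splitlines() if w.strip()
            )
        responses = flag_validity(responses, ValidityRules(invalid_words=invalid))
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    name = stage("featurize")
    try:
        fm_pooled = build_feature_matrix(
            responses, meta, lexicon, taxonomy, mode=config.feature_mode, task_mode="pooled"
        )
        fm_tasks = build_feature_matrix(
            responses, meta, lexicon, taxonomy, mode=config.feature_mode, task_mode="per_task"
        )
        fm_pooled.to_tsv(out / "features_pooled.tsv")
        fm_tasks.to_tsv(out / "features_per_task.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))

    name = stage("group_stats")
    try:
        long = _per_task_long(fm_tasks, meta)
        rows = []
        posthoc_rows = []
        for pair in config.group_pairs:
            pair = tuple(pair)
            for outcome in sorted(long["outcome"].unique()):
                sub = long[long["outcome"] == outcome].rename(columns={"score": "value"})
                try:
                    res = mixed_ancova(sub, between=pair)
                except ValueError as exc:
                    logger.warning("ANCOVA skipped for %s %s: %s", pair, outcome, exc)
                    continue
                df = ancova_results_frame(res)
                df["outcome"] = outcome
                df.insert(0, "pair", "-".join(pair))
                rows.append(df)
                inter = next(r for r in res if r.term == "group:task")
                if inter.p < 0.05:
                    for ph in tukey_posthoc(sub, between=pair):
                        posthoc_rows.append(
                            {
                                "pair": "-".join(pair),
                                "outcome": outcome,
                                "contrast": ph.contrast,
                                "mean_diff": ph.mean_diff,
                                "p": ph.p,
                                "cohen_d": ph.cohen_d,
                            }
                        )
        stats_df = pd.concat(rows, ignore_index=True)
        stats_df.to_csv(out / "ancova.tsv", sep="\t", index=False)
        pd.DataFrame(posthoc_rows).to_csv(out / "posthoc.tsv", sep="\t", index=False)
        summary["stages"]["group_stats"] = {"n_models": len(rows), "n_posthoc": len(posthoc_rows)}
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    name = stage("classify")
    try:
        clf_summary = {}
        for pair in config.group_pairs:
            pair = tuple(pair)
            labels = meta.loc[meta["group"].isin(pair), "group"]
            cfg = ClassifierConfig(
                folds=config.classifier_folds,
                iterations=config.classifier_iterations,
                knn_k=config.knn_k,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            reports = feature_set_battery(fm_pooled, labels, cfg)
            clf_summary["-".join(pair)] = {r.feature_set: r.to_dict() for r in reports}
        (out / "classification.json").write_text(json.dumps(clf_summary, indent=1))
        summary["stages"]["classify"] = {
            pair: {fs: round(rep["auc_mean"], 3) for fs, rep in reps.items()}
            for pair, reps in clf_summary.items()
        }
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    name = stage("correlate")
    try:
        wide = fm_pooled.data.join(meta[["group", config.correlation_target]], how="left")
        for task in ("phonemic", "semantic"):
            wide[f"valid_count_{task}"] = fm_pooled.data[f"valid_count_{task}"]
        measures = [c for c in wide.columns if c.endswith("_mean_both")] + [
            "valid_count_phonemic",
            "valid_count_semantic",
        ]
        corr_rows = []
        for pair in config.group_pairs:
            res = correlation_battery(
                wide,
                measures=measures,
                targets=[config.correlation_target],
                groups=tuple(pair),
                method_policy="spearman",
            )
            df = results_frame(res)
            df.insert(0, "pair", "-".join(pair))
            corr_rows.append(df)
        corr_df = pd.concat(corr_rows, ignore_index=True)
        corr_df.to_csv(out / "correlations.tsv", sep="\t", index=False)
        summary["stages"]["correlate"] = {"n_correlations": len(corr_df)}
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    manifest = {
        "config": asdict(config),
        "config_digest": config.digest(),
        "seed": config.seed,
        "fluprop_version": fluprop.__version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    summary["manifest"] = manifest["config_digest"]
    return summary


def _per_task_long(fm_tasks, meta) -> pd.DataFrame:
    """Long table of per-task outcomes: valid counts + property means."""
    records = []
    data = fm_tasks.data
    for task in ("phonemic", "semantic"):
        for col, outcome in [(f"valid_count_{task}", "valid_count")] + [
            (f"{p}_mean_{task}", p)
            for p in ("frequency", "granularity", "neighborhood", "length", "familiarity", "imageability")
        ]:
            for pid, v in data[col].items():
                records.append(
                    {"participant_id": pid, "task": task, "outcome": outcome, "score": v}
                )
    long = pd.DataFrame(records)
    return long.merge(
        meta[["participant_id", "group", "sex", "age", "education"]], on="participant_id"
    )
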