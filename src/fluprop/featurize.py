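"""Participant-level word-property feature matrices.

Each participant's responses are mapped to per-word property values
(frequency, granularity, neighborhood, length, familiarity, imageability)
and each property is summarized by seven distributional statistics: mean,
median, standard deviation, minimum, maximum, skewness, and kurtosis — 6 x 7
= 42 property-derived features, plus the per-task valid-response counts.

Trimming variants mirror the robustness checks used in group analyses:
``all_responses`` (the primary analysis; properties are computed across all
valid and invalid responses), ``valid_only``, and ``valid_outlier_trimmed``
(valid responses minus word-level values beyond k standard deviations from
the participant's group mean, per property x task x group).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from fluprop.fluency_corpus import TASKS, FluencyResponse, responses_to_frame
from fluprop.lexicon import Lexicon, TaxonomyGraph, property_table

logger = logging.getLogger(__name__)

PROPERTIES = ("frequency", "granularity", "neighborhood", "length", "familiarity", "imageability")
STATISTICS = ("mean", "median", "sd", "min", "max", "skewness", "kurtosis")
MODES = ("all_responses", "valid_only", "valid_outlier_trimmed")


def distributional_features(values: Sequence[float]) -> dict[str, float]:
    """Seven distributional statistics of a value sequence.

    Sample mean and median; standard deviation with the n-1 denominator;
    min and max; moment skewness g1 = m3 / m2^1.5 and excess kurtosis
    g2 = m4 / m2^2 - 3 (bias-uncorrected moment estimators).  Skewness and
    kurtosis are NaN when n < 3 or the sd is zero; all seven are NaN for an
    empty sequence.  Missing values must be removed by the caller.
    """
    x = np.asarray(values, dtype=float)
    out = {s: math.nan for s in STATISTICS}
    n = x.size
    if n == 0:
        return out
    out["mean"] = float(np.mean(x))
    out["median"] = float(np.median(x))
    out["sd"] = float(np.std(x, ddof=1)) if n > 1 else math.nan
    out["min"] = float(np.min(x))
    out["max"] = float(np.max(x))
    if n >= 3:
        d = x - x.mean()
        m2 = float(np.mean(d**2))
        if m2 > 0:
            out["skewness"] = float(np.mean(d**3) / m2**1.5)
            out["kurtosis"] = float(np.mean(d**4) / m2**2 - 3.0)
    return out


def trim_outliers(
    values_by_group: Mapping[str, Sequence[float]], k: float = 3.0
) -> dict[str, np.ndarray]:
    """Drop word-level values beyond ``k`` SDs from their group mean.

    Operates within one property x task; the reference mean and SD are those
    of the group's pooled word-level values.  ``k=inf`` is the identity; a
    zero-variance group keeps all its values.
    """
    out: dict[str, np.ndarray] = {}
    for group, vals in values_by_group.items():
        x = np.asarray(vals, dtype=float)
        x = x[~np.isnan(x)]
        if x.size == 0 or not np.isfinite(k):
            out[group] = x
            continue
        mu, sd = x.mean(), x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0:
            out[group] = x
        else:
            out[group] = x[np.abs(x - mu) <= k * sd]
    return out


@dataclass
class FeatureMatrix:
    """Participants x features, with explicit column metadata.

    ``data`` holds one row per participant; property-derived columns are
    named ``{property}_{statistic}_{task}`` with ``task`` in
    ``{phonemic, semantic, both}``; valid counts are ``valid_count_{task}``.
    ``column_meta`` records (property, statistic, task) per column.
    ``missingness`` counts, per participant and property x task, the words
    whose value for that property was unavailable and therefore ignored —
    the raw material for the data-comparability check across groups.
    """

    data: pd.DataFrame
    column_meta: pd.DataFrame
    missingness: pd.DataFrame
    mode: str = "all_responses"
    task_mode: str = "pooled"

    @property
    def property_columns(self) -> list[str]:
        return list(self.column_meta.index[self.column_meta["kind"] == "property"])

    @property
    def count_columns(self) -> list[str]:
        return list(self.column_meta.index[self.column_meta["kind"] == "valid_count"])

    def features(self) -> pd.DataFrame:
        """The classifier input: property-derived columns only."""
        return self.data[self.property_columns]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", na_rep="")
        sidecar = {
            "mode": self.mode,
            "task_mode": self.task_mode,
            "columns": {
                c: {k: (None if pd.isna(v) else v) for k, v in row.items()}
                for c, row in self.column_meta.to_dict(orient="index").items()
            },
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        data = pd.read_csv(path, sep="\t", index_col=0)
        sidecar = json.loads(path.with_suffix(path.suffix + ".meta.json").read_text())
        meta = pd.DataFrame.from_dict(sidecar["columns"], orient="index")
        return cls(
            data=data,
            column_meta=meta,
            missingness=pd.DataFrame(index=data.index),
            mode=sidecar["mode"],
            task_mode=sidecar["task_mode"],
        )


def _column_name(prop: str, stat: str, task: str) -> str:
    return f"{prop}_{stat}_{task}"


def build_feature_matrix(
    responses: Iterable[FluencyResponse],
    participants: pd.DataFrame,
    lexicon: Lexicon,
    taxonomy: TaxonomyGraph,
    mode: str = "all_responses",
    task_mode: str = "pooled",
    k_sd: float = 3.0,
) -> FeatureMatrix:
    """Build the participant x feature matrix.

    Per participant (x task when ``task_mode='per_task'``; both tasks' words
    pooled when ``'pooled'``) and property, the per-word values are collected
    (per-word missing values ignored), the trimming ``mode`` applied, and the
    seven distributional statistics computed.  Valid counts per task are
    attached, as are per-participant missing-word counts.

    ``task_mode='pooled'`` yields exactly 42 property-derived columns, the
    all-features classifier input; ``'per_task'`` yields 42 per task and is
    what the group-level task x group analyses consume.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    if task_mode not in ("pooled", "per_task"):
        raise ValueError(f"task_mode must be 'pooled' or 'per_task', got {task_mode!r}")
    rdf = responses_to_frame(list(responses))
    if rdf.empty or participants.empty:
        raise ValueError("empty cohort: no responses or no participants")
    if "group" not in participants.columns:
        raise ValueError("participants table must carry a 'group' column")
    pids = list(participants["participant_id"]) if "participant_id" in participants.columns else list(participants.index)

    # unintelligible tokens never reach property extraction
    rdf = rdf[rdf["invalid_reason"] != "unintelligible"]
    props = property_table(lexicon, taxonomy)
    rdf = rdf.join(props, on="normalized")
    group_of = dict(zip(pids, participants["group"]))
    rdf["group"] = rdf["participant_id"].map(group_of)

    if mode in ("valid_only", "valid_outlier_trimmed"):
        rdf = rdf[rdf["valid"]]

    feature_tasks = ("both",) if task_mode == "pooled" else TASKS
    rows: dict[str, dict[str, float]] = {pid: {} for pid in pids}
    miss_rows: dict[str, dict[str, float]] = {pid: {} for pid in pids}

    for ftask in feature_tasks:
        sub = rdf if ftask == "both" else rdf[rdf["task"] == ftask]
        for prop in PROPERTIES:
            col = sub[["participant_id", "group", prop]]
            if mode == "valid_outlier_trimmed":
                keep = np.ones(len(col), dtype=bool)
                vals = col[prop].to_numpy(dtype=float)
                for g, gidx in col.groupby("group").groups.items():
                    loc = col.index.get_indexer(gidx)
                    gv = vals[loc]
                    ok = ~np.isnan(gv)
                    if ok.sum() > 1:
                        mu, sd = gv[ok].mean(), gv[ok].std(ddof=1)
                        if sd > 0:
                            keep[loc[ok]] = np.abs(gv[ok] - mu) <= k_sd * sd
                col = col[keep]
            grouped = {pid: sub_df[prop].dropna().to_numpy() for pid, sub_df in col.groupby("participant_id")}
            n_missing = {
                pid: int(sub_df[prop].isna().sum())
                for pid, sub_df in sub.groupby("participant_id")[[prop]]
            }
            for pid in pids:
                stats = distributional_features(grouped.get(pid, ()))
                for stat, v in stats.items():
                    rows[pid][_column_name(prop, stat, ftask)] = v
                miss_rows[pid][f"{prop}_missing_{ftask}"] = n_missing.get(pid, 0)

    # valid counts always per task
    flagged = rdf if mode == "all_responses" else responses_to_frame(list(responses))
    for task in TASKS:
        cnt = (
            flagged[(flagged["task"] == task) & flagged["valid"]]
            .groupby("participant_id")
            .size()
        )
        for pid in pids:
            rows[pid][f"valid_count_{task}"] = float(cnt.get(pid, 0))

    data = pd.DataFrame.from_dict(rows, orient="index").loc[pids]
    data.index.name = "participant_id"
    meta_records = {}
    for c in data.columns:
        if c.startswith("valid_count_"):
            meta_records[c] = {"kind": "valid_count", "property": None, "statistic": None, "task": c.rsplit("_", 1)[1]}
        else:
            prop, stat, task = c.rsplit("_", 2)
            meta_records[c] = {"kind": "property", "property": prop, "statistic": stat, "task": task}
    column_meta = pd.DataFrame.from_dict(meta_records, orient="index")
    missingness = pd.DataFrame.from_dict(miss_rows, orient="index").loc[pids].fillna(0).astype(int)
    missingness.index.name = "participant_id"

    n_prop = int((column_meta["kind"] == "property").sum())
    expected = 42 * len(feature_tasks)
    if n_prop != expected:
        raise AssertionError(f"property column count {n_prop} != {expected}")
    return FeatureMatrix(
        data=data,
        column_meta=column_meta,
        missingness=missingness,
        mode=mode,
        task_mode=task_mode,
    )
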