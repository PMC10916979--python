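"""Shared fixtures: a small deterministic lexicon/taxonomy and a synthetic cohort."""

from __future__ import annotations

import networkx as nx
import pandas as pd
import pytest

from fluprop.fluency_corpus import flag_validity
from fluprop.featurize import FeatureMatrix, build_feature_matrix
from fluprop.lexicon import Lexicon, LexiconEntry, TaxonomyGraph
from fluprop.synthetic_data import SyntheticCohortSpec, make_cohort, make_lexicon


@pytest.fixture(scope="session")
def toy_taxonomy() -> TaxonomyGraph:
    """entity -> animal -> dog -> bulldog chain plus a polysemous word."""
    g = nx.DiGraph()
    for child, parent in [
        ("animal", "entity"),
        ("dog", "animal"),
        ("bulldog", "dog"),
        ("plant", "entity"),
        ("rose", "plant"),
    ]:
        g.add_edge(child, parent)
    senses = {
        "animal": {"animal"},
        "dog": {"dog"},
        "bulldog": {"bulldog"},
        "rose": {"rose"},
        # polysemous form: one shallow and one deep sense
        "mole": {"animal", "bulldog"},
    }
    return TaxonomyGraph(graph=g, senses=senses)


@pytest.fixture(scope="session")
def toy_lexicon() -> Lexicon:
    return Lexicon(
        [
            LexiconEntry("pat", ("p", "a", "t"), 1.2, 5.0, 6.0),
            LexiconEntry("bat", ("b", "a", "t"), 1.0, 4.0, 6.5),
            LexiconEntry("pit", ("p", "i", "t"), 0.8, 4.5, 5.0),
            LexiconEntry("pats", ("p", "a", "t", "s"), 0.5, 3.0, 4.0),
            LexiconEntry("at", ("a", "t"), 2.5, 6.0, 2.0),
            LexiconEntry("dog", ("d", "o", "g"), 1.8, 6.5, 6.8),
        ]
    )


@pytest.fixture(scope="session")
def ad_bundle():
    """Default AD-like synthetic cohort with feature matrices (seed 7)."""
    spec = SyntheticCohortSpec(seed=7)
    lexicon, taxonomy = make_lexicon(spec)
    responses, meta = make_cohort(spec, lexicon, taxonomy)
    responses = flag_validity(responses)
    fm_pooled = build_feature_matrix(responses, meta, lexicon, taxonomy)
    fm_tasks = build_feature_matrix(responses, meta, lexicon, taxonomy, task_mode="per_task")
    return {
        "spec": spec,
        "lexicon": lexicon,
        "taxonomy": taxonomy,
        "responses": responses,
        "meta": meta,
        "fm_pooled": fm_pooled,
        "fm_tasks": fm_tasks,
    }


def per_task_long(fm_tasks: FeatureMatrix, meta: pd.DataFrame, outcome_col: str) -> pd.DataFrame:
    """Long-format group-stats input for one per-task outcome stem."""
    rows = []
    for task in ("phonemic", "semantic"):
        for pid, v in fm_tasks.data[f"{outcome_col}_{task}"].items():
            rows.append({"participant_id": pid, "task": task, "value": v})
    return pd.DataFrame(rows).merge(
        meta[["participant_id", "group", "sex", "age", "education"]], on="participant_id"
    )
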