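"""Fluency transcripts, response validity, and the valid-response score.

A verbal-fluency trial is one minute of word generation constrained by an
initial phoneme (phonemic task) or a semantic category (semantic task).  The
standard performance score is the number of *valid* responses: words
complying with the instructions (no proper names, numbers, repetitions, or
same-family/morphological variants).  Unintelligible tokens are discarded
from all property analyses but retained in the raw records for audit.

Proper-name and morphological-family judgments are adjudicated by human
examiners in practice; they enter here through a per-study invalid-word
list rather than an automated heuristic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from fluprop.lexicon import normalize_form

logger = logging.getLogger(__name__)

TASKS = ("phonemic", "semantic")
GROUPS = ("AD", "bvFTD", "HC")

INVALID_REASONS = ("repetition", "rule_violation", "listed_invalid", "unintelligible")

_DIGIT_RE = re.compile(r"\d")


@dataclass(frozen=True)
class FluencyResponse:
    """One uttered word in a participant x task trial."""

    participant_id: str
    task: str
    position: int  # 1-based utterance index
    raw: str
    normalized: str = ""
    valid: bool = True
    invalid_reason: str | None = None

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}; expected one of {TASKS}")
        if self.position < 1:
            raise ValueError("position is 1-based")
        if (self.invalid_reason is None) != self.valid:
            raise ValueError("valid=False iff invalid_reason is set")
        if self.invalid_reason is not None and self.invalid_reason not in INVALID_REASONS:
            raise ValueError(f"unknown invalid_reason {self.invalid_reason!r}")


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject: diagnostic group, demographics, cognitive scores."""

    participant_id: str
    group: str
    sex: str = "F"
    age: float = 0.0
    education: float = 0.0
    handedness: str = "R"
    moca: float | None = None
    ifs: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.age < 0 or self.education < 0:
            raise ValueError("age and education must be non-negative")


@dataclass
class ValidityRules:
    """Configuration of the validity flags.

    invalid_words: the study-specific list of examiner-adjudicated invalid
    tokens (proper names, same-family variants).  unintelligible_markers:
    transcription placeholders for unintelligible speech.
    """

    invalid_words: frozenset[str] = frozenset()
    unintelligible_markers: frozenset[str] = frozenset({"xxx", "<unintelligible>"})

    def __post_init__(self) -> None:
        self.invalid_words = frozenset(normalize_form(w) for w in self.invalid_words)
        self.unintelligible_markers = frozenset(
            normalize_form(w) for w in self.unintelligible_markers
        )


def load_transcripts(
    path: str | Path, metadata_path: str | Path
) -> tuple[list[FluencyResponse], pd.DataFrame]:
    """Read long-format transcripts and the participant metadata table.

    Transcripts: TSV with columns ``participant_id, task, position, word``.
    Metadata: TSV with columns ``participant_id, group, sex, age, education,
    handedness, moca, ifs`` (cognitive scores optional).  Every transcript
    participant must appear in the metadata; orphans raise an error naming
    them.  Responses are returned ordered by participant, task, position.
    """
    tdf = pd.read_csv(path, sep="\t", dtype={"participant_id": str, "word": str})
    required = {"participant_id", "task", "position", "word"}
    if not required.issubset(tdf.columns):
        raise ValueError(f"transcript file missing columns {sorted(required - set(tdf.columns))}")
    bad_tasks = sorted(set(tdf["task"]) - set(TASKS))
    if bad_tasks:
        raise ValueError(f"unknown task labels {bad_tasks}; expected {TASKS}")
    mdf = pd.read_csv(metadata_path, sep="\t", dtype={"participant_id": str})
    if "participant_id" not in mdf.columns or "group" not in mdf.columns:
        raise ValueError("metadata file must have participant_id and group columns")
    orphans = sorted(set(tdf["participant_id"]) - set(mdf["participant_id"]))
    if orphans:
        raise ValueError(f"transcript participants missing from metadata: {orphans}")
    # empty-trial sentinel rows (word == "") keep zero-response trials visible
    tdf = tdf[tdf["word"].fillna("") != ""]
    tdf = tdf.sort_values(["participant_id", "task", "position"])
    responses = [
        FluencyResponse(
            participant_id=row.participant_id,
            task=row.task,
            position=int(row.position),
            raw=row.word,
            normalized=normalize_form(row.word),
        )
        for row in tdf.itertuples()
    ]
    mdf = mdf.set_index("participant_id", drop=False)
    mdf.index.name = None  # keep participant_id addressable as a column
    return responses, mdf


def flag_validity(
    responses: Iterable[FluencyResponse], rules: ValidityRules | None = None
) -> list[FluencyResponse]:
    """Set validity flags on responses.

    Within each participant x task trial, in utterance order:

    - tokens matching an unintelligible marker -> ``unintelligible`` (these
      are excluded from all downstream property analysis);
    - tokens containing a digit -> ``rule_violation``;
    - tokens on the study's invalid-word list -> ``listed_invalid``;
    - exact normalized duplicates after their first occurrence ->
      ``repetition`` (the first occurrence keeps its own status).

    Idempotent: reflagging already-flagged responses yields the same result.
    """
    rules = rules or ValidityRules()
    out: list[FluencyResponse] = []
    seen: dict[tuple[str, str], set[str]] = {}
    for r in sorted(responses, key=lambda r: (r.participant_id, r.task, r.position)):
        norm = r.normalized or normalize_form(r.raw)
        trial = seen.setdefault((r.participant_id, r.task), set())
        if norm in rules.unintelligible_markers:
            reason = "unintelligible"
        elif _DIGIT_RE.search(norm):
            reason = "rule_violation"
        elif norm in rules.invalid_words:
            reason = "listed_invalid"
        elif norm in trial:
            reason = "repetition"
        else:
            reason = None
        if reason != "unintelligible":
            trial.add(norm)
        out.append(replace(r, normalized=norm, valid=reason is None, invalid_reason=reason))
    return out


def valid_count(
    responses: Iterable[FluencyResponse], participant_id: str, task: str
) -> int:
    """Number of valid responses for one participant x task trial."""
    if task not in TASKS:
        raise KeyError(f"unknown task {task!r}")
    matched = [r for r in responses if r.participant_id == participant_id and r.task == task]
    if not matched:
        # distinguish "trial exists but empty" from "no such participant":
        # callers track empty trials with zero rows either way, so a missing
        # pair is a lookup error only when the participant never appears.
        all_ids = {r.participant_id for r in responses}
        if participant_id not in all_ids:
            raise KeyError(f"no responses for participant {participant_id!r}")
        return 0
    return sum(r.valid for r in matched)


def responses_to_frame(responses: Sequence[FluencyResponse]) -> pd.DataFrame:
    """Long-format DataFrame view of a response list."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in responses],
            "task": [r.task for r in responses],
            "position": [r.position for r in responses],
            "word": [r.raw for r in responses],
            "normalized": [r.normalized for r in responses],
            "valid": [r.valid for r in responses],
            "invalid_reason": [r.invalid_reason for r in responses],
        }
    )
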