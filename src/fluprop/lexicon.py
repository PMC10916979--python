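"""Psycholinguistic lexicons, hypernym taxonomies, and per-word properties.

A lexicon maps each orthographic word form to its normative psycholinguistic
variables: log10 frequency per million tokens, a phoneme sequence,
familiarity, and imageability (both rated 1-7).  A taxonomy is a rooted
hypernym hierarchy ("entity" -> "animal" -> "dog" -> "bulldog"); the depth of
a word's concept in that hierarchy is its *granularity* — larger values mean
more specific concepts.  The sixth word property, *phonological
neighborhood*, is the number of lexicon words reachable from a form by
substituting, adding, or omitting exactly one phoneme.

Any property a word lacks resolves to missing (``None`` / NaN), never to an
error: downstream stages ignore missing values per property.
"""

from __future__ import annotations

import logging
import unicodedata
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ROOT_CONCEPT = "entity"

#: canonical lexicon column order
LEXICON_COLUMNS = ("form", "phonemes", "log_freq_pm", "familiarity", "imageability")


def normalize_form(form: str) -> str:
    """Lowercase and strip combining accent marks for lookup keys.

    Transcript/lexicon orthography mismatch (casing, accents) is the dominant
    lookup failure mode; normalization is applied to keys only, the original
    form is preserved wherever entries are stored.
    """
    decomposed = unicodedata.normalize("NFKD", form.strip().lower())
    return "".join(ch for ch in decomposed if not unicodedata.combining(ch))


@dataclass(frozen=True)
class LexiconEntry:
    """One word form with its normative psycholinguistic variables."""

    form: str
    phonemes: tuple[str, ...] | None = None
    log_freq_pm: float | None = None
    familiarity: float | None = None
    imageability: float | None = None

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError("LexiconEntry.form must be non-empty")
        for name in ("familiarity", "imageability"):
            v = getattr(self, name)
            if v is not None and not (1.0 <= v <= 7.0):
                raise ValueError(f"{name}={v} outside the 1-7 rating scale")
        if self.phonemes is not None and len(self.phonemes) == 0:
            raise ValueError("phoneme sequence must be non-empty when present")


@dataclass(frozen=True)
class PropertyVector:
    """The six per-word properties; each value real-or-missing.

    granularity, neighborhood and length are non-negative integers when
    present.
    """

    frequency: float | None = None
    granularity: int | None = None
    neighborhood: int | None = None
    length: int | None = None
    familiarity: float | None = None
    imageability: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "frequency": self.frequency,
            "granularity": self.granularity,
            "neighborhood": self.neighborhood,
            "length": self.length,
            "familiarity": self.familiarity,
            "imageability": self.imageability,
        }


class Lexicon:
    """A collection of :class:`LexiconEntry`, keyed by normalized form."""

    def __init__(self, entries: Iterable[LexiconEntry]):
        self._entries: dict[str, LexiconEntry] = {}
        for e in entries:
            key = normalize_form(e.form)
            if key in self._entries:
                logger.warning("duplicate lexicon form %r collapsed to first occurrence", e.form)
                continue
            self._entries[key] = e
        self._neighborhood: dict[str, int] | None = None

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, form: str) -> bool:
        return normalize_form(form) in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def get(self, form: str) -> LexiconEntry | None:
        return self._entries.get(normalize_form(form))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "form": e.form,
                "phonemes": " ".join(e.phonemes) if e.phonemes else "",
                "log_freq_pm": e.log_freq_pm,
                "familiarity": e.familiarity,
                "imageability": e.imageability,
            }
            for e in self._entries.values()
        ]
        return pd.DataFrame(rows, columns=list(LEXICON_COLUMNS))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    # -- phonological neighborhood -------------------------------------------------

    def _sequences(self) -> dict[str, tuple[str, ...]]:
        """Phoneme sequence per key.

        A lexicon with no phoneme data at all is treated as graphemic: each
        form's characters stand in for phonemes, with a logged downgrade (a
        usable approximation for orthographically shallow languages).  In a
        mixed lexicon, forms lacking a phoneme sequence are simply absent
        (their neighborhood is missing) rather than silently mixing units.
        """
        if all(e.phonemes is None for e in self._entries.values()):
            logger.warning("lexicon has no phoneme data; grapheme fallback for neighborhood")
            return {key: tuple(key) for key in self._entries}
        return {key: e.phonemes for key, e in self._entries.items() if e.phonemes}

    def neighborhood_counts(self) -> dict[str, int]:
        """One-edit phonological neighbor count per normalized form.

        Two forms are neighbors when their phoneme sequences differ by exactly
        one substitution, insertion, or deletion (no transpositions).  Forms
        with identical sequences (homophones) are distance 0, not neighbors.
        Computed once per lexicon with a wildcard/deletion index instead of an
        all-pairs scan.
        """
        if self._neighborhood is not None:
            return self._neighborhood
        seqs = self._sequences()
        seq_count: Counter[tuple[str, ...]] = Counter(seqs.values())
        # substitution index: (position-wildcarded sequence) -> count
        sub_index: Counter[tuple] = Counter()
        for seq in seqs.values():
            for i in range(len(seq)):
                sub_index[(i, seq[:i], seq[i + 1 :])] += 1
        # deletion index: string obtained by deleting one phoneme -> count of source words
        del_index: Counter[tuple[str, ...]] = Counter()
        for seq in seqs.values():
            for d in {seq[:i] + seq[i + 1 :] for i in range(len(seq))}:
                del_index[d] += 1
        counts: dict[str, int] = {}
        for key, seq in seqs.items():
            homophones = seq_count[seq] - 1
            subs = sum(
                sub_index[(i, seq[:i], seq[i + 1 :])] - 1 for i in range(len(seq))
            )
            # identical sequences matched the wildcard at every position
            subs -= len(seq) * homophones
            deletions = sum(seq_count[d] for d in {seq[:i] + seq[i + 1 :] for i in range(len(seq))})
            insertions = del_index[seq]
            counts[key] = subs + deletions + insertions
        self._neighborhood = counts
        return counts


def load_lexicon(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> Lexicon:
    """Load a delimited-text lexicon.

    Parameters
    ----------
    path
        UTF-8 CSV/TSV with a header row.  The delimiter is sniffed from the
        extension unless ``sep`` is given.
    dialect
        Optional mapping from the file's column names to the canonical names
        ``form, phonemes, log_freq_pm, familiarity, imageability``, so
        database exports load without editing.  Phonemes are space-separated
        symbols.

    Absent columns yield missing values; duplicate forms collapse to the
    first occurrence with a logged warning.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise OSError(f"cannot read lexicon file {path}: {exc}") from exc
    if dialect:
        df = df.rename(columns=dict(dialect))
    if "form" not in df.columns:
        raise ValueError(f"lexicon file {path} has no 'form' column (columns: {list(df.columns)})")

    def _num(row: pd.Series, col: str) -> float | None:
        raw = row.get(col, "")
        if raw is None or str(raw).strip() == "":
            return None
        return float(raw)

    entries = []
    for _, row in df.iterrows():
        phon_raw = str(row.get("phonemes", "")).strip()
        entries.append(
            LexiconEntry(
                form=str(row["form"]).strip(),
                phonemes=tuple(phon_raw.split()) if phon_raw else None,
                log_freq_pm=_num(row, "log_freq_pm"),
                familiarity=_num(row, "familiarity"),
                imageability=_num(row, "imageability"),
            )
        )
    return Lexicon(entries)


@dataclass
class TaxonomyGraph:
    """A rooted hypernym hierarchy with a word-form -> concept sense map.

    Edges point child -> parent (hyponym -> hypernym); every node must reach
    the root concept ``entity``.  A word form may map to several senses
    (polysemy).
    """

    graph: nx.DiGraph
    senses: dict[str, set[str]] = field(default_factory=dict)
    root: str = ROOT_CONCEPT

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.root not in self.graph:
            raise ValueError(f"root concept {self.root!r} not in taxonomy")
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("taxonomy graph contains a cycle")
        unreachable = [
            n for n in self.graph.nodes if not nx.has_path(self.graph, n, self.root)
        ]
        if unreachable:
            raise ValueError(f"taxonomy nodes cannot reach root: {unreachable[:10]}")
        missing = {
            n for nodes in self.senses.values() for n in nodes if n not in self.graph
        }
        if missing:
            raise ValueError(f"sense map references unknown nodes: {sorted(missing)[:10]}")

    def depth(self, node: str) -> int:
        """Shortest hypernym-path length in edges from node to root."""
        return nx.shortest_path_length(self.graph, node, self.root)

    def senses_of(self, form: str) -> set[str]:
        return self.senses.get(normalize_form(form), set())


def load_taxonomy(
    edges_path: str | Path,
    senses_path: str | Path | None = None,
    root: str = ROOT_CONCEPT,
) -> TaxonomyGraph:
    """Load a taxonomy from a child<TAB>parent edge list.

    ``senses_path`` is an optional two-column ``form<TAB>node`` file; without
    it, each node identifier doubles as its own word form.  WordNet-style
    noun hierarchies can be exported to this format (synset name per node,
    lemma -> synset pairs in the sense file).
    """
    g = nx.DiGraph()
    g.add_node(root)
    with open(edges_path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            child, parent = line.split("\t")
            g.add_edge(child, parent)
    senses: dict[str, set[str]] = defaultdict(set)
    if senses_path is not None:
        with open(senses_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                form, node = line.split("\t")
                senses[normalize_form(form)].add(node)
    else:
        for n in g.nodes:
            senses[normalize_form(n)].add(n)
    return TaxonomyGraph(graph=g, senses=dict(senses), root=root)


def granularity(form: str, taxonomy: TaxonomyGraph) -> int | None:
    """Depth of a word's concept below the root hypernym, in edges.

    Counts edges on the shortest path from a sense node to the root
    ("entity"); with several senses the minimum depth wins, so the measure is
    deterministic without sense disambiguation.  Larger values mean more
    specific concepts.  Missing (``None``) when the form has no sense in the
    taxonomy.
    """
    nodes = taxonomy.senses_of(form)
    if not nodes:
        return None
    return min(taxonomy.depth(n) for n in nodes)


def one_phoneme_apart(a: Sequence[str], b: Sequence[str]) -> bool:
    """True when sequences differ by exactly one substitution/insertion/deletion."""
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # a is shorter by one: check b with one element deleted equals a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return tuple(a[i:]) == tuple(b[i + 1 :])


def phonological_neighborhood(form: str, lexicon: Lexicon) -> int | None:
    """Number of lexicon words one phoneme edit away from ``form``.

    Counts entries (excluding the form itself) whose phoneme sequence differs
    by exactly one substitution, insertion, or deletion; transpositions do not
    count.  Missing when the form is not in the lexicon.
    """
    key = normalize_form(form)
    if lexicon.get(key) is None:
        return None
    return lexicon.neighborhood_counts().get(key)


def word_properties(
    form: str, lexicon: Lexicon, taxonomy: TaxonomyGraph
) -> PropertyVector:
    """Assemble the six-property vector for one word.

    Frequency, familiarity and imageability come straight from the lexicon,
    length is the phoneme count, neighborhood and granularity come from
    :func:`phonological_neighborhood` and :func:`granularity`.  Every
    unavailable source resolves to a per-property missing value; the function
    never raises on arbitrary strings.
    """
    entry = lexicon.get(form)
    gran = granularity(form, taxonomy)
    if entry is None:
        return PropertyVector(granularity=gran)
    return PropertyVector(
        frequency=entry.log_freq_pm,
        granularity=gran,
        neighborhood=phonological_neighborhood(form, lexicon),
        length=len(entry.phonemes) if entry.phonemes else None,
        familiarity=entry.familiarity,
        imageability=entry.imageability,
    )


def property_table(lexicon: Lexicon, taxonomy: TaxonomyGraph) -> pd.DataFrame:
    """Six-property table for every lexicon form, indexed by normalized form.

    Bulk companion to :func:`word_properties`; the neighborhood index is
    built once, so featurizing whole cohorts stays cheap.
    """
    nb = lexicon.neighborhood_counts()
    rows = {}
    for e in lexicon:
        key = normalize_form(e.form)
        gran = granularity(key, taxonomy)
        rows[key] = (
            e.log_freq_pm,
            float(gran) if gran is not None else np.nan,
            float(nb[key]) if key in nb else np.nan,
            float(len(e.phonemes)) if e.phonemes else np.nan,
            e.familiarity,
            e.imageability,
        )
    df = pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["frequency", "granularity", "neighborhood", "length", "familiarity", "imageability"],
    ).astype(float)
    df.index.name = "form"
    return df
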