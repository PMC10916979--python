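"""Lexicon loading, granularity, and phonological neighborhood."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluprop.lexicon import (
    Lexicon,
    LexiconEntry,
    granularity,
    load_lexicon,
    load_taxonomy,
    normalize_form,
    one_phoneme_apart,
    phonological_neighborhood,
    word_properties,
)


class TestLoadLexicon:
    def test_full_roundtrip(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text(
            "form\tphonemes\tlog_freq_pm\tfamiliarity\timageability\n"
            "perro\tp e r o\t1.5\t6.5\t6.9\n"
            "gato\tg a t o\t1.3\t6.0\t6.8\n"
            "ornitorrinco\to r n i t o r i n k o\t-0.5\t2.0\t4.0\n"
        )
        lex = load_lexicon(p)
        assert len(lex) == 3
        e = lex.get("perro")
        assert e.phonemes == ("p", "e", "r", "o")
        assert e.log_freq_pm == 1.5 and e.familiarity == 6.5

    def test_missing_cell_propagates(self, tmp_path):
        p = tmp_path / "lex.csv"
        p.write_text("form,phonemes,log_freq_pm,familiarity,imageability\nperro,p e r o,1.5,,6.9\n")
        assert load_lexicon(p).get("perro").familiarity is None

    def test_absent_column_yields_missing(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("form\tlog_freq_pm\nperro\t1.5\n")
        e = load_lexicon(p).get("perro")
        assert e.familiarity is None and e.imageability is None and e.phonemes is None

    def test_duplicate_form_collapses_with_warning(self, tmp_path, caplog):
        p = tmp_path / "lex.tsv"
        p.write_text("form\tlog_freq_pm\nperro\t1.5\nperro\t9.9\n")
        with caplog.at_level(logging.WARNING):
            lex = load_lexicon(p)
        assert len(lex) == 1
        assert lex.get("perro").log_freq_pm == 1.5  # first occurrence wins
        assert any("duplicate" in r.message for r in caplog.records)

    def test_no_form_column_is_schema_error(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("word\tfreq\nperro\t1\n")
        with pytest.raises(ValueError, match="form"):
            load_lexicon(p)

    def test_dialect_remaps_columns(self, tmp_path):
        p = tmp_path / "espal_export.csv"
        p.write_text("palabra,frq\nperro,1.5\n")
        lex = load_lexicon(p, dialect={"palabra": "form", "frq": "log_freq_pm"})
        assert lex.get("perro").log_freq_pm == 1.5

    def test_normalization_strips_accents(self):
        assert normalize_form("  Árbol ") == "arbol"


class TestGranularity:
    def test_direct_child_of_root(self, toy_taxonomy):
        assert granularity("animal", toy_taxonomy) == 1

    def test_chain_depth_counts_edges(self, toy_taxonomy):
        # entity -> animal -> dog -> bulldog: three edges below the root
        assert granularity("bulldog", toy_taxonomy) == 3
        assert granularity("dog", toy_taxonomy) == 2

    def test_polysemy_resolves_to_minimum_depth(self, toy_taxonomy):
        # "mole" has senses at depths 1 and 3; shallower (more general) wins,
        # consistent with low-bin words being closer to the root
        assert granularity("mole", toy_taxonomy) == 1

    def test_absent_word_is_missing_not_error(self, toy_taxonomy):
        assert granularity("unicornio", toy_taxonomy) is None

    def test_depth_monotone_along_edges(self, ad_bundle):
        tax = ad_bundle["taxonomy"]
        for child, parent in tax.graph.edges:
            assert tax.depth(parent) <= tax.depth(child)

    def test_taxonomy_file_roundtrip(self, tmp_path, toy_taxonomy):
        edges = tmp_path / "edges.tsv"
        edges.write_text(
            "".join(f"{c}\t{p}\n" for c, p in toy_taxonomy.graph.edges)
        )
        senses = tmp_path / "senses.tsv"
        senses.write_text(
            "".join(
                f"{form}\t{node}\n"
                for form, nodes in toy_taxonomy.senses.items()
                for node in sorted(nodes)
            )
        )
        tax = load_taxonomy(edges, senses)
        assert granularity("bulldog", tax) == 3
        assert granularity("mole", tax) == 1

    def test_cycle_rejected(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        edges.write_text("a\tb\nb\ta\n")
        with pytest.raises(ValueError):
            load_taxonomy(edges)

    def test_unreachable_node_rejected(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        edges.write_text("a\tentity\nc\td\n")
        with pytest.raises(ValueError, match="reach root"):
            load_taxonomy(edges)


class TestNeighborhood:
    def test_substitution_insertion_deletion_counted(self, toy_lexicon):
        # pat: bat (sub), pit (sub), pats (insertion), at (deletion) -> 4
        assert phonological_neighborhood("pat", toy_lexicon) == 4

    def test_lonely_target_has_zero(self):
        lex = Lexicon([LexiconEntry("dog", ("d", "o", "g"))])
        assert phonological_neighborhood("dog", lex) == 0

    def test_form_without_phonemes_in_mixed_lexicon_is_missing(self):
        lex = Lexicon(
            [LexiconEntry("dog", ("d", "o", "g")), LexiconEntry("cat", None, 1.0)]
        )
        assert phonological_neighborhood("cat", lex) is None

    def test_graphemic_lexicon_falls_back_to_characters(self, caplog):
        lex = Lexicon([LexiconEntry("cat"), LexiconEntry("bat"), LexiconEntry("cut")])
        with caplog.at_level(logging.WARNING):
            assert phonological_neighborhood("cat", lex) == 2

    def test_counts_match_pairwise_oracle_on_random_lexicons(self):
        rng = np.random.default_rng(42)
        symbols = list("abcdt")
        for trial in range(5):
            n = 40
            seqs = []
            forms = set()
            for i in range(n):
                seq = tuple(rng.choice(symbols, size=rng.integers(1, 5)))
                form = f"w{i}_" + "".join(seq)
                forms.add(form)
                seqs.append((form, seq))
            lex = Lexicon([LexiconEntry(f, s) for f, s in seqs])
            counts = lex.neighborhood_counts()
            for f, s in seqs:
                oracle = sum(
                    one_phoneme_apart(s, s2) for f2, s2 in seqs if f2 != f
                )
                assert counts[f.lower()] == oracle, (f, s)

    def test_neighbor_relation_is_symmetric(self):
        rng = np.random.default_rng(3)
        seqs = [tuple(rng.choice(list("abc"), size=rng.integers(1, 4))) for _ in range(30)]
        for a in seqs:
            for b in seqs:
                assert one_phoneme_apart(a, b) == one_phoneme_apart(b, a)


class TestWordProperties:
    def test_fully_resolvable_word(self, toy_lexicon, toy_taxonomy):
        lex2 = Lexicon(list(toy_lexicon))
        pv = word_properties("dog", lex2, toy_taxonomy)
        assert pv.frequency == 1.8
        assert pv.granularity == 2
        assert pv.length == 3
        assert pv.neighborhood == 0
        assert pv.familiarity == 6.5

    def test_out_of_lexicon_word_fully_missing(self, toy_lexicon, toy_taxonomy):
        pv = word_properties("zzzz", toy_lexicon, toy_taxonomy)
        assert all(v is None for v in pv.as_dict().values())

    def test_missingness_is_per_property(self, toy_lexicon, toy_taxonomy):
        # in lexicon but absent from taxonomy: only granularity missing
        pv = word_properties("pat", toy_lexicon, toy_taxonomy)
        assert pv.granularity is None
        assert pv.frequency == 1.2 and pv.neighborhood == 4 and pv.length == 3

    @settings(max_examples=50, deadline=None)
    @given(st.text(max_size=12))
    def test_never_raises_on_arbitrary_strings(self, toy_lexicon, toy_taxonomy, form):
        word_properties(form, toy_lexicon, toy_taxonomy)


def test_entry_invariants_enforced():
    with pytest.raises(ValueError):
        LexiconEntry("")
    with pytest.raises(ValueError):
        LexiconEntry("perro", familiarity=8.0)
    with pytest.raises(ValueError):
        LexiconEntry("perro", phonemes=())
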