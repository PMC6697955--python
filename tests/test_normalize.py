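"""Mention normalization: cleaning, positional splitting, expansion."""

import pytest

from anatomap import (
    Mention,
    expand_abbreviation,
    normalize_mention,
    reattach_positional,
    resolve_term,
    stem_and_clean,
    strip_positional,
)
from anatomap.normalize import (
    InvalidMentionError,
    Resources,
    load_coref_chains,
    singularize,
)


def mk(surface, chain=None):
    return Mention("doc1", "m1", 0, max(len(surface), 1), surface, chain)


class TestStemAndClean:
    def test_plural_and_positional_tokens(self):
        assert stem_and_clean("left extremities") == ["left", "extrem"]

    def test_stopwords_removed(self):
        assert stem_and_clean("the heart") == ["heart"]

    def test_empty(self):
        assert stem_and_clean("") == []

    def test_case_and_punctuation(self):
        assert stem_and_clean("HEART!") == ["heart"]

    @pytest.mark.parametrize(
        "plural,singular",
        [("feet", "foot"), ("teeth", "tooth"), ("vertebrae", "vertebra"),
         ("legs", "leg"), ("branches", "branch"), ("pelvises", "pelvis")],
    )
    def test_singularize(self, plural, singular):
        assert singularize(plural) == singular


class TestStripPositional:
    def test_trailing_adverb(self, resources, onto):
        tokens = stem_and_clean("legs bilaterally")
        pos, core = strip_positional(tokens, resources.positional_vocab, onto)
        assert pos == ["bilateral"] and core == ["leg"]

    def test_leading_positional(self, resources, onto):
        tokens = stem_and_clean("left extremities")
        pos, core = strip_positional(tokens, resources.positional_vocab, onto)
        assert pos == ["left"] and core == ["extrem"]

    def test_no_positional(self, resources, onto):
        pos, core = strip_positional(["heart"], resources.positional_vocab, onto)
        assert pos == [] and core == ["heart"]

    def test_protected_part_name(self, resources, onto):
        # "lower extremity" is itself a part name: nothing may be stripped
        tokens = stem_and_clean("lower extremity")
        pos, core = strip_positional(tokens, resources.positional_vocab, onto)
        assert pos == [] and core == tokens

    def test_positional_before_protected_name(self, resources, onto):
        tokens = stem_and_clean("left lower extremity")
        pos, core = strip_positional(tokens, resources.positional_vocab, onto)
        assert pos == ["left"]
        assert resolve_term(onto, core).id == "lower-extremity"

    def test_protection_over_all_aliases(self, resources, onto):
        # stripping never alters a sequence that already names a part
        for key in onto.alias_index:
            pos, core = strip_positional(
                list(key), resources.positional_vocab, onto
            )
            assert pos == [] and tuple(core) == key

    def test_purely_positional_mention(self, resources, onto):
        pos, core = strip_positional(["bilater"], resources.positional_vocab, onto)
        assert pos == ["bilateral"] and core == []


class TestExpandAbbreviation:
    def test_multi_part_dictionary_entry(self, resources):
        expansions, prov = expand_abbreviation(["heent"], resources)
        assert prov == "dictionary"
        assert [" ".join(e) for e in expansions] == ["head", "ey", "ear", "nose", "throat"]

    def test_single_dictionary_entry(self, resources):
        expansions, prov = expand_abbreviation(["ext"], resources)
        assert prov == "dictionary" and expansions == [("extrem",)]

    def test_unknown_key(self, resources):
        assert expand_abbreviation(["qzx"], resources) == ([], "plain")

    def test_coreference_initials_beat_dictionary(self, resources, tmp_path):
        chains_path = tmp_path / "coref_chains.tsv"
        chains_path.write_text(
            "chain_id\tdoc_id\tmember_text\n"
            "c1\tdoc1\tUE\n"
            "c1\tdoc1\tupper extremity\n"
        )
        res = Resources(
            stopwords=resources.stopwords,
            positional_vocab=resources.positional_vocab,
            abbreviations=resources.abbreviations,
            coref_chains=load_coref_chains(chains_path),
        )
        expansions, prov = expand_abbreviation(
            ["ue"], res, doc_id="doc1", coref_chain_id="c1", surface="UE"
        )
        assert prov == "coreference" and expansions == [("upper", "extrem")]

    def test_coreference_prefix_rule(self, resources):
        res = Resources(
            stopwords=resources.stopwords,
            positional_vocab=resources.positional_vocab,
            abbreviations=resources.abbreviations,
            coref_chains={("doc1", "c9"): ["extrem", "extremities"]},
        )
        expansions, prov = expand_abbreviation(
            ["extrem"], res, doc_id="doc1", coref_chain_id="c9", surface="extrem"
        )
        assert prov == "coreference" and expansions == [("extrem",)]


class TestNormalizeMention:
    def test_positional_split(self, resources, onto):
        nm = normalize_mention(mk("legs bilaterally"), resources, onto)
        assert nm.core_tokens == ("leg",)
        assert nm.positionals == ("bilateral",)
        assert nm.provenance == "plain"

    def test_dictionary_expansion(self, resources, onto):
        nm = normalize_mention(mk("EXT"), resources, onto)
        assert nm.expansions == (("extrem",),) and nm.provenance == "dictionary"

    def test_plain_term(self, resources, onto):
        nm = normalize_mention(mk("heart"), resources, onto)
        assert nm.core_tokens == ("heart",)
        assert nm.positionals == () and nm.expansions == ()

    def test_empty_surface_rejected(self, resources, onto):
        with pytest.raises(InvalidMentionError):
            normalize_mention(mk("   "), resources, onto)

    def test_idempotent_on_own_output(self, resources, onto):
        for surface in ("legs bilaterally", "left extremities", "the heart",
                        "lower extremity", "mitral valve"):
            first = normalize_mention(mk(surface), resources, onto)
            rendered = " ".join(first.positionals + first.core_tokens)
            second = normalize_mention(mk(rendered), resources, onto)
            assert second.core_tokens == first.core_tokens
            assert second.positionals == first.positionals

    def test_plural_invariance_over_all_parts(self, resources, onto):
        # the naive plural of every formal name resolves to the same node
        for node in onto:
            name = node.formal_name
            plural = name + ("es" if name.endswith(("s", "x", "z", "ch", "sh")) else "s")
            nm = normalize_mention(mk(plural), resources, onto)
            part = resolve_term(onto, nm.core_tokens)
            assert part is not None and part.id == node.id, plural


class TestReattach:
    @pytest.mark.parametrize(
        "positionals,label,expected",
        [
            (["bilateral"], "lower extremity", "bilateral lower extremity"),
            (["left"], "extremity", "left extremity"),
            ([], "heart", "heart"),
        ],
    )
    def test_examples(self, positionals, label, expected):
        assert reattach_positional(positionals, label) == expected

    def test_round_trip_through_resolution(self, resources, onto):
        nm = normalize_mention(mk("legs bilaterally"), resources, onto)
        part = resolve_term(onto, nm.core_tokens)
        final = reattach_positional(nm.positionals, part.formal_name)
        assert final == "bilateral lower extremity"
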