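import numpy as np
import pytest

from speechscreen.linguistic import (
    IULexicon,
    TaggedTranscript,
    count_info_units,
    extract_linguistic,
    info_word_ratio,
    pos_ratios,
    read_transcript_conll,
    read_transcripts_jsonl,
    ttr,
    write_transcripts_jsonl,
)


def make_transcript(*pairs):
    return TaggedTranscript(list(pairs), subject_id="t")


class TestDefaultLexicon:
    def test_category_sizes_match_inventory(self):
        sizes = IULexicon.default().category_sizes()
        assert sizes == {"people": 3, "objects": 12, "places": 2, "actions": 7}

    def test_validates(self):
        IULexicon.default().validate()


class TestPosRatios:
    def test_three_nouns_of_ten(self):
        toks = [("a", "NN")] * 3 + [("b", "AD")] * 7
        assert pos_ratios(make_transcript(*toks)) == (0.3, 0.0, 0.0)

    def test_all_pronouns(self):
        toks = [("he", "PN")] * 4
        assert pos_ratios(make_transcript(*toks)) == (0.0, 0.0, 1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pos_ratios(make_transcript())

    def test_custom_tag_mapping(self):
        toks = [("cat", "NOUN"), ("runs", "VERB")]
        mapping = {"noun": ("NOUN",), "verb": ("VERB",), "pronoun": ()}
        assert pos_ratios(make_transcript(*toks), mapping) == (0.5, 0.5, 0.0)


class TestTTR:
    def test_all_identical_tokens(self):
        toks = [("ab", "NN")] * 5
        w, _ = ttr(make_transcript(*toks))
        assert w == pytest.approx(1 / 5)

    def test_all_distinct_tokens(self):
        toks = [(s, "NN") for s in ("aa", "bb", "cc")]
        w, _ = ttr(make_transcript(*toks))
        assert w == 1.0

    def test_hand_counted_characters(self):
        # tokens AB BC AB -> chars A,B,B,C,A,B: 2/3 word types, 3/6 char types
        toks = [("AB", "NN"), ("BC", "NN"), ("AB", "NN")]
        w, c = ttr(make_transcript(*toks))
        assert w == pytest.approx(2 / 3)
        assert c == pytest.approx(3 / 6)

    def test_case_normalization_merges_types(self):
        w, _ = ttr(make_transcript(("Dog", "NN"), ("dog", "NN")))
        assert w == pytest.approx(1 / 2)


class TestInfoWordRatio:
    def test_all_other_tokens_give_zero(self):
        assert info_word_ratio(make_transcript(*[("x", "AD")] * 5)) == 0.0

    def test_four_nouns_of_ten(self):
        toks = [("n", "NN")] * 4 + [("o", "SP")] * 6
        assert info_word_ratio(make_transcript(*toks)) == pytest.approx(0.4)

    def test_adjectives_and_numerals_count(self):
        toks = [("big", "JJ"), ("three", "CD"), ("uh", "SP"), ("run", "VV")]
        assert info_word_ratio(make_transcript(*toks)) == pytest.approx(0.75)


class TestCountInfoUnits:
    def test_three_people_mentioned_once_each(self):
        toks = [("boy", "NN"), ("girl", "NN"), ("mother", "NN")]
        assert count_info_units(make_transcript(*toks))["people"] == 3

    def test_repeated_mention_credits_once(self):
        toks = [("cookie", "NN")] * 5
        counts = count_info_units(make_transcript(*toks))
        assert counts["objects"] == 1

    def test_empty_transcript_all_zero(self):
        counts = count_info_units(make_transcript())
        assert counts == {"people": 0, "objects": 0, "places": 0, "actions": 0}

    def test_action_needs_agent_before_verb_within_window(self):
        hit = make_transcript(("boy", "NN"), ("x", "AD"), ("stealing", "VV"))
        miss = make_transcript(("stealing", "VV"), ("x", "AD"), ("boy", "NN"))
        assert count_info_units(hit)["actions"] == 1
        assert count_info_units(miss)["actions"] == 0

    def test_action_outside_window_not_credited(self):
        toks = [("girl", "NN")] + [("pad", "AD")] * 11 + [("asking", "VV")]
        assert count_info_units(make_transcript(*toks))["actions"] == 0

    def test_counts_monotone_under_token_addition(self):
        base = [("boy", "NN"), ("taking", "VV"), ("cookie", "NN")]
        extra = base + [("window", "NN"), ("mother", "NN"), ("washing", "VV")]
        c1 = count_info_units(make_transcript(*base))
        c2 = count_info_units(make_transcript(*extra))
        assert all(c2[k] >= c1[k] for k in c1)

    def test_occurrence_counting_behind_flag(self):
        toks = [("cookie", "NN")] * 3
        counts = count_info_units(make_transcript(*toks), presence=False)
        assert counts["objects"] == 3


class TestExtractLinguistic:
    def test_full_inventory_embedding_reaches_category_sizes(self):
        lex = IULexicon.default()
        toks = []
        for c in lex.concepts.values():
            if c["category"] == "actions":
                toks.append((c["agent_patterns"][0], "NN"))
                toks.append((c["action_patterns"][0], "VV"))
            else:
                toks.append((c["patterns"][0], "NN"))
        feats = extract_linguistic(make_transcript(*toks))
        assert (feats.iu_people, feats.iu_objects, feats.iu_places, feats.iu_actions) == (
            3, 12, 2, 7,
        )

    def test_vector_has_ten_values_and_ratios_in_unit_interval(self):
        toks = [("boy", "NN"), ("runs", "VV"), ("he", "PN"), ("uh", "SP")]
        vals = extract_linguistic(make_transcript(*toks)).to_list()
        assert len(vals) == 10
        assert all(0.0 <= v <= 1.0 for v in vals[:6])

    def test_ratio_features_invariant_under_shuffling(self, rng):
        toks = [("boy", "NN"), ("runs", "VV"), ("he", "PN"), ("uh", "SP")] * 5
        t1 = make_transcript(*toks)
        order = rng.permutation(len(toks))
        t2 = make_transcript(*[toks[i] for i in order])
        f1, f2 = extract_linguistic(t1), extract_linguistic(t2)
        for name in ("noun_ratio", "verb_ratio", "pronoun_ratio", "ttr_words",
                     "ttr_chars", "info_word_ratio"):
            assert getattr(f1, name) == getattr(f2, name)


class TestTranscriptIO:
    def test_jsonl_roundtrip(self, tmp_path):
        t = make_transcript(("boy", "NN"), ("跑", "VV"))
        path = tmp_path / "t.jsonl"
        write_transcripts_jsonl(path, [t])
        back = read_transcripts_jsonl(path)
        assert len(back) == 1
        assert back[0].tokens == t.tokens

    def test_conll_two_column_format(self, tmp_path):
        path = tmp_path / "s01.txt"
        path.write_text("boy\tNN\n\nruns\tVV\n")
        t = read_transcript_conll(path)
        assert t.subject_id == "s01"
        assert [tok.tag for tok in t.tokens] == ["NN", "VV"]

    def test_jsonl_concatenates_utterances_per_subject(self, tmp_path):
        path = tmp_path / "t.jsonl"
        path.write_text(
            '{"subject_id": "a", "tokens": [["x", "NN"]]}\n'
            '{"subject_id": "a", "tokens": [["y", "VV"]]}\n'
        )
        back = read_transcripts_jsonl(path)
        assert len(back) == 1
        assert [tok.surface for tok in back[0].tokens] == ["x", "y"]
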