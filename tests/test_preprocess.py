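import warnings

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adrminer.label_io import Mention
from adrminer.preprocess import (
    TaggedSentence,
    Token,
    decode_bio2,
    encode_bio2,
    flatten_irregular,
    is_table_row,
    split_sentences,
    tokenize_with_offsets,
    validate_bio2,
)

TABLE2_SENTENCE = (
    "Fatal and serious intestinal perforation occurred in Zydelig-treated patients."
)
TABLE2_EXPECTED = [
    ("Fatal", 2763, 5),
    ("and", 2769, 3),
    ("serious", 2773, 7),
    ("intestinal", 2781, 10),
    ("perforation", 2792, 11),
    ("occurred", 2804, 8),
    ("in", 2813, 2),
    ("Zydelig-treated", 2816, 15),
    ("patients", 2832, 8),
    (".", 2840, 1),
]


class TestTokenize:
    def test_table2_worked_example(self):
        tokens = tokenize_with_offsets(TABLE2_SENTENCE, 2763)
        assert [(t.text, t.start, t.length) for t in tokens] == TABLE2_EXPECTED

    def test_empty(self):
        assert tokenize_with_offsets("", 0) == []

    def test_trailing_period_peeled(self):
        tokens = tokenize_with_offsets("cancer.", 100)
        assert [(t.text, t.start, t.length) for t in tokens] == [
            ("cancer", 100, 6),
            (".", 106, 1),
        ]

    def test_brackets_and_internal_slash(self):
        tokens = tokenize_with_offsets("(mg/kg)", 0)
        assert [t.text for t in tokens] == ["(", "mg/kg", ")"]

    def test_offset_faithfulness(self):
        text = "A dose of 3.5 mg/kg (twice daily) was well-tolerated."
        for tok in tokenize_with_offsets(text, 0):
            assert text[tok.start : tok.end] == tok.text


class TestSplitSentences:
    def test_single_sentence(self):
        section = " " * 2763 + TABLE2_SENTENCE
        result = split_sentences(section)
        assert result == [(TABLE2_SENTENCE, 2763)]

    def test_empty(self):
        assert split_sentences("") == []

    def test_two_sentences_offset_arithmetic(self):
        s1, s2 = "Dizziness was reported", "Headache was not"
        text = f"{s1}. {s2}."
        result = split_sentences(text)
        assert len(result) == 2
        (t1, o1), (t2, o2) = result
        assert o1 == 0 and t1 == s1 + "."
        assert o2 - o1 == len(s1) + 2

    def test_offsets_exact(self):
        text = "First sentence here. Second one!  Third?\nTable col1  col2  col3\nPlain again."
        for sent, offset in split_sentences(text):
            assert text[offset : offset + len(sent)] == sent

    def test_table_rows_one_sentence_per_line(self):
        text = (
            "Reaction  Placebo  Drug\n"
            "Nausea  1%  5%\n"
            "Prose sentence one. Prose two."
        )
        result = split_sentences(text)
        texts = [s for s, _ in result]
        assert texts[0] == "Reaction  Placebo  Drug"
        assert texts[1] == "Nausea  1%  5%"
        assert texts[2:] == ["Prose sentence one.", "Prose two."]

    def test_pipe_table_detection(self):
        assert is_table_row("a | b | c")
        assert not is_table_row("ordinary prose line")

    def test_no_characters_lost(self):
        text = "One. Two sentences\nacross lines. Col  a  b\n\nFinal bit"
        spans = sorted(
            (o, o + len(s)) for s, o in split_sentences(text)
        )
        covered = set()
        for lo, hi in spans:
            covered.update(range(lo, hi))
        for i, ch in enumerate(text):
            if not ch.isspace():
                assert i in covered


def _mention(mid, spans, text, mtype="AdverseReaction", section="S1"):
    return Mention(id=mid, section_id=section, type=mtype, spans=tuple(spans), text=text)


class TestEncodeBio2:
    def test_table2_tags(self):
        tokens = tokenize_with_offsets(TABLE2_SENTENCE, 2763)
        mentions = [
            _mention("M1", [(2763, 5)], "Fatal"),
            _mention("M2", [(2773, 7)], "serious", "Severity"),
            _mention("M3", [(2781, 22)], "intestinal perforation"),
        ]
        tags = encode_bio2(tokens, mentions)
        assert tags == ["B-ADR", "O", "B-SEV", "B-ADR", "I-ADR", "O", "O", "O", "O", "O"]

    def test_no_mentions_all_o(self):
        tokens = tokenize_with_offsets("Nothing to see here.", 0)
        assert encode_bio2(tokens, []) == ["O"] * len(tokens)

    def test_two_token_adr(self):
        text = "hypersensitivity reactions"
        tokens = tokenize_with_offsets(text, 0)
        tags = encode_bio2(tokens, [_mention("M1", [(0, len(text))], text)])
        assert tags == ["B-ADR", "I-ADR"]

    def test_unaligned_span_expanded_with_warning(self):
        tokens = tokenize_with_offsets("hypersensitivity reactions", 0)
        with pytest.warns(UserWarning, match="not token-aligned"):
            tags = encode_bio2(tokens, [_mention("M1", [(2, 10)], "persensitiv")])
        assert tags == ["B-ADR", "O"]


class TestDecodeBio2:
    def test_two_token_run(self):
        text = "hypersensitivity reactions"
        tokens = tokenize_with_offsets(text, 0)
        (mention,) = decode_bio2(tokens, ["B-ADR", "I-ADR"], "S1", text)
        assert mention.type == "AdverseReaction"
        assert mention.spans == ((0, len(text)),)
        assert mention.text == text

    def test_all_o(self):
        tokens = tokenize_with_offsets("nothing here", 0)
        assert decode_bio2(tokens, ["O", "O"]) == []

    def test_lenient_repair_of_dangling_i(self):
        tokens = tokenize_with_offsets("a b c", 0)
        mentions = decode_bio2(tokens, ["O", "I-ADR", "I-SEV"])
        assert [(m.type, m.spans) for m in mentions] == [
            ("AdverseReaction", ((2, 1),)),
            ("Severity", ((4, 1),)),
        ]

    def test_encode_decode_round_trip(self):
        text = "Severe rash and mild nausea occurred in rats."
        tokens = tokenize_with_offsets(text, 0)
        mentions = [
            _mention("M1", [(0, 6)], "Severe", "Severity"),
            _mention("M2", [(7, 4)], "rash"),
            _mention("M3", [(21, 6)], "nausea"),
            _mention("M4", [(40, 4)], "rats", "Animal"),
        ]
        tags = encode_bio2(tokens, mentions)
        decoded = decode_bio2(tokens, tags, "S1", text)
        assert {(m.type, m.spans) for m in decoded} == {
            (m.type, m.spans) for m in mentions
        }
        assert encode_bio2(tokens, decoded) == tags


class TestFlattenIrregular:
    def test_toviaz_pattern(self):
        text = "Angioedema of the face, lips, tongue, and larynx has been reported."
        shared = (0, 17)
        face, lips, tongue, larynx = (18, 4), (24, 4), (30, 6), (42, 6)
        mentions = [
            _mention("M1", [(0, 22)], text[0:22]),
            _mention("M2", [shared, lips], "Angioedema of the lips"),
            _mention("M3", [shared, tongue], "Angioedema of the tongue"),
            _mention("M4", [shared, larynx], "Angioedema of the larynx"),
        ]
        flat = flatten_irregular(mentions, text)
        pieces = [(text[m.start : m.end]) for m in flat]
        assert pieces == [
            "Angioedema of the face",
            "lips",
            "tongue",
            "larynx",
        ]
        starts = [m.start for m in flat]
        assert starts == sorted(starts)
        # contiguous & non-overlapping
        for a, b in zip(flat, flat[1:]):
            assert a.end <= b.start
        assert all(len(m.spans) == 1 for m in flat)

    def test_identity_on_regular_input(self):
        text = "Severe rash occurred."
        mentions = [
            _mention("M1", [(0, 6)], "Severe", "Severity"),
            _mention("M2", [(7, 4)], "rash"),
        ]
        flat = flatten_irregular(mentions, text)
        assert [(m.type, m.spans) for m in flat] == [
            ("Severity", ((0, 6),)),
            ("AdverseReaction", ((7, 4),)),
        ]

    def test_identical_spans_priority(self):
        text = "fatal"
        mentions = [
            _mention("M1", [(0, 5)], "fatal", "Severity"),
            _mention("M2", [(0, 5)], "fatal", "AdverseReaction"),
        ]
        flat = flatten_irregular(mentions, text)
        assert len(flat) == 1
        assert flat[0].type == "AdverseReaction"

    def test_empty(self):
        assert flatten_irregular([]) == []

    def test_synthetic_irregular_labels_flatten_clean(self, synth_labels_irregular):
        for label in synth_labels_irregular:
            for section in label.sections:
                local = [m for m in label.mentions if m.section_id == section.id]
                flat = flatten_irregular(local, section.text)
                for m in flat:
                    assert len(m.spans) == 1
                    assert section.text[m.start : m.end] == m.text
                for a, b in zip(flat, flat[1:]):
                    assert a.end <= b.start


# --- property tests --------------------------------------------------------

WORDS = ["alpha", "beta", "gamma", "delta", "nausea", "rash", "fever", "ache"]


@st.composite
def sentence_with_mentions(draw):
    n = draw(st.integers(min_value=1, max_value=8))
    words = [draw(st.sampled_from(WORDS)) for _ in range(n)]
    text = " ".join(words)
    tokens = tokenize_with_offsets(text, 0)
    # non-overlapping token ranges
    mentions = []
    i = 0
    mid = 0
    while i < len(tokens):
        take = draw(st.integers(min_value=0, max_value=2))
        if take and i + take <= len(tokens):
            mtype = draw(
                st.sampled_from(["AdverseReaction", "Severity", "Factor", "Animal"])
            )
            first, last = tokens[i], tokens[i + take - 1]
            mid += 1
            mentions.append(
                _mention(
                    f"M{mid}",
                    [(first.start, last.end - first.start)],
                    text[first.start : last.end],
                    mtype,
                )
            )
            i += take + 1
        else:
            i += 1
    return text, tokens, mentions


@settings(max_examples=100, deadline=None)
@given(sentence_with_mentions())
def test_encode_decode_identity_property(data):
    text, tokens, mentions = data
    tags = encode_bio2(tokens, mentions)
    validate_bio2(tags)
    decoded = decode_bio2(tokens, tags, "S1", text)
    assert {(m.type, m.spans) for m in decoded} == {(m.type, m.spans) for m in mentions}
    assert encode_bio2(tokens, decoded) == tags


@settings(max_examples=60, deadline=None)
@given(st.text(alphabet=" abcdef.!?\n|\t", max_size=200))
def test_split_sentences_preserves_characters(text):
    for sent, offset in split_sentences(text):
        assert text[offset : offset + len(sent)] == sent
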