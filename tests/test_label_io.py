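import pytest

from adrminer import label_io
from adrminer.label_io import (
    ConllFormatError,
    DrugLabel,
    LabelValidationError,
    Mention,
    Normalization,
    Reaction,
    Section,
    read_conll,
    read_label_xml,
    write_conll,
    write_label_xml,
)
from adrminer.preprocess import TaggedSentence, Token, sentences_from_section


class TestReadLabelXml:
    def test_worked_example(self, example_label_xml):
        label = read_label_xml(example_label_xml)
        assert label.drug_name == "choline"
        assert [m.type for m in label.mentions] == ["Factor", "AdverseReaction"]
        factor, adr = label.mentions
        assert factor.spans == ((2309, 4),) and factor.text == "risk"
        assert adr.spans == ((2318, 6),) and adr.text == "cancer"
        (reaction,) = label.reactions
        norm = reaction.normalizations[0]
        assert norm.pt_id == "10028997"
        assert norm.pt_name == "Neoplasm malignant"
        assert norm.llt_id == "10007050"
        assert norm.llt_name == "Cancer"

    def test_empty_mentions_element(self):
        xml = '<Label drug="x"><Text><Section id="S1">abc</Section></Text><Mentions/></Label>'
        label = read_label_xml(xml)
        assert label.mentions == []

    def test_str_mismatch_raises_naming_mention(self):
        xml = (
            '<Label drug="x"><Text><Section id="S1">abcdef</Section></Text>'
            '<Mentions><Mention id="M1" section="S1" type="Factor" start="0" '
            'len="3" str="zzz"/></Mentions></Label>'
        )
        with pytest.raises(LabelValidationError, match="M1"):
            read_label_xml(xml)

    def test_span_outside_section_bounds(self):
        xml = (
            '<Label drug="x"><Text><Section id="S1">ab</Section></Text>'
            '<Mentions><Mention id="M9" section="S1" type="Factor" start="1" '
            'len="5" str="b"/></Mentions></Label>'
        )
        with pytest.raises(LabelValidationError, match="M9"):
            read_label_xml(xml)

    def test_malformed_xml(self):
        with pytest.raises(ValueError, match="malformed"):
            read_label_xml("<Label><unclosed>")

    def test_unknown_mention_type_warns_but_parses(self):
        xml = (
            '<Label drug="x"><Text><Section id="S1">abc def</Section></Text>'
            '<Mentions><Mention id="M1" section="S1" type="Exotic" start="0" '
            'len="3" str="abc"/></Mentions></Label>'
        )
        with pytest.warns(UserWarning, match="unknown type"):
            label = read_label_xml(xml)
        assert label.mentions[0].type == "Exotic"


def _make_label():
    return DrugLabel(
        drug_name="demo",
        sections=[
            Section(id="S1", text="Severe headache occurred. No cases reported."),
            Section(id="S2", text="Angioedema of the face, lips noted."),
        ],
        mentions=[
            Mention(
                id="M1",
                section_id="S1",
                type="AdverseReaction",
                spans=((7, 8),),
                text="headache",
            ),
            Mention(
                id="M2",
                section_id="S2",
                type="AdverseReaction",
                spans=((0, 17), (24, 4)),
                text="Angioedema of the lips",
            ),
        ],
        reactions=[
            Reaction(
                text="headache",
                normalizations=(Normalization(pt_id="10000001", pt_name="Headachea"),),
            )
        ],
    )


class TestWriteLabelXml:
    def test_round_trip_all_fields(self):
        label = _make_label()
        again = read_label_xml(write_label_xml(label))
        assert again.drug_name == label.drug_name
        assert again.sections == label.sections
        assert again.mentions == label.mentions
        assert again.reactions == label.reactions

    def test_multi_span_attributes_comma_joined(self):
        text = write_label_xml(_make_label())
        assert 'start="0,24"' in text
        assert 'len="17,4"' in text

    def test_empty_label(self):
        label = DrugLabel(drug_name="empty")
        assert read_label_xml(write_label_xml(label)).sections == []

    def test_invariant_violation_blocks_writing(self):
        label = _make_label()
        label.mentions.append(
            Mention(id="M3", section_id="NOPE", type="Factor", spans=((0, 1),), text="S")
        )
        with pytest.raises(LabelValidationError, match="NOPE"):
            write_label_xml(label)


TABLE2_SENTENCE = (
    "Fatal and serious intestinal perforation occurred in Zydelig-treated patients."
)


def _table2_label_and_sentences():
    pad = 2763
    section_text = " " * pad + TABLE2_SENTENCE
    label = DrugLabel(drug_name="zydelig", sections=[Section(id="S3", text=section_text)])
    mentions = [
        Mention(id="M1", section_id="S3", type="AdverseReaction", spans=((2763, 5),), text="Fatal"),
        Mention(id="M2", section_id="S3", type="Severity", spans=((2773, 7),), text="serious"),
        Mention(
            id="M3",
            section_id="S3",
            type="AdverseReaction",
            spans=((2781, 22),),
            text="intestinal perforation",
        ),
    ]
    label.mentions = mentions
    sentences = sentences_from_section("S3", section_text, mentions)
    return label, sentences


class TestConll:
    def test_table2_sentence_rows(self):
        label, sentences = _table2_label_and_sentences()
        text = write_conll(label, sentences)
        rows = [line.split("\t") for line in text.strip().splitlines()]
        assert len(rows) == 10
        assert rows[4] == ["perforation", "I-ADR", "S3", "2792", "11", "_"]
        assert rows[0] == ["Fatal", "B-ADR", "S3", "2763", "5", "_"]
        assert rows[2] == ["serious", "B-SEV", "S3", "2773", "7", "_"]

    def test_empty_sentence_list(self):
        label = DrugLabel(drug_name="x", sections=[Section(id="S1", text="abc")])
        assert write_conll(label, []) == ""

    def test_round_trip_identity(self):
        label, sentences = _table2_label_and_sentences()
        text = write_conll(label, sentences)
        back = read_conll(text)
        assert len(back) == 1
        assert back[0].tokens == sentences[0].tokens
        assert back[0].tags == sentences[0].tags
        assert back[0].section_id == "S3"

    def test_read_empty(self):
        assert read_conll("") == []

    def test_wrong_column_count_reports_line(self):
        with pytest.raises(ConllFormatError, match="line 2"):
            read_conll("a\tO\tS1\t0\t1\t_\nbad\tline\n")

    def test_illegal_tag_sequence(self):
        bad = "a\tO\tS1\t0\t1\t_\nb\tI-ADR\tS1\t2\t1\t_\n"
        with pytest.raises(LabelValidationError):
            read_conll(bad)

    def test_illegal_tag_label(self):
        with pytest.raises(ConllFormatError, match="tag"):
            read_conll("a\tQ-ADR\tS1\t0\t1\t_\n")

    def test_offset_inconsistency_blocks_write(self):
        label = DrugLabel(drug_name="x", sections=[Section(id="S1", text="abc def")])
        bad = TaggedSentence(
            section_id="S1", tokens=[Token("zzz", 0, 3)], tags=["O"]
        )
        with pytest.raises(LabelValidationError, match="inconsistent"):
            write_conll(label, [bad])


class TestSyntheticRoundTrips:
    def test_xml_round_trip_on_synthetic_corpus(self, synth_labels_irregular):
        for label in synth_labels_irregular:
            again = read_label_xml(write_label_xml(label))
            assert again.drug_name == label.drug_name
            assert again.sections == label.sections
            assert again.mentions == label.mentions
            assert again.reactions == label.reactions

    def test_gold_mention_fragments_match_section_text(self, synth_labels_irregular):
        for label in synth_labels_irregular:
            for mention in label.mentions:
                section = label.section(mention.section_id)
                frags = mention.fragments(section.text)
                assert " ".join(frags) == mention.text

    def test_conll_round_trip_on_synthetic_corpus(self, synth_labels):
        from adrminer.synthetic_fixtures import corpus_sentences

        for label in synth_labels:
            sentences = [
                s
                for s in corpus_sentences([label])
                if s.tokens
            ]
            text = write_conll(label, sentences)
            back = read_conll(text)
            assert [s.tokens for s in back] == [s.tokens for s in sentences]
            assert [s.tags for s in back] == [s.tags for s in sentences]
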