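"""Drug-label XML dialect and 6-column CoNLL interchange I/O.

The XML dialect is the TAC-style layout: a ``Label`` root holding a
``Text`` element with offset-addressed ``Section`` children, a
``Mentions`` element with ``Mention`` children (``start``/``len`` may be
comma-separated lists for discontinuous mentions), and a ``Reactions``
element whose ``Reaction`` children carry ``Normalization`` records with
MedDRA PT (and optionally LLT) ids and names.

The CoNLL dialect is tab-separated, one token per line, six columns::

    token  bio_tag  section_id  start  length  reserved

with sentences separated by a blank line.  The sixth column is reserved
and ignored on read; it is written as ``_``.
"""

from __future__ import annotations

import re
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional

if TYPE_CHECKING:  # pragma: no cover
    from adrminer.preprocess import TaggedSentence

#: Canonical mention types and their BIO2 tag abbreviations.
MENTION_TYPES = (
    "AdverseReaction",
    "Severity",
    "Factor",
    "DrugClass",
    "Negation",
    "Animal",
)

TYPE_TO_ABBREV = {
    "AdverseReaction": "ADR",
    "Severity": "SEV",
    "Factor": "FAC",
    "DrugClass": "DCL",
    "Negation": "NEG",
    "Animal": "ANI",
}
ABBREV_TO_TYPE = {v: k for k, v in TYPE_TO_ABBREV.items()}

_TAG_RE = re.compile(r"^(O|[BI]-[A-Za-z]+)$")


class LabelValidationError(ValueError):
    """A drug label violated a structural invariant."""


class ConllFormatError(ValueError):
    """A CoNLL document violated the 6-column format."""


@dataclass(frozen=True)
class Section:
    id: str
    text: str

    def __post_init__(self) -> None:
        if not self.id:
            raise LabelValidationError("section id must be non-empty")


@dataclass(frozen=True)
class Mention:
    """An entity mention located by one or more character spans.

    ``spans`` is an ordered list of ``(start, length)`` pairs with 0-based
    character offsets into the owning section's raw text.  Contiguous
    mentions have exactly one span; discontinuous mentions have several.
    """

    id: str
    section_id: str
    type: str
    spans: tuple[tuple[int, int], ...]
    text: str

    def __post_init__(self) -> None:
        if not self.spans:
            raise LabelValidationError(f"mention {self.id!r}: spans must be non-empty")
        prev_end = -1
        for start, length in self.spans:
            if length < 1:
                raise LabelValidationError(
                    f"mention {self.id!r}: span length must be >= 1, got {length}"
                )
            if start < 0:
                raise LabelValidationError(
                    f"mention {self.id!r}: negative span start {start}"
                )
            if start < prev_end:
                raise LabelValidationError(
                    f"mention {self.id!r}: spans overlap or are unsorted"
                )
            prev_end = start + length
        if self.type not in MENTION_TYPES:
            warnings.warn(
                f"mention {self.id!r} has unknown type {self.type!r}; preserved",
                stacklevel=2,
            )

    @property
    def start(self) -> int:
        return self.spans[0][0]

    @property
    def end(self) -> int:
        return self.spans[-1][0] + self.spans[-1][1]

    def fragments(self, section_text: str) -> list[str]:
        return [section_text[s : s + l] for s, l in self.spans]


@dataclass(frozen=True)
class Normalization:
    pt_id: Optional[str] = None
    pt_name: Optional[str] = None
    llt_id: Optional[str] = None
    llt_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pt_id is None and not (self.llt_id and self.llt_name):
            raise LabelValidationError(
                "normalization needs pt_id or the (llt_id, llt_name) pair"
            )


@dataclass(frozen=True)
class Reaction:
    text: str
    normalizations: tuple[Normalization, ...] = ()


@dataclass
class DrugLabel:
    drug_name: str
    sections: list[Section] = field(default_factory=list)
    mentions: list[Mention] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def section(self, section_id: str) -> Section:
        for sec in self.sections:
            if sec.id == section_id:
                return sec
        raise KeyError(section_id)

    def validate(self) -> None:
        ids = [s.id for s in self.sections]
        if len(ids) != len(set(ids)):
            raise LabelValidationError(f"duplicate section ids in label {self.drug_name!r}")
        by_id = {s.id: s for s in self.sections}
        for m in self.mentions:
            if m.section_id not in by_id:
                raise LabelValidationError(
                    f"mention {m.id!r} references unknown section {m.section_id!r}"
                )
            text = by_id[m.section_id].text
            if m.end > len(text):
                raise LabelValidationError(
                    f"mention {m.id!r} span exceeds section {m.section_id!r} bounds"
                )
            _check_mention_text(m, text)


def _check_mention_text(mention: Mention, section_text: str) -> None:
    """Verify mention.text against the section substrings at its spans.

    Multi-span fragments are conventionally joined by a single space in the
    ``str`` attribute, but a fragment-wise match is also tolerated.
    """
    frags = mention.fragments(section_text)
    if " ".join(frags) == mention.text or "".join(frags) == mention.text:
        return
    raise LabelValidationError(
        f"mention {mention.id!r}: text {mention.text!r} does not match section "
        f"substrings {frags!r}"
    )


@dataclass(frozen=True)
class ConllRow:
    token_text: str
    bio_tag: str
    section_id: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if not _TAG_RE.match(self.bio_tag):
            raise ConllFormatError(f"illegal BIO2 tag {self.bio_tag!r}")


# ---------------------------------------------------------------------------
# XML
# ---------------------------------------------------------------------------

def read_label_xml(path_or_text) -> DrugLabel:
    """Parse a drug label from an XML file path, file object or string."""
    if hasattr(path_or_text, "read"):
        source = path_or_text.read()
    else:
        source = str(path_or_text)
    if "<" not in source:  # looks like a path
        with open(source, encoding="utf-8") as fh:
            source = fh.read()
    try:
        root = ET.fromstring(source)
    except ET.ParseError as exc:
        raise ConllFormatError(f"malformed label XML: {exc}") from exc

    label = DrugLabel(drug_name=root.get("drug", ""))
    text_el = root.find("Text")
    if text_el is not None:
        for sec in text_el.findall("Section"):
            label.sections.append(Section(id=sec.get("id", ""), text=sec.text or ""))
    mentions_el = root.find("Mentions")
    if mentions_el is not None:
        for el in mentions_el.findall("Mention"):
            starts = [int(x) for x in el.get("start", "").split(",")]
            lens = [int(x) for x in el.get("len", "").split(",")]
            if len(starts) != len(lens):
                raise LabelValidationError(
                    f"mention {el.get('id')!r}: start/len count mismatch"
                )
            label.mentions.append(
                Mention(
                    id=el.get("id", ""),
                    section_id=el.get("section", ""),
                    type=el.get("type", ""),
                    spans=tuple(zip(starts, lens)),
                    text=el.get("str", ""),
                )
            )
    reactions_el = root.find("Reactions")
    if reactions_el is not None:
        for rel in reactions_el.findall("Reaction"):
            norms = []
            for nel in rel.findall("Normalization"):
                norms.append(
                    Normalization(
                        pt_id=nel.get("meddra_pt_id"),
                        pt_name=nel.get("meddra_pt"),
                        llt_id=nel.get("meddra_llt_id"),
                        llt_name=nel.get("meddra_llt"),
                    )
                )
            label.reactions.append(
                Reaction(text=rel.get("str", ""), normalizations=tuple(norms))
            )
    label.validate()
    return label


def write_label_xml(label: DrugLabel) -> str:
    """Serialize a :class:`DrugLabel` to the XML dialect (round-trip safe)."""
    label.validate()
    root = ET.Element("Label", drug=label.drug_name)
    text_el = ET.SubElement(root, "Text")
    for sec in label.sections:
        sec_el = ET.SubElement(text_el, "Section", id=sec.id)
        sec_el.text = sec.text
    mentions_el = ET.SubElement(root, "Mentions")
    for m in label.mentions:
        ET.SubElement(
            mentions_el,
            "Mention",
            id=m.id,
            section=m.section_id,
            type=m.type,
            start=",".join(str(s) for s, _ in m.spans),
            len=",".join(str(l) for _, l in m.spans),
            str=m.text,
        )
    reactions_el = ET.SubElement(root, "Reactions")
    for r in label.reactions:
        rel = ET.SubElement(reactions_el, "Reaction", str=r.text)
        for n in r.normalizations:
            attrs = {}
            if n.pt_name is not None:
                attrs["meddra_pt"] = n.pt_name
            if n.pt_id is not None:
                attrs["meddra_pt_id"] = n.pt_id
            if n.llt_name is not None:
                attrs["meddra_llt"] = n.llt_name
            if n.llt_id is not None:
                attrs["meddra_llt_id"] = n.llt_id
            ET.SubElement(rel, "Normalization", **attrs)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


# ---------------------------------------------------------------------------
# CoNLL
# ---------------------------------------------------------------------------

def write_conll(label: DrugLabel, sentences: Iterable["TaggedSentence"]) -> str:
    """Render tagged sentences as 6-column CoNLL text.

    Token offsets are checked against the label's section text before
    writing; sentences are blank-line separated.
    """
    by_id = {s.id: s for s in label.sections}
    blocks = []
    for sent in sentences:
        lines = []
        section = by_id.get(sent.section_id)
        if section is None:
            raise LabelValidationError(f"unknown section {sent.section_id!r}")
        for tok, tag in zip(sent.tokens, sent.tags):
            actual = section.text[tok.start : tok.start + tok.length]
            if actual != tok.text:
                raise LabelValidationError(
                    f"token {tok.text!r} offset {tok.start} inconsistent with "
                    f"section {sent.section_id!r} (found {actual!r})"
                )
            lines.append(
                "\t".join(
                    [tok.text, tag, sent.section_id, str(tok.start), str(tok.length), "_"]
                )
            )
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def read_conll(text: str) -> list["TaggedSentence"]:
    """Parse 6-column CoNLL text back into tagged sentences."""
    from adrminer.preprocess import TaggedSentence, Token, validate_bio2

    sentences: list[TaggedSentence] = []
    tokens: list[Token] = []
    tags: list[str] = []
    section_id: Optional[str] = None

    def flush() -> None:
        nonlocal tokens, tags, section_id
        if tokens:
            validate_bio2(tags)
            sentences.append(
                TaggedSentence(section_id=section_id or "", tokens=tokens, tags=tags)
            )
        tokens, tags, section_id = [], [], None

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            flush()
            continue
        cols = line.split("\t")
        if len(cols) != 6:
            raise ConllFormatError(
                f"line {lineno}: expected 6 tab-separated columns, got {len(cols)}"
            )
        tok_text, tag, sec, start, length = cols[0], cols[1], cols[2], cols[3], cols[4]
        if not _TAG_RE.match(tag):
            raise ConllFormatError(f"line {lineno}: illegal BIO2 tag {tag!r}")
        if section_id is None:
            section_id = sec
        tokens.append(Token(text=tok_text, start=int(start), length=int(length)))
        tags.append(tag)
    flush()
    return sentences
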