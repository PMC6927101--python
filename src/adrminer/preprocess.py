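"""Sentence splitting, offset-preserving tokenization and BIO2 coding.

All offsets are 0-based character positions counted from the first
character of the owning section's raw text; a token's offset is the number
of characters before its first character.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from adrminer.label_io import (
    ABBREV_TO_TYPE,
    MENTION_TYPES,
    TYPE_TO_ABBREV,
    LabelValidationError,
    Mention,
)

#: Characters peeled off token edges into their own tokens.  Internal
#: hyphens and slashes are never split, so "Zydelig-treated" stays intact.
EDGE_PUNCTUATION = ".,;:!?()[]{}\"'`%<>=+*&#@~"

#: Conflict priority when overlapping mentions of different types force a
#: choice (highest first); ADR is the task's target class.
TYPE_PRIORITY = (
    "AdverseReaction",
    "Severity",
    "Factor",
    "DrugClass",
    "Negation",
    "Animal",
)

_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")
_TABLE_CELL_GAP = re.compile(r"[ \t]{2,}")


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    length: int

    def __post_init__(self) -> None:
        if self.length != len(self.text):
            raise ValueError(
                f"token {self.text!r}: length {self.length} != {len(self.text)}"
            )

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class TaggedSentence:
    section_id: str
    tokens: list[Token] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.tags):
            raise ValueError("tokens and tags must have equal length")
        validate_bio2(self.tags)


def validate_bio2(tags: list[str]) -> None:
    """Raise if an I-tag follows O, the sentence start, or a different type."""
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            if prev == "O" or prev[2:] != tag[2:]:
                raise LabelValidationError(
                    f"illegal BIO2 transition {prev!r} -> {tag!r}"
                )
        prev = tag


def is_table_row(line: str) -> bool:
    """Heuristic table detection: multi-space cell gaps or pipe delimiters."""
    stripped = line.strip()
    if stripped.count("|") >= 2:
        return True
    return len(_TABLE_CELL_GAP.findall(stripped)) >= 2


def split_sentences(section_text: str) -> list[tuple[str, int]]:
    """Split section text into (sentence_text, section_offset) pairs.

    Lines classified as table rows are emitted one sentence per line;
    consecutive prose lines are merged into blocks and split on terminal
    punctuation.  Offsets are exact: every returned sentence equals
    ``section_text[offset : offset + len(sentence)]``.
    """
    if not section_text:
        return []
    out: list[tuple[str, int]] = []
    block_start: int | None = None

    def flush_block(block_end: int) -> None:
        nonlocal block_start
        if block_start is None:
            return
        _split_prose(section_text, block_start, block_end, out)
        block_start = None

    pos = 0
    for line in section_text.splitlines(keepends=True):
        content = line.rstrip("\n")
        if not content.strip():
            flush_block(pos)
        elif is_table_row(content):
            flush_block(pos)
            lstart = pos + (len(content) - len(content.lstrip()))
            out.append((content.strip(), lstart))
        else:
            if block_start is None:
                block_start = pos
        pos += len(line)
    flush_block(len(section_text))
    return out


def _split_prose(text: str, start: int, end: int, out: list[tuple[str, int]]) -> None:
    block = text[start:end]
    cursor = 0
    for m in _SENT_BOUNDARY.finditer(block):
        _emit(text, start + cursor, block[cursor : m.start()], out)
        cursor = m.end()
    _emit(text, start + cursor, block[cursor:], out)


def _emit(text: str, offset: int, sent: str, out: list[tuple[str, int]]) -> None:
    stripped = sent.strip()
    if not stripped:
        return
    offset += len(sent) - len(sent.lstrip())
    out.append((stripped, offset))


def tokenize_with_offsets(
    sentence_text: str,
    sentence_start: int = 0,
    edge_punctuation: str = EDGE_PUNCTUATION,
) -> list[Token]:
    """Whitespace tokenization with edge punctuation peeled off.

    Each leading/trailing punctuation character of a whitespace-delimited
    chunk becomes its own single-character token; internal punctuation
    (hyphens, slashes, decimal points) is preserved.
    """
    tokens: list[Token] = []
    for m in re.finditer(r"\S+", sentence_text):
        chunk, cstart = m.group(), sentence_start + m.start()
        lead = 0
        while lead < len(chunk) and chunk[lead] in edge_punctuation:
            lead += 1
        trail = len(chunk)
        while trail > lead and chunk[trail - 1] in edge_punctuation:
            trail -= 1
        for i in range(lead):
            tokens.append(Token(chunk[i], cstart + i, 1))
        if trail > lead:
            core = chunk[lead:trail]
            tokens.append(Token(core, cstart + lead, len(core)))
        for i in range(trail, len(chunk)):
            tokens.append(Token(chunk[i], cstart + i, 1))
    return tokens


def _covering_token_range(
    tokens: list[Token], start: int, end: int
) -> tuple[int, int] | None:
    """Indices [i, j) of tokens overlapping [start, end), or None."""
    idx = [k for k, t in enumerate(tokens) if t.start < end and t.end > start]
    if not idx:
        return None
    return idx[0], idx[-1] + 1


def encode_bio2(tokens: list[Token], mentions: list[Mention]) -> list[str]:
    """Tag tokens in BIO2 for the given (ideally flattened) mentions.

    Each contiguous mention fragment opens with ``B-<TYPE>`` and continues
    with ``I-<TYPE>``.  Spans not aligned to token boundaries are expanded
    outward to the covering tokens with a warning.  If mentions conflict,
    the higher-priority mention (``TYPE_PRIORITY``) wins and the loser is
    dropped with a warning; the output is always BIO2-valid.
    """
    tags = ["O"] * len(tokens)
    rank = {t: i for i, t in enumerate(TYPE_PRIORITY)}
    ordered = sorted(mentions, key=lambda m: (rank.get(m.type, len(rank)), m.start))
    for mention in ordered:
        abbrev = TYPE_TO_ABBREV.get(mention.type, mention.type.upper()[:3])
        for start, length in mention.spans:
            rng = _covering_token_range(tokens, start, start + length)
            if rng is None:
                warnings.warn(
                    f"mention {mention.id!r} span ({start},{length}) covers no token",
                    stacklevel=2,
                )
                continue
            i, j = rng
            if tokens[i].start != start or tokens[j - 1].end != start + length:
                warnings.warn(
                    f"mention {mention.id!r} span not token-aligned; expanded to "
                    f"covering tokens",
                    stacklevel=2,
                )
            if any(tags[k] != "O" for k in range(i, j)):
                warnings.warn(
                    f"mention {mention.id!r} overlaps a higher-priority mention; "
                    "dropped from BIO2 encoding",
                    stacklevel=2,
                )
                continue
            tags[i] = f"B-{abbrev}"
            for k in range(i + 1, j):
                tags[k] = f"I-{abbrev}"
    validate_bio2(tags)
    return tags


def decode_bio2(
    tokens: list[Token],
    tags: list[str],
    section_id: str = "",
    section_text: str | None = None,
    id_prefix: str = "M",
) -> list[Mention]:
    """Recover contiguous single-span mentions from a BIO2 tag sequence.

    An ``I-X`` following ``O`` or a different type is leniently repaired to
    ``B-X``.  Mention text is cut from ``section_text`` when available,
    otherwise rebuilt by joining token texts with single spaces.
    """
    if len(tokens) != len(tags):
        raise ValueError("tokens and tags must have equal length")
    mentions: list[Mention] = []
    run_start: int | None = None
    run_type = ""

    def close(upto: int) -> None:
        nonlocal run_start
        if run_start is None:
            return
        first, last = tokens[run_start], tokens[upto - 1]
        start, length = first.start, last.end - first.start
        if section_text is not None:
            text = section_text[start : start + length]
        else:
            text = " ".join(t.text for t in tokens[run_start:upto])
        mentions.append(
            Mention(
                id=f"{id_prefix}{len(mentions) + 1}",
                section_id=section_id,
                type=ABBREV_TO_TYPE.get(run_type, run_type),
                spans=((start, length),),
                text=text,
            )
        )
        run_start = None

    for i, tag in enumerate(tags):
        if tag == "O":
            close(i)
        elif tag.startswith("B-") or (
            tag.startswith("I-") and (run_start is None or tag[2:] != run_type)
        ):
            close(i)
            run_start, run_type = i, tag[2:]
        # else: I- continuing the current run
    close(len(tags))
    return mentions


def flatten_irregular(
    mentions: list[Mention], section_text: str | None = None
) -> list[Mention]:
    """Flatten discontinuous/overlapping mentions to contiguous pieces.

    Every mention contributes its fragments as independent contiguous
    spans; duplicated or overlapping fragments of the same type are merged
    (interval union), and a fragment overlapping a kept fragment of a
    higher-priority type is dropped.  The result is a set of contiguous,
    non-overlapping mentions suitable for BIO2 encoding.
    """
    rank = {t: i for i, t in enumerate(TYPE_PRIORITY)}
    # (start, end, text) fragments per type
    frags: dict[str, list[tuple[int, int, str]]] = {}
    for m in mentions:
        texts = _fragment_texts(m, section_text)
        for (start, length), text in zip(m.spans, texts):
            frags.setdefault(m.type, []).append((start, start + length, text))

    merged: dict[str, list[tuple[int, int, str]]] = {}
    for mtype, items in frags.items():
        items.sort()
        acc: list[tuple[int, int, str]] = []
        for start, end, text in items:
            if acc and start <= acc[-1][1]:
                pstart, pend, ptext = acc[-1]
                nend = max(pend, end)
                if section_text is not None:
                    ntext = section_text[pstart:nend]
                elif (start, end) == (pstart, pend) or end <= pend:
                    ntext = ptext
                elif start == pstart:
                    ntext = text
                else:
                    raise ValueError(
                        "merging partially overlapping fragments requires "
                        "section_text to rebuild the surface string"
                    )
                acc[-1] = (pstart, nend, ntext)
            else:
                acc.append((start, end, text))
        merged[mtype] = acc

    kept: list[tuple[int, int, str, str]] = []  # start, end, type, text
    for mtype in sorted(merged, key=lambda t: rank.get(t, len(rank))):
        for start, end, text in merged[mtype]:
            if any(start < ke and end > ks for ks, ke, _, _ in kept):
                continue
            kept.append((start, end, mtype, text))
    kept.sort()

    section_id = mentions[0].section_id if mentions else ""
    return [
        Mention(
            id=f"F{i + 1}",
            section_id=section_id,
            type=mtype,
            spans=((start, end - start),),
            text=text,
        )
        for i, (start, end, mtype, text) in enumerate(kept)
    ]


def _fragment_texts(mention: Mention, section_text: str | None) -> list[str]:
    if section_text is not None:
        return mention.fragments(section_text)
    # Rebuild fragment surfaces from mention.text assuming the single-space
    # join convention; fall back to a character walk over span lengths.
    texts, cursor = [], 0
    for i, (_, length) in enumerate(mention.spans):
        texts.append(mention.text[cursor : cursor + length])
        cursor += length + 1  # skip the joining space
    return texts


def sentences_from_section(
    section_id: str, section_text: str, mentions: list[Mention] | None = None
) -> list[TaggedSentence]:
    """Convenience: split, tokenize and (optionally) BIO2-tag a section."""
    mentions = mentions or []
    out = []
    for sent_text, sent_start in split_sentences(section_text):
        tokens = tokenize_with_offsets(sent_text, sent_start)
        if not tokens:
            continue
        lo, hi = tokens[0].start, tokens[-1].end
        local = [
            m
            for m in mentions
            if m.section_id == section_id and m.start < hi and m.end > lo
        ]
        flat = flatten_irregular(local, section_text) if local else []
        tags = encode_bio2(tokens, flat)
        out.append(TaggedSentence(section_id=section_id, tokens=tokens, tags=tags))
    return out


__all__ = [
    "Token",
    "TaggedSentence",
    "EDGE_PUNCTUATION",
    "TYPE_PRIORITY",
    "MENTION_TYPES",
    "validate_bio2",
    "is_table_row",
    "split_sentences",
    "tokenize_with_offsets",
    "encode_bio2",
    "decode_bio2",
    "flatten_irregular",
    "sentences_from_section",
]
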