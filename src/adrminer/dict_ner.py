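"""Dictionary- and rule-based ADR mention recognition.

A two-level terminology (Preferred Terms and Lowest Level Terms, each LLT
pointing at exactly one parent PT) is loaded from tab-separated flat
files, its surface index expanded with regular plural/singular variants,
and matched against section text with a case-insensitive longest-match
scan at token boundaries.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from adrminer.label_io import Mention, Section
from adrminer.preprocess import tokenize_with_offsets

_WS = re.compile(r"\s+")


class DictionaryError(ValueError):
    """The dictionary files violate a structural invariant."""


def normalize_surface(form: str) -> str:
    """Case-fold, treat hyphens as spaces, collapse internal whitespace."""
    return _WS.sub(" ", form.replace("-", " ").casefold()).strip()


def pluralize(word: str) -> str:
    """Regular English plural of a single word."""
    if re.search(r"[^aeiou]y$", word):
        return word[:-1] + "ies"
    if re.search(r"(s|x|z|ch|sh)$", word):
        return word + "es"
    return word + "s"


def singularize(word: str) -> list[str]:
    """Candidate singulars under the inverse pluralization rules.

    Suffixes like "-ches" are genuinely ambiguous ("headaches" → headache,
    "rashes" → rash), so every rule-consistent candidate is returned;
    empty list when the word is not a regular plural.
    """
    out: list[str] = []
    if word.endswith("ies") and len(word) > 3:
        out.append(word[:-3] + "y")
    elif word.endswith("es") and re.search(r"(s|x|z|ch|sh)es$", word):
        out.append(word[:-2])
        out.append(word[:-1])
    elif word.endswith("s") and not word.endswith("ss") and len(word) > 1:
        out.append(word[:-1])
    return out


def _variants(form: str) -> list[str]:
    """Plural and singular variants of a multi-word form (last word varies)."""
    words = form.split(" ")
    head, last = words[:-1], words[-1]
    out = [" ".join(head + [pluralize(last)])]
    for singular in singularize(last):
        out.append(" ".join(head + [singular]))
    return out


@dataclass
class MedDRADictionary:
    """PT/LLT entries plus a normalized surface-form index.

    ``surface_index`` maps a normalized surface to ``(level, id)`` with
    level ``"PT"`` or ``"LLT"``; PT surfaces take priority when a string
    names both.  ``expanded_index`` holds plural/singular variants added
    by :func:`expand_terms` and is consulted after the base index.
    """

    pt_entries: dict[str, str] = field(default_factory=dict)
    llt_entries: dict[str, tuple[str, str]] = field(default_factory=dict)
    surface_index: dict[str, tuple[str, str]] = field(default_factory=dict)
    expanded_index: dict[str, tuple[str, str]] = field(default_factory=dict)

    def add_pt(self, pt_id: str, pt_name: str) -> None:
        if pt_id in self.pt_entries:
            warnings.warn(f"duplicate PT id {pt_id!r}; first entry kept", stacklevel=2)
            return
        self.pt_entries[pt_id] = pt_name
        surface = normalize_surface(pt_name)
        prior = self.surface_index.get(surface)
        if prior is not None and prior != ("PT", pt_id):
            warnings.warn(
                f"surface {surface!r} already indexed as {prior}; first wins",
                stacklevel=2,
            )
            return
        self.surface_index[surface] = ("PT", pt_id)

    def add_llt(self, llt_id: str, llt_name: str, parent_pt_id: str) -> None:
        if parent_pt_id not in self.pt_entries:
            raise DictionaryError(
                f"LLT {llt_id!r} references missing PT {parent_pt_id!r}"
            )
        if llt_id in self.llt_entries:
            warnings.warn(f"duplicate LLT id {llt_id!r}; first entry kept", stacklevel=2)
            return
        self.llt_entries[llt_id] = (llt_name, parent_pt_id)
        surface = normalize_surface(llt_name)
        prior = self.surface_index.get(surface)
        if prior is None:
            self.surface_index[surface] = ("LLT", llt_id)
            return
        if prior[0] == "LLT":
            prior_parent = self.llt_entries[prior[1]][1]
            if prior_parent != parent_pt_id:
                raise DictionaryError(
                    f"ambiguous LLT surface {surface!r}: maps to PTs "
                    f"{prior_parent!r} and {parent_pt_id!r}"
                )
            warnings.warn(
                f"duplicate LLT surface {surface!r}; first entry wins", stacklevel=2
            )
        # PT surface priority: keep the PT mapping silently

    def resolve_pt(self, level: str, entry_id: str) -> tuple[str, str]:
        """(pt_id, pt_name) of an index entry, following LLT → parent PT."""
        if level == "PT":
            return entry_id, self.pt_entries[entry_id]
        _, parent = self.llt_entries[entry_id]
        return parent, self.pt_entries[parent]

    def combined_index(self) -> dict[str, tuple[str, str]]:
        merged = dict(self.expanded_index)
        merged.update(self.surface_index)
        return merged

    @property
    def max_words(self) -> int:
        forms = list(self.surface_index) + list(self.expanded_index)
        return max((f.count(" ") + 1 for f in forms), default=0)


def load_dictionary(pt_file, llt_file) -> MedDRADictionary:
    """Load ``pt.tsv`` (pt_id, pt_name) and ``llt.tsv`` (llt_id, llt_name,
    pt_id) into an indexed dictionary."""
    d = MedDRADictionary()
    for lineno, cols in _read_tsv(pt_file):
        if len(cols) < 2:
            raise DictionaryError(f"pt file line {lineno}: expected 2 columns")
        d.add_pt(cols[0], cols[1])
    for lineno, cols in _read_tsv(llt_file):
        if len(cols) < 3:
            raise DictionaryError(f"llt file line {lineno}: expected 3 columns")
        d.add_llt(cols[0], cols[1], cols[2])
    return d


def _read_tsv(path_or_file):
    if hasattr(path_or_file, "read"):
        lines = path_or_file.read().splitlines()
    else:
        with open(path_or_file, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        yield lineno, line.rstrip("\n").split("\t")


def load_exclusions(path_or_file) -> set[str]:
    """One normalized surface form per line; blank lines and # comments skipped."""
    return {normalize_surface(line) for _, (line, *_) in _read_tsv(path_or_file)}


def expand_terms(dictionary: MedDRADictionary) -> MedDRADictionary:
    """Add regular plural (and singular) variants for every indexed surface.

    Variants point at the same entry; already-present forms are never
    overwritten, so expansion is idempotent.
    """
    for surface, target in list(dictionary.surface_index.items()):
        for variant in _variants(surface):
            if (
                variant not in dictionary.surface_index
                and variant not in dictionary.expanded_index
            ):
                dictionary.expanded_index[variant] = target
    return dictionary


def match_mentions(
    section: Section,
    dictionary: MedDRADictionary,
    exclusions: set[str] | None = None,
    id_prefix: str = "D",
) -> list[Mention]:
    """Longest-match-first dictionary scan of a section's text.

    Matching is case-insensitive, at token boundaries, with hyphens
    treated as spaces; a match suppresses any shorter match starting
    inside it.  Every hit becomes a single-span AdverseReaction mention
    with exact character offsets.
    """
    exclusions = exclusions or set()
    index = dictionary.combined_index()
    if not index:
        return []
    max_n = dictionary.max_words
    tokens = tokenize_with_offsets(section.text, 0)
    mentions: list[Mention] = []
    i = 0
    while i < len(tokens):
        matched = False
        for n in range(min(max_n, len(tokens) - i), 0, -1):
            first, last = tokens[i], tokens[i + n - 1]
            surface = section.text[first.start : last.end]
            key = normalize_surface(surface)
            if key in index and key not in exclusions:
                mentions.append(
                    Mention(
                        id=f"{id_prefix}{len(mentions) + 1}",
                        section_id=section.id,
                        type="AdverseReaction",
                        spans=((first.start, last.end - first.start),),
                        text=surface,
                    )
                )
                i += n
                matched = True
                break
        if not matched:
            i += 1
    return mentions
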