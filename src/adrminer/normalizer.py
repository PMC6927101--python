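"""Normalization of recognized ADR mention strings to MedDRA Preferred Terms.

Lookup walks the dictionary's base surface index first (where a PT surface
outranks an LLT surface) and then the expanded plural/singular index; an
LLT hit resolves to its parent PT.  Per-label aggregation collapses
duplicates into a distinct PT set and keeps count of unmappable mentions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from adrminer.dict_ner import MedDRADictionary, normalize_surface
from adrminer.label_io import Mention, Normalization, Reaction


def normalize_mention(
    mention_text: str, dictionary: MedDRADictionary
) -> tuple[str, str] | None:
    """(pt_id, pt_name) for a mention string, or None when unmappable."""
    key = normalize_surface(mention_text)
    for index in (dictionary.surface_index, dictionary.expanded_index):
        hit = index.get(key)
        if hit is not None:
            return dictionary.resolve_pt(*hit)
    return None


@dataclass
class LabelNormalization:
    """Distinct PT set for one drug label, plus the unmapped leftovers."""

    pts: set[tuple[str, str]] = field(default_factory=set)
    unmapped: list[str] = field(default_factory=list)

    @property
    def unmapped_count(self) -> int:
        return len(self.unmapped)

    @property
    def pt_ids(self) -> set[str]:
        return {pt_id for pt_id, _ in self.pts}

    def to_reactions(self) -> list[Reaction]:
        return [
            Reaction(
                text=name,
                normalizations=(Normalization(pt_id=pt_id, pt_name=name),),
            )
            for pt_id, name in sorted(self.pts)
        ]


def normalize_label(
    mentions: list[Mention], dictionary: MedDRADictionary
) -> LabelNormalization:
    """Normalize the AdverseReaction mentions of one label.

    Non-ADR mention types are ignored (only ADRs are normalized);
    unmappable ADR mentions are recorded, not silently dropped.
    """
    result = LabelNormalization()
    for mention in mentions:
        if mention.type != "AdverseReaction":
            continue
        pt = normalize_mention(mention.text, dictionary)
        if pt is None:
            result.unmapped.append(mention.text)
        else:
            result.pts.add(pt)
    return result


def normalization_tsv(per_label: dict[str, LabelNormalization]) -> str:
    """Render per-label PT sets as drug_id / pt_id / pt_name TSV."""
    lines = ["drug_id\tpt_id\tpt_name"]
    for drug_id in sorted(per_label):
        for pt_id, pt_name in sorted(per_label[drug_id].pts):
            lines.append(f"{drug_id}\t{pt_id}\t{pt_name}")
    return "\n".join(lines) + "\n"
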