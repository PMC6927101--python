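"""Seeded synthetic corpora: mini PT/LLT dictionaries and annotated labels.

The vocabulary is a synthetic pseudo-medical word stock; no real
terminology strings are emitted.  Generated labels carry gold mentions of
all six types with exact offsets, optional discontinuous/overlapping ADR
mentions in the "X of the a, b, and c" pattern, and gold Reactions with
the true PT of every planted ADR, so the whole pipeline (recognition,
normalization, evaluation, tagger training) is testable offline.

Tags are a deterministic function of the word stock: ADR surfaces come
only from the dictionary, cue words (severity, factor, negation, drug
class, animal) appear only inside mentions of their type, and filler
words never collide with either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from adrminer.dict_ner import MedDRADictionary, expand_terms
from adrminer.label_io import DrugLabel, Mention, Normalization, Reaction, Section
from adrminer.preprocess import TaggedSentence, sentences_from_section

_PREFIXES = [
    "card", "derm", "neur", "hepat", "nephr", "gastr", "pulmon", "oste",
    "myel", "phleb", "rhin", "cephal", "arthr", "vascul", "cutan", "ocul",
    "aural", "lingu", "thorac", "splen",
]
_SUFFIXES = [
    "algia", "itis", "osis", "opathy", "emia", "oma", "orrhea",
    "asthenia", "odynia", "ectasia", "oplegia", "otrophy", "ospasm",
    "uria", "iasis",
]
_ADJECTIVES = [
    "acute", "chronic", "diffuse", "focal", "transient", "recurrent",
    "persistent", "latent", "atypical", "generalized",
]

_SEVERITY = ["severe", "serious", "moderate", "intense"]
_FACTOR = ["risk", "possibility", "likelihood", "chance"]
_NEGATION = ["no", "not", "without", "never"]
_DRUG_CLASS = ["anticoagulants", "diuretics", "corticosteroids", "statins"]
_ANIMAL = ["rats", "mice", "rabbits", "dogs"]
_BODY_PARTS = ["face", "lips", "tongue", "larynx"]
_DRUG_NAMES = ["Zelovir", "Cortanex", "Mabrelin", "Dolquexa", "Veltrizan", "Paxolemb"]

_FILLERS = [
    "Store at room temperature away from direct light.",
    "Dosage adjustment may be required in elderly patients.",
    "The recommended starting dose is {num} mg daily.",
    "Clinical monitoring is advised during the first weeks of therapy.",
    "Tablets should be swallowed whole with water.",
]


def generate_dictionary(
    n_pt: int, llt_per_pt: int, seed: int = 0
) -> MedDRADictionary:
    """Deterministic mini-dictionary: ``n_pt`` PTs, ``llt_per_pt`` LLTs each.

    The LLT list for a PT starts with its regular plural and a multi-word
    synonym ("<name> disorder"); further LLTs prepend adjectives.
    """
    if n_pt < 1:
        raise ValueError("n_pt must be >= 1")
    if llt_per_pt > 2 + len(_ADJECTIVES):
        raise ValueError(f"llt_per_pt must be <= {2 + len(_ADJECTIVES)}")
    rng = np.random.default_rng(seed)
    combos = [p + s for p in _PREFIXES for s in _SUFFIXES]
    if n_pt > len(combos):
        raise ValueError(f"n_pt must be <= {len(combos)}")
    order = rng.permutation(len(combos))
    d = MedDRADictionary()
    llt_counter = 0
    for i in range(n_pt):
        base = combos[order[i]]
        pt_id = str(10_000_000 + i)
        pt_name = base.capitalize()
        d.add_pt(pt_id, pt_name)
        variants = [base + "s", base + " disorder"] + [
            f"{adj} {base}" for adj in _ADJECTIVES
        ]
        for j in range(llt_per_pt):
            llt_counter += 1
            d.add_llt(str(20_000_000 + llt_counter), variants[j].capitalize(), pt_id)
    return d


def dictionary_files(dictionary: MedDRADictionary) -> tuple[str, str]:
    """Render (pt.tsv, llt.tsv) flat-file texts."""
    pt_lines = [f"{pt_id}\t{name}" for pt_id, name in dictionary.pt_entries.items()]
    llt_lines = [
        f"{llt_id}\t{name}\t{parent}"
        for llt_id, (name, parent) in dictionary.llt_entries.items()
    ]
    return "\n".join(pt_lines) + "\n", "\n".join(llt_lines) + "\n"


@dataclass
class _Planted:
    """One planted ADR with its gold normalization."""

    pt_id: str
    pt_name: str
    llt_id: str | None
    llt_name: str | None
    surface: str


class _SentenceBuilder:
    """Accumulates section text and records mention spans while writing."""

    def __init__(self, label: DrugLabel, section_id: str):
        self.label = label
        self.section_id = section_id
        self.parts: list[str] = []
        self.cursor = 0
        self._pending: dict[str, list[tuple[int, int]]] = {}

    def add(self, text: str, mention_key: str | None = None) -> None:
        if mention_key is not None:
            self._pending.setdefault(mention_key, []).append((self.cursor, len(text)))
        self.parts.append(text)
        self.cursor += len(text)

    def finish_mention(self, key: str, mtype: str) -> None:
        spans = tuple(self._pending.pop(key))
        text = " ".join(self.parts_at(spans))
        self.label.mentions.append(
            Mention(
                id=f"M{len(self.label.mentions) + 1}",
                section_id=self.section_id,
                type=mtype,
                spans=spans,
                text=text,
            )
        )

    def parts_at(self, spans) -> list[str]:
        full = "".join(self.parts)
        return [full[s : s + l] for s, l in spans]

    @property
    def text(self) -> str:
        return "".join(self.parts)


def _adr_surfaces(dictionary: MedDRADictionary) -> list[_Planted]:
    out = []
    for pt_id, pt_name in dictionary.pt_entries.items():
        out.append(_Planted(pt_id, pt_name, None, None, pt_name))
    for llt_id, (llt_name, parent) in dictionary.llt_entries.items():
        out.append(
            _Planted(parent, dictionary.pt_entries[parent], llt_id, llt_name, llt_name)
        )
    return out


def generate_labels(
    n_labels: int,
    dictionary: MedDRADictionary,
    mention_rate: float = 0.3,
    irregular_fraction: float = 0.0,
    seed: int = 0,
    casing_perturbation: float = 0.0,
    hyphen_variants: float = 0.0,
    sentences_per_section: tuple[int, int] = (3, 6),
) -> list[DrugLabel]:
    """Generate annotated labels with 2–4 sections of template prose.

    ``mention_rate`` is the probability that a sentence carries mentions;
    ``irregular_fraction`` is the probability that an ADR-bearing sentence
    uses the discontinuous/overlapping pattern.  ``casing_perturbation``
    and ``hyphen_variants`` perturb planted ADR surfaces (the dictionary
    matcher is insensitive to both).
    """
    if not dictionary.pt_entries:
        raise ValueError("dictionary must be non-empty")
    if not 0 <= mention_rate <= 1 or not 0 <= irregular_fraction <= 1:
        raise ValueError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    surfaces = _adr_surfaces(dictionary)
    labels = []
    for li in range(n_labels):
        drug = _DRUG_NAMES[li % len(_DRUG_NAMES)] + (
            str(li // len(_DRUG_NAMES)) if li >= len(_DRUG_NAMES) else ""
        )
        label = DrugLabel(drug_name=drug)
        reactions: dict[str, Reaction] = {}
        n_sections = int(rng.integers(2, 5))
        for si in range(n_sections):
            builder = _SentenceBuilder(label, f"S{si + 1}")
            n_sent = int(rng.integers(*sentences_per_section))
            for sj in range(n_sent):
                if sj > 0:
                    builder.add(" ")
                if rng.random() < mention_rate:
                    if rng.random() < irregular_fraction:
                        _irregular_sentence(builder, rng, surfaces, reactions)
                    else:
                        _mention_sentence(
                            builder,
                            rng,
                            surfaces,
                            reactions,
                            casing_perturbation,
                            hyphen_variants,
                        )
                else:
                    filler = _FILLERS[int(rng.integers(len(_FILLERS)))]
                    builder.add(filler.format(num=int(rng.integers(5, 500))))
            label.sections.append(Section(id=builder.section_id, text=builder.text))
        label.reactions = list(reactions.values())
        label.validate()
        labels.append(label)
    return labels


def _pick_surface(
    rng, surfaces, casing_perturbation: float, hyphen_variants: float
) -> tuple[_Planted, str]:
    planted = surfaces[int(rng.integers(len(surfaces)))]
    surface = planted.surface.lower()
    if " " in surface and rng.random() < hyphen_variants:
        surface = surface.replace(" ", "-", 1)
    if rng.random() < casing_perturbation:
        surface = surface.upper() if rng.random() < 0.5 else surface.capitalize()
    return planted, surface


def _record_reaction(reactions: dict, planted: _Planted) -> None:
    if planted.pt_id not in reactions:
        reactions[planted.pt_id] = Reaction(
            text=planted.surface,
            normalizations=(
                Normalization(
                    pt_id=planted.pt_id,
                    pt_name=planted.pt_name,
                    llt_id=planted.llt_id,
                    llt_name=planted.llt_name,
                ),
            ),
        )


def _mention_sentence(builder, rng, surfaces, reactions, casing, hyphens) -> None:
    planted, surface = _pick_surface(rng, surfaces, casing, hyphens)
    _record_reaction(reactions, planted)
    template = int(rng.integers(4))
    if template == 0:
        sev = _SEVERITY[int(rng.integers(len(_SEVERITY)))].capitalize()
        builder.add(sev, "sev")
        builder.finish_mention("sev", "Severity")
        builder.add(" ")
        builder.add(surface, "adr")
        builder.finish_mention("adr", "AdverseReaction")
        builder.add(" occurred in treated patients.")
    elif template == 1:
        fac = _FACTOR[int(rng.integers(len(_FACTOR)))]
        ani = _ANIMAL[int(rng.integers(len(_ANIMAL)))]
        builder.add("An increased ")
        builder.add(fac, "fac")
        builder.finish_mention("fac", "Factor")
        builder.add(" of ")
        builder.add(surface, "adr")
        builder.finish_mention("adr", "AdverseReaction")
        builder.add(" was observed in ")
        builder.add(ani, "ani")
        builder.finish_mention("ani", "Animal")
        builder.add(".")
    elif template == 2:
        neg = _NEGATION[int(rng.integers(len(_NEGATION)))].capitalize()
        dcl = _DRUG_CLASS[int(rng.integers(len(_DRUG_CLASS)))]
        builder.add(neg, "neg")
        builder.finish_mention("neg", "Negation")
        builder.add(" cases of ")
        builder.add(surface, "adr")
        builder.finish_mention("adr", "AdverseReaction")
        builder.add(" were reported with concomitant ")
        builder.add(dcl, "dcl")
        builder.finish_mention("dcl", "DrugClass")
        builder.add(".")
    else:
        drug = _DRUG_NAMES[int(rng.integers(len(_DRUG_NAMES)))]
        builder.add(f"Patients receiving {drug} reported ")
        builder.add(surface, "adr")
        builder.finish_mention("adr", "AdverseReaction")
        builder.add(" during the trial.")


def _irregular_sentence(builder, rng, surfaces, reactions) -> None:
    """Overlapping + discontinuous pattern: "X of the a, b, and c"."""
    planted = surfaces[int(rng.integers(len(surfaces)))]
    base = planted.surface.split(" ")[0].capitalize()
    _record_reaction(reactions, planted)
    part_idx = rng.permutation(len(_BODY_PARTS))[:3]
    parts = [_BODY_PARTS[i] for i in part_idx]
    builder.add(f"{base} of the", "shared")
    builder.add(" ")
    builder.add(parts[0], "p0")
    builder.add(", ")
    builder.add(parts[1], "p1")
    builder.add(", and ")
    builder.add(parts[2], "p2")
    builder.add(" has been reported.")
    shared = builder._pending.pop("shared")[0]
    p0 = builder._pending.pop("p0")[0]
    p1 = builder._pending.pop("p1")[0]
    p2 = builder._pending.pop("p2")[0]
    # first mention is contiguous ("X of the face"); the rest are
    # discontinuous, all overlapping on the shared fragment
    contiguous = (shared[0], p0[0] + p0[1] - shared[0])
    full = builder.text
    specs = [
        ((contiguous,), full[contiguous[0] : contiguous[0] + contiguous[1]]),
        ((shared, p1), " ".join([full[shared[0] : shared[0] + shared[1]],
                                 full[p1[0] : p1[0] + p1[1]]])),
        ((shared, p2), " ".join([full[shared[0] : shared[0] + shared[1]],
                                 full[p2[0] : p2[0] + p2[1]]])),
    ]
    for spans, text in specs:
        builder.label.mentions.append(
            Mention(
                id=f"M{len(builder.label.mentions) + 1}",
                section_id=builder.section_id,
                type="AdverseReaction",
                spans=spans,
                text=text,
            )
        )


def corpus_sentences(labels: list[DrugLabel]) -> list[TaggedSentence]:
    """BIO2-tagged sentences for every section of every label."""
    out: list[TaggedSentence] = []
    for label in labels:
        for section in label.sections:
            out.extend(
                sentences_from_section(section.id, section.text, label.mentions)
            )
    return out


def gold_pt_sets(labels: list[DrugLabel]) -> dict[str, set[str]]:
    """Per-label distinct PT-id sets from the gold Reactions blocks."""
    out: dict[str, set[str]] = {}
    for label in labels:
        pts = set()
        for reaction in label.reactions:
            for norm in reaction.normalizations:
                if norm.pt_id is not None:
                    pts.add(norm.pt_id)
        out[label.drug_name] = pts
    return out


def expanded_copy(dictionary: MedDRADictionary) -> MedDRADictionary:
    """Convenience: expanded (plural/singular) view of a generated dictionary."""
    clone = MedDRADictionary(
        pt_entries=dict(dictionary.pt_entries),
        llt_entries=dict(dictionary.llt_entries),
        surface_index=dict(dictionary.surface_index),
        expanded_index=dict(dictionary.expanded_index),
    )
    return expand_terms(clone)
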