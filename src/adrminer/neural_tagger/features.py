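"""Token-level input features: case classes and word-embedding lookup."""

from __future__ import annotations

import re

import numpy as np

PAD_TOKEN = "<PAD>"
OOV_TOKEN = "<OOV>"

#: The eight orthographic case classes, in index order.
CASE_CLASSES = (
    "numeric",
    "mainly-numeric",
    "all-lower",
    "all-upper",
    "initial-upper",
    "contains-digit",
    "other",
    "padding",
)
CASE_INDEX = {name: i for i, name in enumerate(CASE_CLASSES)}

_DIGIT_RUN = re.compile(r"\d+")
_NUMERIC = re.compile(r"^\d+([.,]\d+)*$")


def case_feature(token_text: str) -> int:
    """Classify a token into one of the 8 case classes; returns the index.

    Exactly one class applies, checked in order: numeric (a pure number),
    mainly-numeric (> 50% digit characters), all-lower, all-upper,
    initial-upper, contains-digit, other.  The padding class is reserved
    for the padding pseudo-token.
    """
    if not token_text:
        raise ValueError("case_feature: empty token")
    if token_text == PAD_TOKEN:
        return CASE_INDEX["padding"]
    n_digits = sum(c.isdigit() for c in token_text)
    if _NUMERIC.match(token_text):
        return CASE_INDEX["numeric"]
    if n_digits / len(token_text) > 0.5:
        return CASE_INDEX["mainly-numeric"]
    if token_text.isalpha():
        if token_text.islower():
            return CASE_INDEX["all-lower"]
        if token_text.isupper():
            return CASE_INDEX["all-upper"]
        if token_text[0].isupper() and token_text[1:].islower():
            return CASE_INDEX["initial-upper"]
    if n_digits:
        return CASE_INDEX["contains-digit"]
    return CASE_INDEX["other"]


def case_one_hot(token_text: str) -> np.ndarray:
    vec = np.zeros(len(CASE_CLASSES))
    vec[case_feature(token_text)] = 1.0
    return vec


def normalize_word(token_text: str) -> str:
    """Lookup normalization: lowercase with every digit run replaced by 0."""
    return _DIGIT_RUN.sub("0", token_text.lower())


class EmbeddingTable:
    """Word → vector table with OOV/padding entries and lookup fallbacks."""

    def __init__(self, vectors: dict[str, np.ndarray], dim: int):
        self.dim = dim
        self.vectors = vectors
        if OOV_TOKEN not in vectors:
            raise ValueError("embedding table must contain an OOV entry")
        vectors.setdefault(PAD_TOKEN, np.zeros(dim))
        for word, vec in vectors.items():
            if vec.shape != (dim,):
                raise ValueError(f"vector for {word!r} has wrong length")

    @classmethod
    def random(cls, vocabulary, dim: int = 200, seed: int = 0) -> "EmbeddingTable":
        """Seeded uniform(-0.25, 0.25) vectors for a vocabulary (plus OOV)."""
        rng = np.random.default_rng(seed)
        words = sorted(set(vocabulary)) + [OOV_TOKEN]
        vectors = {w: rng.uniform(-0.25, 0.25, size=dim) for w in words}
        vectors[PAD_TOKEN] = np.zeros(dim)
        return cls(vectors, dim)

    @classmethod
    def from_text(cls, path_or_file, seed: int = 0) -> "EmbeddingTable":
        """Read the standard text word-vector format.

        One line per word: the token followed by whitespace-separated
        floats; an optional leading ``<count> <dim>`` header is skipped.
        """
        if hasattr(path_or_file, "read"):
            lines = path_or_file.read().splitlines()
        else:
            with open(path_or_file, encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        vectors: dict[str, np.ndarray] = {}
        dim = None
        for i, line in enumerate(lines):
            parts = line.rstrip().split(" ")
            if not line.strip():
                continue
            if i == 0 and len(parts) == 2:
                continue  # count/dim header
            word, vals = parts[0], np.array([float(x) for x in parts[1:]])
            if dim is None:
                dim = len(vals)
            elif len(vals) != dim:
                raise ValueError(f"line {i + 1}: expected {dim} floats")
            vectors[word] = vals
        if dim is None:
            raise ValueError("empty embedding file")
        if OOV_TOKEN not in vectors:
            rng = np.random.default_rng(seed)
            vectors[OOV_TOKEN] = rng.uniform(-0.25, 0.25, size=dim)
        return cls(vectors, dim)

    def lookup_key(self, token_text: str) -> str:
        """Resolve a token to a table key: exact → lower → digit-normalized
        lowercase → OOV."""
        if token_text in self.vectors:
            return token_text
        lower = token_text.lower()
        if lower in self.vectors:
            return lower
        norm = normalize_word(token_text)
        if norm in self.vectors:
            return norm
        return OOV_TOKEN

    def lookup(self, token_text: str) -> np.ndarray:
        return self.vectors[self.lookup_key(token_text)]

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def word_lookup(token_text: str, table: EmbeddingTable) -> np.ndarray:
    """Vector for a token via the exact → lower → normalized → OOV chain."""
    return table.lookup(token_text)
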