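"""Char-CNN + word/case embedding, stacked Bi-LSTM, CRF sequence tagger.

Architecture: each token is represented by the concatenation of a 30-dim
character-CNN feature (filter width 3, stride 1, 30 filters, max-pooled
over the padded character matrix), a 200-dim word embedding (pre-trained
table or seeded random init, resolved through the exact → lowercase →
digit-normalized → OOV chain) and an 8-dim one-hot case embedding.  Two
stacked Bi-LSTMs (100 and 75 units per direction) with variational
dropout feed a linear projection into a linear-chain CRF.  Training
minimizes the mean negative CRF log-likelihood with NADAM and global
gradient-norm clipping.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from adrminer.label_io import MENTION_TYPES, TYPE_TO_ABBREV
from adrminer.neural_tagger._autodiff import Nadam, Parameter, Tensor, concat, stack_rows
from adrminer.neural_tagger.crf import (
    crf_neg_log_likelihood_graph,
    crf_viterbi,
)
from adrminer.neural_tagger.features import (
    CASE_CLASSES,
    EmbeddingTable,
    OOV_TOKEN,
    PAD_TOKEN,
    case_one_hot,
    normalize_word,
)
from adrminer.preprocess import TaggedSentence, Token


@dataclass
class TaggerConfig:
    char_emb_dim: int = 30
    char_filters: int = 30
    char_filter_width: int = 3
    char_stride: int = 1
    word_emb_dim: int = 200
    case_emb_dim: int = 8
    lstm_units: tuple[int, ...] = (100, 75)
    variational_dropout: float = 0.25
    grad_norm_clip: float = 1.0
    optimizer: str = "nadam"
    learning_rate: float = 2e-3
    max_epochs: int = 50
    batch_size: int = 32
    patience: int = 5
    dev_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (
            self.char_emb_dim,
            self.char_filters,
            self.char_filter_width,
            self.word_emb_dim,
            self.case_emb_dim,
            *self.lstm_units,
        )
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be positive")
        if not 0 <= self.variational_dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.grad_norm_clip <= 0:
            raise ValueError("grad_norm_clip must be > 0")
        if self.case_emb_dim != len(CASE_CLASSES):
            raise ValueError(f"case_emb_dim must be {len(CASE_CLASSES)}")
        self.lstm_units = tuple(self.lstm_units)

    @property
    def input_dim(self) -> int:
        return self.char_filters + self.word_emb_dim + self.case_emb_dim


class TagSet:
    """Stable bijection between BIO2 labels and indices (plus start/stop)."""

    def __init__(self, labels: list[str] | None = None):
        if labels is None:
            labels = ["O"]
            for mtype in MENTION_TYPES:
                ab = TYPE_TO_ABBREV[mtype]
                labels += [f"B-{ab}", f"I-{ab}"]
        self.labels = list(labels)
        self.index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self.index) != len(self.labels):
            raise ValueError("duplicate labels in tag set")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def start(self) -> int:
        return len(self.labels)

    @property
    def stop(self) -> int:
        return len(self.labels) + 1

    def encode(self, tags: list[str]) -> list[int]:
        return [self.index[t] for t in tags]

    def decode(self, indices: list[int]) -> list[str]:
        return [self.labels[i] for i in indices]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def char_conv_maxpool(
    emb_matrix: Tensor, filters: Tensor, bias: Tensor, width: int, stride: int = 1
) -> Tensor:
    """Valid 1-D convolution over character embeddings, tanh, max-pool.

    ``emb_matrix`` is (L, char_emb_dim); ``filters`` is (width * char_emb_dim,
    n_filters); returns a vector of length n_filters — the per-filter max
    over all window responses.
    """
    L = emb_matrix.shape[0]
    if L < width:
        raise ValueError(f"character matrix length {L} < filter width {width}")
    starts = np.arange(0, L - width + 1, stride)
    win_idx = starts[:, None] + np.arange(width)[None, :]  # (n_win, width)
    windows = emb_matrix[win_idx]  # (n_win, width, d)
    flat = windows.reshape(len(starts), -1)  # (n_win, width*d)
    responses = (flat @ filters + bias).tanh()  # (n_win, n_filters)
    return responses.max(axis=0)


class TaggerModel:
    """Trained (or freshly initialized) sequence tagger."""

    def __init__(
        self,
        config: TaggerConfig,
        tagset: TagSet,
        word_index: dict[str, int],
        char_index: dict[str, int],
        max_word_len: int,
        word_vectors: np.ndarray,
        rng: np.random.Generator | None = None,
    ):
        self.config = config
        self.tagset = tagset
        self.word_index = word_index
        self.char_index = char_index
        self.max_word_len = max(max_word_len, config.char_filter_width)
        rng = rng or np.random.default_rng(config.seed)
        cfg = config
        K = len(tagset)
        p: dict[str, Parameter] = {}
        p["word_emb"] = Parameter(np.asarray(word_vectors, dtype=float))
        p["char_emb"] = Parameter(
            rng.uniform(-0.5, 0.5, size=(len(char_index), cfg.char_emb_dim))
        )
        p["char_emb"].data[char_index[PAD_TOKEN]] = 0.0
        p["char_W"] = Parameter(
            _glorot(rng, (cfg.char_filter_width * cfg.char_emb_dim, cfg.char_filters))
        )
        p["char_b"] = Parameter(np.zeros(cfg.char_filters))
        in_dim = cfg.input_dim
        for layer, units in enumerate(cfg.lstm_units):
            for direction in ("fw", "bw"):
                W = _glorot(rng, (in_dim + units, 4 * units))
                b = np.zeros(4 * units)
                b[units : 2 * units] = 1.0  # forget-gate bias
                p[f"lstm{layer}_{direction}_W"] = Parameter(W)
                p[f"lstm{layer}_{direction}_b"] = Parameter(b)
            in_dim = 2 * units
        p["proj_W"] = Parameter(_glorot(rng, (in_dim, K)))
        p["proj_b"] = Parameter(np.zeros(K))
        p["transitions"] = Parameter(np.zeros((K + 2, K + 2)))
        self.params = p

    # -- input representation ---------------------------------------------

    def _char_ids(self, token_text: str) -> np.ndarray:
        pad = self.char_index[PAD_TOKEN]
        oov = self.char_index[OOV_TOKEN]
        length = max(self.max_word_len, len(token_text))
        ids = np.full(length, pad, dtype=int)
        for i, ch in enumerate(token_text):
            ids[i] = self.char_index.get(ch, oov)
        return ids

    def _word_row(self, token_text: str) -> int:
        idx = self.word_index
        for key in (token_text, token_text.lower(), normalize_word(token_text)):
            if key in idx:
                return idx[key]
        return idx[OOV_TOKEN]

    def char_representation(self, token_text: str) -> Tensor:
        """30-dim char-CNN feature for one token (padded, conv, max-pool)."""
        cfg = self.config
        emb = self.params["char_emb"][self._char_ids(token_text)]
        return char_conv_maxpool(
            emb,
            self.params["char_W"],
            self.params["char_b"],
            cfg.char_filter_width,
            cfg.char_stride,
        )

    def build_input(self, tokens: list[Token]) -> Tensor:
        """Per-token concatenation char ⊕ word ⊕ case-one-hot, shape (T, 238)."""
        rows = []
        for tok in tokens:
            char_vec = self.char_representation(tok.text)
            word_vec = self.params["word_emb"][self._word_row(tok.text)]
            case_vec = Tensor(case_one_hot(tok.text))
            rows.append(concat([char_vec, word_vec, case_vec]))
        return stack_rows(rows)

    # -- recurrence --------------------------------------------------------

    def _lstm_pass(
        self,
        X: Tensor,
        layer: int,
        direction: str,
        units: int,
        in_mask: np.ndarray | None,
        rec_mask: np.ndarray | None,
    ) -> list[Tensor]:
        W = self.params[f"lstm{layer}_{direction}_W"]
        b = self.params[f"lstm{layer}_{direction}_b"]
        T = X.shape[0]
        h = Tensor(np.zeros(units))
        c = Tensor(np.zeros(units))
        outs: list[Tensor | None] = [None] * T
        order = range(T - 1, -1, -1) if direction == "bw" else range(T)
        for t in order:
            x = X[t]
            if in_mask is not None:
                x = x * Tensor(in_mask)
            h_in = h * Tensor(rec_mask) if rec_mask is not None else h
            z = concat([x, h_in]) @ W + b
            i = z[0:units].sigmoid()
            f = z[units : 2 * units].sigmoid()
            g = z[2 * units : 3 * units].tanh()
            o = z[3 * units : 4 * units].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
            outs[t] = h
        return outs  # type: ignore[return-value]

    def _bilstm(
        self, X: Tensor, train: bool, rng: np.random.Generator | None
    ) -> Tensor:
        cfg = self.config
        p_drop = cfg.variational_dropout
        H = X
        for layer, units in enumerate(cfg.lstm_units):
            in_dim = H.shape[1]
            cols = []
            for direction in ("fw", "bw"):
                in_mask = rec_mask = None
                if train and p_drop > 0 and rng is not None:
                    # variational dropout: one mask per sequence, shared
                    # across time steps (inverted scaling)
                    in_mask = (rng.random(in_dim) >= p_drop) / (1 - p_drop)
                    rec_mask = (rng.random(units) >= p_drop) / (1 - p_drop)
                outs = self._lstm_pass(H, layer, direction, units, in_mask, rec_mask)
                cols.append(stack_rows(outs))
            H = concat(cols, axis=1)
        return H

    def emissions(
        self, tokens: list[Token], train: bool = False, rng=None
    ) -> Tensor:
        X = self.build_input(tokens)
        H = self._bilstm(X, train, rng)
        return H @ self.params["proj_W"] + self.params["proj_b"]

    # -- training / inference ---------------------------------------------

    def sentence_loss(
        self, sentence: TaggedSentence, train: bool = True, rng=None
    ) -> Tensor:
        emissions = self.emissions(sentence.tokens, train=train, rng=rng)
        gold = self.tagset.encode(sentence.tags)
        return crf_neg_log_likelihood_graph(
            emissions, self.params["transitions"], gold
        )

    def predict_sentence(self, tokens: list[Token]) -> list[str]:
        if not tokens:
            return []
        emissions = self.emissions(tokens, train=False)
        path, _ = crf_viterbi(emissions.data, self.params["transitions"].data)
        return repair_bio2(self.tagset.decode(path))

    # -- serialization -----------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "config": asdict(self.config),
            "labels": self.tagset.labels,
            "word_index": self.word_index,
            "char_index": self.char_index,
            "max_word_len": self.max_word_len,
        }
        arrays = {k: p.data for k, p in self.params.items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "TaggerModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
        cfg_dict = meta["config"]
        cfg_dict["lstm_units"] = tuple(cfg_dict["lstm_units"])
        config = TaggerConfig(**cfg_dict)
        model = cls(
            config,
            TagSet(meta["labels"]),
            meta["word_index"],
            meta["char_index"],
            meta["max_word_len"],
            arrays["word_emb"],
        )
        for k, arr in arrays.items():
            model.params[k].data = arr.astype(float)
        return model


def repair_bio2(tags: list[str]) -> list[str]:
    """Lenient repair: I-X after O, start, or a different type becomes B-X."""
    out = []
    prev = "O"
    for tag in tags:
        if tag.startswith("I-") and (prev == "O" or prev[2:] != tag[2:]):
            tag = "B-" + tag[2:]
        out.append(tag)
        prev = tag
    return out


def build_vocabularies(
    corpus: list[TaggedSentence], table: EmbeddingTable
) -> tuple[dict[str, int], dict[str, int], int]:
    """Word rows (restricted to table keys reachable from the corpus),
    char index, and longest-token length."""
    keys = {PAD_TOKEN, OOV_TOKEN}
    chars: set[str] = set()
    max_len = 1
    for sent in corpus:
        for tok in sent.tokens:
            keys.add(table.lookup_key(tok.text))
            chars.update(tok.text)
            max_len = max(max_len, len(tok.text))
    word_index = {w: i for i, w in enumerate(sorted(keys))}
    char_index = {PAD_TOKEN: 0, OOV_TOKEN: 1}
    for ch in sorted(chars):
        char_index[ch] = len(char_index)
    return word_index, char_index, max_len


def _chunks(tags: list[str]) -> set[tuple[int, int, str]]:
    out = set()
    start = None
    ctype = ""
    for i, tag in enumerate(repair_bio2(tags)):
        if tag.startswith("B-"):
            if start is not None:
                out.add((start, i, ctype))
            start, ctype = i, tag[2:]
        elif tag == "O":
            if start is not None:
                out.add((start, i, ctype))
            start = None
    if start is not None:
        out.add((start, len(tags), ctype))
    return out


def tagging_f1(gold: list[list[str]], pred: list[list[str]]) -> float:
    """Mention-level (chunk) F1 between two tag-sequence lists."""
    tp = n_gold = n_pred = 0
    for g, p in zip(gold, pred):
        gc, pc = _chunks(g), _chunks(p)
        tp += len(gc & pc)
        n_gold += len(gc)
        n_pred += len(pc)
    if tp == 0:
        return 0.0
    prec, rec = tp / n_pred, tp / n_gold
    return 2 * prec * rec / (prec + rec)


def train_tagger(
    corpus: list[TaggedSentence],
    table: EmbeddingTable | None = None,
    config: TaggerConfig | None = None,
    dev_corpus: list[TaggedSentence] | None = None,
    verbose: bool = False,
) -> TaggerModel:
    """Train the tagger on BIO2-tagged sentences.

    If no embedding table is given, a seeded random table is built over the
    corpus vocabulary.  A held-out slice (``config.dev_fraction``) drives
    early stopping on mention-level F1 with ``config.patience``; the best
    parameters are restored at the end.
    """
    if not corpus:
        raise ValueError("training corpus must be non-empty")
    config = config or TaggerConfig()
    rng = np.random.default_rng(config.seed)
    if table is None:
        vocab = {normalize_word(t.text) for s in corpus for t in s.tokens}
        table = EmbeddingTable.random(vocab, dim=config.word_emb_dim, seed=config.seed)
    if table.dim != config.word_emb_dim:
        raise ValueError(
            f"embedding table dim {table.dim} != config.word_emb_dim "
            f"{config.word_emb_dim}"
        )

    train_set = list(corpus)
    if dev_corpus is None and config.dev_fraction > 0 and len(corpus) >= 10:
        n_dev = max(1, int(round(len(corpus) * config.dev_fraction)))
        perm = rng.permutation(len(corpus))
        dev_corpus = [corpus[i] for i in perm[:n_dev]]
        train_set = [corpus[i] for i in perm[n_dev:]]

    word_index, char_index, max_len = build_vocabularies(train_set, table)
    word_vectors = np.stack([table.vectors[w] for w in sorted(word_index)])
    model = TaggerModel(
        config, TagSet(), word_index, char_index, max_len, word_vectors, rng
    )
    optimizer = Nadam(
        model.params,
        lr=config.learning_rate,
        grad_norm_clip=config.grad_norm_clip,
    )

    best_f1 = -1.0
    best_params: dict[str, np.ndarray] | None = None
    stale = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_set))
        total_loss = 0.0
        for lo in range(0, len(order), config.batch_size):
            batch = [train_set[i] for i in order[lo : lo + config.batch_size]]
            batch = [s for s in batch if s.tokens]
            if not batch:
                continue
            optimizer.zero_grad()
            for sent in batch:
                loss = model.sentence_loss(sent, train=True, rng=rng)
                total_loss += loss.item()
                loss.backward(np.asarray(1.0 / len(batch)))
            optimizer.step()
        if dev_corpus:
            pred = [model.predict_sentence(s.tokens) for s in dev_corpus]
            f1 = tagging_f1([s.tags for s in dev_corpus], pred)
            if verbose:  # pragma: no cover
                print(f"epoch {epoch}: loss={total_loss:.3f} dev_f1={f1:.3f}")
            if f1 > best_f1:
                best_f1, stale = f1, 0
                best_params = {k: p.data.copy() for k, p in model.params.items()}
            else:
                stale += 1
                if stale > config.patience:
                    break
    if best_params is not None:
        for k, p in model.params.items():
            p.data = best_params[k]
    return model


def predict_tags(
    model: TaggerModel, sentences: list[TaggedSentence]
) -> list[TaggedSentence]:
    """Viterbi-decode each sentence; output tags are BIO2-valid."""
    out = []
    for sent in sentences:
        tags = model.predict_sentence(sent.tokens)
        out.append(
            TaggedSentence(section_id=sent.section_id, tokens=sent.tokens, tags=tags)
        )
    return out
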