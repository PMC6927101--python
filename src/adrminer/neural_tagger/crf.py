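"""Linear-chain CRF: sequence scoring, Viterbi decoding, log-likelihood.

Conventions: ``emissions`` has shape (T, K); ``transitions`` has shape
(K + 2, K + 2) where row/column K is the start state and K + 1 the stop
state.  A sequence's score is the sum of its emission scores plus the
transition scores including start→first and last→stop.
"""

from __future__ import annotations

import numpy as np

from adrminer.neural_tagger._autodiff import Tensor


def start_stop_indices(n_tags: int) -> tuple[int, int]:
    return n_tags, n_tags + 1


def _check(emissions: np.ndarray, transitions: np.ndarray) -> tuple[int, int]:
    T, K = emissions.shape
    if transitions.shape != (K + 2, K + 2):
        raise ValueError(
            f"transitions shape {transitions.shape} incompatible with K={K}"
        )
    return T, K


def crf_score(
    emissions: np.ndarray, transitions: np.ndarray, tag_sequence
) -> float:
    """Unnormalized score of one tag sequence."""
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    T, K = _check(emissions, transitions)
    tags = list(tag_sequence)
    if len(tags) != T:
        raise ValueError(f"tag sequence length {len(tags)} != T={T}")
    start, stop = start_stop_indices(K)
    if T == 0:
        return float(transitions[start, stop])
    score = transitions[start, tags[0]] + emissions[0, tags[0]]
    for t in range(1, T):
        score += transitions[tags[t - 1], tags[t]] + emissions[t, tags[t]]
    score += transitions[tags[-1], stop]
    return float(score)


def crf_viterbi(
    emissions: np.ndarray, transitions: np.ndarray
) -> tuple[list[int], float]:
    """Best tag sequence and its score.

    Ties are broken toward the lowest tag index at the earliest differing
    position (the lexicographically smallest optimal sequence), which is
    why the dynamic program runs backwards and the path is picked greedily
    forwards.
    """
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    T, K = _check(emissions, transitions)
    start, stop = start_stop_indices(K)
    if T == 0:
        return [], float(transitions[start, stop])
    # beta[t, k] = best score of emitting positions t..T-1 given tag k at t
    beta = np.empty((T, K))
    beta[T - 1] = emissions[T - 1] + transitions[:K, stop]
    for t in range(T - 2, -1, -1):
        beta[t] = emissions[t] + (transitions[:K, :K] + beta[t + 1][None, :]).max(axis=1)
    first_scores = transitions[start, :K] + beta[0]
    best_score = float(first_scores.max())
    path = [int(np.argmax(first_scores))]
    for t in range(1, T):
        scores = transitions[path[-1], :K] + beta[t]
        path.append(int(np.argmax(scores)))
    return path, best_score


def crf_log_partition(emissions: np.ndarray, transitions: np.ndarray) -> float:
    """log Σ over all K^T sequences of exp(crf_score), forward algorithm."""
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    T, K = _check(emissions, transitions)
    start, stop = start_stop_indices(K)
    if T == 0:
        return float(transitions[start, stop])
    alpha = transitions[start, :K] + emissions[0]
    for t in range(1, T):
        alpha = _logsumexp_cols(alpha[:, None] + transitions[:K, :K]) + emissions[t]
    final = alpha + transitions[:K, stop]
    m = final.max()
    return float(m + np.log(np.exp(final - m).sum()))


def _logsumexp_cols(mat: np.ndarray) -> np.ndarray:
    m = mat.max(axis=0)
    return m + np.log(np.exp(mat - m[None, :]).sum(axis=0))


def crf_log_likelihood(
    emissions: np.ndarray, transitions: np.ndarray, gold_tags
) -> float:
    """log p(gold | emissions) = score(gold) − log-partition; always ≤ 0."""
    return crf_score(emissions, transitions, gold_tags) - crf_log_partition(
        emissions, transitions
    )


def crf_neg_log_likelihood_graph(
    emissions: Tensor, transitions: Tensor, gold_tags
) -> Tensor:
    """Differentiable −log-likelihood on the autodiff tape (for training)."""
    T, K = emissions.shape
    start, stop = start_stop_indices(K)
    tags = list(gold_tags)
    if len(tags) != T:
        raise ValueError(f"tag sequence length {len(tags)} != T={T}")
    if T == 0:
        return Tensor(0.0)
    gold = transitions[start, tags[0]] + emissions[0, tags[0]]
    for t in range(1, T):
        gold = gold + transitions[tags[t - 1], tags[t]] + emissions[t, tags[t]]
    gold = gold + transitions[tags[-1], stop]

    alpha = transitions[start, 0:K] + emissions[0]
    trans_inner = transitions[0:K, 0:K]
    for t in range(1, T):
        alpha = (alpha.reshape(K, 1) + trans_inner).logsumexp(axis=0) + emissions[t]
    log_z = (alpha + transitions[0:K, stop]).logsumexp(axis=0)
    return log_z - gold
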