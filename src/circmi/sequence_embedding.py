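"""k-mer skip-gram sequence embedding.

Each RNA sequence is decomposed into overlapping k-mers (stride 1) and a
skip-gram model with negative sampling is trained over the shared corpus of
circRNA and miRNA token streams: for every (center, context) token pair
within a window of radius ``c`` the objective maximizes

    log sigma(<v'_ctx, v_center>) + sum_{i=1..k_neg} E_{n~P_n} log sigma(-<v'_n, v_center>)

with noise tokens drawn from the unigram distribution raised to a smoothing
power (default 0.75).  Token vectors are then mean-pooled (over at most ``P``
leading tokens) into one fixed-dimension vector per sequence.

Optionally each k-mer token can be augmented with FastText-style character
n-gram buckets (n = 1..k-1); the center representation is then the mean of
the token vector and its bucket vectors.  This is off by default: with short
k-mers the tokens are themselves the subword units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from circmi.io_formats import RnaRecord

logger = logging.getLogger("circmi")


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _scatter_add(target: np.ndarray, idx: np.ndarray, grads: np.ndarray) -> None:
    """target[idx] += grads with duplicate indices, via sort + reduceat."""
    order = np.argsort(idx, kind="stable")
    idx_sorted = idx[order]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(idx_sorted)) + 1])
    target[idx_sorted[starts]] += np.add.reduceat(grads[order], starts, axis=0)


@dataclass
class TokenizedSequence:
    id: str
    tokens: list[str]
    k: int


@dataclass
class EmbeddingTable:
    """Learned input/output vectors for every k-mer token in the corpus."""

    tokens: list[str]
    input_vectors: np.ndarray  # (N, D)
    output_vectors: np.ndarray  # (N, D)
    dim: int
    window: int
    k_neg: int
    noise_exponent: float
    token_index: dict[str, int] = field(repr=False, default_factory=dict)
    subword_vectors: np.ndarray | None = None  # (n_buckets, D) when subwords on
    subword_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not self.token_index:
            self.token_index = {t: i for i, t in enumerate(self.tokens)}

    def vector(self, token: str) -> np.ndarray:
        """Composed input vector of a token (token row, plus buckets if on)."""
        idx = self.token_index[token]
        v = self.input_vectors[idx]
        if self.subword_vectors is None:
            return v
        buckets = _char_ngram_buckets(token, *self.subword_range, self.subword_vectors.shape[0])
        parts = np.vstack([v, self.subword_vectors[buckets]])
        return parts.mean(axis=0)


def kmer_tokenize(record: RnaRecord, k: int) -> TokenizedSequence:
    """Overlapping k-mers, stride 1: L - k + 1 tokens (0 if L < k)."""
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    seq = record.sequence
    if len(seq) < k:
        logger.warning("sequence %s shorter than k=%d: no tokens", record.id, k)
        return TokenizedSequence(id=record.id, tokens=[], k=k)
    return TokenizedSequence(
        id=record.id, tokens=[seq[i : i + k] for i in range(len(seq) - k + 1)], k=k
    )


def _char_ngram_buckets(token: str, min_n: int, max_n: int, n_buckets: int) -> list[int]:
    grams = [
        token[i : i + n]
        for n in range(min_n, max_n + 1)
        for i in range(len(token) - n + 1)
    ]
    # stable FNV-1a so bucket ids do not depend on PYTHONHASHSEED
    out = []
    for g in grams:
        h = 2166136261
        for ch in g.encode():
            h = ((h ^ ch) * 16777619) & 0xFFFFFFFF
        out.append(h % n_buckets)
    return out


def _pair_arrays(token_ids: list[np.ndarray], window: int) -> tuple[np.ndarray, np.ndarray]:
    centers, contexts = [], []
    for ids in token_ids:
        for d in range(1, window + 1):
            if len(ids) <= d:
                continue
            a, b = ids[:-d], ids[d:]
            centers.append(a)
            contexts.append(b)
            centers.append(b)
            contexts.append(a)
    if not centers:
        raise ValueError("corpus yields no (center, context) pairs")
    return np.concatenate(centers), np.concatenate(contexts)


def train_token_embeddings(
    corpus: list[TokenizedSequence],
    dim: int = 64,
    window: int = 5,
    k_neg: int = 5,
    epochs: int = 5,
    seed: int = 0,
    noise_exponent: float = 0.75,
    lr: float = 0.025,
    batch_size: int = 8192,
    subword: bool = False,
    n_buckets: int = 2000,
) -> EmbeddingTable:
    """Train skip-gram-with-negative-sampling token embeddings.

    Stochastic minibatch SGD over all in-window (center, context) pairs,
    with word2vec-style linear learning-rate decay.  Fully seeded: the same
    corpus, config and seed reproduce the table bitwise.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if dim <= 0 or window < 1 or k_neg < 1 or epochs < 1:
        raise ValueError("dim, window, k_neg and epochs must be >= 1")

    vocab = sorted({t for ts in corpus for t in ts.tokens})
    if not vocab:
        raise ValueError("corpus contains no tokens")
    index = {t: i for i, t in enumerate(vocab)}
    n_vocab = len(vocab)
    token_ids = [
        np.asarray([index[t] for t in ts.tokens], dtype=np.int64) for ts in corpus
    ]
    counts = np.bincount(np.concatenate(token_ids), minlength=n_vocab).astype(float)
    noise = counts**noise_exponent
    noise_cdf = np.cumsum(noise / noise.sum())

    centers, contexts = _pair_arrays(token_ids, window)
    n_pairs = len(centers)

    rng = np.random.default_rng(seed)
    v_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_vocab, dim))
    v_out = np.zeros((n_vocab, dim))
    v_sub = None
    sub_ids = None
    if subword:
        k = corpus[0].k
        v_sub = rng.uniform(-0.5 / dim, 0.5 / dim, size=(n_buckets, dim))
        max_n = max(1, k - 1)
        sub_ids = [
            np.asarray(_char_ngram_buckets(t, 1, max_n, n_buckets), dtype=np.int64)
            for t in vocab
        ]

    total_steps = epochs * int(np.ceil(n_pairs / batch_size))
    # With a small vocabulary the batch update can be aggregated by
    # (center, context) token identity: every pair with the same token ids
    # contributes an identical gradient term, so the whole batch collapses
    # to dense V x V matrix operations.  Identical math, far less traffic.
    dense_path = (not subword) and n_vocab <= 512
    step = 0
    for _ in range(epochs):
        order = rng.permutation(n_pairs)
        for lo in range(0, n_pairs, batch_size):
            sel = order[lo : lo + batch_size]
            c_idx = centers[sel]
            o_idx = contexts[sel]
            cur_lr = lr * max(1e-4, 1.0 - step / total_steps)
            step += 1
            neg_idx = np.searchsorted(
                noise_cdf, rng.random((len(c_idx), k_neg))
            ).astype(np.int64)

            if dense_path:
                pos_counts = np.bincount(
                    c_idx * n_vocab + o_idx, minlength=n_vocab * n_vocab
                ).reshape(n_vocab, n_vocab)
                neg_counts = np.bincount(
                    (np.repeat(c_idx, k_neg) * n_vocab + neg_idx.ravel()),
                    minlength=n_vocab * n_vocab,
                ).reshape(n_vocab, n_vocab)
                scores = _stable_sigmoid(v_in @ v_out.T)  # (V, V)
                coeff = pos_counts * (1.0 - scores) - neg_counts * scores
                # per-row mean gradient: keeps the update at per-pair SGD
                # magnitude regardless of how many pairs hit a row per batch
                n_in = np.maximum(pos_counts.sum(axis=1) + neg_counts.sum(axis=1), 1)
                n_out = np.maximum(pos_counts.sum(axis=0) + neg_counts.sum(axis=0), 1)
                grad_in = (coeff @ v_out) / n_in[:, None]
                grad_out = (coeff.T @ v_in) / n_out[:, None]
                v_in += cur_lr * grad_in
                v_out += cur_lr * grad_out
                continue

            if subword:
                # center vector = mean of token row and its bucket rows
                vc = np.empty((len(c_idx), dim))
                for r, ci in enumerate(c_idx):
                    parts = np.vstack([v_in[ci], v_sub[sub_ids[ci]]])
                    vc[r] = parts.mean(axis=0)
            else:
                vc = v_in[c_idx]

            u_pos = v_out[o_idx]  # (B, D)
            u_neg = v_out[neg_idx]  # (B, k, D)
            s_pos = _stable_sigmoid(np.einsum("bd,bd->b", vc, u_pos))
            s_neg = _stable_sigmoid(np.einsum("bd,bkd->bk", vc, u_neg))

            g_pos = (1.0 - s_pos)[:, None]  # ascent gradient coefficients
            g_neg = -s_neg[:, :, None]

            grad_vc = g_pos * u_pos + np.einsum("bki,bkd->bd", g_neg, u_neg)
            grad_u_pos = g_pos * vc
            grad_u_neg = g_neg * vc[:, None, :]

            # same per-row mean normalization as the dense path
            cnt_in = np.maximum(np.bincount(c_idx, minlength=n_vocab), 1)
            cnt_out = np.maximum(
                np.bincount(o_idx, minlength=n_vocab)
                + np.bincount(neg_idx.ravel(), minlength=n_vocab),
                1,
            )
            if subword:
                for r, ci in enumerate(c_idx):
                    share = grad_vc[r] / ((1 + len(sub_ids[ci])) * cnt_in[ci])
                    v_in[ci] += cur_lr * share
                    np.add.at(v_sub, sub_ids[ci], cur_lr * share)
            else:
                acc = np.zeros_like(v_in)
                _scatter_add(acc, c_idx, grad_vc)
                v_in += cur_lr * acc / cnt_in[:, None]
            acc = np.zeros_like(v_out)
            _scatter_add(acc, o_idx, grad_u_pos)
            _scatter_add(acc, neg_idx.ravel(), grad_u_neg.reshape(-1, dim))
            v_out += cur_lr * acc / cnt_out[:, None]

    if not np.all(np.isfinite(v_in)) or not np.all(np.isfinite(v_out)):
        raise FloatingPointError("non-finite embedding after training")
    logger.info("trained %d-token embedding table (D=%d)", n_vocab, dim)
    return EmbeddingTable(
        tokens=vocab,
        input_vectors=v_in,
        output_vectors=v_out,
        dim=dim,
        window=window,
        k_neg=k_neg,
        noise_exponent=noise_exponent,
        subword_vectors=v_sub,
        subword_range=(1, max(1, corpus[0].k - 1)) if subword else None,
    )


def embed_sequence(
    tokens: TokenizedSequence,
    table: EmbeddingTable,
    max_tokens: int = 64,
    pooling: str = "mean",
    oov: str = "skip",
) -> np.ndarray:
    """Pool the input vectors of the first ``min(T, max_tokens)`` tokens.

    ``pooling`` is ``"mean"`` or ``"sum"``.  Out-of-vocabulary tokens are
    skipped (``oov="skip"``) or raise (``oov="error"``); with subword buckets
    enabled, unseen tokens are composed from their bucket vectors instead.
    """
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    if pooling not in ("mean", "sum"):
        raise ValueError(f"unknown pooling {pooling!r}")
    if not tokens.tokens:
        logger.warning("sequence %s has no tokens: zero vector", tokens.id)
        return np.zeros(table.dim)
    rows = []
    for t in tokens.tokens[:max_tokens]:
        if t in table.token_index:
            rows.append(table.vector(t))
        elif table.subword_vectors is not None:
            buckets = _char_ngram_buckets(
                t, *table.subword_range, table.subword_vectors.shape[0]
            )
            rows.append(table.subword_vectors[buckets].mean(axis=0))
        elif oov == "error":
            raise KeyError(f"token {t!r} not in vocabulary")
        # oov == "skip": drop the token
    if not rows:
        logger.warning("sequence %s: all tokens out of vocabulary", tokens.id)
        return np.zeros(table.dim)
    stacked = np.asarray(rows)
    return stacked.mean(axis=0) if pooling == "mean" else stacked.sum(axis=0)


def embed_corpus(
    corpus: list[TokenizedSequence],
    table: EmbeddingTable,
    max_tokens: int = 64,
    pooling: str = "mean",
    oov: str = "skip",
) -> tuple[list[str], np.ndarray]:
    """Embed every sequence; returns (ids, matrix of shape n x D)."""
    ids = [ts.id for ts in corpus]
    mat = np.vstack(
        [embed_sequence(ts, table, max_tokens=max_tokens, pooling=pooling, oov=oov) for ts in corpus]
    )
    return ids, mat


def save_embedding_table(table: EmbeddingTable, token_path, matrix_path) -> None:
    """Serialize as a token list plus a delimited dense matrix (in | out)."""
    with open(token_path, "w") as fh:
        fh.write("\n".join(table.tokens) + "\n")
    np.savetxt(matrix_path, np.hstack([table.input_vectors, table.output_vectors]), delimiter="\t")


def load_embedding_table(token_path, matrix_path, window=5, k_neg=5, noise_exponent=0.75) -> EmbeddingTable:
    tokens = [t for t in open(token_path).read().splitlines() if t]
    mat = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    dim = mat.shape[1] // 2
    return EmbeddingTable(
        tokens=tokens,
        input_vectors=mat[:, :dim],
        output_vectors=mat[:, dim:],
        dim=dim,
        window=window,
        k_neg=k_neg,
        noise_exponent=noise_exponent,
    )
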