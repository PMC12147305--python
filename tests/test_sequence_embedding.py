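import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circmi.io_formats import RnaRecord
from circmi.sequence_embedding import (
    EmbeddingTable,
    TokenizedSequence,
    embed_sequence,
    kmer_tokenize,
    load_embedding_table,
    save_embedding_table,
    train_token_embeddings,
)


def _rec(seq, rid="r"):
    return RnaRecord(id=rid, molecule_class="circRNA", sequence=seq)


class TestTokenize:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGUACGU", 3, ["ACG", "CGU", "GUA", "UAC", "ACG", "CGU"]),
            ("ACG", 3, ["ACG"]),
            ("AC", 3, []),
            ("ACGU", 1, ["A", "C", "G", "U"]),
        ],
    )
    def test_sliding_window(self, seq, k, expected):
        assert kmer_tokenize(_rec(seq), k).tokens == expected

    def test_invalid_k_raises(self):
        with pytest.raises(ValueError):
            kmer_tokenize(_rec("ACGU"), 0)

    @given(st.lists(st.text(alphabet="ACGU", min_size=1, max_size=30), min_size=1, max_size=8))
    @settings(max_examples=30, deadline=None)
    def test_token_count_conservation(self, seqs):
        k = 3
        total = sum(len(kmer_tokenize(_rec(s, f"r{i}"), k).tokens) for i, s in enumerate(seqs))
        assert total == sum(max(0, len(s) - k + 1) for s in seqs)


def _sgns_reference(corpus, dim, window, k_neg, steps, seed, lr=0.1):
    """Independent full-expectation gradient ascent on the skip-gram
    negative-sampling objective, written from the loss definition: exact
    co-occurrence counts, exact expectation over the smoothed unigram noise."""
    vocab = sorted({t for ts in corpus for t in ts.tokens})
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)
    counts = np.zeros((V, V))
    freq = np.zeros(V)
    for ts in corpus:
        ids = [index[t] for t in ts.tokens]
        for i, c in enumerate(ids):
            freq[c] += 1
            for j in range(max(0, i - window), min(len(ids), i + window + 1)):
                if j != i:
                    counts[c, ids[j]] += 1
    noise = freq**0.75
    noise /= noise.sum()
    rng = np.random.default_rng(seed)
    vin = rng.uniform(-0.1, 0.1, (V, dim))
    vout = rng.uniform(-0.1, 0.1, (V, dim))
    neg_counts = k_neg * np.outer(freq, noise)
    for _ in range(steps):
        s = 1.0 / (1.0 + np.exp(-(vin @ vout.T)))
        coeff = counts * (1.0 - s) - neg_counts * s
        gin, gout = coeff @ vout, coeff.T @ vin
        vin += lr * gin / max(1.0, np.abs(gin).max())
        vout += lr * gout / max(1.0, np.abs(gout).max())
    return vocab, vin, vout


def _cosine(a, b):
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + 1e-12))


class TestTrainEmbeddings:
    def _corpus(self):
        # AAA always co-occurs with AAU; GGG lives in a disjoint context
        seqs = ["AAAU" * 6, "AAUA" * 6, "GGGC" * 6, "GCGG" * 6]
        return [
            kmer_tokenize(_rec(s, f"s{i}"), 3) for i, s in enumerate(seqs)
        ]

    def test_vocabulary_coverage_and_shapes(self):
        corpus = self._corpus()
        table = train_token_embeddings(corpus, dim=8, epochs=2, seed=0)
        expected_vocab = {t for ts in corpus for t in ts.tokens}
        assert set(table.tokens) == expected_vocab
        assert table.input_vectors.shape == (len(expected_vocab), 8)
        assert np.all(np.isfinite(table.input_vectors))

    def test_seeded_determinism(self):
        corpus = self._corpus()
        t1 = train_token_embeddings(corpus, dim=8, epochs=2, seed=5)
        t2 = train_token_embeddings(corpus, dim=8, epochs=2, seed=5)
        np.testing.assert_array_equal(t1.input_vectors, t2.input_vectors)
        np.testing.assert_array_equal(t1.output_vectors, t2.output_vectors)

    def test_cooccurring_tokens_closer_than_disjoint_tokens(self):
        """Both the trainer and an independent expectation-gradient reference
        must rank cosine(AAA, AAU') above cosine(AAA, GGG')."""
        corpus = self._corpus()
        table = train_token_embeddings(corpus, dim=16, epochs=30, seed=0)
        idx = table.token_index
        v = table.input_vectors[idx["AAA"]]
        assert _cosine(v, table.output_vectors[idx["AAU"]]) > _cosine(
            v, table.output_vectors[idx["GGG"]]
        )
        vocab, vin, vout = _sgns_reference(corpus, 16, 5, 5, steps=300, seed=0)
        ridx = {t: i for i, t in enumerate(vocab)}
        rv = vin[ridx["AAA"]]
        assert _cosine(rv, vout[ridx["AAU"]]) > _cosine(rv, vout[ridx["GGG"]])

    def test_planted_cliques_separate(self):
        """Two token cliques with disjoint contexts: mean within-clique cosine
        exceeds mean cross-clique cosine after training."""
        rng = np.random.default_rng(0)
        a_seqs = ["".join(rng.choice(list("AU"), 40)) for _ in range(6)]
        b_seqs = ["".join(rng.choice(list("GC"), 40)) for _ in range(6)]
        corpus = [
            kmer_tokenize(_rec(s, f"x{i}"), 2)
            for i, s in enumerate(a_seqs + b_seqs)
        ]
        table = train_token_embeddings(corpus, dim=16, epochs=20, seed=1)
        a_tok = [t for t in table.tokens if set(t) <= set("AU")]
        b_tok = [t for t in table.tokens if set(t) <= set("GC")]
        vecs = {t: table.input_vectors[table.token_index[t]] for t in table.tokens}
        within = np.mean(
            [_cosine(vecs[x], vecs[y]) for grp in (a_tok, b_tok) for x in grp for y in grp if x != y]
        )
        cross = np.mean([_cosine(vecs[x], vecs[y]) for x in a_tok for y in b_tok])
        assert within > cross

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_token_embeddings([], dim=8)

    def test_subword_buckets_change_composition(self):
        corpus = self._corpus()
        table = train_token_embeddings(corpus, dim=8, epochs=2, seed=0, subword=True)
        assert table.subword_vectors is not None
        tok = table.tokens[0]
        composed = table.vector(tok)
        plain = table.input_vectors[table.token_index[tok]]
        assert composed.shape == plain.shape
        assert not np.allclose(composed, plain)


class TestEmbedSequence:
    def _table(self, vectors):
        tokens = sorted(vectors)
        mat = np.array([vectors[t] for t in tokens], dtype=float)
        return EmbeddingTable(
            tokens=tokens,
            input_vectors=mat,
            output_vectors=np.zeros_like(mat),
            dim=mat.shape[1],
            window=5,
            k_neg=5,
            noise_exponent=0.75,
        )

    def test_single_token_returns_its_vector(self):
        table = self._table({"ACG": [1.0, 2.0]})
        out = embed_sequence(TokenizedSequence("s", ["ACG"], 3), table)
        np.testing.assert_allclose(out, [1.0, 2.0])

    def test_opposite_vectors_cancel(self):
        table = self._table({"AAA": [1.0, -1.0], "UUU": [-1.0, 1.0]})
        out = embed_sequence(TokenizedSequence("s", ["AAA", "UUU"], 3), table)
        np.testing.assert_allclose(out, [0.0, 0.0])

    def test_truncation_to_max_tokens(self):
        table = self._table({"AAA": [1.0], "CCC": [3.0]})
        tokens = ["AAA"] * 64 + ["CCC"] * 36
        out = embed_sequence(TokenizedSequence("s", tokens, 3), table, max_tokens=64)
        np.testing.assert_allclose(out, [1.0])

    def test_empty_tokens_give_zero_vector(self):
        table = self._table({"ACG": [1.0, 1.0]})
        out = embed_sequence(TokenizedSequence("s", [], 3), table)
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_oov_policy(self):
        table = self._table({"AAA": [2.0]})
        tokens = TokenizedSequence("s", ["AAA", "ZZZ"], 3)
        np.testing.assert_allclose(embed_sequence(tokens, table, oov="skip"), [2.0])
        with pytest.raises(KeyError):
            embed_sequence(tokens, table, oov="error")

    def test_sum_pooling(self):
        table = self._table({"AAA": [1.0], "CCC": [3.0]})
        out = embed_sequence(
            TokenizedSequence("s", ["AAA", "CCC"], 3), table, pooling="sum"
        )
        np.testing.assert_allclose(out, [4.0])


def test_embedding_table_round_trip(tmp_path):
    corpus = [kmer_tokenize(_rec("ACGUACGUACGU"), 3)]
    table = train_token_embeddings(corpus, dim=8, epochs=1, seed=0)
    save_embedding_table(table, tmp_path / "tokens.txt", tmp_path / "vectors.tsv")
    loaded = load_embedding_table(tmp_path / "tokens.txt", tmp_path / "vectors.tsv")
    assert loaded.tokens == table.tokens
    np.testing.assert_allclose(loaded.input_vectors, table.input_vectors, atol=1e-12)
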