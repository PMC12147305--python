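"""End-to-end feature assembly: sequences and graph to per-pair blocks.

The sequence side (k-mer skip-gram + SAE compression) is label-free and is
computed once per dataset; the structural side (GraRep) depends on the
association matrix and is recomputed per CV fold in leakage-safe mode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from circmi.config import PipelineConfig
from circmi.deep_features import sae_encode, sae_fit
from circmi.graph_embedding import NodeEmbedding, grarep
from circmi.io_formats import (
    AssociationMatrix,
    InteractionTable,
    RnaRecord,
    build_association_matrix,
)
from circmi.sequence_embedding import embed_corpus, kmer_tokenize, train_token_embeddings

logger = logging.getLogger("circmi")


@dataclass
class CmiDataset:
    """Sequences plus the labeled pair universe for one experiment."""

    records_circ: list[RnaRecord]
    records_mi: list[RnaRecord]
    positives: InteractionTable
    negatives: InteractionTable | None = None

    def association(self) -> AssociationMatrix:
        return build_association_matrix(self.records_circ, self.records_mi, self.positives)


@dataclass
class SequenceCodes:
    """SAE bottleneck codes for every molecule, keyed by id."""

    circ_ids: list[str]
    circ_codes: np.ndarray
    mi_ids: list[str]
    mi_codes: np.ndarray
    circ_index: dict[str, int] = field(default_factory=dict)
    mi_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.circ_index:
            self.circ_index = {i: n for n, i in enumerate(self.circ_ids)}
        if not self.mi_index:
            self.mi_index = {i: n for n, i in enumerate(self.mi_ids)}


def compute_sequence_codes(
    records_circ: list[RnaRecord],
    records_mi: list[RnaRecord],
    config: PipelineConfig,
    seed: int = 0,
) -> SequenceCodes:
    """Tokenize, train one shared skip-gram space, pool, compress with two SAEs.

    One embedding space is trained over the union of the circRNA and miRNA
    token corpora; a separate stacked autoencoder is then fitted per
    molecule class.  All stages are unsupervised (no labels touched).
    """
    circ_tok = [kmer_tokenize(r, config.kmer_k) for r in records_circ]
    mi_tok = [kmer_tokenize(r, config.kmer_k) for r in records_mi]
    table = train_token_embeddings(
        circ_tok + mi_tok,
        dim=config.embed_dim,
        window=config.window,
        k_neg=config.k_neg,
        epochs=config.sg_epochs,
        seed=seed,
        noise_exponent=config.noise_exponent,
        lr=config.sg_lr,
        subword=config.subword,
    )
    circ_ids, circ_emb = embed_corpus(
        circ_tok, table, max_tokens=config.pool_max_tokens, pooling=config.pooling
    )
    mi_ids, mi_emb = embed_corpus(
        mi_tok, table, max_tokens=config.pool_max_tokens, pooling=config.pooling
    )
    codes = []
    for emb in (circ_emb, mi_emb):
        sae = sae_fit(
            emb,
            sizes=config.sae_sizes,
            epochs=config.sae_epochs,
            lr=config.sae_lr,
            batch_size=config.sae_batch,
            val_frac=config.sae_val_frac,
            patience=config.sae_patience,
            seed=seed,
        )
        codes.append(sae_encode(sae, emb, "bottleneck"))
    return SequenceCodes(
        circ_ids=circ_ids, circ_codes=codes[0], mi_ids=mi_ids, mi_codes=codes[1]
    )


def compute_structure_features(
    assoc: AssociationMatrix, config: PipelineConfig
) -> NodeEmbedding:
    """GraRep node embedding of the bipartite graph (dim K * d_k per node)."""
    return grarep(
        assoc,
        orders=config.grarep_orders,
        rank=config.grarep_rank,
        lambda_neg=config.grarep_lambda,
    )


def assemble_pair_features(
    pairs: list[tuple[str, str]],
    codes: SequenceCodes,
    struct: NodeEmbedding,
) -> np.ndarray:
    """Raw per-pair block matrix [circ_code | mi_code | circ_struct | mi_struct]."""
    circ_ids = [c for c, _ in pairs]
    mi_ids = [m for _, m in pairs]
    circ_codes = codes.circ_codes[[codes.circ_index[c] for c in circ_ids]]
    mi_codes = codes.mi_codes[[codes.mi_index[m] for m in mi_ids]]
    circ_struct = struct.subset(circ_ids)
    mi_struct = struct.subset(mi_ids)
    return np.hstack([circ_codes, mi_codes, circ_struct, mi_struct])


def masked_association(
    assoc: AssociationMatrix, held_out: list[tuple[str, str]]
) -> AssociationMatrix:
    """Copy of the association matrix with the held-out positive edges zeroed."""
    A = assoc.A.copy()
    for circ, mi in held_out:
        A[assoc.row_index[circ], assoc.col_index[mi]] = 0
    return AssociationMatrix(
        A=A, row_ids=list(assoc.row_ids), col_ids=list(assoc.col_ids)
    )
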