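"""GraRep structural embedding of the bipartite interaction graph.

The circRNA and miRNA node sets form one undirected bipartite graph with
adjacency ``S = [[0, A], [A^T, 0]]``.  For each step order ``k`` up to ``K``
the method forms the k-step transition matrix ``A_k = (D^-1 S)^k``, the
shifted positive log matrix

    Y_k(i, j) = log( A_k(i, j) / Gamma_k(j) ) - log(lambda / |E|),
    Gamma_k(j) = sum_p A_k(p, j)   (column sum),
    X_k = max(Y_k, 0),

and factorizes ``X_k`` by truncated SVD, keeping ``H_k = U_k sqrt(S_k)`` as
the node representation of order k.  The final embedding concatenates
H_1..H_K, dimension ``K * d_k`` per node.

Note on the shift normalization: the column sum Gamma_k(j) (the original
GraRep choice) is used.  A row sum of a row-stochastic matrix is identically
one and would collapse the PPMI structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from circmi.io_formats import AssociationMatrix

logger = logging.getLogger("circmi")


@dataclass
class GraphMatrices:
    S: np.ndarray  # symmetric binary adjacency, (n_circ+n_mi) square
    degrees: np.ndarray
    transition: np.ndarray  # D^-1 S, isolated rows all-zero
    edge_count: int
    n_circ: int
    n_mi: int


@dataclass
class OrderMatrices:
    k: int
    a_k: np.ndarray
    y_k: np.ndarray
    x_k: np.ndarray
    lambda_neg: float
    beta: float


@dataclass
class NodeEmbedding:
    """Concatenated per-order embeddings, circRNA nodes first."""

    node_ids: list[str]
    node_classes: list[str]
    vectors: np.ndarray  # (n_nodes, K * d_k)
    orders: int
    rank: int
    index: dict[str, int]

    def subset(self, ids: list[str]) -> np.ndarray:
        return self.vectors[[self.index[i] for i in ids]]


def build_bipartite_adjacency(assoc: AssociationMatrix) -> GraphMatrices:
    """Block adjacency S = [[0, A], [A^T, 0]] over circ + mi nodes."""
    A = np.asarray(assoc.A, dtype=float)
    if A.sum() == 0:
        raise ValueError("association matrix has no interactions")
    n_c, n_m = A.shape
    S = np.zeros((n_c + n_m, n_c + n_m))
    S[:n_c, n_c:] = A
    S[n_c:, :n_c] = A.T
    degrees = S.sum(axis=1)
    n_isolated = int((degrees == 0).sum())
    if n_isolated:
        logger.warning("%d isolated node(s): zero transition rows", n_isolated)
    trans = transition_from(S, degrees)
    return GraphMatrices(
        S=S,
        degrees=degrees,
        transition=trans,
        edge_count=int(A.sum()),
        n_circ=n_c,
        n_mi=n_m,
    )


def transition_from(S: np.ndarray, degrees: np.ndarray) -> np.ndarray:
    inv = np.where(degrees > 0, 1.0 / np.where(degrees > 0, degrees, 1.0), 0.0)
    return S * inv[:, None]


def transition_matrix(graph: GraphMatrices) -> np.ndarray:
    """Row-normalized transition matrix D^-1 S (isolated rows stay zero)."""
    return graph.transition


def shifted_log_matrix(
    A_trans: np.ndarray,
    k: int,
    lambda_neg: float,
    edge_count: int,
) -> OrderMatrices:
    """k-step transition, column-normalized log shift, clamp at zero."""
    if k < 1:
        raise ValueError("order k must be >= 1")
    if lambda_neg <= 0:
        raise ValueError("lambda_neg must be positive")
    if edge_count <= 0:
        raise ValueError("edge_count must be positive")
    a_k = np.linalg.matrix_power(A_trans, k)
    gamma = a_k.sum(axis=0)  # column sums
    beta = lambda_neg / edge_count
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(gamma > 0, a_k / np.where(gamma > 0, gamma, 1.0), 0.0)
        y_k = np.where(ratio > 0, np.log(np.where(ratio > 0, ratio, 1.0)) - np.log(beta), -np.inf)
    x_k = np.where(np.isfinite(y_k), np.maximum(y_k, 0.0), 0.0)
    return OrderMatrices(k=k, a_k=a_k, y_k=y_k, x_k=x_k, lambda_neg=lambda_neg, beta=beta)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic sign convention: largest-|.| entry of each left vector positive."""
    U = U.copy()
    V = V.copy()
    for j in range(U.shape[1]):
        col = U[:, j]
        i = int(np.argmax(np.abs(col)))
        if col[i] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return U, V


def factorize_order(x_k: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated SVD: H = U sqrt(S), Z = V sqrt(S) for the top-``rank`` values."""
    if rank < 1:
        raise ValueError("rank must be >= 1")
    n = min(x_k.shape)
    if rank > n:
        raise ValueError(f"rank {rank} exceeds matrix dimension {n}")
    if not np.any(x_k):
        logger.warning("all-zero shifted log matrix: zero embeddings")
        return (
            np.zeros((x_k.shape[0], rank)),
            np.zeros((x_k.shape[1], rank)),
        )
    U, s, Vt = np.linalg.svd(x_k, full_matrices=False)
    U, V = _fix_signs(U[:, :rank], Vt[:rank].T)
    root = np.sqrt(s[:rank])
    return U * root, V * root


def grarep(
    assoc: AssociationMatrix,
    orders: int = 4,
    rank: int = 16,
    lambda_neg: float = 1.0,
) -> NodeEmbedding:
    """Full GraRep embedding: concatenate H_1..H_K, per-node dim K * rank."""
    if orders < 1:
        raise ValueError("orders must be >= 1")
    graph = build_bipartite_adjacency(assoc)
    blocks = []
    for k in range(1, orders + 1):
        om = shifted_log_matrix(graph.transition, k, lambda_neg, graph.edge_count)
        H, _ = factorize_order(om.x_k, rank)
        blocks.append(H)
    vectors = np.hstack(blocks)
    node_ids = list(assoc.row_ids) + list(assoc.col_ids)
    node_classes = ["circRNA"] * graph.n_circ + ["miRNA"] * graph.n_mi
    return NodeEmbedding(
        node_ids=node_ids,
        node_classes=node_classes,
        vectors=vectors,
        orders=orders,
        rank=rank,
        index={nid: i for i, nid in enumerate(node_ids)},
    )


def save_node_embedding(emb: NodeEmbedding, path) -> None:
    """Delimited text: node id, class, then the K*d_k coordinates."""
    with open(path, "w") as fh:
        dim = emb.vectors.shape[1]
        fh.write("node_id\tclass\t" + "\t".join(f"e{i}" for i in range(dim)) + "\n")
        for nid, cls, row in zip(emb.node_ids, emb.node_classes, emb.vectors):
            fh.write(nid + "\t" + cls + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")
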