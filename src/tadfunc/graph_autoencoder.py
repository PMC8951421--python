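"""Linear graph autoencoder for link prediction on spatial gene networks.

The encoder is a single linear map on the symmetrically normalised
adjacency, Z = ÃW with Ã = D^{-1/2} A D^{-1/2}; the decoder is the
inner-product reconstruction Â = σ(ZZᵀ).  Edges are split 7:2:1 into
train/validation/test positives, with size-matched negative (non-edge)
samples for validation and test; all remaining non-edges enter the
training loss as down-weighted negatives.  Held-out edges are scored by
their reconstructed probabilities and summarised by ROC AUC and average
precision, with t-based confidence intervals over repeated splits.

The model is a scikit-learn-style estimator: ``fit`` takes the training
adjacency, fitted arrays carry a trailing underscore, and
``get_params``/``set_params`` come from ``BaseEstimator``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.utils.validation import check_is_fitted


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def normalize_adjacency(A: np.ndarray, add_self_loops: bool = False) -> np.ndarray:
    """Symmetric normalisation Ã = D^{-1/2} A D^{-1/2}.

    D holds the row sums of A; rows and columns of zero-degree nodes are
    left all zero.  ``add_self_loops`` applies the normalisation to
    A + I instead.
    """
    A = np.asarray(A, dtype=float)
    if add_self_loops:
        A = A + np.eye(A.shape[0])
    deg = A.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    return A * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class EdgeSplit:
    """7:2:1 positive edge split with matched negative samples.

    Edge arrays have shape (k, 2) with i < j.  ``val_neg`` and
    ``test_neg`` are disjoint samples of non-edges of the same sizes as
    their positive sets; every other non-edge is implicitly a training
    negative (it enters the training loss through the dense adjacency).
    """

    n_nodes: int
    train_pos: np.ndarray
    val_pos: np.ndarray
    test_pos: np.ndarray
    val_neg: np.ndarray
    test_neg: np.ndarray

    def train_adjacency(self) -> np.ndarray:
        A = np.zeros((self.n_nodes, self.n_nodes))
        if len(self.train_pos):
            i, j = self.train_pos[:, 0], self.train_pos[:, 1]
            A[i, j] = 1.0
            A[j, i] = 1.0
        return A


def split_edges(A: np.ndarray, rng: np.random.Generator) -> EdgeSplit:
    """Split the edges of a symmetric binary adjacency 7:2:1.

    Counts: val = floor(0.2 m), test = floor(0.1 m), train = remainder
    after a seeded shuffle.  Validation and test negatives are uniform
    non-edge samples, disjoint from each other.
    """
    A = np.asarray(A)
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    pos_mask = A[iu, ju] > 0
    edges = np.column_stack([iu[pos_mask], ju[pos_mask]])
    m = len(edges)
    if m < 10:
        raise ValueError(f"need >= 10 edges to split 7:2:1, got {m}")
    n_val, n_test = int(0.2 * m), int(0.1 * m)
    order = rng.permutation(m)
    val = edges[order[:n_val]]
    test = edges[order[n_val:n_val + n_test]]
    train = edges[order[n_val + n_test:]]

    non_edges = np.column_stack([iu[~pos_mask], ju[~pos_mask]])
    if len(non_edges) < n_val + n_test:
        raise ValueError(
            f"only {len(non_edges)} non-edges, need {n_val + n_test} negatives"
        )
    neg_order = rng.permutation(len(non_edges))
    val_neg = non_edges[neg_order[:n_val]]
    test_neg = non_edges[neg_order[n_val:n_val + n_test]]
    return EdgeSplit(n, train, val, test, val_neg, test_neg)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LinearGraphAutoencoder(BaseEstimator):
    """Linear graph autoencoder with inner-product decoder.

    Parameters
    ----------
    n_components : embedding dimension d (default 128).
    learning_rate : full-batch gradient-descent step size (default 0.001).
    n_epochs : training epochs (default 200).
    add_self_loops : normalise A + I instead of A (default False, the
        equation as stated).
    random_state : seed for weight initialisation.

    The training objective is the total binary cross-entropy between Â
    and the training adjacency over *all* node pairs, with the positive
    class up-weighted by (#pairs - #edges)/#edges so the sparse
    positives and the dense implicit negatives contribute equally.
    ``loss_curve_`` reports the per-pair mean of this objective; the
    gradient descends the sum, which keeps full-batch steps effective
    at the default learning rate on desk-scale networks.

    Attributes (after fit)
    ----------------------
    W_ : (n, d) weight matrix.
    Z_ : (n, d) embedding ÃW.
    A_hat_ : (n, n) reconstruction σ(ZZᵀ).
    loss_curve_ : per-epoch training loss.
    """

    def __init__(
        self,
        n_components: int = 128,
        learning_rate: float = 0.001,
        n_epochs: int = 200,
        add_self_loops: bool = False,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.learning_rate = learning_rate
        self.n_epochs = n_epochs
        self.add_self_loops = add_self_loops
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "LinearGraphAutoencoder":
        """Fit on a symmetric binary training adjacency X (n x n)."""
        A = np.asarray(X, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"adjacency must be square, got {A.shape}")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        n = A.shape[0]
        d = self.n_components
        rng = np.random.default_rng(self.random_state)
        A_tilde = normalize_adjacency(A, self.add_self_loops)

        n_pos = A.sum()
        n_all = float(n * n)
        if n_pos == 0:
            raise ValueError("training adjacency has no edges")
        pos_weight = (n_all - n_pos) / n_pos
        norm = n_all / (2.0 * (n_all - n_pos))

        limit = np.sqrt(6.0 / (n + d))
        W = rng.uniform(-limit, limit, size=(n, d))
        losses = []
        for _ in range(self.n_epochs):
            Z = A_tilde @ W
            S = Z @ Z.T
            P = _sigmoid(S)
            eps = 1e-12
            bce = -(
                pos_weight * A * np.log(P + eps)
                + (1.0 - A) * np.log(1.0 - P + eps)
            )
            loss = norm * bce.mean()
            if not np.isfinite(loss):
                raise DivergenceError(f"non-finite loss {loss}")
            losses.append(float(loss))
            # dL/dS of the *total* (summed) rebalanced cross-entropy; the
            # sum scaling keeps plain gradient descent effective at this
            # learning rate.  S and A symmetric so the two chain-rule
            # branches through Z coincide.
            G = norm * (P * (pos_weight * A + 1.0 - A) - pos_weight * A)
            dZ = 2.0 * (G @ Z)
            dW = A_tilde.T @ dZ
            W = W - self.learning_rate * dW

        self.n_features_in_ = n
        self.W_ = W
        self.Z_ = A_tilde @ W
        self.A_hat_ = _sigmoid(self.Z_ @ self.Z_.T)
        self.loss_curve_ = losses
        return self

    def reconstruct(self) -> np.ndarray:
        check_is_fitted(self, "A_hat_")
        return self.A_hat_

    def score_pairs(self, pairs: np.ndarray) -> np.ndarray:
        """Reconstructed edge probabilities at (k, 2) index pairs."""
        check_is_fitted(self, "A_hat_")
        pairs = np.asarray(pairs)
        return self.A_hat_[pairs[:, 0], pairs[:, 1]]


def evaluate(
    model: LinearGraphAutoencoder, split: EdgeSplit, subset: str = "test"
) -> tuple[float, float]:
    """(AUC, AP) of the reconstruction on a held-out subset.

    Scores are the Â entries at the subset's positive and negative
    pairs; AUC is the rank-based ROC area and AP the step-interpolated
    precision–recall area.
    """
    pos = split.val_pos if subset == "val" else split.test_pos
    neg = split.val_neg if subset == "val" else split.test_neg
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError(f"empty {subset} subset")
    scores = np.concatenate([model.score_pairs(pos), model.score_pairs(neg)])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))])
    return float(roc_auc_score(labels, scores)), float(
        average_precision_score(labels, scores)
    )


@dataclass(frozen=True)
class IntervalEstimate:
    """A mean with a t-based confidence half-width."""

    mean: float
    half_width: float
    n: int
    level: float = 0.95


def confidence_interval(values: Sequence[float], level: float = 0.95) -> IntervalEstimate:
    """Mean ± t_{(1+level)/2, n-1} · s/√n with s the sample standard
    deviation (ddof 1)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 2:
        raise ValueError(f"need >= 2 values, got {n}")
    t = stats.t.ppf((1 + level) / 2, df=n - 1)
    s = values.std(ddof=1)
    return IntervalEstimate(float(values.mean()), float(t * s / np.sqrt(n)), n, level)


def graph_to_adjacency(graph: nx.Graph) -> tuple[np.ndarray, list[str]]:
    """Dense symmetric binary adjacency plus the sorted node order."""
    nodes = sorted(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    np.fill_diagonal(A, 0.0)
    return A, nodes


def run_repeats(
    graph: nx.Graph,
    n_repeats: int = 10,
    seed: int = 0,
    subset: str = "test",
    **model_params,
):
    """The repeated-split protocol: each repeat re-splits the edges with
    a distinct derived seed, refits, and records (AUC, AP); returns a
    DataFrame of per-repeat rows plus the two IntervalEstimates.
    """
    import pandas as pd

    A, _nodes = graph_to_adjacency(graph)
    rows = []
    for rep in range(n_repeats):
        rep_seed = (seed * 1000 + rep) % (2**31 - 1)
        rng = np.random.default_rng(rep_seed)
        split = split_edges(A, rng)
        model = LinearGraphAutoencoder(random_state=rep_seed, **model_params)
        model.fit(split.train_adjacency())
        auc, ap = evaluate(model, split, subset)
        rows.append({"repeat": rep, "seed": rep_seed, "auc": auc, "ap": ap})
    df = pd.DataFrame(rows)
    return (
        df,
        confidence_interval(df["auc"].to_numpy()),
        confidence_interval(df["ap"].to_numpy()),
    )
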