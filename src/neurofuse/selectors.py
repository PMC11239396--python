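"""Relevance-based feature selection for the FNC and SNP modalities.

A small 1D convolutional classifier is trained on the flattened modality
features (1378 lower-triangle FNC connections, or the SNP dosage vector),
layer-wise relevance propagation attributes its case-class output back to
the inputs, per-subject scores are abs-normalized and mean-aggregated, and
features survive either a relevance threshold (FNC default: scores > 0.002
on a vector summing to 1) or a top-k cut (SNP default: k = 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import lrp
from .cohort import default_domain_map, lower_triangle_indices
from .nn import Conv1d, Dense, Flatten, Network, ReLU, train_network

__all__ = [
    "ConnectionIndexMap",
    "SelectionResult",
    "FNC_THRESHOLD",
    "SNP_TOP_K",
    "vectorize_lower_triangle",
    "devectorize_lower_triangle",
    "vectorize_fnc_stack",
    "train_modality_cnn",
    "rank_features",
    "select_features",
    "apply_selection",
]

#: relevance cut for FNC connections (on normalized scores summing to 1)
FNC_THRESHOLD = 0.002
#: number of SNPs retained by the genomic selector
SNP_TOP_K = 100
#: class index whose pre-softmax activation is propagated (1 = case)
TARGET_CLASS = 1


@dataclass(frozen=True)
class ConnectionIndexMap:
    """Bijection between flat lower-triangle indices and component pairs.

    Flat index i maps to components (row, col) with row > col, enumerated
    row-major over the strict lower triangle, plus the domain label of each
    component.
    """

    n_components: int
    domain_map: list

    def __post_init__(self):
        if len(self.domain_map) != self.n_components:
            raise ValueError("domain_map length must equal n_components")

    @property
    def n_connections(self):
        return self.n_components * (self.n_components - 1) // 2

    def components(self, flat_index):
        rows, cols = lower_triangle_indices(self.n_components)
        if not 0 <= flat_index < self.n_connections:
            raise IndexError(f"flat index {flat_index} out of range")
        return int(rows[flat_index]), int(cols[flat_index])

    def describe(self, flat_index):
        i, j = self.components(flat_index)
        return {
            "component_i": i,
            "component_j": j,
            "domain_i": self.domain_map[i],
            "domain_j": self.domain_map[j],
        }


@dataclass
class SelectionResult:
    """Ordered surviving feature indices plus the rule that produced them."""

    modality: str  # "fnc" | "snp"
    ranked_indices: np.ndarray  # all features, descending relevance
    selected_indices: np.ndarray  # surviving subset, rank order
    rule: str  # e.g. "threshold(0.002)" or "top_k(100)"
    relevance: lrp.RelevanceVector

    @property
    def n_selected(self):
        return len(self.selected_indices)


def vectorize_lower_triangle(matrix, domain_map=None, atol=1e-8):
    """Flatten a symmetric matrix's strict lower triangle (row-major).

    Returns the flat vector and the :class:`ConnectionIndexMap`. A 53x53
    FNC matrix yields 1378 connection values.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("FNC matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=atol):
        raise ValueError(f"matrix asymmetric beyond tolerance {atol}")
    n = matrix.shape[0]
    rows, cols = lower_triangle_indices(n)
    index_map = ConnectionIndexMap(n, list(domain_map or default_domain_map(n)))
    return matrix[rows, cols], index_map


def devectorize_lower_triangle(vector, n_components):
    """Inverse of :func:`vectorize_lower_triangle` (unit diagonal)."""
    vector = np.asarray(vector, dtype=float)
    expected = n_components * (n_components - 1) // 2
    if len(vector) != expected:
        raise ValueError(f"expected {expected} values, got {len(vector)}")
    out = np.eye(n_components)
    rows, cols = lower_triangle_indices(n_components)
    out[rows, cols] = vector
    out[cols, rows] = vector
    return out


def vectorize_fnc_stack(fnc, domain_map=None):
    """Vectorize a stack of per-subject FNC matrices to (n, C)."""
    fnc = np.asarray(fnc)
    flats = []
    index_map = None
    for m in fnc:
        flat, index_map = vectorize_lower_triangle(m, domain_map)
        flats.append(flat)
    return np.stack(flats), index_map


@dataclass
class CNNHyperparams:
    channels: tuple = (8, 16)
    kernel: int = 5
    stride: int = 2
    hidden: int = 32
    epochs: int = 30
    batch_size: int = 32
    lr: float = 1e-3
    weight_decay: float = 1e-4


def build_modality_cnn(n_features, hp: CNNHyperparams, seed=0) -> Network:
    """Two 1D convolution layers, flatten, one hidden dense layer, 2-unit
    output — small enough to train on CPU in seconds, deep enough to
    exercise every relevance rule."""
    rng = np.random.default_rng(seed)
    layers = []
    length = n_features
    c_in = 1
    for c_out in hp.channels:
        conv = Conv1d(c_in, c_out, hp.kernel, hp.stride, rng=rng)
        if conv.out_length(length) < 1:
            raise ValueError(f"feature length {n_features} too short for CNN")
        layers += [conv, ReLU()]
        length = conv.out_length(length)
        c_in = c_out
    layers += [
        Flatten(),
        Dense(length * c_in, hp.hidden, rng=rng),
        ReLU(),
        Dense(hp.hidden, 2, rng=rng),
    ]
    return Network(layers)


def train_modality_cnn(features, labels, hyperparams=None, seed=0) -> Network:
    """Train the per-modality 1D CNN classifier; deterministic given seed."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2:
        raise ValueError("features must be an (n, C) matrix")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    counts = np.bincount(labels, minlength=2)
    if (counts < 2).any():
        raise ValueError("need at least 2 subjects per class")
    hp = hyperparams or CNNHyperparams()
    # standardize per feature so dosage and correlation scales train alike
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd[sd == 0] = 1.0
    X = ((features - mu) / sd)[:, None, :]
    # a rare initialisation/trajectory can kill every hidden ReLU, leaving a
    # constant predictor with nothing to attribute; retry deterministically
    for attempt in range(3):
        net = build_modality_cnn(features.shape[1], hp, seed=seed + 7919 * attempt)
        history = train_network(
            net, X, labels,
            epochs=hp.epochs, batch_size=hp.batch_size, lr=hp.lr,
            seed=seed + 7919 * attempt, weight_decay=hp.weight_decay,
        )
        if not _is_dead(net, X):
            break
        warnings.warn(
            "modality CNN collapsed to a constant predictor; retraining "
            "with a derived seed", stacklevel=2,
        )
    net.meta.update({"standardize_mu": mu, "standardize_sd": sd, **history})
    return net


def _is_dead(net: Network, X):
    """True when the penultimate activations vanish for every sample."""
    net.forward(X, record=True)
    hidden = net.inputs[-2]  # input to the output layer
    return not np.any(hidden)


def rank_features(network: Network, features, labels=None) -> lrp.RelevanceVector:
    """Aggregated, normalized relevance ranking over all input features.

    Per subject: propagate the case-class output activation back to the
    inputs, abs-normalize, then mean-aggregate across subjects. The result
    is non-negative and sums to 1.
    """
    features = np.asarray(features, dtype=float)
    mu = network.meta.get("standardize_mu", 0.0)
    sd = network.meta.get("standardize_sd", 1.0)
    X = ((features - mu) / sd)[:, None, :]
    scores = lrp.propagate_relevance_batch(network, X, TARGET_CLASS)
    if scores.shape[1] != features.shape[1]:
        raise ValueError("network input width does not match features")
    per_subject = []
    n_dead = 0
    for row in scores:
        if not np.any(row):
            # a subject whose activations die everywhere contributes no
            # attributable signal; skip rather than divide by zero
            n_dead += 1
            continue
        rv = lrp.RelevanceVector(scores=row, target_output=TARGET_CLASS)
        per_subject.append(lrp.normalize_relevance(rv))
    if n_dead:
        warnings.warn(
            f"{n_dead} subject(s) produced all-zero relevance and were "
            "excluded from aggregation", stacklevel=2,
        )
    if not per_subject:
        raise ValueError("all subjects produced zero relevance")
    return lrp.aggregate_relevance(per_subject, strategy="mean")


def select_features(relevance: lrp.RelevanceVector, rule) -> SelectionResult:
    """Apply a selection rule to a normalized relevance ranking.

    ``rule`` is ``("threshold", tau)`` (keep scores strictly above tau) or
    ``("top_k", k)`` (keep the k best). Ties break toward the lower feature
    index; rank order is preserved in the output.
    """
    if not relevance.normalized:
        raise ValueError("selection requires a normalized relevance vector")
    kind, value = rule
    scores = relevance.scores
    # stable sort on negated scores: descending score, ascending index ties
    ranked = np.argsort(-scores, kind="stable")
    if kind == "threshold":
        tau = float(value)
        if not 0.0 <= tau < 1.0:
            raise ValueError("threshold must lie in [0, 1)")
        selected = ranked[scores[ranked] > tau]
        label = f"threshold({tau})"
    elif kind == "top_k":
        k = int(value)
        if k <= 0:
            raise ValueError("top_k requires k >= 1")
        selected = ranked[: min(k, len(ranked))]
        label = f"top_k({k})"
    else:
        raise ValueError(f"unknown selection rule {kind!r}")
    if len(selected) == 0:
        warnings.warn("selection rule kept no features", stacklevel=2)
    return SelectionResult(
        modality="",
        ranked_indices=ranked,
        selected_indices=np.asarray(selected),
        rule=label,
        relevance=relevance,
    )


def apply_selection(features, selection: SelectionResult):
    """Column-subset a feature matrix to the selected indices (rank order)."""
    features = np.asarray(features)
    if len(selection.ranked_indices) != features.shape[1]:
        raise ValueError(
            f"selection covers {len(selection.ranked_indices)} features, "
            f"matrix has {features.shape[1]}"
        )
    if selection.n_selected == 0:
        warnings.warn("applying an empty selection yields a 0-width matrix",
                      stacklevel=2)
    return features[:, selection.selected_indices]
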