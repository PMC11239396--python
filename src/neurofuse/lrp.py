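"""Layer-wise relevance propagation (LRP) for feed-forward networks.

Implements the basic z-rule,

    R_l = sum_m  (z_lm / sum_l' z_l'm) * R_m,      z_lm = a_l * w_lm,

redistributing the output activation of a chosen class unit backwards
through dense, 1D-convolution, pooling, activation and flatten layers until
the input is reached. The rule conserves relevance layer by layer
(sum_l R_l = sum_m R_m): the fractions z_lm / sum z_lm sum to one for each
upstream neuron m, so the total entering a layer equals the total leaving
it, up to the numerical stabilizer added to near-zero denominators.

Bias terms absorb no relevance (z_lm excludes the bias), which keeps
conservation onto the input features exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .nn import Network

__all__ = [
    "RelevanceVector",
    "layer_relevance_step",
    "propagate_relevance",
    "propagate_relevance_batch",
    "normalize_relevance",
    "aggregate_relevance",
]

DEFAULT_STABILIZER = 1e-9


@dataclass(frozen=True)
class RelevanceVector:
    """Per-input-feature relevance scores for one propagated class unit."""

    scores: np.ndarray
    target_output: int
    normalized: bool = False
    stabilizer: float = DEFAULT_STABILIZER

    def __post_init__(self):
        object.__setattr__(self, "scores", np.asarray(self.scores, dtype=float))
        if self.normalized:
            total = self.scores.sum()
            if not np.isclose(total, 1.0, atol=1e-9) or (self.scores < 0).any():
                raise ValueError(
                    "normalized relevance must be non-negative and sum to 1"
                )


def _stabilize(denom, stabilizer):
    """Add a sign-matched epsilon so near-zero denominators stay finite."""
    if stabilizer < 0:
        raise ValueError("stabilizer must be non-negative")
    if stabilizer == 0.0 and np.any(denom == 0.0):
        raise FloatingPointError(
            "zero denominator in relevance propagation with zero stabilizer"
        )
    sign = np.where(denom >= 0, 1.0, -1.0)
    return denom + sign * stabilizer


def layer_relevance_step(
    input_activations, weights, bias, upstream_relevance, stabilizer=DEFAULT_STABILIZER
):
    """One dense-layer application of the z-rule.

    Parameters mirror a dense layer ``out = a @ W + b``; ``bias`` is accepted
    for interface completeness but contributes no relevance. Activations and
    relevance may carry a leading batch axis.
    """
    a = np.atleast_2d(np.asarray(input_activations, dtype=float))
    R = np.atleast_2d(np.asarray(upstream_relevance, dtype=float))
    W = np.asarray(weights, dtype=float)
    if a.shape[1] != W.shape[0] or R.shape[1] != W.shape[1]:
        raise ValueError("activation/weight/relevance shapes do not compose")
    denom = _stabilize(a @ W, stabilizer)
    out = a * ((R / denom) @ W.T)
    if np.asarray(input_activations).ndim == 1:
        return out[0]
    return out


def _relevance_dense(layer, R, stabilizer):
    a = layer.cache
    return layer_relevance_step(a, layer.params["W"], None, R, stabilizer)


def _relevance_conv1d(layer, R, stabilizer):
    x = layer.cache
    xs = layer._windows(x)
    W = layer.params["W"]
    denom = _stabilize(np.einsum("nckl,ock->nol", xs, W), stabilizer)
    S = R / denom
    out = np.zeros_like(x)
    lo = R.shape[-1]
    s = layer.stride
    for k in range(layer.kernel):
        out[:, :, k : k + lo * s : s] += np.einsum("nol,oc->ncl", S, W[:, :, k])
    return out * x


def _relevance_maxpool(layer, R, stabilizer):
    # winner-take-all: the maximal input in each window inherits everything
    x, argmax = layer.cache
    out = np.zeros_like(x)
    n, c, lo = R.shape
    pos = argmax + np.arange(lo)[None, None, :] * layer.stride
    np.add.at(
        out,
        (np.arange(n)[:, None, None], np.arange(c)[None, :, None], pos),
        R,
    )
    return out


def _relevance_avgpool(layer, R, stabilizer):
    # z-rule with uniform weights 1/k: split proportionally to activation
    x = layer.cache
    xs = layer._windows(x)
    denom = _stabilize(xs.sum(axis=2), stabilizer)
    S = R / denom
    out = np.zeros_like(x)
    lo = R.shape[-1]
    s = layer.stride
    for k in range(layer.kernel):
        out[:, :, k : k + lo * s : s] += S
    return out * x


def _relevance_layer(layer, R, stabilizer):
    if layer.kind == "dense":
        return _relevance_dense(layer, R, stabilizer)
    if layer.kind == "conv1d":
        return _relevance_conv1d(layer, R, stabilizer)
    if layer.kind == "activation":
        return R
    if layer.kind == "flatten":
        return R.reshape(layer.cache)
    if layer.kind == "pool":
        if layer.mode == "max":
            return _relevance_maxpool(layer, R, stabilizer)
        return _relevance_avgpool(layer, R, stabilizer)
    raise ValueError(f"no relevance rule for layer kind {layer.kind!r}")


def propagate_relevance_batch(
    network: Network, inputs, target_output, stabilizer=DEFAULT_STABILIZER
):
    """Propagate relevance for a batch of inputs; returns (n, features)."""
    inputs = np.asarray(inputs, dtype=float)
    logits = network.forward(inputs)
    if not 0 <= target_output < logits.shape[1]:
        raise ValueError(f"target_output {target_output} out of range")
    # seed relevance: the target unit's pre-softmax activation, others zero
    R = np.zeros_like(logits)
    R[:, target_output] = logits[:, target_output]
    for layer in reversed(network.layers):
        R = _relevance_layer(layer, R, stabilizer)
    return R.reshape(len(inputs), -1)


def propagate_relevance(
    network: Network, input_vector, target_output, stabilizer=DEFAULT_STABILIZER
):
    """Relevance scores of every input feature for one subject.

    A forward pass is run internally to record activations; relevance starts
    at the target class unit's pre-softmax activation and is propagated
    until the input layer is reached. Scores are returned un-normalized.
    """
    x = np.asarray(input_vector, dtype=float)
    scores = propagate_relevance_batch(
        network, x[None, ...], target_output, stabilizer
    )[0]
    return RelevanceVector(
        scores=scores,
        target_output=int(target_output),
        normalized=False,
        stabilizer=stabilizer,
    )


def normalize_relevance(rv: RelevanceVector, mode="abs") -> RelevanceVector:
    """Normalize so scores are non-negative and sum to one.

    ``abs`` (the only supported mode) takes absolute values before dividing
    by the total, so negatively-signed contributions still rank by strength.
    """
    if mode != "abs":
        raise ValueError(f"unknown normalization mode {mode!r}")
    total = np.abs(rv.scores).sum()
    if total == 0.0:
        raise ValueError("cannot normalize an all-zero relevance vector")
    return replace(rv, scores=np.abs(rv.scores) / total, normalized=True)


def aggregate_relevance(per_subject, strategy="mean") -> RelevanceVector:
    """Combine per-subject relevance vectors into one cohort-level ranking.

    ``mean`` averages feature-wise then re-normalizes; the result is
    invariant to subject order.
    """
    if strategy != "mean":
        raise ValueError(f"unknown aggregation strategy {strategy!r}")
    vectors = list(per_subject)
    if not vectors:
        raise ValueError("cannot aggregate an empty list of relevance vectors")
    lengths = {len(v.scores) for v in vectors}
    if len(lengths) != 1:
        raise ValueError("relevance vectors have mixed lengths")
    states = {v.normalized for v in vectors}
    if len(states) != 1:
        raise ValueError("relevance vectors have mixed normalization states")
    mean = np.mean([v.scores for v in vectors], axis=0)
    out = replace(vectors[0], scores=mean, normalized=False)
    if states.pop():
        out = normalize_relevance(out)
    return out
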