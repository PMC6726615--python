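"""Estimated model accuracy (EMA).

A small fully connected network predicts the TM-score of a model to its
(unknown) native structure from four features: target sequence length, the
effective sequence count of the alignment, and the sum and mean of
first-iteration distogram likelihoods read at the bins selected by the
model's own pairwise CB distances. The network has two 10-unit SELU hidden
layers and a 10-way softmax over TM-score ranges (0 <= s < 0.1, ...,
0.9 < s <= 1.0); the expected TM-score is the probability-weighted mean of
the range midpoints, and a model is called fold-correct when the expected
TM-score exceeds 0.5.

Everything here is plain NumPy: forward pass, cross-entropy training with
the adaptive-moment (Adam) optimizer at a maximum learning rate of 1e-3, and
repeated random-split evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .distogram import Distogram
from .structio import Model, cb_distance_matrix

N_CLASSES = 10
CLASS_MIDPOINTS = np.arange(N_CLASSES) / 10.0 + 0.05
FOLD_TM_THRESHOLD = 0.5


@dataclass
class EMAFeatures:
    length: int
    neff: float
    summed_likelihood: float
    mean_likelihood: float

    def as_array(self) -> np.ndarray:
        return np.array([self.length, self.neff, self.summed_likelihood,
                         self.mean_likelihood], dtype=float)


def ema_features(model: Model, first_iteration_distogram: Distogram,
                 neff: float, min_separation: int = 1) -> EMAFeatures:
    """Read, for every residue pair, the first-iteration likelihood of the
    bin containing the model's CB-CB distance; sum and average over pairs."""
    d = first_iteration_distogram
    if len(model) != d.length:
        raise ValueError("model length does not match distogram")
    L = len(model)
    dist = cb_distance_matrix(model)
    iu, ju = np.triu_indices(L, k=max(min_separation, 1))
    bins = d.scheme.bin_of(dist[iu, ju])
    lik = d.likelihoods[iu, ju, bins]
    return EMAFeatures(length=L, neff=float(neff),
                       summed_likelihood=float(lik.sum()),
                       mean_likelihood=float(lik.mean()))


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

_SELU_ALPHA = 1.6732632423543772
_SELU_SCALE = 1.0507009873554805


def _selu(x):
    return _SELU_SCALE * np.where(x > 0, x, _SELU_ALPHA * (np.exp(x) - 1.0))


def _selu_grad(x):
    return _SELU_SCALE * np.where(x > 0, 1.0, _SELU_ALPHA * np.exp(x))


@dataclass
class EMANetwork:
    """4 -> 10 -> 10 -> 10-softmax with SELU hidden activations and
    per-feature standardization."""

    feature_means: np.ndarray = field(
        default_factory=lambda: np.zeros(4))
    feature_stds: np.ndarray = field(
        default_factory=lambda: np.ones(4))
    w1: np.ndarray = field(default_factory=lambda: np.zeros((4, 10)))
    b1: np.ndarray = field(default_factory=lambda: np.zeros(10))
    w2: np.ndarray = field(default_factory=lambda: np.zeros((10, 10)))
    b2: np.ndarray = field(default_factory=lambda: np.zeros(10))
    w3: np.ndarray = field(default_factory=lambda: np.zeros((10, 10)))
    b3: np.ndarray = field(default_factory=lambda: np.zeros(10))

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feature_means) / self.feature_stds

    def destandardize(self, z: np.ndarray) -> np.ndarray:
        return z * self.feature_stds + self.feature_means

    # -- persistence --------------------------------------------------------

    def to_json(self) -> str:
        payload = {"format": "distfold-ema-v1"}
        for name in ("feature_means", "feature_stds",
                     "w1", "b1", "w2", "b2", "w3", "b3"):
            payload[name] = getattr(self, name).tolist()
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "EMANetwork":
        payload = json.loads(text)
        if payload.get("format") != "distfold-ema-v1":
            raise ValueError("not a distfold EMA weight file")
        kwargs = {k: np.array(payload[k]) for k in
                  ("feature_means", "feature_stds",
                   "w1", "b1", "w2", "b2", "w3", "b3")}
        return cls(**kwargs)


def _forward_full(net: EMANetwork, x: np.ndarray):
    z = (x - net.feature_means) / net.feature_stds
    a1 = z @ net.w1 + net.b1
    h1 = _selu(a1)
    a2 = h1 @ net.w2 + net.b2
    h2 = _selu(a2)
    logits = h2 @ net.w3 + net.b3
    logits = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=-1, keepdims=True)
    return probs, (z, a1, h1, a2, h2)


def ema_forward(net: EMANetwork, features) -> np.ndarray:
    """Class probabilities over the 10 TM-score ranges for one feature set
    (EMAFeatures or a 4-vector)."""
    x = features.as_array() if isinstance(features, EMAFeatures) \
        else np.asarray(features, dtype=float)
    probs, _ = _forward_full(net, x[None, :])
    return probs[0]


def expected_tm(probs: np.ndarray) -> float:
    """Probability-weighted mean of the TM-range midpoints 0.05 ... 0.95."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (N_CLASSES,):
        raise ValueError("need 10 class probabilities")
    if abs(probs.sum() - 1.0) > 1e-6 or np.any(probs < -1e-12):
        raise ValueError("probabilities must be normalized")
    return float(probs @ CLASS_MIDPOINTS)


def tm_class(tm: float) -> int:
    """Discretize an observed TM-score into its range index; the top class
    is closed above (0.9 < s <= 1.0)."""
    if not 0.0 <= tm <= 1.0:
        raise ValueError("TM-score must lie in [0, 1]")
    return min(int(tm * 10), N_CLASSES - 1)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _init_network(features: np.ndarray, rng: np.random.Generator) -> EMANetwork:
    means = features.mean(axis=0)
    stds = features.std(axis=0)
    stds[stds < 1e-9] = 1.0
    def glorot(n_in, n_out):
        s = np.sqrt(2.0 / (n_in + n_out))
        return rng.normal(0.0, s, (n_in, n_out))
    return EMANetwork(
        feature_means=means, feature_stds=stds,
        w1=glorot(4, 10), b1=np.zeros(10),
        w2=glorot(10, 10), b2=np.zeros(10),
        w3=glorot(10, 10), b3=np.zeros(10),
    )


def _train_once(x, y, net: EMANetwork, epochs: int, lr: float) -> None:
    """Full-batch cross-entropy training with Adam, in place."""
    params = ["w1", "b1", "w2", "b2", "w3", "b3"]
    m = {p: np.zeros_like(getattr(net, p)) for p in params}
    v = {p: np.zeros_like(getattr(net, p)) for p in params}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    onehot = np.eye(N_CLASSES)[y]
    t = 0
    for _ in range(epochs):
        probs, (z, a1, h1, a2, h2) = _forward_full(net, x)
        n = x.shape[0]
        dlogits = (probs - onehot) / n
        grads = {}
        grads["w3"] = h2.T @ dlogits
        grads["b3"] = dlogits.sum(axis=0)
        dh2 = dlogits @ net.w3.T
        da2 = dh2 * _selu_grad(a2)
        grads["w2"] = h1.T @ da2
        grads["b2"] = da2.sum(axis=0)
        dh1 = da2 @ net.w2.T
        da1 = dh1 * _selu_grad(a1)
        grads["w1"] = z.T @ da1
        grads["b1"] = da1.sum(axis=0)
        t += 1
        for p in params:
            g = grads[p]
            m[p] = beta1 * m[p] + (1 - beta1) * g
            v[p] = beta2 * v[p] + (1 - beta2) * g * g
            mh = m[p] / (1 - beta1 ** t)
            vh = v[p] / (1 - beta2 ** t)
            setattr(net, p, getattr(net, p) - lr * mh / (np.sqrt(vh) + eps))


def _loss(net, x, y):
    probs, _ = _forward_full(net, x)
    return float(-np.log(probs[np.arange(len(y)), y] + 1e-12).mean())


def train_ema(dataset, rng_seed: int = 0, repeats: int = 100,
              epochs: int = 300, lr: float = 1e-3,
              split=(0.7, 0.15, 0.15)) -> tuple[EMANetwork, dict]:
    """Train the EMA network on (features, observed TM) pairs.

    The observed TM-score is discretized into the 10 range classes and the
    network trained with cross-entropy and Adam (maximum learning rate
    ``lr``). Training is repeated over ``repeats`` random
    train/validation/test splits; the returned network is the one with the
    lowest validation loss, and the summary reports mean test
    precision/recall of the fold call (expected TM > 0.5 vs observed
    TM > 0.5) across the splits.

    ``dataset`` is a sequence of (EMAFeatures-or-4-vector, tm) pairs with at
    least 50 examples spanning more than one TM class.
    """
    feats = np.array([
        (f.as_array() if isinstance(f, EMAFeatures) else np.asarray(f, float))
        for f, _ in dataset])
    tms = np.array([t for _, t in dataset], dtype=float)
    if len(dataset) < 50:
        raise ValueError("dataset must hold at least 50 examples")
    y = np.array([tm_class(t) for t in tms])
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate dataset: every example in one TM class; "
                         "training refused")

    rng = np.random.default_rng(rng_seed)
    n = len(y)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    best_net = None
    best_val = np.inf
    precisions, recalls = [], []
    for _ in range(repeats):
        perm = rng.permutation(n)
        tr = perm[:n_train]
        va = perm[n_train:n_train + n_val]
        te = perm[n_train + n_val:]
        net = _init_network(feats[tr], rng)
        _train_once(feats[tr], y[tr], net, epochs, lr)
        val = _loss(net, feats[va], y[va]) if len(va) else _loss(
            net, feats[tr], y[tr])
        if val < best_val:
            best_val, best_net = val, net
        if len(te) == 0:
            continue
        probs, _ = _forward_full(net, feats[te])
        pred_tm = probs @ CLASS_MIDPOINTS
        pred_pos = pred_tm > FOLD_TM_THRESHOLD
        true_pos = tms[te] > FOLD_TM_THRESHOLD
        tp = int((pred_pos & true_pos).sum())
        if pred_pos.sum():
            precisions.append(tp / int(pred_pos.sum()))
        if true_pos.sum():
            recalls.append(tp / int(true_pos.sum()))

    summary = {
        "precision": float(np.mean(precisions)) if precisions else None,
        "recall": float(np.mean(recalls)) if recalls else None,
        "repeats": repeats,
        "n": n,
    }
    return best_net, summary
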