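"""Deep belief network classifier built from stacked RBMs.

A restricted Boltzmann machine (RBM) is a bipartite energy-based model
over binary visible units v (length m) and hidden units h (length n):

    E(v, h) = - sum_ij w_ij v_i h_j - sum_i a_i v_i - sum_j b_j h_j
    p(v, h) = exp(-E(v, h)) / R,   R = sum over all binary states

Bipartiteness factorises the conditionals into logistic units:
p(h_j=1 | v) = sigmoid(sum_i w_ij v_i + b_j) and symmetrically for the
visible side.  RBMs are trained by contrastive divergence (CD-k):
the positive-phase statistic <v h>_data uses the data-driven hidden
probabilities; the negative phase reconstructs after k alternating Gibbs
steps (hidden states sampled, visible mean-field, final statistics from
probabilities) and parameters move along the difference scaled by
learning_rate / batch_size.

The DBN stacks RBMs greedily — each layer is pretrained on the previous
layer's hidden probabilities — then a softmax output layer is appended
and the whole stack is fine-tuned by backpropagation on cross-entropy.
Real-valued features are min-max scaled to [0, 1] upstream and used as
visible probabilities (no Gaussian visible units).

The enumeration routines (:func:`joint_probability`,
:func:`marginal_visible`, :func:`exact_log_likelihood`) are exact but
exponential in m + n; they exist for small-model verification and refuse
models beyond m + n = 20.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RBM",
    "TrainConfig",
    "DBNClassifier",
    "energy",
    "joint_probability",
    "marginal_visible",
    "hidden_conditional",
    "visible_conditional",
    "cd_update",
    "exact_log_likelihood",
    "train_dbn",
    "predict",
    "predict_proba",
    "save_dbn",
    "load_dbn",
]

_ENUM_LIMIT = 20  # max m + n for exhaustive enumeration


def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic 1 / (1 + exp(-x))
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class RBM:
    """Weights and biases of one restricted Boltzmann machine.

    ``weights[i, j]`` links visible unit i to hidden unit j;
    ``visible_bias`` has length m, ``hidden_bias`` length n.
    """

    weights: np.ndarray
    visible_bias: np.ndarray
    hidden_bias: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.visible_bias = np.asarray(self.visible_bias, dtype=float)
        self.hidden_bias = np.asarray(self.hidden_bias, dtype=float)
        if self.weights.ndim != 2:
            raise ValueError("weights must be a 2-D matrix")
        m, n = self.weights.shape
        if self.visible_bias.shape != (m,):
            raise ValueError("visible_bias length must match weights rows")
        if self.hidden_bias.shape != (n,):
            raise ValueError("hidden_bias length must match weights columns")
        if not (
            np.all(np.isfinite(self.weights))
            and np.all(np.isfinite(self.visible_bias))
            and np.all(np.isfinite(self.hidden_bias))
        ):
            raise ValueError("RBM parameters must be finite")

    @property
    def m(self) -> int:
        return self.weights.shape[0]

    @property
    def n(self) -> int:
        return self.weights.shape[1]

    @classmethod
    def initialise(cls, m: int, n: int, rng: np.random.Generator) -> "RBM":
        """Gaussian(0, 0.01^2) weights, zero biases."""
        return cls(
            weights=rng.normal(0.0, 0.01, size=(m, n)),
            visible_bias=np.zeros(m),
            hidden_bias=np.zeros(n),
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters shared by CD pretraining and fine-tuning."""

    learning_rate: float = 0.3
    batch_size: int = 16
    cd_steps: int = 1
    epochs_pretrain: int = 50
    epochs_finetune: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.cd_steps < 1:
            raise ValueError("cd_steps must be >= 1")
        if self.epochs_pretrain < 1:
            raise ValueError("epochs_pretrain must be >= 1")
        if self.epochs_finetune < 0:
            raise ValueError("epochs_finetune must be >= 0")


def energy(rbm: RBM, v: np.ndarray, h: np.ndarray) -> float:
    """E(v, h) for one joint configuration."""
    v = np.asarray(v, dtype=float)
    h = np.asarray(h, dtype=float)
    if v.shape != (rbm.m,) or h.shape != (rbm.n,):
        raise ValueError(
            f"state shapes {v.shape}/{h.shape} do not match RBM ({rbm.m}, {rbm.n})"
        )
    return float(-(v @ rbm.weights @ h) - rbm.visible_bias @ v - rbm.hidden_bias @ h)


def _check_enumerable(rbm: RBM) -> None:
    if rbm.m + rbm.n > _ENUM_LIMIT:
        raise ValueError(
            f"enumeration over 2^{rbm.m + rbm.n} states refused (limit m+n <= {_ENUM_LIMIT})"
        )


def _all_states(k: int) -> np.ndarray:
    return np.array(list(itertools.product((0.0, 1.0), repeat=k)))


def partition_function(rbm: RBM) -> float:
    """Normalisation constant R by exhaustive enumeration (small models)."""
    _check_enumerable(rbm)
    total = 0.0
    for v in _all_states(rbm.m):
        for h in _all_states(rbm.n):
            total += np.exp(-energy(rbm, v, h))
    return total


def joint_probability(rbm: RBM, v: np.ndarray, h: np.ndarray) -> float:
    """p(v, h) = exp(-E) / R via exhaustive enumeration."""
    _check_enumerable(rbm)
    return float(np.exp(-energy(rbm, v, h)) / partition_function(rbm))


def marginal_visible(rbm: RBM, v: np.ndarray) -> float:
    """p(v) = sum_h p(v, h) via exhaustive enumeration."""
    _check_enumerable(rbm)
    r = partition_function(rbm)
    return float(
        sum(np.exp(-energy(rbm, np.asarray(v, float), h)) for h in _all_states(rbm.n)) / r
    )


def hidden_conditional(rbm: RBM, v: np.ndarray) -> np.ndarray:
    """p(h_j = 1 | v) for each hidden unit; accepts [0,1] mean-field input."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    if v.shape[1] != rbm.m:
        raise ValueError(f"visible length {v.shape[1]} != m={rbm.m}")
    out = _sigmoid(v @ rbm.weights + rbm.hidden_bias)
    return out[0] if out.shape[0] == 1 else out


def visible_conditional(rbm: RBM, h: np.ndarray) -> np.ndarray:
    """p(v_i = 1 | h) for each visible unit."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    if h.shape[1] != rbm.n:
        raise ValueError(f"hidden length {h.shape[1]} != n={rbm.n}")
    out = _sigmoid(h @ rbm.weights.T + rbm.visible_bias)
    return out[0] if out.shape[0] == 1 else out


def cd_update(
    rbm: RBM,
    batch: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> RBM:
    """One CD-k parameter update from a batch of visible rows in [0, 1].

    Returns a new RBM; the input model is not mutated.  Hidden states are
    sampled in the Gibbs chain, visible reconstructions stay mean-field,
    and the final negative-phase statistics use probabilities.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.size == 0:
        raise ValueError("empty batch")
    if batch.shape[1] != rbm.m:
        raise ValueError(f"batch width {batch.shape[1]} != m={rbm.m}")
    beta = batch.shape[0]
    scale = config.learning_rate / beta

    h_data = _sigmoid(batch @ rbm.weights + rbm.hidden_bias)
    pos_w = batch.T @ h_data

    h_state = (rng.random(h_data.shape) < h_data).astype(float)
    v_model = batch
    h_model = h_data
    for _ in range(config.cd_steps):
        v_model = _sigmoid(h_state @ rbm.weights.T + rbm.visible_bias)
        h_model = _sigmoid(v_model @ rbm.weights + rbm.hidden_bias)
        h_state = (rng.random(h_model.shape) < h_model).astype(float)
    neg_w = v_model.T @ h_model

    return RBM(
        weights=rbm.weights + scale * (pos_w - neg_w),
        visible_bias=rbm.visible_bias + scale * (batch.sum(0) - v_model.sum(0)),
        hidden_bias=rbm.hidden_bias + scale * (h_data.sum(0) - h_model.sum(0)),
    )


def exact_log_likelihood(rbm: RBM, data: np.ndarray) -> float:
    """Mean log p(v) over data rows, by enumeration (small models only)."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return float(np.mean([np.log(marginal_visible(rbm, v)) for v in data]))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class DBNClassifier:
    """Deep belief network classifier (sklearn estimator interface).

    Parameters
    ----------
    hidden_layer_sizes : tuple of int
        Hidden width of each stacked RBM; two layers by default.
    learning_rate, batch_size, cd_steps, epochs_pretrain, epochs_finetune
        See :class:`TrainConfig`.  ``epochs_finetune=0`` leaves the softmax
        output layer at its random initialisation (prediction near chance).
    random_state : int
        Seeds weight initialisation, Gibbs sampling and batch shuffling;
        identical inputs and seed give bitwise-identical parameters.

    Fitted attributes: ``rbms_``, ``output_weights_``, ``output_bias_``,
    ``classes_``.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (64, 32),
        learning_rate: float = 0.3,
        batch_size: int = 16,
        cd_steps: int = 1,
        epochs_pretrain: int = 50,
        epochs_finetune: int = 50,
        random_state: int = 0,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.cd_steps = cd_steps
        self.epochs_pretrain = epochs_pretrain
        self.epochs_finetune = epochs_finetune
        self.random_state = random_state

    # -- sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "hidden_layer_sizes": self.hidden_layer_sizes,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "cd_steps": self.cd_steps,
            "epochs_pretrain": self.epochs_pretrain,
            "epochs_finetune": self.epochs_finetune,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "DBNClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def _config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            cd_steps=self.cd_steps,
            epochs_pretrain=self.epochs_pretrain,
            epochs_finetune=self.epochs_finetune,
            seed=self.random_state,
        )

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y) -> "DBNClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if np.min(X) < -1e-9 or np.max(X) > 1 + 1e-9:
            raise ValueError("features must be min-max scaled to [0, 1]")
        self.classes_ = np.array(sorted(set(y.tolist())))
        if self.classes_.size < 2:
            raise ValueError("training data must contain at least two classes")
        counts = [(y == c).sum() for c in self.classes_]
        if min(counts) < 2:
            raise ValueError("each class needs at least two training samples")

        config = self._config()
        rng = np.random.default_rng(config.seed)

        # greedy layer-wise CD pretraining
        self.rbms_ = []
        layer_input = np.clip(X, 0.0, 1.0)
        for width in self.hidden_layer_sizes:
            rbm = RBM.initialise(layer_input.shape[1], int(width), rng)
            for _ in range(config.epochs_pretrain):
                order = rng.permutation(layer_input.shape[0])
                for start in range(0, order.size, config.batch_size):
                    batch = layer_input[order[start : start + config.batch_size]]
                    rbm = cd_update(rbm, batch, config, rng)
            self.rbms_.append(rbm)
            layer_input = hidden_conditional(rbm, layer_input)
            layer_input = np.atleast_2d(layer_input)

        # softmax output layer + backpropagation fine-tuning
        n_classes = self.classes_.size
        top = self.hidden_layer_sizes[-1] if self.hidden_layer_sizes else X.shape[1]
        self.output_weights_ = rng.normal(0.0, 0.01, size=(int(top), n_classes))
        self.output_bias_ = np.zeros(n_classes)
        onehot = (y[:, None] == self.classes_[None, :]).astype(float)
        for _ in range(config.epochs_finetune):
            order = rng.permutation(X.shape[0])
            for start in range(0, order.size, config.batch_size):
                idx = order[start : start + config.batch_size]
                self._backprop_batch(X[idx], onehot[idx], config.learning_rate)
        return self

    def _forward(self, X: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        activations = [np.clip(np.asarray(X, dtype=float), 0.0, 1.0)]
        for rbm in self.rbms_:
            activations.append(np.atleast_2d(hidden_conditional(rbm, activations[-1])))
        logits = activations[-1] @ self.output_weights_ + self.output_bias_
        return activations, logits

    def _backprop_batch(self, Xb: np.ndarray, Tb: np.ndarray, lr: float) -> None:
        acts, logits = self._forward(Xb)
        probs = _softmax(logits)
        beta = Xb.shape[0]
        delta = (probs - Tb) / beta  # dL/dlogits, mean cross-entropy
        grad_w = acts[-1].T @ delta
        self.output_weights_ -= lr * grad_w
        self.output_bias_ -= lr * delta.sum(0)
        upstream = delta @ self.output_weights_.T
        for k in range(len(self.rbms_) - 1, -1, -1):
            a = acts[k + 1]
            local = upstream * a * (1.0 - a)  # sigmoid derivative
            rbm = self.rbms_[k]
            rbm.weights = rbm.weights - lr * acts[k].T @ local
            rbm.hidden_bias = rbm.hidden_bias - lr * local.sum(0)
            upstream = local @ rbm.weights.T

    # -- inference ---------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "rbms_"):
            raise RuntimeError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.rbms_ and X.shape[1] != self.rbms_[0].m:
            raise ValueError(f"feature width {X.shape[1]} != {self.rbms_[0].m}")
        _, logits = self._forward(X)
        return _softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        probs = self.predict_proba(X)
        # argmax returns the first (lexicographically smallest label) on ties
        return self.classes_[np.argmax(probs, axis=1)]

    def score(self, X: np.ndarray, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# -- functional wrappers ---------------------------------------------------

def train_dbn(
    features: np.ndarray,
    labels,
    arch: tuple[int, ...] = (64, 32),
    config: TrainConfig | None = None,
) -> DBNClassifier:
    """Train a DBN on [0,1]-scaled features; thin wrapper over the estimator."""
    config = config or TrainConfig()
    clf = DBNClassifier(
        hidden_layer_sizes=tuple(int(w) for w in arch),
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        cd_steps=config.cd_steps,
        epochs_pretrain=config.epochs_pretrain,
        epochs_finetune=config.epochs_finetune,
        random_state=config.seed,
    )
    return clf.fit(features, labels)


def predict_proba(model: DBNClassifier, features: np.ndarray) -> np.ndarray:
    return model.predict_proba(features)


def predict(model: DBNClassifier, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


# -- serialization ---------------------------------------------------------

def save_dbn(model: DBNClassifier, path) -> None:
    """Serialise a fitted DBN to one JSON file (bitwise round-trip stable)."""
    payload = {
        "params": {
            **model.get_params(),
            "hidden_layer_sizes": list(model.hidden_layer_sizes),
        },
        "classes": [
            c.item() if hasattr(c, "item") else c for c in model.classes_
        ],
        "rbms": [
            {
                "weights": rbm.weights.tolist(),
                "visible_bias": rbm.visible_bias.tolist(),
                "hidden_bias": rbm.hidden_bias.tolist(),
            }
            for rbm in model.rbms_
        ],
        "output_weights": model.output_weights_.tolist(),
        "output_bias": model.output_bias_.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_dbn(path) -> DBNClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    params = dict(payload["params"])
    params["hidden_layer_sizes"] = tuple(params["hidden_layer_sizes"])
    model = DBNClassifier(**params)
    model.classes_ = np.array(payload["classes"])
    model.rbms_ = [
        RBM(
            weights=np.array(r["weights"], dtype=float),
            visible_bias=np.array(r["visible_bias"], dtype=float),
            hidden_bias=np.array(r["hidden_bias"], dtype=float),
        )
        for r in payload["rbms"]
    ]
    model.output_weights_ = np.array(payload["output_weights"], dtype=float)
    model.output_bias_ = np.array(payload["output_bias"], dtype=float)
    return model
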