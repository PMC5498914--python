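"""The three classifiers: Fisher's linear discriminant (FLDA), random
forest (RF), and a deep feedforward network (DL).

All three share one contract: ``fit(dataset)`` then
``predict(features) -> Prediction`` with ``score`` the probability (or
vote fraction) of the positive class (case) and ``label`` thresholded at
0.5, ties resolved to the negative class (control) — the discriminant
convention that a non-negative decision value means normal. Everything
is seed-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .dataset import LabelledDataset
from .records import ValidationError

__all__ = [
    "Prediction",
    "FldaModel", "flda_fit",
    "RfModel", "rf_fit", "rf_predict",
    "DlConfig", "DlModel", "dl_fit", "dl_predict",
    "make_model",
]


class TrainingError(RuntimeError):
    """Optimisation failed (non-finite loss, singular scatter, ...)."""


@dataclass(frozen=True)
class Prediction:
    """Scores in [0, 1] (probability of case) and hard labels
    (1 = case iff score > 0.5; a tied score falls to control)."""

    score: np.ndarray
    label: np.ndarray


def _scores_to_prediction(score: np.ndarray) -> Prediction:
    score = np.asarray(score, dtype=float)
    return Prediction(score=score, label=(score > 0.5).astype(int))


# ---------------------------------------------------------------------------
# Fisher's linear discriminant
# ---------------------------------------------------------------------------

@dataclass
class FldaModel:
    """f(x) = w.x + bias with w ∝ S_W^{-1}(mu_control - mu_case); f >= 0
    classifies control, f < 0 case. ``s_w``/``s_b`` are the within- and
    between-class scatter matrices; the bias puts the projected midpoint
    of the class means at zero."""

    w: np.ndarray
    bias: float
    class_means: dict
    s_w: np.ndarray
    s_b: np.ndarray
    feature_names: tuple

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        return np.asarray(features, float) @ self.w + self.bias

    def predict(self, features: np.ndarray) -> Prediction:
        f = self.decision_values(features)
        # logistic link for a monotone ROC score only; the decision rule
        # itself is the sign of f
        return _scores_to_prediction(1.0 / (1.0 + np.exp(np.clip(f, -500, 500))))

    def fit(self, data: LabelledDataset) -> "FldaModel":  # uniform contract
        fitted = flda_fit(data)
        self.__dict__.update(fitted.__dict__)
        return self


def flda_fit(data: LabelledDataset, ridge: float | None = None) -> FldaModel:
    """Fit FLDA. A singular within-class scatter is regularised with a
    small ridge (lambda = 1e-6 * trace(S_W)/d by default)."""
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present to fit FLDA")
    x = data.features
    mu = {c: x[y == c].mean(axis=0) for c in (0, 1)}
    overall = x.mean(axis=0)
    d = x.shape[1]
    s_w = np.zeros((d, d))
    s_b = np.zeros((d, d))
    for c in (0, 1):
        xc = x[y == c] - mu[c]
        s_w += xc.T @ xc
        diff = (mu[c] - overall)[:, None]
        s_b += (y == c).sum() * (diff @ diff.T)
    delta = mu[0] - mu[1]  # control minus case
    if ridge is not None:
        lam = ridge
    else:
        lam = 1e-6 * np.trace(s_w) / d
        if lam <= 0.0:  # degenerate scatter (e.g. constant features)
            lam = 1e-8
    try:
        w = np.linalg.solve(s_w + lam * np.eye(d), delta)
    except np.linalg.LinAlgError as exc:
        raise TrainingError(
            "within-class scatter is singular; increase the ridge parameter"
        ) from exc
    bias = -0.5 * float(w @ (mu[0] + mu[1]))
    return FldaModel(w=w, bias=bias, class_means=mu, s_w=s_w, s_b=s_b,
                     feature_names=data.feature_names)


# ---------------------------------------------------------------------------
# Random forest
# ---------------------------------------------------------------------------

@dataclass
class RfModel:
    """Bagged unpruned decision trees with m features sampled per split;
    the score is the fraction of trees voting case and prediction is the
    majority vote (tie -> control).

    The trees themselves are grown by scikit-learn; this class pins down
    the voting and tie conventions and the uniform fit/predict contract.
    """

    n_trees: int = 500
    m_features: int | None = None     # default floor(sqrt(n_features))
    seed: int = 0
    estimator: RandomForestClassifier | None = None
    feature_names: tuple | None = None

    def fit(self, data: LabelledDataset) -> "RfModel":
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        n_feat = data.features.shape[1]
        m = self.m_features if self.m_features is not None else max(1, int(np.sqrt(n_feat)))
        if not (1 <= m <= n_feat):
            raise ValidationError(f"m_features={m} outside [1, {n_feat}]")
        self.estimator = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=m,
            criterion="gini",
            bootstrap=True,
            random_state=self.seed,
        )
        self.estimator.fit(data.features, data.labels)
        self.feature_names = data.feature_names
        return self

    def vote_fraction(self, features: np.ndarray) -> np.ndarray:
        """Fraction of trees voting case. With a single-class training set
        sklearn fits constant trees, so this degrades to the constant model."""
        if self.estimator is None:
            raise ValidationError("model not fitted")
        x = np.asarray(features, float)
        classes = self.estimator.classes_
        votes = np.zeros(x.shape[0])
        for tree in self.estimator.estimators_:
            leaf_class = classes[np.argmax(tree.predict_proba(x), axis=1)]
            votes += leaf_class == 1
        return votes / len(self.estimator.estimators_)

    def predict(self, features: np.ndarray) -> Prediction:
        return _scores_to_prediction(self.vote_fraction(features))

    @property
    def feature_importances(self) -> np.ndarray:
        if self.estimator is None:
            raise ValidationError("model not fitted")
        return self.estimator.feature_importances_


def rf_fit(data: LabelledDataset, n_trees: int = 500, m_features: int | None = None,
           seed: int = 0) -> RfModel:
    return RfModel(n_trees=n_trees, m_features=m_features, seed=seed).fit(data)


def rf_predict(model: RfModel, features: np.ndarray) -> Prediction:
    return model.predict(features)


# ---------------------------------------------------------------------------
# Deep feedforward network
# ---------------------------------------------------------------------------

@dataclass
class DlConfig:
    """Feedforward net hyperparameters.

    tanh hidden units, 2-way softmax output, cross-entropy loss, SGD with
    momentum velocity updates and learning-rate annealing
    alpha_t = alpha0 / (1 + t * anneal_rate), inverted dropout during
    training only (input probability < 0.2, hidden <= 0.5), and uniform
    fan-scaled initialisation U(+-sqrt(6 / (fan_in + fan_out))).
    """

    hidden_layers: tuple = (32, 32)
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 0.05
    anneal_rate: float = 1e-6
    momentum: float = 0.9
    dropout_input: float = 0.1
    dropout_hidden: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if not (0.0 <= self.dropout_input < 0.2):
            raise ValidationError("input dropout must be in [0, 0.2)")
        if not (0.0 <= self.dropout_hidden <= 0.5):
            raise ValidationError("hidden dropout must be in [0, 0.5]")


@dataclass
class DlModel:
    config: DlConfig
    weights: list = field(default_factory=list)   # W_i: (fan_in, fan_out)
    biases: list = field(default_factory=list)
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None
    loss_history: list = field(default_factory=list)
    feature_names: tuple | None = None

    # -- forward ----------------------------------------------------------
    def _forward(self, x: np.ndarray, rng: np.random.Generator | None = None):
        """One pass through the net.

        Returns ``(layer_inputs, output, derivs)``: the (post-dropout)
        input to each weight layer, the softmax output, and per hidden
        layer d(activation)/d(logit) — ``(1 - tanh^2) * scaled_mask`` so
        inverted-dropout training backpropagates correctly. Dropout is
        active only when an rng is given (training mode).
        """
        cfg = self.config
        h = x
        if rng is not None and cfg.dropout_input > 0:
            mask = (rng.random(h.shape) >= cfg.dropout_input) / (1.0 - cfg.dropout_input)
            h = h * mask
        layer_inputs, derivs = [h], []
        last = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ w + b
            if i < last:
                th = np.tanh(z)
                deriv = 1.0 - th ** 2
                if rng is not None and cfg.dropout_hidden > 0:
                    mask = (rng.random(th.shape) >= cfg.dropout_hidden) / (1.0 - cfg.dropout_hidden)
                    th = th * mask
                    deriv = deriv * mask
                h = th
                derivs.append(deriv)
                layer_inputs.append(h)
            else:
                z = z - z.max(axis=1, keepdims=True)
                e = np.exp(z)
                h = e / e.sum(axis=1, keepdims=True)
        return layer_inputs, h, derivs

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        x = (np.asarray(features, float) - self.scaler_mean) / self.scaler_sd
        return self._forward(x)[1]

    def predict(self, features: np.ndarray) -> Prediction:
        return _scores_to_prediction(self.predict_proba(features)[:, 1])

    def fit(self, data: LabelledDataset) -> "DlModel":
        return dl_fit(data, self.config, into=self)


def dl_loss(output: np.ndarray, target_onehot: np.ndarray) -> float:
    """Mean over examples of the two-term cross-entropy
    -sum_y [t ln O + (1 - t) ln(1 - O)] against the softmax output."""
    o = np.clip(output, 1e-12, 1.0 - 1e-12)
    per_example = -np.sum(
        target_onehot * np.log(o) + (1.0 - target_onehot) * np.log(1.0 - o), axis=1
    )
    return float(np.mean(per_example))


def _loss_grad_wrt_logits(o: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Gradient of the mean two-term cross-entropy w.r.t. the softmax
    logits, via the softmax Jacobian (diag(o) - o o^T) per example."""
    oc = np.clip(o, 1e-12, 1.0 - 1e-12)
    dl_do = -(t / oc - (1.0 - t) / (1.0 - oc))          # (n, K)
    s = np.sum(dl_do * o, axis=1, keepdims=True)
    return (dl_do - s) * o / o.shape[0]


def dl_fit(data: LabelledDataset, config: DlConfig | None = None,
           into: DlModel | None = None) -> DlModel:
    """Train the network by minibatch SGD with momentum and annealing.
    Features are standardised at fit time and the scaler is stored in the
    model. Deterministic given ``config.seed``; with zero dropout, equal
    seeds give identical per-epoch losses."""
    cfg = config or DlConfig()
    cfg.validate()
    model = into or DlModel(config=cfg)
    model.config = cfg
    rng = np.random.default_rng(cfg.seed)

    x = data.features
    model.scaler_mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0.0] = 1.0
    model.scaler_sd = sd
    xs = (x - model.scaler_mean) / sd
    y = data.labels
    t = np.eye(2)[y]

    sizes = [xs.shape[1], *cfg.hidden_layers, 2]
    model.weights = []
    model.biases = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        model.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        model.biases.append(np.zeros(fan_out))
    vel_w = [np.zeros_like(w) for w in model.weights]
    vel_b = [np.zeros_like(b) for b in model.biases]

    model.loss_history = []
    model.feature_names = data.feature_names
    n = xs.shape[0]
    step = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb, tb = xs[idx], t[idx]
            train_rng = rng if (cfg.dropout_input > 0 or cfg.dropout_hidden > 0) else None
            layer_inputs, output, derivs = model._forward(xb, rng=train_rng)
            delta = _loss_grad_wrt_logits(output, tb)   # d loss / d logits
            alpha = cfg.learning_rate / (1.0 + step * cfg.anneal_rate)
            grads_w, grads_b = [], []
            for layer in range(len(model.weights) - 1, -1, -1):
                grads_w.append(layer_inputs[layer].T @ delta)
                grads_b.append(delta.sum(axis=0))
                if layer > 0:
                    delta = (delta @ model.weights[layer].T) * derivs[layer - 1]
            grads_w.reverse()
            grads_b.reverse()
            for layer in range(len(model.weights)):
                vel_w[layer] = cfg.momentum * vel_w[layer] - alpha * grads_w[layer]
                vel_b[layer] = cfg.momentum * vel_b[layer] - alpha * grads_b[layer]
                model.weights[layer] += vel_w[layer]
                model.biases[layer] += vel_b[layer]
            step += 1
        epoch_loss = dl_loss(model._forward(xs)[1], t)
        diverged = not np.isfinite(epoch_loss) or any(
            not np.isfinite(w).all() for w in model.weights
        )
        if diverged:
            raise TrainingError(
                f"training diverged at step {step} (non-finite loss or weights); "
                "reduce the learning rate"
            )
        model.loss_history.append(epoch_loss)
    return model


def dl_predict(model: DlModel, features: np.ndarray) -> Prediction:
    return model.predict(features)


# ---------------------------------------------------------------------------
# Factory used by evaluation / pipeline
# ---------------------------------------------------------------------------

def make_model(kind: str, seed: int = 0, **params):
    """Fresh unfitted model of the given kind ('flda' | 'rf' | 'dl')."""
    if kind == "flda":
        return FldaModel(w=np.empty(0), bias=0.0, class_means={},
                         s_w=np.empty((0, 0)), s_b=np.empty((0, 0)), feature_names=())
    if kind == "rf":
        return RfModel(seed=seed, **params)
    if kind == "dl":
        return DlModel(config=DlConfig(seed=seed, **params))
    raise ValidationError(f"unknown model kind {kind!r}")
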