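"""Feed-forward networks with a Cox proportional-hazards output layer.

The model maps standardized features through H fully connected hidden layers
(ReLU or tanh, optional inverted dropout during training) into a linear Cox
output layer: the predicted risk is the linear score X_i beta of the final
hidden activations, with no exponential applied.  Training minimizes the
negative log partial likelihood

    l(beta, X) = - sum_{i in U} ( X_i beta - log sum_{j in R_i} exp(X_j beta) )

where U is the set of uncensored patients and R_i = {j : Y_j >= Y_i} is the
risk set (Breslow handling of tied times).  The loss gradient with respect to
the per-patient scores has the closed form

    dl/ds_i = -( c_i - sum_{j in U, i in R_j} exp(s_i) / sum_{k in R_j} exp(s_k) )

with c_i the event indicator; it is backpropagated through the hidden layers
by the chain rule.  Optimization is full-batch gradient descent with a
backtracking (Armijo) line search, one update per epoch — mini-batching is
exposed as an option but the partial likelihood couples patients through the
risk sets, so full batches are the default.
"""

from __future__ import annotations

import base64
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .data import SurvivalDataset

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "DeepSurvivalModel",
    "neg_log_partial_likelihood",
    "loss_gradient_wrt_risk",
    "forward",
    "train",
    "predict_risk",
]


# ---------------------------------------------------------------------------
# Cox partial likelihood


def _risk_set_terms(risk, times, events):
    """Sorted-order quantities shared by the loss and its gradient.

    Returns (order, s, e_scaled, denom, group_start, group_end) where patients
    are sorted by ascending time, ``denom[i]`` is sum of exp(s_j - m) over the
    risk set of patient i (all j with t_j >= t_i, ties included), and
    group_start/group_end delimit i's tie group in sorted order.
    """
    risk = np.asarray(risk, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if not np.all(np.isfinite(risk)):
        raise ValueError("risk scores contain NaN or Inf")
    if not np.any(events == 1.0):
        raise ValueError("no uncensored samples")

    order = np.argsort(times, kind="stable")
    t = times[order]
    s = risk[order]
    m = s.max()
    es = np.exp(s - m)
    suffix = np.cumsum(es[::-1])[::-1]  # suffix[i] = sum_{j>=i} es[j]

    n = len(t)
    # first/last sorted position of each tie group
    new_group = np.empty(n, dtype=bool)
    new_group[0] = True
    new_group[1:] = t[1:] != t[:-1]
    group_id = np.cumsum(new_group) - 1
    starts = np.flatnonzero(new_group)
    ends = np.append(starts[1:], n) - 1
    group_start = starts[group_id]
    group_end = ends[group_id]

    denom = suffix[group_start]  # risk set includes the whole tie group
    return order, s, events[order], es, denom, group_start, group_end, m


def neg_log_partial_likelihood(risk, times, events) -> float:
    """Negative log Cox partial likelihood of per-patient risk scores.

    Breslow convention for tied event times; the log-sum-exp over each risk
    set is computed stably by subtracting the maximum score.  Invariant to
    adding a constant to all scores.
    """
    order, s, e, es, denom, gs, ge, m = _risk_set_terms(risk, times, events)
    ev = e == 1.0
    with np.errstate(divide="ignore"):
        # denom can underflow for extreme score spreads; the resulting inf
        # loss is rejected by the line search rather than silently clipped
        return float(np.sum(np.log(denom[ev]) + m - s[ev]))


def loss_gradient_wrt_risk(risk, times, events) -> np.ndarray:
    """Analytic gradient of :func:`neg_log_partial_likelihood` wrt the scores.

    Component i is ``-(c_i - sum_{j in U, i in R_j} exp(s_i)/sum_{k in R_j}
    exp(s_k))``; matches central finite differences of the loss to high
    relative accuracy.  Components sum to zero.
    """
    order, s, e, es, denom, gs, ge, m = _risk_set_terms(risk, times, events)
    n = len(s)
    # prefix over events of 1/denom_j, for all events j with t_j <= t_i:
    # i is in R_j iff t_i >= t_j, so include i's entire tie group.
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        inv = np.where(e == 1.0, 1.0 / denom, 0.0)
        cum = np.cumsum(inv)
        cum_through_group = cum[ge]
        g_sorted = -(e - es * cum_through_group)
    if not np.all(np.isfinite(g_sorted)):
        raise FloatingPointError("partial-likelihood gradient overflowed; "
                                 "risk scores too extreme")
    g = np.empty(n)
    g[order] = g_sorted
    return g


# ---------------------------------------------------------------------------
# Network configuration and model


@dataclass
class LineSearch:
    """Backtracking (Armijo) line-search parameters."""

    initial_step: float = 1.0
    shrink: float = 0.5
    sufficient_decrease: float = 1e-4
    max_shrinks: int = 50
    adaptive: bool = True  # warm-start the next epoch at 2x the accepted step


@dataclass
class NetworkConfig:
    """One concrete network design.

    ``n_hidden_layers`` 0 is the plain linear Cox model (used internally for
    recovery oracles); hyperparameter search produces 1-5 layers, widths
    10-1000, dropout 0-0.9, and ReLU or tanh activations.
    """

    n_hidden_layers: int = 1
    layer_width: int = 50
    activation: str = "relu"
    dropout_frac: float = 0.0
    max_epochs: int = 500
    init_seed: int = 0
    dropout_seed: int = 0
    line_search: LineSearch = field(default_factory=LineSearch)
    rel_tol: float = 1e-6
    patience: int = 10
    batch_size: int | None = None  # None = single full batch (default)
    dropconnect: bool = False  # drop weights instead of units

    def __post_init__(self):
        if self.activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if not 0 <= self.n_hidden_layers:
            raise ValueError("n_hidden_layers must be >= 0")
        if not 0.0 <= self.dropout_frac <= 0.9:
            raise ValueError("dropout_frac must be in [0, 0.9]")
        if self.n_hidden_layers > 0 and self.layer_width < 1:
            raise ValueError("layer_width must be >= 1")
        if isinstance(self.line_search, dict):
            self.line_search = LineSearch(**self.line_search)


def _activation(name):
    if name == "relu":
        return lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)
    # subgradient 0 at exactly 0 for relu; tanh' = 1 - tanh^2
    return np.tanh, lambda z: 1.0 - np.tanh(z) ** 2


@dataclass
class DeepSurvivalModel:
    """Trained weights of a deep Cox network.

    ``weights[h]``/``biases[h]`` parameterize hidden layer h; ``beta`` is the
    Cox output-layer coefficient vector acting on the final hidden
    activations (or directly on the inputs when there are no hidden layers).
    """

    weights: list
    biases: list
    beta: np.ndarray
    activation: str
    dropout_frac: float
    feature_names: list
    config: NetworkConfig | None = None
    training_log: list = field(default_factory=list)
    dropconnect: bool = False

    def __post_init__(self):
        dims = [len(self.feature_names)]
        for W in self.weights:
            dims.append(W.shape[1])
        for W, d in zip(self.weights, dims):
            if W.shape[0] != d:
                raise ValueError("layer dimensions do not chain")
        if self.beta.shape != (dims[-1],):
            raise ValueError("beta length does not match final layer width")
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("beta must be finite")

    @property
    def n_hidden_layers(self) -> int:
        return len(self.weights)

    # -- forward / backward ------------------------------------------------

    def _draw_masks(self, rng, n):
        """Inverted dropout masks: unit dropout by default, DropConnect
        (per-weight masks) when the model was configured that way."""
        q = self.dropout_frac
        if q == 0.0:
            return [None] * self.n_hidden_layers
        if self.dropconnect:
            return [(rng.uniform(size=W.shape) >= q) / (1.0 - q)
                    for W in self.weights]
        return [(rng.uniform(size=(n, W.shape[1])) >= q) / (1.0 - q)
                for W in self.weights]

    def forward(self, X, train_mode=False, dropout_rng=None, masks=None):
        """Compute risk scores; returns ``(risk, cache)`` for backprop.

        In training mode inverted dropout masks (scale 1/(1-q)) are applied
        to hidden activations (or to the weights under DropConnect);
        evaluation mode applies no dropout and no scaling, so the linear
        score X_i beta is deterministic.
        """
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}")
        act, _ = _activation(self.activation)
        if masks is None:
            masks = [None] * self.n_hidden_layers
            if train_mode and self.dropout_frac > 0.0:
                rng = dropout_rng or np.random.default_rng(0)
                masks = self._draw_masks(rng, X.shape[0])
        a = X
        zs, activs = [], [a]
        for W, b, mask in zip(self.weights, self.biases, masks):
            if mask is not None and self.dropconnect:
                z = a @ (W * mask) + b
                a = act(z)
            else:
                z = a @ W + b
                a = act(z)
                if mask is not None:
                    a = a * mask
            zs.append(z)
            activs.append(a)
        risk = a @ self.beta
        cache = {"zs": zs, "activations": activs, "masks": masks}
        return risk, cache

    def backward(self, grad_risk, cache):
        """Chain-rule gradients of the loss given dl/d(risk scores).

        Returns (grad_weights, grad_biases, grad_beta).
        """
        _, dact = _activation(self.activation)
        activs, zs, masks = cache["activations"], cache["zs"], cache["masks"]
        g_beta = activs[-1].T @ grad_risk
        da = np.outer(grad_risk, self.beta)
        gWs, gbs = [], []
        for h in range(self.n_hidden_layers - 1, -1, -1):
            mask = masks[h]
            unit_mask = mask is not None and not self.dropconnect
            if unit_mask:
                da = da * mask
            dz = da * dact(zs[h])
            gW = activs[h].T @ dz
            if mask is not None and self.dropconnect:
                gW = gW * mask
                da = dz @ (self.weights[h] * mask).T
            else:
                da = dz @ self.weights[h].T
            gWs.append(gW)
            gbs.append(dz.sum(axis=0))
        gWs.reverse()
        gbs.reverse()
        return gWs, gbs, g_beta

    def input_gradients(self, X) -> np.ndarray:
        """Per-patient gradient of the risk score wrt each input feature.

        Evaluation-mode chain rule: beta composed with the Jacobian of every
        hidden layer evaluated at that patient's activations.  For a model
        with no hidden layers every row is beta.
        """
        X = np.asarray(X, dtype=float)
        _, cache = self.forward(X, train_mode=False)
        _, dact = _activation(self.activation)
        G = np.broadcast_to(self.beta, (X.shape[0], len(self.beta))).copy()
        for h in range(self.n_hidden_layers - 1, -1, -1):
            G = (G * dact(cache["zs"][h])) @ self.weights[h].T
        return G

    def predict(self, X) -> np.ndarray:
        risk, _ = self.forward(X, train_mode=False)
        return risk

    # -- parameter vector helpers ------------------------------------------

    def _get_flat(self):
        parts = [W.ravel() for W in self.weights] + \
                [b.ravel() for b in self.biases] + [self.beta.ravel()]
        return np.concatenate(parts) if parts else np.array([])

    def _set_flat(self, theta):
        pos = 0
        for i, W in enumerate(self.weights):
            k = W.size
            self.weights[i] = theta[pos:pos + k].reshape(W.shape)
            pos += k
        for i, b in enumerate(self.biases):
            k = b.size
            self.biases[i] = theta[pos:pos + k].reshape(b.shape)
            pos += k
        self.beta = theta[pos:].copy()

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def enc(a):
            a = np.ascontiguousarray(a, dtype=np.float64)
            return {"shape": list(a.shape),
                    "data": base64.b64encode(a.tobytes()).decode("ascii")}

        cfg = asdict(self.config) if self.config is not None else None
        return json.dumps({
            "format": "deepcox-model-v1",
            "activation": self.activation,
            "dropout_frac": self.dropout_frac,
            "feature_names": list(self.feature_names),
            "dropconnect": self.dropconnect,
            "config": cfg,
            "training_log": list(self.training_log),
            "weights": [enc(W) for W in self.weights],
            "biases": [enc(b) for b in self.biases],
            "beta": enc(self.beta),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DeepSurvivalModel":
        d = json.loads(text)
        if d.get("format") != "deepcox-model-v1":
            raise ValueError("not a deepcox model file")

        def dec(e):
            a = np.frombuffer(base64.b64decode(e["data"]), dtype=np.float64)
            return a.reshape(e["shape"]).copy()

        cfg = d["config"]
        return cls(
            weights=[dec(e) for e in d["weights"]],
            biases=[dec(e) for e in d["biases"]],
            beta=dec(d["beta"]),
            activation=d["activation"],
            dropout_frac=d["dropout_frac"],
            feature_names=d["feature_names"],
            config=NetworkConfig(**cfg) if cfg else None,
            training_log=d["training_log"],
            dropconnect=d.get("dropconnect", False),
        )

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "DeepSurvivalModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


# ---------------------------------------------------------------------------
# Module-level operation surface


def forward(model, features, train_mode=False, dropout_seed=0):
    """Functional forward pass; see :meth:`DeepSurvivalModel.forward`."""
    rng = np.random.default_rng(dropout_seed)
    return model.forward(features, train_mode=train_mode, dropout_rng=rng)


def _init_model(n_features, config: NetworkConfig) -> DeepSurvivalModel:
    """Scaled-uniform (fan-in + fan-out) initialization, seeded."""
    rng = np.random.default_rng(config.init_seed)
    dims = [n_features] + [config.layer_width] * config.n_hidden_layers
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (d_in + d_out))
        weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
        biases.append(np.zeros(d_out))
    limit = np.sqrt(6.0 / (dims[-1] + 1))
    beta = rng.uniform(-limit, limit, size=dims[-1])
    return DeepSurvivalModel(
        weights=weights, biases=biases, beta=beta,
        activation=config.activation, dropout_frac=config.dropout_frac,
        feature_names=[f"x{j}" for j in range(n_features)], config=config,
        dropconnect=config.dropconnect)


def train(ds: SurvivalDataset, config: NetworkConfig) -> DeepSurvivalModel:
    """Fit a deep Cox network by full-batch line-search gradient descent.

    Each epoch draws fresh dropout masks, runs one forward/backward pass over
    the whole training set, and takes a single backtracking line-search step
    on all parameters jointly (Armijo sufficient decrease on the masked
    training loss).  The evaluation-mode loss (event-averaged) is logged per
    epoch; training stops at ``max_epochs``, when the relative improvement of
    the logged loss over the last ``patience`` epochs falls below
    ``rel_tol``, or when the line search cannot find a decrease.
    Deterministic for fixed seeds.
    """
    times, events = ds.times, ds.events
    if not np.any(events == 1.0):
        raise ValueError("training set has no events")
    X = ds.X
    n_events = float(events.sum())
    model = _init_model(X.shape[1], config)
    model.feature_names = ds.feature_names
    ls = config.line_search
    drop_rng = np.random.default_rng(config.dropout_seed)

    if config.batch_size is not None:
        warnings.warn("mini-batch training is exposed for experimentation; "
                      "the partial likelihood couples samples, full batch is "
                      "the supported mode")

    def batches():
        if config.batch_size is None or config.batch_size >= ds.n:
            yield np.arange(ds.n)
            return
        perm = drop_rng.permutation(ds.n)
        for start in range(0, ds.n, config.batch_size):
            yield perm[start:start + config.batch_size]

    step0 = ls.initial_step
    for epoch in range(config.max_epochs):
        stop = False
        for idx in batches():
            Xb, tb, eb = X[idx], times[idx], events[idx]
            if not np.any(eb == 1.0):
                continue
            nb = float(eb.sum())
            risk, cache = model.forward(Xb, train_mode=True,
                                        dropout_rng=drop_rng)
            loss0 = neg_log_partial_likelihood(risk, tb, eb) / nb
            g_risk = loss_gradient_wrt_risk(risk, tb, eb) / nb
            gWs, gbs, g_beta = model.backward(g_risk, cache)
            grad = np.concatenate([g.ravel() for g in gWs] +
                                  [g.ravel() for g in gbs] + [g_beta.ravel()])
            theta0 = model._get_flat()
            gg = float(grad @ grad)
            if gg == 0.0:
                stop = True
                break

            # line search evaluates the loss with the SAME dropout masks, so
            # the Armijo condition applies to a fixed objective within the epoch
            masks = cache["masks"]

            def loss_at(theta):
                model._set_flat(theta)
                r, _ = model.forward(Xb, train_mode=True, masks=masks)
                if not np.all(np.isfinite(r)):
                    return np.inf
                return neg_log_partial_likelihood(r, tb, eb) / nb

            alpha = step0
            accepted = False
            for _ in range(ls.max_shrinks + 1):
                if loss_at(theta0 - alpha * grad) <= \
                        loss0 - ls.sufficient_decrease * alpha * gg:
                    accepted = True
                    break
                alpha *= ls.shrink
            if not accepted:
                model._set_flat(theta0)
                warnings.warn("line search found no decrease after "
                              f"{ls.max_shrinks} shrinks; stopping at epoch "
                              f"{epoch}")
                stop = True
                break
            model._set_flat(theta0 - alpha * grad)
            if ls.adaptive:
                step0 = min(alpha * 2.0, 1e3)
            else:
                step0 = ls.initial_step

        eval_risk, _ = model.forward(X, train_mode=False)
        eval_loss = neg_log_partial_likelihood(eval_risk, times, events) / n_events
        model.training_log.append(float(eval_loss))
        if stop:
            break
        log = model.training_log
        if len(log) > config.patience:
            prev, cur = log[-config.patience - 1], log[-1]
            if prev - cur < config.rel_tol * max(1.0, abs(prev)):
                break
    return model


def predict_risk(model: DeepSurvivalModel, ds: SurvivalDataset) -> np.ndarray:
    """Evaluation-mode risk scores, aligning dataset columns by name."""
    missing = [c for c in model.feature_names if c not in ds.features.columns]
    if missing:
        raise KeyError(f"dataset is missing model features: {missing}")
    X = ds.features[model.feature_names].to_numpy(dtype=float)
    return model.predict(X)
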