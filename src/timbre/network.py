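"""TIMBRE: a shallow complex-valued network for carrier-free decoding.

The network reads the complex (whitened) multichannel theta-band LFP x(t) and
computes

    h(t) = softmax(|W1 x(t)|),        y(t) = softmax(W2 h(t) + b),

where W1 is a complex hidden-weight matrix whose rows are constrained to unit
L2 norm and W2 is real.  Taking the modulus of the hidden projection discards
the oscillatory phase, so the classifier is exactly invariant to any
time-varying phase rotation applied jointly to all channels — the property
that makes it robust to shared phase noise.  The softmax on the hidden layer
induces competition among nodes, driving each to learn a distinct
position-tuned oscillatory pattern (a "p-theta").

Training minimizes categorical cross-entropy with Adam.  Gradients with
respect to the complex W1 are conjugate-Wirtinger derivatives, computed by
hand (the real and imaginary parts of 2 dL/dW1* are the ordinary partial
derivatives of the real loss, so Adam runs on the real view of the
parameters).  The unit-norm constraint is enforced by projection: rows of W1
are renormalized after every optimizer step.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["TrainConfig", "ComplexSoftmaxNet", "SoftmaxRegressor",
           "AdamState", "softmax", "train", "predict_arm", "extract_ptheta"]


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    e = np.exp(x - np.max(x, axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings (Adam, lr 1e-3, early stopping on held-out loss)."""

    lr: float = 1e-3
    max_epochs: int = 100
    batch_size: int = 64
    patience: int = 1
    n_restarts: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class AdamState:
    """Minimal Adam optimizer over a list of real ndarrays."""

    def __init__(self, shapes, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            out.append(p - self.lr * mhat / (np.sqrt(vhat) + self.eps))
        return out


class ComplexSoftmaxNet:
    """Complex projection -> modulus -> softmax [-> real output layer -> softmax].

    With ``n_classes`` set this is the full three-layer TIMBRE classifier;
    with ``n_classes=None`` the softmaxed hidden amplitudes *are* the output
    (the form used for radial-basis pose decoding with a KL objective).
    ``unit_norm`` controls the per-row L2 constraint on W1.
    """

    def __init__(self, n_inputs: int, n_hidden: int, n_classes: int | None = None,
                 unit_norm: bool = True, seed: int = 0):
        self.n_inputs, self.n_hidden, self.seed = n_inputs, n_hidden, seed
        rng = np.random.default_rng(seed)
        w = rng.standard_normal((n_hidden, n_inputs)) + \
            1j * rng.standard_normal((n_hidden, n_inputs))
        self.W1 = w / np.linalg.norm(w, axis=1, keepdims=True)
        if not unit_norm:
            self.W1 = self.W1 / np.sqrt(n_inputs)
        self.unit_norm = unit_norm
        self.n_classes = n_classes
        if n_classes is not None:
            self.W2 = 0.01 * rng.standard_normal((n_classes, n_hidden))
            self.b = np.zeros(n_classes)
        else:
            self.W2 = None
            self.b = None

    # -- forward ----------------------------------------------------------
    def hidden_projection(self, x: np.ndarray) -> np.ndarray:
        """Complex hidden pre-activations a(t) = conj(W1) x(t), one per node.

        These are the p-theta oscillations: multiplying the LFP by the
        conjugate of a node's weights yields that node's complex time series.
        """
        return x @ self.W1.conj().T

    def forward(self, x: np.ndarray):
        """Return (h, y): softmaxed hidden activations and class probabilities."""
        a = self.hidden_projection(x)
        h = softmax(np.abs(a), axis=1)
        if self.n_classes is None:
            return h, h
        y = softmax(h @ self.W2.T + self.b, axis=1)
        return h, y

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)[1]

    def decode_hidden(self, x: np.ndarray) -> np.ndarray:
        """argmax over hidden nodes of |W1 x| (carrier-free decision rule)."""
        return np.argmax(np.abs(self.hidden_projection(x)), axis=1)

    # -- loss / gradients -------------------------------------------------
    def loss(self, x: np.ndarray, targets: np.ndarray) -> float:
        _, y = self.forward(x)
        return float(-np.mean(np.sum(targets * np.log(y + 1e-12), axis=1)))

    def loss_and_grads(self, x: np.ndarray, targets: np.ndarray):
        """Cross-entropy loss and gradients (real view of complex W1).

        The W1 gradient is the conjugate-Wirtinger derivative of the real
        loss: with a = x conj(W1)^T and u = |a|,
        2 dL/dW1* = (dL/du * conj(a)/|a|)^T x, whose real/imaginary parts are
        the partial derivatives with respect to Re(W1) and Im(W1).
        """
        B = x.shape[0]
        a = self.hidden_projection(x)
        u = np.abs(a)
        h = softmax(u, axis=1)
        if self.n_classes is not None:
            logits = h @ self.W2.T + self.b
            y = softmax(logits, axis=1)
            loss = float(-np.mean(np.sum(targets * np.log(y + 1e-12), axis=1)))
            dlogits = (y - targets) / B
            gW2 = dlogits.T @ h
            gb = dlogits.sum(axis=0)
            dh = dlogits @ self.W2
        else:
            y = h
            loss = float(-np.mean(np.sum(targets * np.log(y + 1e-12), axis=1)))
            dh = (y - targets) / B          # gradient w.r.t. softmax output path
            gW2 = gb = None
        # softmax backward on the hidden layer
        if self.n_classes is not None:
            du = h * (dh - np.sum(dh * h, axis=1, keepdims=True))
        else:
            # dh here is already dL/d(softmax input) composed with CE:
            # for CE-with-softmax the combined gradient is (y - t)/B w.r.t. u
            du = dh
        phase = np.where(u > 0, a / np.where(u > 0, u, 1.0), 0.0)
        gW1 = (du * np.conj(phase)).T @ x       # complex [H x N] = 2 dL/dW1*
        grads = {"W1re": gW1.real, "W1im": gW1.imag}
        if self.n_classes is not None:
            grads["W2"] = gW2
            grads["b"] = gb
        return loss, grads

    # -- parameter plumbing ------------------------------------------------
    def _params(self):
        p = [self.W1.real.copy(), self.W1.imag.copy()]
        names = ["W1re", "W1im"]
        if self.n_classes is not None:
            p += [self.W2.copy(), self.b.copy()]
            names += ["W2", "b"]
        return p, names

    def _set_params(self, params, names):
        d = dict(zip(names, params))
        self.W1 = d["W1re"] + 1j * d["W1im"]
        if self.unit_norm:
            norms = np.linalg.norm(self.W1, axis=1, keepdims=True)
            self.W1 = self.W1 / np.where(norms > 0, norms, 1.0)
        if self.n_classes is not None:
            self.W2 = d["W2"]
            self.b = d["b"]

    def copy_weights(self):
        return (self.W1.copy(),
                None if self.W2 is None else self.W2.copy(),
                None if self.b is None else self.b.copy())

    def restore_weights(self, saved):
        self.W1 = saved[0].copy()
        if saved[1] is not None:
            self.W2 = saved[1].copy()
            self.b = saved[2].copy()


class SoftmaxRegressor:
    """Real-input linear model with softmax output (for carrier-based / spike
    pose decoding with a KL objective)."""

    def __init__(self, n_inputs: int, n_outputs: int, seed: int = 0):
        self.n_inputs, self.n_outputs, self.seed = n_inputs, n_outputs, seed
        rng = np.random.default_rng(seed)
        self.W = 0.01 * rng.standard_normal((n_outputs, n_inputs))
        self.b = np.zeros(n_outputs)
        self.n_classes = n_outputs

    def forward(self, x):
        y = softmax(x @ self.W.T + self.b, axis=1)
        return y, y

    def predict_proba(self, x):
        return self.forward(x)[1]

    def loss(self, x, targets):
        y = self.predict_proba(x)
        return float(-np.mean(np.sum(targets * np.log(y + 1e-12), axis=1)))

    def loss_and_grads(self, x, targets):
        B = x.shape[0]
        y = self.predict_proba(x)
        loss = float(-np.mean(np.sum(targets * np.log(y + 1e-12), axis=1)))
        dlogits = (y - targets) / B
        return loss, {"W": dlogits.T @ x, "b": dlogits.sum(axis=0)}

    def _params(self):
        return [self.W.copy(), self.b.copy()], ["W", "b"]

    def _set_params(self, params, names):
        d = dict(zip(names, params))
        self.W, self.b = d["W"], d["b"]

    def copy_weights(self):
        return (self.W.copy(), self.b.copy())

    def restore_weights(self, saved):
        self.W, self.b = saved[0].copy(), saved[1].copy()


def _as_one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim == 2:
        return np.asarray(labels, dtype=float)
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels.astype(int)] = 1.0
    return out


def train(model, x_train, targets_train, x_val, targets_val,
          cfg: TrainConfig | None = None):
    """Train with minibatch Adam and early stopping on the held-out loss.

    Targets may be integer labels or probability rows (soft targets for the
    KL objective; KL differs from cross-entropy only by the target entropy,
    a constant in the model).  Training halts at ``max_epochs`` or once the
    validation loss has risen for ``patience`` consecutive epochs; the
    weights from the best validation epoch are restored.

    The softmax competition between hidden nodes admits collapsed local
    optima (two nodes sharing one behavioral state); with ``n_restarts > 1``
    the model is retrained from fresh initializations and the run with the
    lowest validation loss is kept — the collapse is plainly visible in that
    loss, so the selection is automatic.

    Returns (model, history) where history has per-epoch train/val losses of
    the selected run.
    """
    cfg = cfg or TrainConfig()
    if cfg.n_restarts > 1:
        best = None
        for r in range(cfg.n_restarts):
            if r == 0:
                candidate = model
            elif isinstance(model, ComplexSoftmaxNet):
                candidate = ComplexSoftmaxNet(
                    model.n_inputs, model.n_hidden, model.n_classes,
                    unit_norm=model.unit_norm,
                    seed=(model.seed + 7919 * r) % 2**31)
            else:
                candidate = type(model)(model.n_inputs, model.n_classes,
                                        seed=(model.seed + 7919 * r) % 2**31)
            single = dataclasses.replace(cfg, n_restarts=1,
                                         seed=(cfg.seed + 7919 * r) % 2**31)
            candidate, history = train(candidate, x_train, targets_train,
                                       x_val, targets_val, single)
            score = min(history["val_loss"])
            if best is None or score < best[0]:
                best = (score, candidate, history)
        return best[1], best[2]
    n_out = model.n_classes if model.n_classes is not None else model.W1.shape[0]
    t_train = _as_one_hot(targets_train, n_out)
    t_val = _as_one_hot(targets_val, n_out)
    present = np.flatnonzero(t_train.sum(axis=0) > 0)
    if np.asarray(targets_train).ndim == 1 and len(present) < n_out:
        raise ValueError("every class must appear in the training labels")
    rng = np.random.default_rng(cfg.seed)
    params, names = model._params()
    opt = AdamState([p.shape for p in params], lr=cfg.lr)
    n = x_train.shape[0]
    bs = min(cfg.batch_size, n)
    best_val = np.inf
    best_weights = model.copy_weights()
    bad_epochs = 0
    history = {"train_loss": [], "val_loss": []}
    for _ in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            loss, grads = model.loss_and_grads(x_train[idx], t_train[idx])
            epoch_loss += loss * len(idx)
            params, names = model._params()
            params = opt.step(params, [grads[k] for k in names])
            model._set_params(params, names)
        val_loss = model.loss(x_val, t_val)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.copy_weights()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.restore_weights(best_weights)
    return model, history


def extract_ptheta(model: ComplexSoftmaxNet, x: np.ndarray) -> np.ndarray:
    """One complex p-theta oscillation per hidden node: conj(W1[j]) . x(t)."""
    return model.hidden_projection(x)


def predict_arm(model, x: np.ndarray, arm_of_class: np.ndarray,
                true_arms: np.ndarray | None = None):
    """Map per-sample argmax classes to arms; optionally score arm accuracy.

    A prediction counts as correct when the predicted class maps to the arm
    the animal occupies (so a 12-class run decoder is scored at arm level).
    Ties break to the lowest class index.
    """
    y = model.predict_proba(x)
    classes = np.argmax(y, axis=1)
    arms = np.asarray(arm_of_class)[classes]
    if true_arms is None:
        return y, arms, None
    accuracy = float(np.mean(arms == np.asarray(true_arms)))
    return y, arms, accuracy
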