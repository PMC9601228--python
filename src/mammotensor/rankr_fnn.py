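"""Rank-R fully-connected neural network with CP-factorized first-layer weights.

The model is a one-hidden-layer network on third-order tensor inputs
``X in R^{s x s x b}``. The weight tensor of hidden neuron q is constrained
to a rank-R canonical polyadic (CP) form

    W(q) = sum_{k=1..R} w1_k(q) o w2_k(q) o w3_k(q),

with ``w1, w2 in R^s`` acting on the two spatial axes and ``w3 in R^b`` on
the channel axis ("o" is the vector outer product). The hidden activation is

    u_q = g(<W(q), X>),

computed by sequential contraction without ever materializing W(q), and the
output layer maps u through per-class weight vectors v(c) into a softmax.
Factorization shrinks the first layer from ``s^2 b`` to ``R (2s + b)``
trainable scalars per neuron, which is what lets the model learn from small
datasets.

Training minimizes mean cross-entropy with manually derived gradients
(chain rule through the three sequential contractions, validated against
finite differences) and the Adam optimizer. Everything is plain NumPy and
fully deterministic given a seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ModelDims",
    "CPNeuronFactors",
    "RankRFNNParams",
    "TrainConfig",
    "TrainingHistory",
    "cp_reconstruct",
    "hidden_preactivation",
    "forward",
    "predict",
    "cross_entropy",
    "init_params",
    "loss_and_grads",
    "train",
    "fit_arrays",
    "count_parameters",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class ModelDims:
    """Dimensions (s, b, C, Q, R): window size, channels, classes, hidden
    neurons, CP rank."""

    s: int
    b: int
    C: int
    Q: int = 25
    R: int = 4

    def __post_init__(self) -> None:
        for name in ("s", "b", "C", "Q", "R"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class CPNeuronFactors:
    """CP factors of a single hidden neuron: w1, w2 (R x s), w3 (R x b)."""

    w1: np.ndarray
    w2: np.ndarray
    w3: np.ndarray

    def __post_init__(self) -> None:
        w1, w2, w3 = (np.atleast_2d(np.asarray(w, dtype=np.float64))
                      for w in (self.w1, self.w2, self.w3))
        if not (w1.shape[0] == w2.shape[0] == w3.shape[0]):
            raise ValueError("factor matrices must share the rank dimension")
        if w1.shape[1] != w2.shape[1]:
            raise ValueError("w1 and w2 must share the spatial length s")
        for name, w in (("w1", w1), ("w2", w2), ("w3", w3)):
            if not np.isfinite(w).all():
                raise ValueError(f"{name} contains non-finite entries")
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "w2", w2)
        object.__setattr__(self, "w3", w3)

    @property
    def rank(self) -> int:
        return self.w1.shape[0]


def _activation(name: str):
    if name == "relu":
        return (lambda z: np.maximum(z, 0.0)), (lambda z: (z > 0).astype(z.dtype))
    if name == "sigmoid":
        def sig(z):
            return 1.0 / (1.0 + np.exp(-z))
        return sig, (lambda z: sig(z) * (1.0 - sig(z)))
    raise ValueError(f"unknown activation {name!r}; use 'relu' or 'sigmoid'")


@dataclass
class RankRFNNParams:
    """All trainable parameters: stacked CP factors and output weights.

    W1, W2: (Q, R, s); W3: (Q, R, b); V: (C, Q). ``activation`` names the
    hidden nonlinearity g.
    """

    W1: np.ndarray
    W2: np.ndarray
    W3: np.ndarray
    V: np.ndarray
    activation: str = "relu"

    @property
    def dims(self) -> ModelDims:
        Q, R, s = self.W1.shape
        b = self.W3.shape[2]
        C = self.V.shape[0]
        return ModelDims(s=s, b=b, C=C, Q=Q, R=R)

    def neuron(self, q: int) -> CPNeuronFactors:
        return CPNeuronFactors(self.W1[q], self.W2[q], self.W3[q])

    def copy(self) -> "RankRFNNParams":
        return RankRFNNParams(
            self.W1.copy(), self.W2.copy(), self.W3.copy(), self.V.copy(),
            self.activation,
        )


@dataclass
class TrainConfig:
    """Optimization settings: 70 Adam epochs with test-set evaluation every
    10 epochs by default; experiments repeat 10 times with derived seeds."""

    epochs: int = 70
    eval_every: int = 10
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int | None = None  # None: full batch if N <= 1024, else 128
    seed: int = 0
    repetitions: int = 10
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.epochs and self.eval_every > self.epochs:
            raise ValueError("eval_every must not exceed epochs")


@dataclass
class TrainingHistory:
    """Per-epoch training loss and periodic test metrics."""

    train_loss: list[float] = field(default_factory=list)
    eval_epochs: list[int] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    test_macro_f1: list[float] = field(default_factory=list)
    diverged: bool = False


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def cp_reconstruct(factors: CPNeuronFactors) -> np.ndarray:
    """Materialize a neuron's weight tensor W(q) as an s x s x b array.

    Element (j, l, m) = sum_k w1_k[j] * w2_k[l] * w3_k[m].
    """
    return np.einsum("kj,kl,km->jlm", factors.w1, factors.w2, factors.w3)


def hidden_preactivation(factors: CPNeuronFactors, X: np.ndarray) -> float:
    """Inner product <W(q), X> without materializing W(q).

    For each rank term, X is contracted sequentially against w3 (channel
    axis), w2 (width) and w1 (height); the R scalars are summed. Cost
    O(R (s^2 b + s^2 + s)) versus O(s^2 b) per-materialized-dot — results
    identical to floating-point roundoff.
    """
    X = np.asarray(X, dtype=np.float64)
    s = factors.w1.shape[1]
    b = factors.w3.shape[1]
    if X.ndim != 3:
        raise ValueError("X must be a third-order tensor (height, width, channels)")
    for axis, (size, expected) in enumerate(zip(X.shape, (s, s, b))):
        if size != expected:
            raise ValueError(
                f"axis {axis} of X has length {size}, expected {expected}"
            )
    t1 = X @ factors.w3.T             # (s, s, R): contract channels
    t2 = np.einsum("hwr,rw->hr", t1, factors.w2)   # contract width
    t3 = np.einsum("hr,rh->r", t2, factors.w1)     # contract height
    return float(t3.sum())


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _rank1_weight_matrix(params: RankRFNNParams) -> np.ndarray:
    """Stack the Q*R rank-1 weight tensors as columns of an (s*s*b, K) matrix.

    Materializing the K rank-1 terms costs only K s^2 b multiplies and lets
    the batched forward/backward run as one large BLAS matmul; the result
    is identical to the sequential per-sample contraction (the
    :func:`hidden_preactivation` route, which never materializes weights).
    """
    d = params.dims
    K = d.Q * d.R
    W = np.einsum(
        "kh,kl,km->khlm",
        params.W1.reshape(K, d.s),
        params.W2.reshape(K, d.s),
        params.W3.reshape(K, d.b),
    )
    return W.reshape(K, d.s * d.s * d.b).T


def _forward_batch(params: RankRFNNParams, X: np.ndarray, want_cache: bool = False):
    """Vectorized forward over a batch (N, s, s, b) of tensors."""
    d = params.dims
    N = X.shape[0]
    Wmat = _rank1_weight_matrix(params)
    zk = X.reshape(N, -1) @ Wmat                 # (N, K)
    z = zk.reshape(N, d.Q, d.R).sum(axis=2)
    g, _ = _activation(params.activation)
    u = g(z)
    logits = u @ params.V.T
    if not np.isfinite(logits).all():
        raise FloatingPointError(
            "non-finite logits; parameter norms: "
            + ", ".join(
                f"{n}={np.linalg.norm(getattr(params, n)):.3e}"
                for n in ("W1", "W2", "W3", "V")
            )
        )
    p = _softmax(logits)
    if want_cache:
        return p, (z, u)
    return p


def forward(params: RankRFNNParams, X: np.ndarray, chunk: int = 512) -> np.ndarray:
    """Class-probability vector(s) for one tensor or a batch of tensors.

    Returns shape (C,) for a single (s, s, b) input, (N, C) for a batch.
    Probabilities are positive and sum to 1.
    """
    X = np.asarray(X, dtype=np.float64)
    single = X.ndim == 3
    if single:
        X = X[None]
    if X.shape[0] <= chunk:
        p = _forward_batch(params, X)
    else:
        p = np.concatenate(
            [_forward_batch(params, X[i : i + chunk]) for i in range(0, X.shape[0], chunk)]
        )
    return p[0] if single else p


def predict(params: RankRFNNParams, X: np.ndarray) -> np.ndarray:
    """One-hot prediction(s) at the argmax probability.

    Ties are broken toward the lowest class index.
    """
    p = forward(params, X)
    single = p.ndim == 1
    if single:
        p = p[None]
    out = np.zeros_like(p)
    out[np.arange(p.shape[0]), p.argmax(axis=1)] = 1.0
    return out[0] if single else out


def cross_entropy(p: np.ndarray, t: np.ndarray) -> float:
    """Mean cross-entropy -sum_c t_c log p_c; on one-hot targets this is
    exactly -log(probability of the true class)."""
    p = np.atleast_2d(p)
    t = np.atleast_2d(t)
    return float(-(t * np.log(np.clip(p, _EPS, None))).sum(axis=1).mean())


# ---------------------------------------------------------------------------
# Initialization, gradients, training
# ---------------------------------------------------------------------------

def init_params(
    dims: ModelDims, seed: int = 0, activation: str = "relu"
) -> RankRFNNParams:
    """Variance-preserving random initialization.

    Factor entries ~ Normal(0, 1/sqrt(R (2s + b))); output weights
    ~ Normal(0, 1/sqrt(Q)).
    """
    rng = np.random.default_rng(seed)
    sd_f = 1.0 / np.sqrt(dims.R * (2 * dims.s + dims.b))
    sd_v = 1.0 / np.sqrt(dims.Q)
    return RankRFNNParams(
        W1=rng.normal(0.0, sd_f, (dims.Q, dims.R, dims.s)),
        W2=rng.normal(0.0, sd_f, (dims.Q, dims.R, dims.s)),
        W3=rng.normal(0.0, sd_f, (dims.Q, dims.R, dims.b)),
        V=rng.normal(0.0, sd_v, (dims.C, dims.Q)),
        activation=activation,
    )


def loss_and_grads(
    params: RankRFNNParams, X: np.ndarray, T: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean cross-entropy and its gradient w.r.t. every parameter array.

    Gradients are derived by hand through softmax, the hidden nonlinearity
    and the three sequential CP contractions; every factor vector and every
    v(c) receives gradient.
    """
    X = np.asarray(X, dtype=np.float64)
    T = np.asarray(T, dtype=np.float64)
    d = params.dims
    N = X.shape[0]
    K = d.Q * d.R
    W1k = params.W1.reshape(K, d.s)
    W2k = params.W2.reshape(K, d.s)
    W3k = params.W3.reshape(K, d.b)
    p, (z, u) = _forward_batch(params, X, want_cache=True)
    loss = cross_entropy(p, T)

    dlogits = (p - T) / N                      # softmax + CE combined
    dV = dlogits.T @ u
    du = dlogits @ params.V
    _, gprime = _activation(params.activation)
    dz = du * gprime(z)                        # (N, Q)
    dzk = np.repeat(dz, d.R, axis=1)           # (N, K), q-major like reshape

    # gradient w.r.t. each rank-1 weight tensor, then chain into its factors
    dW = (X.reshape(N, -1).T @ dzk).T.reshape(K, d.s, d.s, d.b)
    dw_m = np.einsum("khlm,kl->khm", dW, W2k)           # width contracted
    dW1 = np.einsum("khm,km->kh", dw_m, W3k).reshape(d.Q, d.R, d.s)
    dw_h = np.einsum("khlm,kh->klm", dW, W1k)           # height contracted
    dW2 = np.einsum("klm,km->kl", dw_h, W3k).reshape(d.Q, d.R, d.s)
    dW3 = np.einsum("klm,kl->km", dw_h, W2k).reshape(d.Q, d.R, d.b)
    return loss, {"W1": dW1, "W2": dW2, "W3": dW3, "V": dV}


class _Adam:
    def __init__(self, cfg: TrainConfig, shapes: dict[str, tuple]):
        self.cfg = cfg
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: RankRFNNParams, grads: dict[str, np.ndarray]) -> None:
        c = self.cfg
        self.t += 1
        for name, g in grads.items():
            m = self.m[name] = c.beta1 * self.m[name] + (1 - c.beta1) * g
            v = self.v[name] = c.beta2 * self.v[name] + (1 - c.beta2) * g * g
            mhat = m / (1 - c.beta1 ** self.t)
            vhat = v / (1 - c.beta2 ** self.t)
            arr = getattr(params, name)
            arr -= c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)


def fit_arrays(
    X_train: np.ndarray,
    T_train: np.ndarray,
    dims: ModelDims,
    cfg: TrainConfig,
    X_test: np.ndarray | None = None,
    T_test: np.ndarray | None = None,
) -> tuple[RankRFNNParams, TrainingHistory]:
    """Train on dense arrays; evaluate on the test arrays every
    ``cfg.eval_every`` epochs when provided.

    Fully reproducible given ``cfg.seed``. If the loss goes non-finite the
    last finite parameters are returned with ``history.diverged`` set.
    """
    from .evaluation import confusion_matrix_labels, scores  # local: avoid cycle

    X_train = np.asarray(X_train, dtype=np.float64)
    T_train = np.asarray(T_train, dtype=np.float64)
    n = X_train.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    params = init_params(dims, seed=int(rng.integers(2**31 - 1)),
                         activation=cfg.activation)
    history = TrainingHistory()
    batch = cfg.batch_size or (n if n <= 1024 else 128)
    opt = _Adam(cfg, {k: getattr(params, k).shape for k in ("W1", "W2", "W3", "V")})
    last_good = params.copy()

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses, weights = [], []
        for i in range(0, n, batch):
            idx = order[i : i + batch]
            try:
                loss, grads = loss_and_grads(params, X_train[idx], T_train[idx])
            except FloatingPointError:
                loss = float("nan")
            if not np.isfinite(loss):
                logger.error("training diverged at epoch %d; returning last "
                             "finite checkpoint", epoch)
                history.diverged = True
                return last_good, history
            opt.step(params, grads)
            losses.append(loss)
            weights.append(len(idx))
        history.train_loss.append(float(np.average(losses, weights=weights)))
        last_good = params.copy()
        if X_test is not None and len(X_test) and epoch % cfg.eval_every == 0:
            pred = predict(params, X_test)
            cm = confusion_matrix_labels(
                T_test.argmax(axis=1), pred.argmax(axis=1), dims.C
            )
            acc, f1 = scores(cm)
            history.eval_epochs.append(epoch)
            history.test_accuracy.append(acc)
            history.test_macro_f1.append(f1)
    return params, history


def train(dataset, dims: ModelDims, cfg: TrainConfig):
    """Train on a :class:`~mammotensor.sampling.Dataset` (its 30% split),
    evaluating on the held-out 70% every ``cfg.eval_every`` epochs."""
    from .sampling import stack_samples

    tr = [dataset.samples[i] for i in dataset.train_idx]
    te = [dataset.samples[i] for i in dataset.test_idx]
    X_train, T_train = stack_samples(tr)
    if te:
        X_test, T_test = stack_samples(te)
    else:
        X_test = T_test = None
    return fit_arrays(X_train, T_train, dims, cfg, X_test, T_test)


def count_parameters(dims: ModelDims) -> tuple[int, int]:
    """Trainable-scalar counts: (CP-factorized, dense equivalent).

    factorized = Q R (2s + b) + C Q; dense = Q s^2 b + C Q. Warns when the
    rank is too high for the factorization to save parameters.
    """
    factorized = dims.Q * dims.R * (2 * dims.s + dims.b) + dims.C * dims.Q
    dense = dims.Q * dims.s * dims.s * dims.b + dims.C * dims.Q
    if dims.R * (2 * dims.s + dims.b) >= dims.s * dims.s * dims.b:
        warnings.warn(
            f"rank R={dims.R} is too high to save parameters "
            f"(factorized {factorized} >= dense {dense})",
            stacklevel=2,
        )
    return factorized, dense
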