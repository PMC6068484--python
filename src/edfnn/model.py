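"""The exponentially delayed fully connected network (ED-FNN).

One feed-forward branch per IMU sensor (gyroscope, accelerometer): each branch
sees only its own sensor's exponentially windowed history and carries two
hidden layers of six ReLU units. The branch outputs are concatenated and a
single linear head maps them to the ``f`` forecast percent values. Training
one branch per sensor and concatenating late is what keeps run-to-run variance
low compared to a monolithic network of the same size.

Everything is plain numpy: the forward pass, the analytic backward pass and
the Adam/SGD updates operate on one flat parameter vector whose per-layer
weight matrices are views into it, which keeps the minibatch loop cheap and
makes finite-difference gradient checking trivial.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embedding import DelayConfig, EmbeddedDataset
from .errors import TrainingDivergenceError

HIDDEN_UNITS = 6  # per hidden layer, per branch


@dataclass
class LayerParams:
    """One dense layer: activation(theta @ a_prev + bias)."""

    theta: np.ndarray  # (n_units, n_inputs)
    bias: np.ndarray  # (n_units,)


def relu(z: np.ndarray) -> np.ndarray:
    """Rectified linear unit, elementwise max(0, z)."""
    return np.maximum(0.0, z)


def layer_forward(a_prev: np.ndarray, params: LayerParams, activation=relu) -> np.ndarray:
    """Dense-layer forward pass: activation(theta · a_prev + bias)."""
    a_prev = np.asarray(a_prev, dtype=float)
    if a_prev.shape[-1] != params.theta.shape[1]:
        raise ValueError(
            f"input width {a_prev.shape[-1]} does not match layer ({params.theta.shape})"
        )
    z = a_prev @ params.theta.T + params.bias
    return activation(z) if activation is not None else z


def concat_branches(branch_outputs: list[np.ndarray]) -> np.ndarray:
    """Concatenate per-sensor branch activations, branch order preserved."""
    return np.concatenate(branch_outputs, axis=-1)


def mse_cost(pred: np.ndarray, truth: np.ndarray) -> float:
    """Training cost: (1/2N) Σ_i ||pred_i − truth_i||² (the ½ aids gradients).

    Reported evaluation metrics use the standard MSE without the ½; see
    :mod:`edfnn.metrics`.
    """
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    truth = np.atleast_2d(np.asarray(truth, dtype=float))
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    n = pred.shape[0]
    if n < 1:
        raise ValueError("need at least one row")
    return float(np.sum((pred - truth) ** 2) / (2 * n))


@dataclass
class TrainConfig:
    """Optimisation settings; defaults are Adam, 1e-3, 200 epochs, batch 256."""

    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 256
    optimizer: str = "adam"  # "adam" | "gradient-descent"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer not in ("adam", "gradient-descent"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class LearningCurve:
    """Per-epoch Eq.-style half-MSE cost on the training (and validation) data."""

    train: np.ndarray
    validation: np.ndarray | None = None


class EDFNN:
    """Per-sensor branched feed-forward percent estimator.

    Parameters
    ----------
    branch_sizes : input width of each sensor branch (windowed features per
        sensor), e.g. ``[21, 21]`` for 6 channels × 7 lags split in two.
    f : forecast horizon — width of the linear output head.
    hidden : units in each of the two hidden layers per branch.
    seed : seeds the fan-in-scaled uniform weight initialisation.
    """

    def __init__(self, branch_sizes: list[int], f: int = 1,
                 hidden: int = HIDDEN_UNITS, seed: int = 0):
        self.branch_sizes = [int(b) for b in branch_sizes]
        self.f = int(f)
        self.hidden = int(hidden)
        self.seed = int(seed)
        self.delay_config: DelayConfig | None = None

        shapes: list[tuple[int, ...]] = []
        for kb in self.branch_sizes:
            shapes += [(hidden, kb), (hidden,), (hidden, hidden), (hidden,)]
        concat_width = hidden * len(self.branch_sizes)
        shapes += [(self.f, concat_width), (self.f,)]
        self._shapes = shapes
        sizes = [int(np.prod(s)) for s in shapes]
        self._offsets = np.concatenate([[0], np.cumsum(sizes)])
        self.params = np.empty(self._offsets[-1], dtype=float)
        self._init_params()

        k = sum(self.branch_sizes)
        self.mu = np.zeros(k)
        self.sigma = np.ones(k)

    # ------------------------------------------------------------ params
    def _view(self, i: int) -> np.ndarray:
        return self.params[self._offsets[i]:self._offsets[i + 1]].reshape(self._shapes[i])

    def _layers(self) -> list[LayerParams]:
        return [LayerParams(self._view(2 * j), self._view(2 * j + 1))
                for j in range(len(self._shapes) // 2)]

    def _init_params(self) -> None:
        # uniform(-1/sqrt(fan_in), +1/sqrt(fan_in)) per layer, seeded
        rng = np.random.default_rng(self.seed)
        for j in range(len(self._shapes) // 2):
            W, b = self._view(2 * j), self._view(2 * j + 1)
            lim = 1.0 / np.sqrt(W.shape[1])
            W[...] = rng.uniform(-lim, lim, W.shape)
            b[...] = rng.uniform(-lim, lim, b.shape)

    @classmethod
    def for_dataset(cls, dataset: EmbeddedDataset, hidden: int = HIDDEN_UNITS,
                    seed: int = 0, channels_per_sensor: int = 3) -> "EDFNN":
        """Build a model matching an embedded dataset's branch layout."""
        sizes = [sl.stop - sl.start for sl in dataset.branch_slices(channels_per_sensor)]
        f = dataset.Yd.shape[1]
        model = cls(sizes, f=f, hidden=hidden, seed=seed)
        model.delay_config = dataset.config
        return model

    # ------------------------------------------------------- normalization
    def fit_normalization(self, X: np.ndarray, feature_channels: np.ndarray | None = None) -> None:
        """Standardise inputs using training-split statistics.

        With ``feature_channels`` given, one mean/std is estimated per sensor
        channel (shared across all lags of that channel); otherwise per
        feature column.
        """
        X = np.asarray(X, dtype=float)
        if feature_channels is None:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
        else:
            feature_channels = np.asarray(feature_channels)
            mu = np.empty(X.shape[1])
            sd = np.empty(X.shape[1])
            for c in np.unique(feature_channels):
                cols = feature_channels == c
                mu[cols] = X[:, cols].mean()
                sd[cols] = X[:, cols].std()
        sd[sd < 1e-12] = 1.0
        self.mu, self.sigma = mu, sd

    def normalize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mu) / self.sigma

    # ------------------------------------------------------------ forward
    def _split(self, X: np.ndarray) -> list[np.ndarray]:
        out, start = [], 0
        for kb in self.branch_sizes:
            out.append(X[:, start:start + kb])
            start += kb
        return out

    def _forward(self, Xn: np.ndarray, cache: bool = False):
        layers = self._layers()
        acts = []
        zs = []
        for i, Xb in enumerate(self._split(Xn)):
            z1 = Xb @ layers[2 * i].theta.T + layers[2 * i].bias
            a1 = np.maximum(z1, 0.0)
            z2 = a1 @ layers[2 * i + 1].theta.T + layers[2 * i + 1].bias
            a2 = np.maximum(z2, 0.0)
            acts.append((Xb, a1, a2))
            zs.append((z1, z2))
        head = layers[-1]
        ac = np.concatenate([a[2] for a in acts], axis=1)
        out = ac @ head.theta.T + head.bias
        if cache:
            return out, (acts, zs, ac)
        return out

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Percent estimates for feature rows laid out per sensor branch.

        Output is (rows, f), unclamped; :meth:`forecast` clamps to [0, 1).
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != sum(self.branch_sizes):
            raise ValueError(
                f"feature width {X.shape[1]} does not match branches {self.branch_sizes}"
            )
        return self._forward(self.normalize(X))

    def forecast(self, recent_window: np.ndarray) -> np.ndarray:
        """Forward pass clamped to valid percent values [0, 1).

        The first output column is the estimate for t+1, i.e. 10 ms ahead.
        """
        out = self.forward(recent_window)
        return np.clip(out, 0.0, np.nextafter(1.0, 0.0))

    # ----------------------------------------------------------- backward
    def gradients(self, Xn: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, float]:
        """Analytic gradient of the half-MSE cost w.r.t. the flat parameter vector.

        ``Xn`` must already be normalised (training standardises once up front).
        """
        N = Xn.shape[0]
        out, (acts, zs, ac) = self._forward(Xn, cache=True)
        diff = out - Y
        cost = float(np.sum(diff ** 2) / (2 * N))

        grad = np.empty_like(self.params)
        g = lambda i: grad[self._offsets[i]:self._offsets[i + 1]].reshape(self._shapes[i])
        layers = self._layers()

        d_out = diff / N
        head_idx = len(self._shapes) // 2 - 1
        g(2 * head_idx)[...] = d_out.T @ ac
        g(2 * head_idx + 1)[...] = d_out.sum(axis=0)
        d_ac = d_out @ layers[head_idx].theta

        start = 0
        for i, kb in enumerate(self.branch_sizes):
            Xb, a1, a2 = acts[i]
            z1, z2 = zs[i]
            d_a2 = d_ac[:, self.hidden * i:self.hidden * (i + 1)]
            d_z2 = d_a2 * (z2 > 0)
            g(4 * i + 2)[...] = d_z2.T @ a1
            g(4 * i + 3)[...] = d_z2.sum(axis=0)
            d_a1 = d_z2 @ layers[2 * i + 1].theta
            d_z1 = d_a1 * (z1 > 0)
            g(4 * i)[...] = d_z1.T @ Xb
            g(4 * i + 1)[...] = d_z1.sum(axis=0)
            start += kb
        return grad, cost

    # ----------------------------------------------------------- training
    def save(self, path: str | Path) -> None:
        """Serialise shapes, parameters, normalisation stats and delay config."""
        cfg = self.delay_config
        np.savez(
            Path(path), params=self.params, mu=self.mu, sigma=self.sigma,
            branch_sizes=np.array(self.branch_sizes), f=self.f,
            hidden=self.hidden, seed=self.seed,
            delay=np.array([cfg.d, cfg.delta, cfg.base, cfg.f]) if cfg else np.empty(0),
        )

    @classmethod
    def load(cls, path: str | Path) -> "EDFNN":
        with np.load(Path(path)) as z:
            model = cls(list(z["branch_sizes"]), f=int(z["f"]),
                        hidden=int(z["hidden"]), seed=int(z["seed"]))
            model.params[...] = z["params"]
            model.mu, model.sigma = z["mu"], z["sigma"]
            if z["delay"].size:
                d, delta, base, f = z["delay"]
                model.delay_config = DelayConfig(int(d), int(delta), float(base), int(f))
        return model


def train(
    model: EDFNN,
    dataset: EmbeddedDataset,
    cfg: TrainConfig = TrainConfig(),
    validation: EmbeddedDataset | None = None,
) -> LearningCurve:
    """Minibatch gradient training of the ED-FNN, fully reproducible by seed.

    Fits the per-channel standardisation on the training split, then runs
    ``cfg.epochs`` shuffled minibatch passes of Adam (or plain gradient
    descent). Returns the per-epoch cost curve; raises
    :class:`TrainingDivergenceError` the first epoch the cost goes non-finite.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    model.fit_normalization(dataset.Xd, dataset.feature_channels)
    Xn = model.normalize(dataset.Xd)
    Y = dataset.Yd
    Xv = model.normalize(validation.Xd) if validation is not None else None

    rng = np.random.default_rng(cfg.seed)
    theta = model.params
    adam = cfg.optimizer == "adam"
    if adam:
        m = np.zeros_like(theta)
        v = np.zeros_like(theta)
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0
    N, B = len(Xn), cfg.batch_size
    train_curve = np.empty(cfg.epochs)
    val_curve = np.empty(cfg.epochs) if validation is not None else None

    for epoch in range(cfg.epochs):
        perm = rng.permutation(N)
        Xp, Yp = Xn[perm], Y[perm]
        total = 0.0
        for i in range(0, N, B):
            xb, yb = Xp[i:i + B], Yp[i:i + B]
            grad, cost = model.gradients(xb, yb)
            total += cost * len(xb)
            if adam:
                step += 1
                m *= b1
                m += (1 - b1) * grad
                v *= b2
                v += (1 - b2) * grad * grad
                mhat = m / (1 - b1 ** step)
                vhat = v / (1 - b2 ** step)
                theta -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
            else:
                theta -= cfg.learning_rate * grad
        train_curve[epoch] = total / N
        if not np.isfinite(train_curve[epoch]):
            raise TrainingDivergenceError(epoch)
        if val_curve is not None:
            val_curve[epoch] = mse_cost(model._forward(Xv), validation.Yd)
    return LearningCurve(train=train_curve, validation=val_curve)
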