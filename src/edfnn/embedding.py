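"""Delay embedding with exponential windows.

A feed-forward network has no notion of time, so the percent estimator is fed
a short history of the signal: for an anchor sample ``t`` the full delayed row
holds the window ``X[t-d] .. X[t]`` for every channel, and the forecast target
holds the next ``f`` percent labels ``y[t+1] .. y[t+f]``.

The exponential window thins that history to the lags ``round(b^k)`` for
``k = 0..δ`` — dense near the present, sparse in the past — which keeps both
fast percent changes and the slow cycle trend visible to the model while
shrinking the input width.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, InsufficientDataError
from .segmentation import PercentLabeledDataset


@dataclass(frozen=True)
class DelayConfig:
    """Delay-embedding hyper-parameters.

    d : past-window length in samples (the full delay depth).
    delta : number of exponents in the exponential window (lags b^0..b^delta).
    base : exponential base b > 1; 1.6 spreads six lags over ~100 ms.
    f : forecast horizon in samples (targets y[t+1..t+f]).
    """

    d: int = 16
    delta: int = 5
    base: float = 1.6
    f: int = 1

    def __post_init__(self):
        if self.d < 1:
            raise ConfigurationError("d must be >= 1")
        if self.delta < 0:
            raise ConfigurationError("delta must be >= 0")
        if self.base <= 1:
            raise ConfigurationError("base must be > 1")
        if self.f < 1:
            raise ConfigurationError("f must be >= 1")
        if int(np.rint(self.base ** self.delta)) > self.d:
            raise ConfigurationError(
                f"exponential window round({self.base}^{self.delta}) exceeds delay depth d={self.d}"
            )

    @property
    def offsets(self) -> np.ndarray:
        return exponential_offsets(self.delta, self.base)

    @property
    def lags(self) -> np.ndarray:
        """Offsets plus lag 0 (the current sample is always a feature)."""
        return np.concatenate([[0], self.offsets])


@dataclass
class EmbeddedDataset:
    """Delay-embedded inputs and forecast targets.

    ``Xd`` is laid out channel-major: for channel c and lag index j the column
    is ``c * n_lags + j``, so the first ``3 * n_lags`` columns belong to the
    gyroscope branch and the next ``3 * n_lags`` to the accelerometer branch.
    ``t_index`` gives each row's anchor sample t in the source matrix;
    ``cycle_ids`` (when present) gives the gait cycle containing each anchor.
    """

    Xd: np.ndarray
    Yd: np.ndarray
    t_index: np.ndarray
    lags: np.ndarray
    n_channels: int
    cycle_ids: np.ndarray | None = None
    config: DelayConfig | None = None

    def __len__(self) -> int:
        return len(self.Xd)

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    @property
    def k(self) -> int:
        """Feature count per row."""
        return self.Xd.shape[1]

    @property
    def feature_channels(self) -> np.ndarray:
        """Channel index of every feature column (for per-channel scaling)."""
        return np.repeat(np.arange(self.n_channels), self.n_lags)

    def branch_slices(self, channels_per_sensor: int = 3) -> list[slice]:
        """Column slices of the per-sensor feature blocks (gyro, accel)."""
        w = channels_per_sensor * self.n_lags
        n_branches = self.n_channels // channels_per_sensor
        return [slice(i * w, (i + 1) * w) for i in range(n_branches)]

    def save(self, path) -> None:
        """Serialise to a portable ``.npz`` container with the config echoed."""
        cfg = self.config
        np.savez(
            path, Xd=self.Xd, Yd=self.Yd, t_index=self.t_index, lags=self.lags,
            n_channels=self.n_channels,
            cycle_ids=self.cycle_ids if self.cycle_ids is not None else np.empty(0, int),
            delay=np.array([cfg.d, cfg.delta, cfg.base, cfg.f]) if cfg else np.empty(0),
        )

    @classmethod
    def load(cls, path) -> "EmbeddedDataset":
        with np.load(path) as z:
            cfg = None
            if z["delay"].size:
                d, delta, base, f = z["delay"]
                cfg = DelayConfig(int(d), int(delta), float(base), int(f))
            ids = z["cycle_ids"]
            return cls(
                Xd=z["Xd"], Yd=z["Yd"], t_index=z["t_index"], lags=z["lags"],
                n_channels=int(z["n_channels"]),
                cycle_ids=ids if ids.size else None, config=cfg,
            )

    def subset(self, rows: np.ndarray) -> "EmbeddedDataset":
        return EmbeddedDataset(
            Xd=self.Xd[rows], Yd=self.Yd[rows], t_index=self.t_index[rows],
            lags=self.lags, n_channels=self.n_channels,
            cycle_ids=None if self.cycle_ids is None else self.cycle_ids[rows],
            config=self.config,
        )


def exponential_offsets(delta: int, base: float) -> np.ndarray:
    """Sorted unique past lags {round(base^k) : k = 0..delta}.

    Offset o means "sample t − o". With base 1.6 and delta 5 the lags are
    {1, 2, 3, 4, 7, 10}: denser near the present than in the past.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    if base <= 1:
        raise ValueError("base must be > 1")
    raw = np.rint(base ** np.arange(delta + 1)).astype(int)
    return np.unique(raw)


def _embed(X: np.ndarray, lags: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    # (rows, n_lags, C) gathered then flattened channel-major to (rows, C*n_lags)
    win = X[anchors[:, None] - lags[None, :], :]
    return win.transpose(0, 2, 1).reshape(len(anchors), -1)


def _as_matrix(X) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    if isinstance(X, PercentLabeledDataset):
        ids = X.cycle_ids if len(X.cycle_ids) else None
        return np.asarray(X.X, dtype=float), np.asarray(X.y, dtype=float), ids
    return np.atleast_2d(np.asarray(X, dtype=float)), None, None


def build_delayed_tensor(
    X, cfg: DelayConfig, y: np.ndarray | None = None
) -> EmbeddedDataset:
    """Full-window delay embedding: every lag 0..d for every channel.

    Anchors run t = d .. T−1−f, giving exactly T − f − d rows. ``X`` may be a
    plain (T, C) matrix or a :class:`PercentLabeledDataset` (whose labels then
    provide the targets).
    """
    M, y_ds, ids = _as_matrix(X)
    if y is None:
        y = y_ds
    T = M.shape[0]
    if T <= cfg.d + cfg.f:
        raise InsufficientDataError(f"need T > d + f = {cfg.d + cfg.f}, got T = {T}")
    anchors = np.arange(cfg.d, T - cfg.f)
    lags = np.arange(cfg.d + 1)
    Xd = _embed(M, lags, anchors)
    Yd = build_targets(y, anchors, cfg.f) if y is not None else np.empty((len(anchors), 0))
    return EmbeddedDataset(
        Xd=Xd, Yd=Yd, t_index=anchors, lags=lags, n_channels=M.shape[1],
        cycle_ids=None if ids is None else ids[anchors], config=cfg,
    )


def apply_exponential_window(
    X, cfg: DelayConfig, y: np.ndarray | None = None,
    drop_boundary_spanning: bool = False,
) -> EmbeddedDataset:
    """Exponentially windowed delay embedding.

    Per anchor t the features are the current sample X[t] plus X[t−o] for each
    exponential offset o, concatenated channel-major, so the feature count is
    k = (|offsets| + 1) · C. Identical to selecting the exponential-lag
    columns out of :func:`build_delayed_tensor`.

    ``drop_boundary_spanning`` removes rows whose window reaches across a gait
    cycle boundary (requires cycle ids); by default windows may span the reset.
    """
    M, y_ds, ids = _as_matrix(X)
    if y is None:
        y = y_ds
    T = M.shape[0]
    if T <= cfg.d + cfg.f:
        raise InsufficientDataError(f"need T > d + f = {cfg.d + cfg.f}, got T = {T}")
    lags = cfg.lags
    if lags.max() > cfg.d:
        raise ConfigurationError("exponential window exceeds delay depth d")
    anchors = np.arange(cfg.d, T - cfg.f)
    Xd = _embed(M, lags, anchors)
    Yd = build_targets(y, anchors, cfg.f) if y is not None else np.empty((len(anchors), 0))
    cyc = None if ids is None else ids[anchors]
    ds = EmbeddedDataset(
        Xd=Xd, Yd=Yd, t_index=anchors, lags=lags, n_channels=M.shape[1],
        cycle_ids=cyc, config=cfg,
    )
    if drop_boundary_spanning:
        if ids is None:
            raise ConfigurationError("drop_boundary_spanning requires cycle ids")
        keep = ids[anchors] == ids[anchors - lags.max()]
        ds = ds.subset(np.flatnonzero(keep))
    return ds


def build_targets(y: np.ndarray, anchors: np.ndarray, f: int) -> np.ndarray:
    """Forecast targets: the row for anchor t is [y_{t+1}, …, y_{t+f}].

    At a cycle boundary the targets simply continue into the next cycle's
    small percent values, preserving the sawtooth the model must learn.
    """
    y = np.asarray(y, dtype=float)
    anchors = np.asarray(anchors, dtype=int)
    if f < 1:
        raise ValueError("f must be >= 1")
    if anchors.size and (anchors.min() < 0 or anchors.max() + f >= len(y)):
        raise ValueError("anchor + f out of bounds")
    return y[anchors[:, None] + np.arange(1, f + 1)[None, :]]
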