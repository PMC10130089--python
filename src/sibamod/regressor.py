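"""Residual-MADRS regressor: an MLP ensemble with a fixed ν-derived shape.

Architecture: input ν -> hidden (8ν, 4ν, 2ν) with rectifier units -> scalar
output.  Training minimizes MSE by plain minibatch SGD (batch 16, learning
rate 0.01 by default) for at most 500 epochs with early stopping (patience 5
epochs on validation loss, min-delta 0, best-validation weights restored).
To smooth out initialization luck and local minima the fit is repeated 11
times and the per-day prediction is the element-wise median of the members.

Everything is plain numpy and fully deterministic given the seeds: member i
of an ensemble draws its initialization and minibatch shuffles from its own
``default_rng(base_seed + i)`` stream, so training the eleven members jointly
(as one stacked tensor, which is how this module does it) or one at a time
gives bitwise-identical models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class MlpSpec:
    """Network and training-loop constants derived from the signature size ν."""

    input_dim: int
    hidden_dims: tuple[int, int, int]
    output_dim: int = 1
    batch_size: int = 16
    max_epochs: int = 500
    patience: int = 5
    repeats: int = 11
    learning_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        expected = (8 * self.input_dim, 4 * self.input_dim, 2 * self.input_dim)
        if tuple(self.hidden_dims) != expected:
            raise ValueError(f"hidden_dims must be {expected}, got {self.hidden_dims}")
        if self.output_dim != 1:
            raise ValueError("output must be scalar")

    @property
    def dims(self) -> tuple[int, ...]:
        return (self.input_dim, *self.hidden_dims, self.output_dim)


def build_spec(nu: int, **overrides) -> MlpSpec:
    """MlpSpec for signature size ν: dims exactly (ν, 8ν, 4ν, 2ν, 1)."""
    if nu < 1:
        raise ValueError(f"nu must be >= 1, got {nu}")
    return MlpSpec(input_dim=nu, hidden_dims=(8 * nu, 4 * nu, 2 * nu), **overrides)


@dataclass
class MlpModel:
    """One trained member: layer weights/biases plus its training trace."""

    spec: MlpSpec
    seed: int
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    epochs_run: int = 0
    best_val_loss: float = float("nan")

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.input_dim:
            raise ValueError(f"X must have {self.spec.input_dim} columns, got shape {X.shape}")
        a = X
        last = len(self.weights) - 1
        for l, (W, b) in enumerate(zip(self.weights, self.biases)):
            a = a @ W + b
            if l < last:
                np.maximum(a, 0.0, out=a)
        return a.ravel()


@dataclass
class TrainedEnsemble:
    """The repeated fits; identical data and validation split, independent
    initializations (seeds base_seed+0 .. base_seed+repeats-1)."""

    spec: MlpSpec
    base_seed: int
    members: list[MlpModel] = field(default_factory=list)

    @property
    def seeds(self) -> list[int]:
        return [m.seed for m in self.members]

    @property
    def val_losses(self) -> list[float]:
        return [m.best_val_loss for m in self.members]


def _check_xy(X, y, name: str, input_dim: int) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != input_dim:
        raise ValueError(f"{name}: expected {input_dim} columns, got shape {X.shape}")
    if X.shape[0] != y.size:
        raise ValueError(f"{name}: X and y row counts differ")
    return X, y


def _train_members(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: MlpSpec,
    seeds: Sequence[int],
) -> list[MlpModel]:
    """Train one MLP per seed, jointly as stacked (k, ., .) tensors."""
    X, y = _check_xy(X_train, y_train, "train", spec.input_dim)
    Xv, yv = _check_xy(X_val, y_val, "val", spec.input_dim)
    n = X.shape[0]
    if n < 1:
        raise ValueError("empty training set")
    if Xv.shape[0] < 1:
        raise ValueError("empty validation set")
    k = len(seeds)
    dims = spec.dims
    rngs = [np.random.default_rng(int(s)) for s in seeds]

    # He-normal initialization per member, drawn layer by layer from the
    # member's own stream (same draw order as a solo fit).
    W = [np.empty((k, dims[l], dims[l + 1])) for l in range(len(dims) - 1)]
    b = [np.zeros((k, dims[l + 1])) for l in range(len(dims) - 1)]
    for i, rng in enumerate(rngs):
        for l in range(len(dims) - 1):
            W[l][i] = rng.normal(0.0, np.sqrt(2.0 / dims[l]), size=(dims[l], dims[l + 1]))

    n_layers = len(W)
    lr = spec.learning_rate
    bs = min(spec.batch_size, n)
    n_batches = (n + bs - 1) // bs
    yv_t = np.broadcast_to(yv[None, :], (k, yv.size))

    best_loss = np.full(k, np.inf)
    stall = np.zeros(k, dtype=int)
    active = np.ones(k, dtype=bool)
    stop_epoch = np.zeros(k, dtype=int)
    best_W = [[Wl[i].copy() for Wl in W] for i in range(k)]
    best_b = [[bl[i].copy() for bl in b] for i in range(k)]

    # A member can diverge under plain SGD (its loss goes non-finite); early
    # stopping then freezes its best finite-loss weights and the ensemble
    # median absorbs the member, so overflow in a diverged member is benign.
    np_err = np.seterr(over="ignore", invalid="ignore")
    for epoch in range(1, spec.max_epochs + 1):
        perms = np.stack([rng.permutation(n) for rng in rngs])  # (k, n)
        for bi in range(n_batches):
            idx = perms[:, bi * bs : (bi + 1) * bs]  # (k, B)
            a = X[idx]  # (k, B, d_in)
            yb = y[idx][..., None]  # (k, B, 1)
            acts = [a]
            for l in range(n_layers):
                a = a @ W[l] + b[l][:, None, :]
                if l < n_layers - 1:
                    a = np.maximum(a, 0.0)
                acts.append(a)
            delta = (2.0 / idx.shape[1]) * (acts[-1] - yb)  # dMSE/dout
            for l in range(n_layers - 1, -1, -1):
                gW = acts[l].transpose(0, 2, 1) @ delta
                gb = delta.sum(axis=1)
                if l > 0:
                    delta = (delta @ W[l].transpose(0, 2, 1)) * (acts[l] > 0)
                W[l] -= lr * gW
                b[l] -= lr * gb

        # per-member validation loss
        a = np.broadcast_to(Xv[None], (k, *Xv.shape))
        for l in range(n_layers):
            a = a @ W[l] + b[l][:, None, :]
            if l < n_layers - 1:
                a = np.maximum(a, 0.0)
        val_loss = np.mean((a[..., 0] - yv_t) ** 2, axis=1)  # (k,)

        improved = active & (val_loss < best_loss)
        for i in np.flatnonzero(improved):
            best_loss[i] = val_loss[i]
            stall[i] = 0
            best_W[i] = [Wl[i].copy() for Wl in W]
            best_b[i] = [bl[i].copy() for bl in b]
        stalled = active & ~improved
        stall[stalled] += 1
        newly_stopped = active & (stall >= spec.patience)
        stop_epoch[newly_stopped] = epoch
        active[newly_stopped] = False
        if not active.any():
            break
    np.seterr(**np_err)
    stop_epoch[active] = spec.max_epochs

    return [
        MlpModel(
            spec=spec,
            seed=int(seeds[i]),
            weights=best_W[i],
            biases=best_b[i],
            epochs_run=int(stop_epoch[i]),
            best_val_loss=float(best_loss[i]),
        )
        for i in range(k)
    ]


def fit_once(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: MlpSpec,
    seed: int,
) -> MlpModel:
    """Train a single MLP; deterministic given ``seed``."""
    return _train_members(X_train, y_train, X_val, y_val, spec, [seed])[0]


def train_ensemble(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    spec: MlpSpec,
    base_seed: int,
) -> TrainedEnsemble:
    """Train ``spec.repeats`` members with seeds base_seed+0 .. +(repeats-1)."""
    seeds = [int(base_seed) + i for i in range(spec.repeats)]
    members = _train_members(X_train, y_train, X_val, y_val, spec, seeds)
    return TrainedEnsemble(spec=spec, base_seed=int(base_seed), members=members)


def predict_median(ensemble: TrainedEnsemble, X: np.ndarray) -> np.ndarray:
    """Element-wise median of the member predictions."""
    if not ensemble.members:
        raise ValueError("ensemble has no members")
    preds = np.stack([m.predict(X) for m in ensemble.members])
    return np.median(preds, axis=0)
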