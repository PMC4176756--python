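"""From-scratch back-propagation neural network for barrier regression.

One hidden layer of sigmoid neurons, a sigmoid output neuron, and *online*
training: weights are corrected immediately after each object with

    dw[j,k] = phi * delta[j] * out[k]  +  gamma * dw[j,k]_previous

where phi is the learning rate, gamma the momentum, delta the
back-propagated error term of the receiving neuron and out[k] the emitting
neuron's output (a fixed bias input of 1 contributes the (n+1)-th term of
every net input).  One epoch is one full pass over the training objects in
dataset order (optionally a seeded shuffle per epoch).

Because the output neuron is a sigmoid, inputs are min-max scaled to [0,1]
on the training ranges and targets to [0.1, 0.9] (kept off the asymptotes);
predictions are mapped back to kcal/mol.  The error function is the sum of
squared errors with the 1/2 factor absorbed into the delta definition.

Everything is plain numpy and deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np


class DivergenceError(RuntimeError):
    """A weight or activation became non-finite during training."""


@dataclass(frozen=True)
class TrainingConfig:
    """Training schedule for the back-propagation network.

    Defaults follow the reference protocol for this problem family:
    five hidden neurons, learning rate 0.6, momentum 0.2, 4800 epochs.
    ``decay``, when given as ``(phi_final, gamma_final)``, ramps both
    parameters linearly from their start values across the epochs.
    """

    n_hidden: int = 5
    learning_rate: float = 0.6
    momentum: float = 0.2
    epochs: int = 4800
    seed: int = 0
    shuffle: bool = False
    decay: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class NetworkWeights:
    """Weight tensors; the last column of each layer is the bias weight."""

    w_hidden: np.ndarray  # (n_hidden, n_in + 1)
    w_out: np.ndarray     # (n_out, n_hidden + 1)
    dw_hidden_prev: np.ndarray
    dw_out_prev: np.ndarray

    @property
    def n_in(self) -> int:
        return self.w_hidden.shape[1] - 1

    @property
    def n_hidden(self) -> int:
        return self.w_hidden.shape[0]


def init_network(n_in: int, config: TrainingConfig, n_out: int = 1) -> NetworkWeights:
    """Seeded uniform U[-0.5, 0.5] initial weights, zero momentum store."""
    if n_in < 1:
        raise ValueError("n_in must be >= 1")
    rng = np.random.default_rng(config.seed)
    w_hidden = rng.uniform(-0.5, 0.5, size=(config.n_hidden, n_in + 1))
    w_out = rng.uniform(-0.5, 0.5, size=(n_out, config.n_hidden + 1))
    return NetworkWeights(
        w_hidden=w_hidden,
        w_out=w_out,
        dw_hidden_prev=np.zeros_like(w_hidden),
        dw_out_prev=np.zeros_like(w_out),
    )


def _sigmoid(net: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-net))


def forward(
    net: NetworkWeights, x: np.ndarray
) -> Tuple[np.ndarray, Tuple[np.ndarray, np.ndarray]]:
    """One forward pass; returns (output vector, (hidden, output) activations)."""
    x = np.asarray(x, dtype=float).ravel()
    if x.size != net.n_in:
        raise ValueError(f"expected input of length {net.n_in}, got {x.size}")
    x_aug = np.append(x, 1.0)
    hidden = _sigmoid(net.w_hidden @ x_aug)
    h_aug = np.append(hidden, 1.0)
    out = _sigmoid(net.w_out @ h_aug)
    return out, (hidden, out)


@dataclass
class Scaler:
    """Min-max scaling fitted on training ranges.

    Inputs map to [0,1]; targets to [0.1, 0.9].  The same affine map is
    applied to query values outside the training range (they may leave the
    unit interval and are flagged).
    """

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float
    y_max: float
    y_lo: float = 0.1
    y_hi: float = 0.9

    def scale_x(self, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scaled = (X - self.x_min) / (self.x_max - self.x_min)
        out_of_range = np.any((scaled < 0.0) | (scaled > 1.0), axis=1)
        return scaled, out_of_range

    def scale_y(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return self.y_lo + (y - self.y_min) / (self.y_max - self.y_min) * (
            self.y_hi - self.y_lo
        )

    def unscale_y(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.y_min + (t - self.y_lo) / (self.y_hi - self.y_lo) * (
            self.y_max - self.y_min
        )


def scale_fit(X: np.ndarray, y: np.ndarray) -> Scaler:
    """Fit min-max scaling parameters on the training data."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    x_min, x_max = X.min(axis=0), X.max(axis=0)
    degenerate = np.nonzero(x_max - x_min == 0.0)[0]
    if degenerate.size:
        raise ValueError(f"constant input column(s) {degenerate.tolist()}: cannot scale")
    if y.max() == y.min():
        # Constant target: centre it mid-range with a unit-wide band.
        return Scaler(x_min, x_max, float(y.min()) - 0.5, float(y.max()) + 0.5)
    return Scaler(x_min, x_max, float(y.min()), float(y.max()))


def train(
    net: NetworkWeights,
    X_scaled: np.ndarray,
    y_scaled: np.ndarray,
    config: TrainingConfig,
) -> Tuple[NetworkWeights, List[float]]:
    """Online back-propagation training; returns the net and per-epoch RMS.

    Weights are updated after every object; the per-epoch trace records the
    RMS error over the training set (scaled units) at the end of each
    epoch.  Non-finite weights abort with :class:`DivergenceError`.
    """
    X = np.atleast_2d(np.asarray(X_scaled, dtype=float))
    y = np.atleast_2d(np.asarray(y_scaled, dtype=float))
    if y.shape[0] == 1 and X.shape[0] != 1:
        y = y.T
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("X and y disagree on the number of objects")
    X_aug = np.hstack([X, np.ones((n, 1))])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5F5E1]))
    trace: List[float] = []

    phi0, gam0 = config.learning_rate, config.momentum
    for epoch in range(config.epochs):
        if config.decay is not None and config.epochs > 1:
            frac = epoch / (config.epochs - 1)
            phi = phi0 + (config.decay[0] - phi0) * frac
            gam = gam0 + (config.decay[1] - gam0) * frac
        else:
            phi, gam = phi0, gam0
        order = rng.permutation(n) if config.shuffle else range(n)
        for i in order:
            x_aug = X_aug[i]
            hidden = _sigmoid(net.w_hidden @ x_aug)
            h_aug = np.append(hidden, 1.0)
            out = _sigmoid(net.w_out @ h_aug)

            delta_out = (y[i] - out) * out * (1.0 - out)
            delta_hidden = (
                hidden * (1.0 - hidden) * (net.w_out[:, :-1].T @ delta_out)
            )
            dw_out = phi * np.outer(delta_out, h_aug) + gam * net.dw_out_prev
            dw_hidden = phi * np.outer(delta_hidden, x_aug) + gam * net.dw_hidden_prev
            net.w_out += dw_out
            net.w_hidden += dw_hidden
            net.dw_out_prev = dw_out
            net.dw_hidden_prev = dw_hidden
        if not (np.all(np.isfinite(net.w_out)) and np.all(np.isfinite(net.w_hidden))):
            raise DivergenceError(f"non-finite weights at epoch {epoch}")
        preds = _sigmoid(
            np.hstack([_sigmoid(X_aug @ net.w_hidden.T), np.ones((n, 1))])
            @ net.w_out.T
        )
        trace.append(float(np.sqrt(np.mean((y - preds) ** 2))))
    return net, trace


@dataclass
class BPANNModel:
    """A trained network bundled with its scaler and training trace."""

    net: NetworkWeights
    scaler: Scaler
    config: TrainingConfig
    rms_trace: List[float] = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict barriers in original units (kcal/mol)."""
        Xs, _ = self.scaler.scale_x(X)
        n = Xs.shape[0]
        X_aug = np.hstack([Xs, np.ones((n, 1))])
        hidden = _sigmoid(X_aug @ self.net.w_hidden.T)
        out = _sigmoid(np.hstack([hidden, np.ones((n, 1))]) @ self.net.w_out.T)
        return self.scaler.unscale_y(out.ravel())

    def to_dict(self) -> dict:
        return {
            "w_hidden": self.net.w_hidden.tolist(),
            "w_out": self.net.w_out.tolist(),
            "x_min": self.scaler.x_min.tolist(),
            "x_max": self.scaler.x_max.tolist(),
            "y_min": self.scaler.y_min,
            "y_max": self.scaler.y_max,
            "config": {
                "n_hidden": self.config.n_hidden,
                "learning_rate": self.config.learning_rate,
                "momentum": self.config.momentum,
                "epochs": self.config.epochs,
                "seed": self.config.seed,
                "shuffle": self.config.shuffle,
                "decay": list(self.config.decay) if self.config.decay else None,
            },
            "final_rms_scaled": self.rms_trace[-1] if self.rms_trace else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BPANNModel":
        cfg = d["config"]
        config = TrainingConfig(
            n_hidden=cfg["n_hidden"],
            learning_rate=cfg["learning_rate"],
            momentum=cfg["momentum"],
            epochs=cfg["epochs"],
            seed=cfg["seed"],
            shuffle=cfg["shuffle"],
            decay=tuple(cfg["decay"]) if cfg.get("decay") else None,
        )
        w_hidden = np.asarray(d["w_hidden"], dtype=float)
        w_out = np.asarray(d["w_out"], dtype=float)
        net = NetworkWeights(
            w_hidden=w_hidden,
            w_out=w_out,
            dw_hidden_prev=np.zeros_like(w_hidden),
            dw_out_prev=np.zeros_like(w_out),
        )
        scaler = Scaler(
            x_min=np.asarray(d["x_min"], dtype=float),
            x_max=np.asarray(d["x_max"], dtype=float),
            y_min=d["y_min"],
            y_max=d["y_max"],
        )
        return cls(net=net, scaler=scaler, config=config)


def fit_bpann(X: np.ndarray, y: np.ndarray, config: TrainingConfig) -> BPANNModel:
    """Scale, initialise and train a network on (X, y) in original units."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    scaler = scale_fit(X, y)
    Xs, _ = scaler.scale_x(X)
    ys = scaler.scale_y(y)
    net = init_network(X.shape[1], config)
    net, trace = train(net, Xs, ys[:, None], config)
    return BPANNModel(net=net, scaler=scaler, config=config, rms_trace=trace)


def loo_rms(X: np.ndarray, y: np.ndarray, config: TrainingConfig) -> float:
    """Leave-one-out RMS error (kcal/mol) with a fresh net per fold.

    Fold i trains on all-but-i with a seed derived deterministically from
    ``config.seed`` and i, then predicts object i.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 objects")
    errors = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        fold_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        fold_cfg = TrainingConfig(
            n_hidden=config.n_hidden,
            learning_rate=config.learning_rate,
            momentum=config.momentum,
            epochs=config.epochs,
            seed=fold_seed,
            shuffle=config.shuffle,
            decay=config.decay,
        )
        try:
            model = fit_bpann(X[mask], y[mask], fold_cfg)
        except DivergenceError as exc:
            raise DivergenceError(f"fold {i}: {exc}") from exc
        errors[i] = model.predict(X[i : i + 1])[0] - y[i]
    return float(np.sqrt(np.mean(errors**2)))
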