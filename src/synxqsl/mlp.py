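"""A small fully-connected regressor trained with Adam.

ReLU hidden layers, linear scalar output, mean-squared-error loss,
inverted dropout on the hidden activations, seeded minibatch shuffling.
Fixed-epoch training (no early stopping) so that epoch count and batch
size behave as genuine hyperparameter-grid dimensions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP"]


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class MLP:
    """Single-output multi-layer perceptron on NumPy.

    Parameters
    ----------
    in_dim
        Number of input features.
    n_hidden
        Number of hidden (mid) layers.
    units
        Units per hidden layer.
    dropout
        Dropout ratio applied to every hidden activation during training.
    seed
        Seeds both weight initialisation and minibatch shuffling/dropout.
    standardize
        Z-score the inputs with statistics estimated from the training
        set (decay-ratio features at different b-values differ in spread
        by orders of magnitude; standardisation equalises the first-layer
        gradient scales).
    z_clip
        Optional symmetric clip on the standardised inputs.  Decay
        ratios whose (noisy) baseline is near zero can reach z-scores in
        the hundreds; saturating them bounds their leverage on the MSE
        loss.  A clip of ~2 is a no-op on uniform-like clean features
        (whose |z| never exceeds sqrt(3)) and only truncates
        noise-driven tails.
    """

    def __init__(
        self,
        in_dim: int,
        n_hidden: int,
        units: int,
        dropout: float = 0.0,
        seed: int = 0,
        standardize: bool = True,
        z_clip: float | None = None,
    ) -> None:
        if not 0.0 <= dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if z_clip is not None and z_clip <= 0:
            raise ValueError("z_clip must be positive")
        self.in_dim = int(in_dim)
        self.n_hidden = int(n_hidden)
        self.units = int(units)
        self.dropout = float(dropout)
        self.seed = int(seed)
        self.standardize = bool(standardize)
        self.z_clip = None if z_clip is None else float(z_clip)
        self.x_mean = np.zeros(self.in_dim)
        self.x_scale = np.ones(self.in_dim)
        rng = np.random.default_rng(seed)
        dims = [self.in_dim] + [self.units] * self.n_hidden + [1]
        # He-normal initialisation for the ReLU stack
        self.W = [
            rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
            for i in range(len(dims) - 1)
        ]
        self.b = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        self._train_rng = rng

    @property
    def n_weights(self) -> int:
        """Total number of trainable scalars (tie-break criterion)."""
        return sum(w.size for w in self.W) + sum(b.size for b in self.b)

    # -- inference -------------------------------------------------------
    def predict(self, X: np.ndarray, batch: int = 200_000) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.in_dim:
            raise ValueError(
                f"expected (n, {self.in_dim}) features, got {X.shape}"
            )
        out = np.empty(X.shape[0])
        for lo in range(0, X.shape[0], batch):
            a = (X[lo : lo + batch] - self.x_mean) / self.x_scale
            if self.z_clip is not None:
                a = np.clip(a, -self.z_clip, self.z_clip)
            for W, b in zip(self.W[:-1], self.b[:-1]):
                a = _relu(a @ W + b)
            out[lo : lo + batch] = (a @ self.W[-1] + self.b[-1]).ravel()
        return out

    # -- training --------------------------------------------------------
    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        lr: float = 1e-3,
    ) -> "MLP":
        """Minimise MSE over fixed epochs with Adam (beta1=0.9, beta2=0.999)."""
        X = np.ascontiguousarray(X, dtype=float)
        y = np.ascontiguousarray(y, dtype=float).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y length mismatch")
        if X.shape[1] != self.in_dim:
            raise ValueError(
                f"expected (n, {self.in_dim}) features, got {X.shape}"
            )
        if self.standardize:
            self.x_mean = X.mean(axis=0)
            scale = X.std(axis=0)
            self.x_scale = np.where(scale > 0, scale, 1.0)
            X = (X - self.x_mean) / self.x_scale
        if self.z_clip is not None:
            X = np.clip(X, -self.z_clip, self.z_clip)
        n = X.shape[0]
        bs = min(int(batch_size), n)
        rng = self._train_rng
        mW = [np.zeros_like(w) for w in self.W]
        vW = [np.zeros_like(w) for w in self.W]
        mb = [np.zeros_like(b) for b in self.b]
        vb = [np.zeros_like(b) for b in self.b]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for _ in range(int(epochs)):
            order = rng.permutation(n)
            for lo in range(0, n, bs):
                idx = order[lo : lo + bs]
                xb, yb = X[idx], y[idx]
                # forward with cached activations
                acts = [xb]
                masks = []
                a = xb
                for W, b in zip(self.W[:-1], self.b[:-1]):
                    a = _relu(a @ W + b)
                    if self.dropout > 0.0:
                        keep = 1.0 - self.dropout
                        m = (rng.random(a.shape) < keep) / keep
                        a = a * m
                        masks.append(m)
                    acts.append(a)
                pred = (a @ self.W[-1] + self.b[-1]).ravel()
                err = pred - yb
                if not np.all(np.isfinite(err)):
                    raise FloatingPointError(
                        "training diverged (non-finite loss) with "
                        f"n_hidden={self.n_hidden}, units={self.units}, "
                        f"dropout={self.dropout}, batch_size={bs}"
                    )
                # backward
                grad = (2.0 / xb.shape[0]) * err[:, None]
                gW = [None] * len(self.W)
                gb = [None] * len(self.b)
                delta = grad
                for li in range(len(self.W) - 1, -1, -1):
                    gW[li] = acts[li].T @ delta
                    gb[li] = delta.sum(axis=0)
                    if li > 0:
                        delta = delta @ self.W[li].T
                        if self.dropout > 0.0:
                            delta = delta * masks[li - 1]
                        delta = delta * (acts[li] > 0)
                # Adam update
                t += 1
                c1 = 1.0 - beta1**t
                c2 = 1.0 - beta2**t
                for li in range(len(self.W)):
                    mW[li] = beta1 * mW[li] + (1 - beta1) * gW[li]
                    vW[li] = beta2 * vW[li] + (1 - beta2) * gW[li] ** 2
                    self.W[li] -= lr * (mW[li] / c1) / (np.sqrt(vW[li] / c2) + eps)
                    mb[li] = beta1 * mb[li] + (1 - beta1) * gb[li]
                    vb[li] = beta2 * vb[li] + (1 - beta2) * gb[li] ** 2
                    self.b[li] -= lr * (mb[li] / c1) / (np.sqrt(vb[li] / c2) + eps)
        return self

    # -- persistence ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {
            "x_mean": self.x_mean,
            "x_scale": self.x_scale,
        }
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            state[f"W{i}"] = w
            state[f"b{i}"] = b
        return state

    @classmethod
    def from_state(
        cls,
        state: dict[str, np.ndarray],
        n_hidden: int,
        dropout: float,
        seed: int,
        z_clip: float | None = None,
    ) -> "MLP":
        w0 = state["W0"]
        units = w0.shape[1] if n_hidden > 0 else 0
        obj = cls(
            w0.shape[0], n_hidden, units, dropout=dropout, seed=seed,
            z_clip=z_clip,
        )
        obj.W = [np.asarray(state[f"W{i}"]) for i in range(n_hidden + 1)]
        obj.b = [np.asarray(state[f"b{i}"]) for i in range(n_hidden + 1)]
        obj.x_mean = np.asarray(state["x_mean"])
        obj.x_scale = np.asarray(state["x_scale"])
        return obj
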