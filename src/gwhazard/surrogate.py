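"""RBF and MLP surrogate networks predicting pollution/risk indices from
element concentrations.

Both families are single-hidden-layer networks over min-max normalized
covariates, trained on a random train/test split:

* RBF: hidden units are Gaussian responses to distances from cluster
  centers, normalized across units to sum to one per case (a softmax over
  the radial responses); the output layer is identity with weights fitted
  by linear least squares on standardized targets.  Learning is two-stage:
  unsupervised center placement (k-means) then a supervised linear solve.
* MLP: hyperbolic-tangent activations in the hidden *and* output layers,
  targets mapped to an adjusted-normalized range (correction 0.02) so the
  bounded output can reach them, trained in batch mode by scaled conjugate
  gradient (SCG) with early stopping on test-partition error.

The hidden-unit count is selected automatically by minimizing
test-partition error over a configured grid.  Everything draws from one
seeded generator, so (seed, config, data) fully determine the model.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

log = logging.getLogger("gwhazard")

__all__ = [
    "Partition",
    "partition",
    "RBFConfig",
    "MLPConfig",
    "SurrogateModel",
    "train_rbf",
    "train_mlp",
    "predict",
    "importance",
]


# ---------------------------------------------------------------------------
# data partitioning


@dataclass(frozen=True)
class Partition:
    train_ids: tuple
    test_ids: tuple
    train_fraction: float
    seed: int

    def labels(self, ids: Sequence) -> np.ndarray:
        train = set(self.train_ids)
        return np.array(["train" if i in train else "test" for i in ids])


def partition(sample_ids: Sequence, train_fraction: float, seed: int) -> Partition:
    """Random train/test assignment without replacement, reproducible from seed."""
    ids = list(sample_ids)
    n = len(ids)
    if n < 4:
        raise ValueError(f"need at least 4 ids, got {n}")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty partition for n={n}")
    order = np.random.default_rng(seed).permutation(n)
    train = tuple(ids[i] for i in sorted(order[:n_train]))
    test = tuple(ids[i] for i in sorted(order[n_train:]))
    return Partition(train, test, train_fraction, seed)


# ---------------------------------------------------------------------------
# rescaling


def _minmax_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng = np.where(rng == 0.0, 1.0, rng)  # constant feature -> maps to 0
    return lo, rng


def _target_forward(Y: np.ndarray, scaler: Mapping) -> np.ndarray:
    kind = scaler["kind"]
    if kind == "standardized":
        return (Y - np.asarray(scaler["mean"])) / np.asarray(scaler["sd"])
    if kind == "adjusted_normalized":
        lo = np.asarray(scaler["min"])
        rng = np.asarray(scaler["range"])
        eps = scaler["correction"]
        return 2.0 * (Y - lo + eps * rng) / ((1.0 + 2.0 * eps) * rng) - 1.0
    raise ValueError(f"unknown target scaler {kind!r}")


def _target_inverse(Ys: np.ndarray, scaler: Mapping) -> np.ndarray:
    kind = scaler["kind"]
    if kind == "standardized":
        return Ys * np.asarray(scaler["sd"]) + np.asarray(scaler["mean"])
    if kind == "adjusted_normalized":
        lo = np.asarray(scaler["min"])
        rng = np.asarray(scaler["range"])
        eps = scaler["correction"]
        return (Ys + 1.0) / 2.0 * (1.0 + 2.0 * eps) * rng + lo - eps * rng
    raise ValueError(f"unknown target scaler {kind!r}")


def _fit_standardizer(Y: np.ndarray) -> dict:
    sd = Y.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return {"kind": "standardized", "mean": Y.mean(axis=0), "sd": sd}


def _fit_adjusted_normalizer(Y: np.ndarray, correction: float = 0.02) -> dict:
    lo = Y.min(axis=0)
    rng = Y.max(axis=0) - lo
    rng = np.where(rng == 0.0, 1.0, rng)
    return {"kind": "adjusted_normalized", "min": lo, "range": rng,
            "correction": correction}


# ---------------------------------------------------------------------------
# model container


@dataclass
class SurrogateModel:
    """A trained RBF or MLP network with all rescaling parameters.

    The prediction pipeline applies the stored input normalization, the
    network forward pass, and the inverse target rescaling, so predictions
    are on the original index scale.  All rescaling parameters were
    computed on the training partition only.
    """

    family: str
    input_names: list[str]
    output_names: list[str]
    x_min: np.ndarray
    x_range: np.ndarray
    target_scaler: dict
    hidden_units: int
    params: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    # -- forward passes -----------------------------------------------------

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_min) / self.x_range

    def hidden_activations(self, X: np.ndarray) -> np.ndarray:
        """RBF only: normalized Gaussian responses (rows sum to one)."""
        if self.family != "rbf":
            raise ValueError("hidden_activations is defined for RBF models")
        Z = self._normalize(X)
        centers = self.params["centers"]
        widths = self.params["widths"]
        d2 = ((Z[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        s = -d2 / (2.0 * widths ** 2)
        s -= s.max(axis=1, keepdims=True)
        u = np.exp(s)
        return u / u.sum(axis=1, keepdims=True)

    def _forward_scaled(self, X: np.ndarray) -> np.ndarray:
        if self.family == "rbf":
            u = self.hidden_activations(X)
            return np.hstack([u, np.ones((len(u), 1))]) @ self.params["weights"]
        if self.family == "mlp":
            Z = self._normalize(X)
            a1 = np.tanh(Z @ self.params["w1"] + self.params["b1"])
            return np.tanh(a1 @ self.params["w2"] + self.params["b2"])
        raise ValueError(f"unknown family {self.family!r}")

    def predict(self, X) -> pd.DataFrame:
        """Predict targets on the original scale; columns aligned by name."""
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.input_names if c not in X.columns]
            if missing:
                raise ValueError(f"missing input columns {missing}")
            index = X.index
            Xa = X[self.input_names].to_numpy(dtype=float)
        else:
            Xa = np.asarray(X, dtype=float)
            index = pd.RangeIndex(len(Xa))
        Yh = _target_inverse(self._forward_scaled(Xa), self.target_scaler)
        return pd.DataFrame(Yh, columns=self.output_names, index=index)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        def enc(v):
            if isinstance(v, np.ndarray):
                return {"__array__": v.tolist()}
            if isinstance(v, np.generic):
                return v.item()
            if isinstance(v, dict):
                return {k: enc(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [enc(x) for x in v]
            return v

        payload = {
            "family": self.family,
            "input_names": self.input_names,
            "output_names": self.output_names,
            "x_min": enc(self.x_min),
            "x_range": enc(self.x_range),
            "target_scaler": enc(self.target_scaler),
            "hidden_units": self.hidden_units,
            "params": enc(self.params),
            "metadata": enc(self.metadata),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SurrogateModel":
        def dec(v):
            if isinstance(v, dict):
                if "__array__" in v:
                    return np.asarray(v["__array__"], dtype=float)
                return {k: dec(x) for k, x in v.items()}
            if isinstance(v, list):
                return [dec(x) for x in v]
            return v

        d = json.loads(text)
        return cls(
            family=d["family"],
            input_names=list(d["input_names"]),
            output_names=list(d["output_names"]),
            x_min=np.asarray(d["x_min"]["__array__"], dtype=float),
            x_range=np.asarray(d["x_range"]["__array__"], dtype=float),
            target_scaler=dec(d["target_scaler"]),
            hidden_units=int(d["hidden_units"]),
            params=dec(d["params"]),
            metadata=dec(d["metadata"]),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def predict(model: SurrogateModel, X) -> pd.DataFrame:
    """Functional alias for :meth:`SurrogateModel.predict`."""
    return model.predict(X)


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class RBFConfig:
    hidden_range: tuple[int, ...] | None = None  # None -> 2..min(20, n_train/2)
    hidden_units: int | None = None              # fixed count bypasses the grid
    overlap: float = 1.0                         # width multiplier
    kmeans_n_init: int = 4


@dataclass(frozen=True)
class MLPConfig:
    hidden_range: tuple[int, ...] | None = None
    hidden_units: int | None = None
    max_epochs: int = 1000
    correction: float = 0.02
    eval_every: int = 10      # test-error checks, in SCG iterations
    patience: int = 12        # stop after this many checks without improvement
    sigma0: float = 5e-5      # SCG finite-difference step scale
    lambda0: float = 5e-7     # SCG initial scale (regulation) parameter
    grad_tol: float = 1e-10


def _grid(hidden_range: tuple[int, ...] | None, hidden_units: int | None,
          n_train: int) -> list[int]:
    if hidden_units is not None:
        return [int(hidden_units)]
    if hidden_range is not None:
        return [int(h) for h in hidden_range]
    hi = max(2, min(20, n_train // 2))
    return list(range(2, hi + 1))


def _split_arrays(X: pd.DataFrame, Y: pd.DataFrame, part: Partition):
    Xtr = X.loc[list(part.train_ids)].to_numpy(dtype=float)
    Xte = X.loc[list(part.test_ids)].to_numpy(dtype=float)
    Ytr = Y.loc[list(part.train_ids)].to_numpy(dtype=float)
    Yte = Y.loc[list(part.test_ids)].to_numpy(dtype=float)
    if Ytr.ndim == 1:
        Ytr, Yte = Ytr[:, None], Yte[:, None]
    return Xtr, Xte, Ytr, Yte


# ---------------------------------------------------------------------------
# RBF training


def _rbf_widths(centers: np.ndarray, train_Z: np.ndarray, overlap: float) -> np.ndarray:
    k = len(centers)
    if k == 1:
        d = np.linalg.norm(train_Z - centers[0], axis=1)
        w = d.mean() if d.mean() > 0 else 1.0
        return np.array([w * overlap])
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    m = min(2, k - 1)
    nearest = np.sort(d, axis=1)[:, :m]
    widths = nearest.mean(axis=1) * overlap
    floor = widths[widths > 0].min() if (widths > 0).any() else 1.0
    return np.where(widths <= 0, floor, widths)


def _fit_rbf_single(Xtr: np.ndarray, Ytr_s: np.ndarray, h: int,
                    x_min: np.ndarray, x_range: np.ndarray,
                    overlap: float, n_init: int, seed: int) -> dict[str, np.ndarray]:
    Ztr = (Xtr - x_min) / x_range
    h = min(h, len(Ztr))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # k-means warns when clusters end up empty
        km = KMeans(n_clusters=h, n_init=n_init, random_state=seed).fit(Ztr)
    centers = km.cluster_centers_
    widths = _rbf_widths(centers, Ztr, overlap)
    d2 = ((Ztr[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    s = -d2 / (2.0 * widths ** 2)
    s -= s.max(axis=1, keepdims=True)
    u = np.exp(s)
    u /= u.sum(axis=1, keepdims=True)
    A = np.hstack([u, np.ones((len(u), 1))])
    W, *_ = np.linalg.lstsq(A, Ytr_s, rcond=None)
    return {"centers": centers, "widths": widths, "weights": W}


def train_rbf(X: pd.DataFrame, Y: pd.DataFrame, part: Partition,
              config: RBFConfig = RBFConfig(), seed: int = 0) -> SurrogateModel:
    """Two-stage RBF training with automatic hidden-unit selection.

    Stage 1 places centers by k-means on the normalized training inputs
    and sets per-center widths from the mean distance to the two nearest
    other centers (times ``config.overlap``); stage 2 solves the identity
    output layer by least squares on standardized targets.  The unit count
    minimizing test-partition SOSE (original scale) over the grid wins.
    """
    Y = Y.to_frame() if isinstance(Y, pd.Series) else Y
    Xtr, Xte, Ytr, Yte = _split_arrays(X, Y, part)
    x_min, x_range = _minmax_fit(Xtr)
    scaler = _fit_standardizer(Ytr)
    Ytr_s = _target_forward(Ytr, scaler)

    ss = np.random.SeedSequence([seed, 0x5bf])
    kmeans_seeds = [int(s) % (2 ** 31) for s in
                    ss.generate_state(len(_grid(config.hidden_range,
                                                config.hidden_units, len(Xtr))))]
    best = None
    trace = []
    for h, kseed in zip(_grid(config.hidden_range, config.hidden_units, len(Xtr)),
                        kmeans_seeds):
        params = _fit_rbf_single(Xtr, Ytr_s, h, x_min, x_range,
                                 config.overlap, config.kmeans_n_init, kseed)
        model = SurrogateModel(
            family="rbf", input_names=list(X.columns),
            output_names=list(Y.columns), x_min=x_min, x_range=x_range,
            target_scaler=scaler, hidden_units=len(params["centers"]),
            params=params)
        err = float(np.sum((model.predict(Xte).to_numpy() - Yte) ** 2))
        trace.append({"hidden_units": int(len(params["centers"])), "test_sose": err})
        if best is None or err < best[0]:
            best = (err, model)
    err, model = best
    model.metadata = {
        "seed": seed, "partition_seed": part.seed,
        "train_fraction": part.train_fraction,
        "n_train": len(Xtr), "n_test": len(Xte),
        "overlap": config.overlap, "selection": trace,
        "test_sose": err,
    }
    return model


# ---------------------------------------------------------------------------
# MLP training (batch scaled conjugate gradient)


class _MLPNet:
    """Parameter bookkeeping for the tanh-tanh single-hidden-layer network."""

    def __init__(self, d: int, h: int, t: int, rng: np.random.Generator):
        self.shapes = {"w1": (d, h), "b1": (h,), "w2": (h, t), "b2": (t,)}
        a1 = np.sqrt(6.0 / (d + h))
        a2 = np.sqrt(6.0 / (h + t))
        self.theta = np.concatenate([
            rng.uniform(-a1, a1, size=d * h),
            np.zeros(h),
            rng.uniform(-a2, a2, size=h * t),
            np.zeros(t),
        ])

    def unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        i = 0
        for name, shape in self.shapes.items():
            size = int(np.prod(shape))
            out[name] = theta[i:i + size].reshape(shape)
            i += size
        return out

    def loss_grad(self, theta: np.ndarray, Z: np.ndarray,
                  T: np.ndarray) -> tuple[float, np.ndarray]:
        p = self.unpack(theta)
        a1 = np.tanh(Z @ p["w1"] + p["b1"])
        out = np.tanh(a1 @ p["w2"] + p["b2"])
        diff = out - T
        loss = 0.5 * float(np.sum(diff ** 2))
        d_out = diff * (1.0 - out ** 2)
        g_w2 = a1.T @ d_out
        g_b2 = d_out.sum(axis=0)
        d_a1 = (d_out @ p["w2"].T) * (1.0 - a1 ** 2)
        g_w1 = Z.T @ d_a1
        g_b1 = d_a1.sum(axis=0)
        grad = np.concatenate([g_w1.ravel(), g_b1, g_w2.ravel(), g_b2])
        return loss, grad


def _scg(net: _MLPNet, theta: np.ndarray, Z: np.ndarray, T: np.ndarray,
         Zte: np.ndarray, Yte: np.ndarray, scaler: Mapping,
         cfg: MLPConfig) -> tuple[np.ndarray, dict]:
    """Scaled conjugate gradient (Moller 1993) with test-error early stopping.

    Returns the parameter vector with the lowest test-partition error seen
    and a small metadata dict (epochs run, convergence flag).
    """
    n_params = theta.size
    lam = cfg.lambda0
    lam_bar = 0.0
    f, grad = net.loss_grad(theta, Z, T)
    r = -grad
    p = r.copy()
    success = True
    delta = 0.0
    s = np.zeros_like(theta)

    def test_error(th: np.ndarray) -> float:
        pp = net.unpack(th)
        a1 = np.tanh(Zte @ pp["w1"] + pp["b1"])
        out = np.tanh(a1 @ pp["w2"] + pp["b2"])
        return float(np.sum((_target_inverse(out, scaler) - Yte) ** 2))

    best_theta = theta.copy()
    best_test = test_error(theta)
    stale = 0
    converged = False
    k = 0
    for k in range(1, cfg.max_epochs + 1):
        p_norm2 = float(p @ p)
        if p_norm2 == 0.0:
            converged = True
            break
        if success:
            sigma = cfg.sigma0 / np.sqrt(p_norm2)
            _, grad_plus = net.loss_grad(theta + sigma * p, Z, T)
            s = (grad_plus - grad) / sigma
            delta = float(p @ s)
        delta += (lam - lam_bar) * p_norm2
        if delta <= 0.0:
            lam_bar = 2.0 * (lam - delta / p_norm2)
            delta = -delta + lam * p_norm2
            lam = lam_bar
        mu = float(p @ r)
        alpha = mu / delta
        f_new, grad_new = net.loss_grad(theta + alpha * p, Z, T)
        comparison = 2.0 * delta * (f - f_new) / mu ** 2
        if comparison >= 0.0:
            theta = theta + alpha * p
            f = f_new
            grad = grad_new
            r_new = -grad
            lam_bar = 0.0
            success = True
            if k % n_params == 0:
                p = r_new.copy()
            else:
                beta = (float(r_new @ r_new) - float(r_new @ r)) / mu
                p = r_new + beta * p
            r = r_new
            if comparison >= 0.75:
                lam = max(lam * 0.25, 1e-15)
        else:
            lam_bar = lam
            success = False
        if comparison < 0.25:
            lam = lam + delta * (1.0 - comparison) / p_norm2
        if float(r @ r) < cfg.grad_tol:
            converged = True
            break
        if k % cfg.eval_every == 0:
            err = test_error(theta)
            if err < best_test - 1e-15:
                best_test = err
                best_theta = theta.copy()
                stale = 0
            else:
                stale += 1
                if stale >= cfg.patience:
                    break
    final_err = test_error(theta)
    if final_err < best_test:
        best_test = final_err
        best_theta = theta.copy()
    return best_theta, {"epochs": k, "converged": converged,
                        "test_sose": best_test}


def train_mlp(X: pd.DataFrame, Y: pd.DataFrame, part: Partition,
              config: MLPConfig = MLPConfig(), seed: int = 0) -> SurrogateModel:
    """Batch SCG training of the tanh-tanh MLP with unit-count selection.

    Targets are rescaled to the adjusted-normalized range (correction
    0.02), mapping the training span into (-1, 1) so the tanh output can
    reach it; the unit count minimizing test-partition SOSE on the
    original scale wins.  Non-convergence within ``max_epochs`` returns
    the best parameters seen, flagged in the metadata.
    """
    Y = Y.to_frame() if isinstance(Y, pd.Series) else Y
    Xtr, Xte, Ytr, Yte = _split_arrays(X, Y, part)
    x_min, x_range = _minmax_fit(Xtr)
    scaler = _fit_adjusted_normalizer(Ytr, config.correction)
    Ttr = _target_forward(Ytr, scaler)
    Ztr = (Xtr - x_min) / x_range
    Zte = (Xte - x_min) / x_range

    grid = _grid(config.hidden_range, config.hidden_units, len(Xtr))
    ss = np.random.SeedSequence([seed, 0x31f])
    child_seeds = ss.spawn(len(grid))
    best = None
    trace = []
    for h, child in zip(grid, child_seeds):
        rng = np.random.default_rng(child)
        net = _MLPNet(Ztr.shape[1], h, Ttr.shape[1], rng)
        if config.max_epochs == 0:
            theta, info = net.theta, {"epochs": 0, "converged": False,
                                      "test_sose": np.inf}
            pp = net.unpack(theta)
            a1 = np.tanh(Zte @ pp["w1"] + pp["b1"])
            out = np.tanh(a1 @ pp["w2"] + pp["b2"])
            info["test_sose"] = float(np.sum((_target_inverse(out, scaler) - Yte) ** 2))
        else:
            theta, info = _scg(net, net.theta, Ztr, Ttr, Zte, Yte, scaler, config)
        trace.append({"hidden_units": h, **info})
        if best is None or info["test_sose"] < best[0]:
            best = (info["test_sose"], h, net.unpack(theta), info)
    err, h, params, info = best
    return SurrogateModel(
        family="mlp", input_names=list(X.columns), output_names=list(Y.columns),
        x_min=x_min, x_range=x_range, target_scaler=scaler, hidden_units=h,
        params={k: np.asarray(v) for k, v in params.items()},
        metadata={
            "seed": seed, "partition_seed": part.seed,
            "train_fraction": part.train_fraction,
            "n_train": len(Xtr), "n_test": len(Xte),
            "epochs": info["epochs"], "converged": info["converged"],
            "selection": trace, "test_sose": err,
        },
    )


# ---------------------------------------------------------------------------
# permutation importance


def importance(model: SurrogateModel, X: pd.DataFrame, Y: pd.DataFrame,
               n_repeats: int = 10, seed: int = 0) -> pd.Series:
    """Permutation-based predictor importance, normalized to sum to one.

    For each input column the error (SOSE) inflation when that column is
    shuffled is averaged over ``n_repeats`` permutations and over outputs;
    negative inflations are clipped at zero.  A column the model ignores
    (or a constant column) scores ~0.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    Y = Y.to_frame() if isinstance(Y, pd.Series) else Y
    Xa = X[model.input_names].to_numpy(dtype=float)
    Ya = Y[model.output_names].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    base = np.sum((model.predict(Xa).to_numpy() - Ya) ** 2, axis=0)
    scale = np.where(base == 0.0, 1.0, base)

    inflation = np.zeros(len(model.input_names))
    for j, name in enumerate(model.input_names):
        if np.all(Xa[:, j] == Xa[0, j]):
            warnings.warn(f"constant input column {name!r}: importance 0")
            continue
        infl = 0.0
        for _ in range(n_repeats):
            Xp = Xa.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            err = np.sum((model.predict(Xp).to_numpy() - Ya) ** 2, axis=0)
            # relative inflation per output, then averaged across outputs
            infl += float(np.mean((err - base) / scale))
        inflation[j] = max(infl / n_repeats, 0.0)

    total = inflation.sum()
    if total == 0.0:
        warnings.warn("no input permutation inflates the error; returning zeros")
        return pd.Series(inflation, index=model.input_names, name="importance")
    return pd.Series(inflation / total, index=model.input_names, name="importance")
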