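"""Neural classifiers for trigger identification and argument detection.

Both models are plain-numpy, CPU-only, and deterministic for a fixed
``random_state``: a feed-forward softmax network for token-level trigger
classification and a convolutional network (parallel filter widths, max
pooling over positions) for dependency-path relation classification.  Both
are trained with Adadelta and inverted dropout.

The estimators follow scikit-learn conventions (``get_params``/
``set_params``, ``fit``/``predict``/``predict_proba``, trailing-underscore
fitted attributes) and accept two kinds of input:

* dense arrays — a 2-D feature matrix for the feed-forward net, a 3-D
  (samples, rows, columns) stack for the CNN; or
* index arrays plus a :class:`VectorLayout`/:class:`MatrixLayout` and a
  :class:`~bioevent.representations.FeatureTables` — the features are then
  gathered from the embedding tables at each forward pass and the tables
  themselves receive gradient updates (their rows are model parameters),
  which is how the POS/distance/type tables are learned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

from .representations import FeatureTables

DENSE = "dense"


@dataclass
class VectorLayout:
    """Column plan of a 2-D input: ordered (table_key | "dense", n_cols) blocks.

    An index block of n columns contributes ``n * table_width`` input
    features (the looked-up rows, concatenated); a dense block passes its
    columns through unchanged.
    """

    blocks: list[tuple[str, int]]

    @property
    def n_input_cols(self) -> int:
        return sum(n for _, n in self.blocks)

    def width(self, tables: FeatureTables) -> int:
        total = 0
        for key, n in self.blocks:
            if key == DENSE:
                total += n
            else:
                total += n * tables.matrix(key).shape[1]
        return total


@dataclass
class MatrixLayout:
    """Row plan of a 3-D input: vertically stacked blocks of table rows.

    Each block spans ``n_cols`` matrix columns; ``tables_per_col`` names the
    table each column's row index points into (the word block mixes the
    word table with the type table at its two flanking columns).  All
    tables within a block must share one width.
    """

    n_cols: int
    blocks: list[list[str]] = field(default_factory=list)

    def n_rows(self, tables: FeatureTables) -> int:
        return sum(tables.matrix(block[0]).shape[1] for block in self.blocks)

    @property
    def n_input_cols(self) -> int:
        return self.n_cols * len(self.blocks)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _xent(probs: np.ndarray, y_idx: np.ndarray) -> float:
    return float(-np.mean(np.log(probs[np.arange(len(y_idx)), y_idx] + 1e-12)))


class _Adadelta:
    """Adadelta state for one parameter array (Zeiler's update rule)."""

    def __init__(self, shape, rho: float, eps: float):
        self.rho, self.eps = rho, eps
        self.eg = np.zeros(shape)
        self.edx = np.zeros(shape)

    def step(self, param: np.ndarray, grad: np.ndarray) -> None:
        self.eg = self.rho * self.eg + (1 - self.rho) * grad**2
        dx = -np.sqrt(self.edx + self.eps) / np.sqrt(self.eg + self.eps) * grad
        self.edx = self.rho * self.edx + (1 - self.rho) * dx**2
        param += dx


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _validate_classes(y: np.ndarray) -> np.ndarray:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"need at least 2 classes to train, got {classes.size}"
        )
    return classes


def _train_val_split(n: int, fraction: float, rng: np.random.Generator):
    order = rng.permutation(n)
    n_val = int(round(n * fraction))
    if n_val == 0 or n - n_val < 2:
        return order, np.array([], dtype=np.intp)
    return order[n_val:], order[:n_val]


class _BestWeights:
    """Snapshot/restore of model parameters and trainable table rows at the
    best validation epoch (early stopping with weight restoration)."""

    def __init__(self, tables: FeatureTables | None, table_keys: set[str]):
        self.tables = tables
        self.table_keys = table_keys
        self.params: list[np.ndarray] | None = None
        self.table_mats: dict[str, np.ndarray] = {}

    def snapshot(self, params: list[np.ndarray]) -> None:
        self.params = [p.copy() for p in params]
        if self.tables is not None:
            for key in self.table_keys:
                table = getattr(self.tables, key)
                if getattr(table, "trainable", False):
                    self.table_mats[key] = table.matrix.copy()

    def restore(self, params: list[np.ndarray]) -> None:
        if self.params is None:
            return
        for live, saved in zip(params, self.params):
            live[...] = saved
        if self.tables is not None:
            for key, saved in self.table_mats.items():
                getattr(self.tables, key).matrix[...] = saved


class _TableGradients:
    """Accumulates scatter gradients into embedding tables during a batch."""

    def __init__(self, tables: FeatureTables, rho: float, eps: float):
        self.tables = tables
        self.rho, self.eps = rho, eps
        self.grads: dict[str, np.ndarray] = {}
        self.opt: dict[str, _Adadelta] = {}

    def accumulate(self, key: str, idx: np.ndarray, values: np.ndarray) -> None:
        table = getattr(self.tables, key)
        if not getattr(table, "trainable", False):
            return
        if key not in self.grads:
            self.grads[key] = np.zeros_like(table.matrix)
        np.add.at(self.grads[key], idx, values)

    def apply(self) -> None:
        for key, grad in self.grads.items():
            table = getattr(self.tables, key)
            if key not in self.opt:
                self.opt[key] = _Adadelta(table.matrix.shape, self.rho, self.eps)
            self.opt[key].step(table.matrix, grad)
        self.grads.clear()


class FeedForwardClassifier(ClassifierMixin, BaseEstimator):
    """Multi-layer softmax classifier (ReLU hidden layers, Adadelta, dropout).

    Defaults follow the trigger-identification configuration: three hidden
    layers of 1000 units, batch size 512, dropout rate 0.2.

    Parameters
    ----------
    tables, layout : optional
        When given, ``X`` holds integer table indices (plus any dense
        columns) as described by ``layout``; embedding rows are gathered at
        forward time and, if ``update_tables``, trained along with the
        network weights.
    """

    def __init__(
        self,
        hidden_layers: int = 3,
        hidden_units: int = 1000,
        batch_size: int = 512,
        dropout: float = 0.2,
        epochs: int = 30,
        patience: int | None = 5,
        validation_fraction: float = 0.1,
        rho: float = 0.95,
        eps: float = 1e-6,
        random_state: int = 0,
        tables: FeatureTables | None = None,
        layout: VectorLayout | None = None,
        update_tables: bool = True,
    ):
        self.hidden_layers = hidden_layers
        self.hidden_units = hidden_units
        self.batch_size = batch_size
        self.dropout = dropout
        self.epochs = epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.rho = rho
        self.eps = eps
        self.random_state = random_state
        self.tables = tables
        self.layout = layout
        self.update_tables = update_tables

    # -- feature assembly ---------------------------------------------------

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError(f"expected a 2-D input array, got ndim={X.ndim}")
        if self.layout is not None and X.shape[1] != self.layout.n_input_cols:
            raise ValueError(
                f"layout expects {self.layout.n_input_cols} columns, "
                f"got {X.shape[1]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        return X

    def _assemble(self, X: np.ndarray):
        """Gather table rows; returns (dense input, gather plan for backprop)."""
        if self.layout is None:
            return X, None
        parts, plan, col, out = [], [], 0, 0
        for key, n in self.layout.blocks:
            if key == DENSE:
                parts.append(X[:, col : col + n])
                out += n
            else:
                idx = X[:, col : col + n].astype(np.intp)
                mat = self.tables.matrix(key)
                width = mat.shape[1]
                parts.append(mat[idx].reshape(len(X), n * width))
                plan.append((key, idx, out, n, width))
                out += n * width
            col += n
        return np.hstack(parts), plan

    # -- forward / backward -------------------------------------------------

    def _forward(self, inp, rng=None):
        acts, masks = [inp], []
        h = inp
        for i in range(self.hidden_layers):
            h = np.maximum(h @ self.weights_[i] + self.biases_[i], 0.0)
            if rng is not None and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1 - self.dropout)
                h = h * mask
                masks.append(mask)
            acts.append(h)
        probs = _softmax(h @ self.weights_[-1] + self.biases_[-1])
        return probs, acts, masks

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = _validate_classes(y)
        self.n_features_in_ = X.shape[1]
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.asarray([class_to_idx[c] for c in y], dtype=np.intp)

        rng = np.random.default_rng(self.random_state)
        input_dim = (
            self.layout.width(self.tables) if self.layout is not None
            else X.shape[1]
        )
        sizes = (
            [input_dim]
            + [self.hidden_units] * self.hidden_layers
            + [len(self.classes_)]
        )
        self.weights_ = [
            _glorot(rng, sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)
        ]
        self.biases_ = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        opt = [_Adadelta(w.shape, self.rho, self.eps) for w in self.weights_]
        opt_b = [_Adadelta(b.shape, self.rho, self.eps) for b in self.biases_]
        table_grads = (
            _TableGradients(self.tables, self.rho, self.eps)
            if self.layout is not None and self.update_tables
            else None
        )

        train_idx, val_idx = _train_val_split(
            len(X),
            self.validation_fraction if self.patience is not None else 0.0,
            rng,
        )
        self.history_ = {"train_loss": [], "val_loss": []}
        best_val, since_best = np.inf, 0
        best = _BestWeights(
            self.tables if self.layout is not None else None,
            {key for key, _ in (self.layout.blocks if self.layout else [])
             if key != DENSE},
        )
        for epoch in range(self.epochs):
            order = train_idx[rng.permutation(len(train_idx))]
            losses = []
            for lo in range(0, len(order), self.batch_size):
                batch = order[lo : lo + self.batch_size]
                inp, plan = self._assemble(X[batch])
                probs, acts, masks = self._forward(inp, rng)
                yb = y_idx[batch]
                losses.append(_xent(probs, yb) * len(batch))

                delta = probs.copy()
                delta[np.arange(len(yb)), yb] -= 1.0
                delta /= len(yb)
                grads_w, grads_b = [None] * len(self.weights_), [None] * len(self.biases_)
                for layer in range(len(self.weights_) - 1, -1, -1):
                    grads_w[layer] = acts[layer].T @ delta
                    grads_b[layer] = delta.sum(axis=0)
                    if layer > 0:
                        delta = delta @ self.weights_[layer].T
                        if masks:
                            delta *= masks[layer - 1]
                        delta *= acts[layer] > 0
                    elif table_grads is not None:
                        dinp = delta @ self.weights_[0].T
                        for key, idx, out, n, width in plan:
                            vals = dinp[:, out : out + n * width].reshape(
                                len(batch), n, width
                            )
                            table_grads.accumulate(key, idx, vals)
                for layer in range(len(self.weights_)):
                    opt[layer].step(self.weights_[layer], grads_w[layer])
                    opt_b[layer].step(self.biases_[layer], grads_b[layer])
                if table_grads is not None:
                    table_grads.apply()
            self.history_["train_loss"].append(sum(losses) / max(len(order), 1))

            if len(val_idx):
                val_probs = self._predict_proba_raw(X[val_idx])
                val_loss = _xent(val_probs, y_idx[val_idx])
                self.history_["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val, since_best = val_loss, 0
                    best.snapshot(self.weights_ + self.biases_)
                elif self.patience is not None:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        best.restore(self.weights_ + self.biases_)
        self.n_epochs_ = len(self.history_["train_loss"])
        return self

    def _predict_proba_raw(self, X: np.ndarray) -> np.ndarray:
        inp, _ = self._assemble(X)
        probs, _, _ = self._forward(inp, rng=None)
        return probs

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "weights_"):
            raise ValueError("estimator is not fitted")
        X = self._check_X(X)
        return self._predict_proba_raw(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


class PathCNNClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional relation classifier over dependency-path matrices.

    Parallel convolution filters of widths 3/5/7 slide along the column
    (path-position) axis over the full row depth; max pooling over positions
    gives a fixed-width representation regardless of path length, followed
    by a 1000-unit ReLU layer and a softmax output.  Defaults follow the
    argument-detection configuration (batch 128, dropout 0.2).
    """

    def __init__(
        self,
        filter_widths: tuple[int, ...] = (3, 5, 7),
        n_filters: int = 100,
        hidden_units: int = 1000,
        batch_size: int = 128,
        dropout: float = 0.2,
        epochs: int = 30,
        patience: int | None = 5,
        validation_fraction: float = 0.1,
        rho: float = 0.95,
        eps: float = 1e-6,
        random_state: int = 0,
        tables: FeatureTables | None = None,
        layout: MatrixLayout | None = None,
        update_tables: bool = True,
    ):
        self.filter_widths = filter_widths
        self.n_filters = n_filters
        self.hidden_units = hidden_units
        self.batch_size = batch_size
        self.dropout = dropout
        self.epochs = epochs
        self.patience = patience
        self.validation_fraction = validation_fraction
        self.rho = rho
        self.eps = eps
        self.random_state = random_state
        self.tables = tables
        self.layout = layout
        self.update_tables = update_tables

    @property
    def pooled_width_(self) -> int:
        return len(self.filter_widths) * self.n_filters

    # -- input handling -----------------------------------------------------

    def _check_X(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.layout is None:
            if X.ndim != 3:
                raise ValueError(
                    f"expected 3-D (samples, rows, cols) input, got ndim={X.ndim}"
                )
        else:
            if X.ndim != 2 or X.shape[1] != self.layout.n_input_cols:
                raise ValueError(
                    f"layout expects 2-D input with {self.layout.n_input_cols} "
                    f"columns"
                )
        if not np.all(np.isfinite(X)):
            raise ValueError("input contains non-finite values")
        return X

    def _assemble(self, X: np.ndarray):
        """Build the 3-D feature stack from index columns (or pass through)."""
        if self.layout is None:
            return X, None
        n, n_cols = len(X), self.layout.n_cols
        rows = self.layout.n_rows(self.tables)
        M = np.empty((n, rows, n_cols))
        plan, r0 = [], 0
        for b, block in enumerate(self.layout.blocks):
            width = self.tables.matrix(block[0]).shape[1]
            xcols_base = b * n_cols
            by_table: dict[str, list[int]] = {}
            for c, key in enumerate(block):
                if self.tables.matrix(key).shape[1] != width:
                    raise ValueError(
                        f"table {key} width mismatch within matrix block"
                    )
                by_table.setdefault(key, []).append(c)
            for key, cols in by_table.items():
                idx = X[:, [xcols_base + c for c in cols]].astype(np.intp)
                M[:, r0 : r0 + width, cols] = self.tables.matrix(key)[
                    idx
                ].transpose(0, 2, 1)
                plan.append((key, idx, r0, width, cols))
            r0 += width
        return M, plan

    # -- forward / backward -------------------------------------------------

    def _pad_cols(self, M: np.ndarray) -> np.ndarray:
        """Zero-pad short inputs so every filter width fits (paths shorter
        than the largest filter are padded with the padding column)."""
        need = max(self.filter_widths)
        if M.shape[2] >= need:
            return M
        pad = np.zeros((M.shape[0], M.shape[1], need - M.shape[2]))
        return np.concatenate([M, pad], axis=2)

    def _forward(self, M: np.ndarray, rng=None):
        n, rows, cols = M.shape
        pooled_parts, cache = [], []
        for k, w in enumerate(self.filter_widths):
            win = sliding_window_view(M, w, axis=2)  # (n, rows, P, w)
            P = win.shape[2]
            flat = win.transpose(0, 2, 1, 3).reshape(n, P, rows * w)
            z = flat @ self.filters_[k] + self.filter_biases_[k]
            a = np.maximum(z, 0.0)
            pooled = a.max(axis=1)
            arg = a.argmax(axis=1)
            pooled_parts.append(pooled)
            cache.append((flat, z, arg, P))
        h0 = np.hstack(pooled_parts)
        mask0 = mask1 = None
        if rng is not None and self.dropout > 0:
            mask0 = (rng.random(h0.shape) >= self.dropout) / (1 - self.dropout)
            h0 = h0 * mask0
        h1 = np.maximum(h0 @ self.dense_w_ + self.dense_b_, 0.0)
        if rng is not None and self.dropout > 0:
            mask1 = (rng.random(h1.shape) >= self.dropout) / (1 - self.dropout)
            h1 = h1 * mask1
        probs = _softmax(h1 @ self.out_w_ + self.out_b_)
        return probs, (h0, h1, mask0, mask1, cache)

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.classes_ = _validate_classes(y)
        class_to_idx = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.asarray([class_to_idx[c] for c in y], dtype=np.intp)

        rng = np.random.default_rng(self.random_state)
        if self.layout is None:
            rows = X.shape[1]
        else:
            rows = self.layout.n_rows(self.tables)
        self.n_rows_ = rows
        self.filters_ = [
            _glorot(rng, rows * w, self.n_filters) for w in self.filter_widths
        ]
        self.filter_biases_ = [np.zeros(self.n_filters) for _ in self.filter_widths]
        self.dense_w_ = _glorot(rng, self.pooled_width_, self.hidden_units)
        self.dense_b_ = np.zeros(self.hidden_units)
        self.out_w_ = _glorot(rng, self.hidden_units, len(self.classes_))
        self.out_b_ = np.zeros(len(self.classes_))

        params = (
            self.filters_
            + self.filter_biases_
            + [self.dense_w_, self.dense_b_, self.out_w_, self.out_b_]
        )
        opts = [_Adadelta(p.shape, self.rho, self.eps) for p in params]
        table_grads = (
            _TableGradients(self.tables, self.rho, self.eps)
            if self.layout is not None and self.update_tables
            else None
        )

        train_idx, val_idx = _train_val_split(
            len(X),
            self.validation_fraction if self.patience is not None else 0.0,
            rng,
        )
        self.history_ = {"train_loss": [], "val_loss": []}
        best_val, since_best = np.inf, 0
        best = _BestWeights(
            self.tables if self.layout is not None else None,
            {key for block in (self.layout.blocks if self.layout else [])
             for key in block},
        )
        nf = self.n_filters
        for epoch in range(self.epochs):
            order = train_idx[rng.permutation(len(train_idx))]
            losses = []
            for lo in range(0, len(order), self.batch_size):
                batch = order[lo : lo + self.batch_size]
                M, plan = self._assemble(X[batch])
                M = self._pad_cols(M)
                probs, (h0, h1, mask0, mask1, cache) = self._forward(M, rng)
                yb = y_idx[batch]
                losses.append(_xent(probs, yb) * len(batch))

                delta = probs.copy()
                delta[np.arange(len(yb)), yb] -= 1.0
                delta /= len(yb)
                g_out_w = h1.T @ delta
                g_out_b = delta.sum(axis=0)
                dh1 = delta @ self.out_w_.T
                if mask1 is not None:
                    dh1 *= mask1
                dh1 *= h1 > 0
                g_dense_w = h0.T @ dh1
                g_dense_b = dh1.sum(axis=0)
                dh0 = dh1 @ self.dense_w_.T
                if mask0 is not None:
                    dh0 *= mask0

                dM = np.zeros_like(M) if (plan or self.layout is None) else None
                g_filters, g_fbias = [], []
                for k, w in enumerate(self.filter_widths):
                    flat, z, arg, P = cache[k]
                    dpool = dh0[:, k * nf : (k + 1) * nf]
                    da = np.zeros((len(batch), P, nf))
                    np.put_along_axis(da, arg[:, None, :], dpool[:, None, :], axis=1)
                    dz = da * (z > 0)
                    g_filters.append(
                        flat.reshape(-1, rows * w).T @ dz.reshape(-1, nf)
                    )
                    g_fbias.append(dz.sum(axis=(0, 1)))
                    if dM is not None:
                        dflat = dz @ self.filters_[k].T
                        dwin = dflat.reshape(len(batch), P, rows, w)
                        for j in range(w):
                            dM[:, :, j : j + P] += dwin[:, :, :, j].transpose(
                                0, 2, 1
                            )

                grads = (
                    g_filters
                    + g_fbias
                    + [g_dense_w, g_dense_b, g_out_w, g_out_b]
                )
                for p, o, g in zip(params, opts, grads):
                    o.step(p, g)
                if table_grads is not None and plan is not None:
                    for key, idx, r0, width, cols in plan:
                        vals = dM[:, r0 : r0 + width, cols].transpose(0, 2, 1)
                        table_grads.accumulate(key, idx, vals)
                    table_grads.apply()
            self.history_["train_loss"].append(sum(losses) / max(len(order), 1))

            if len(val_idx):
                val_loss = _xent(
                    self._predict_proba_raw(X[val_idx]), y_idx[val_idx]
                )
                self.history_["val_loss"].append(val_loss)
                if val_loss < best_val - 1e-6:
                    best_val, since_best = val_loss, 0
                    best.snapshot(params)
                elif self.patience is not None:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        best.restore(params)
        self.n_epochs_ = len(self.history_["train_loss"])
        return self

    def _predict_proba_raw(self, X: np.ndarray) -> np.ndarray:
        out = []
        for lo in range(0, len(X), max(self.batch_size, 1)):
            M, _ = self._assemble(X[lo : lo + self.batch_size])
            M = self._pad_cols(M)
            probs, _ = self._forward(M, rng=None)
            out.append(probs)
        return np.vstack(out)

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "filters_"):
            raise ValueError("estimator is not fitted")
        X = self._check_X(X)
        if len(X) == 0:
            return np.zeros((0, len(self.classes_)))
        return self._predict_proba_raw(X)

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        if len(proba) == 0:
            return np.asarray([], dtype=self.classes_.dtype)
        return self.classes_[np.argmax(proba, axis=1)]
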