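"""Supervised MRL predictors.

Three model families, each a model class whose ``fit()`` returns a
results object with the estimates, diagnostics and a ``summary()``:

* :class:`ConvolutionalMRLRegression` -- a VGG-style convolutional
  network over one-hot sequences (blocks of two ReLU convolutions, a
  size/stride-2 max pool and dropout; filters double per block) trained
  with an MSE loss, Adam, and validation-loss early stopping.
* :class:`PositionalTrimerRegression` -- a linear model on binary
  (offset, 3-mer) indicators, solved by ridge with a tiny stabilizer.
* :class:`KmerOracleRegression` -- the independent design oracle:
  log2(1+count) k-mer features (k=2..6), Lasso feature selection on a
  seeded subset, then an unpenalized least-squares refit on the selected
  support.

Throughout, r^2 denotes the squared Pearson correlation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LinearRegression, Ridge

from .autodiff import Tensor
from .nnet import Adam, Conv1DSame, Dense, dropout, max_pool2
from .seqcore import (
    Architecture,
    encode_batch,
    kmer_feature_names,
    kmer_log_features,
    positional_3mer_features,
    scan_start_codons,
)

__all__ = [
    "CNNSpec",
    "TrainSplit",
    "make_split",
    "ConvolutionalMRLRegression",
    "ConvNetResults",
    "PositionalTrimerRegression",
    "PositionalTrimerResults",
    "KmerFilterSpec",
    "KmerOracleRegression",
    "KmerOracleResults",
    "evaluate_r2",
    "random_search_cnn",
]


# ---------------------------------------------------------------------------
# architecture spec and splits


@dataclass(frozen=True)
class CNNSpec:
    """Convolutional architecture family; ranges follow the tuned search space."""

    input_length: int = 25
    n_blocks: int = 2
    base_filters: int = 32
    kernel_size: int = 5
    conv_dropout: float = 0.1
    dense_units: int = 40
    dense_dropout: float = 0.1

    def __post_init__(self) -> None:
        if not 1 <= self.n_blocks <= 5:
            raise ValueError("n_blocks must be in [1, 5]")
        if not 2 <= self.kernel_size <= 7:
            raise ValueError("kernel_size must be in [2, 7]")
        if not 16 <= self.base_filters <= 128:
            raise ValueError("base_filters must be in [16, 128]")
        if not (0 <= self.conv_dropout <= 0.5 and 0 <= self.dense_dropout <= 0.5):
            raise ValueError("dropouts must be in [0, 0.5]")
        if not 10 <= self.dense_units <= 100:
            raise ValueError("dense_units must be in [10, 100]")

    def block_filters(self, block: int) -> int:
        """Filters in block b (1-based): base_filters * 2**(b-1)."""
        return self.base_filters * 2 ** (block - 1)


@dataclass(frozen=True)
class TrainSplit:
    """Depth-stratified split: deepest K_test variants test, next K_val
    validation, remainder training; ties broken by variant id."""

    train: pd.DataFrame
    validation: pd.DataFrame
    test: pd.DataFrame

    def __post_init__(self) -> None:
        sets = [set(self.train.index), set(self.validation.index), set(self.test.index)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("split partitions overlap")


def make_split(table: pd.DataFrame, k_test: int = 2000, k_val: int = 2000,
               min_reads: int | None = None) -> TrainSplit:
    """Sort by read depth (descending, ties by variant id) and cut.

    ``table`` is indexed by variant id with at least ``mrl`` and ``reads``
    columns; ``min_reads`` optionally re-applies the depth filter first.
    """
    df = table
    if min_reads is not None:
        df = df[df["reads"] >= min_reads]
    if len(df) <= k_test + k_val:
        raise ValueError(
            f"table has {len(df)} variants; need more than k_test+k_val={k_test + k_val}"
        )
    # stable mergesort on descending reads after an index sort gives the
    # deterministic (depth desc, id asc) order
    ordered = df.sort_index(kind="mergesort").sort_values(
        "reads", ascending=False, kind="mergesort"
    )
    return TrainSplit(
        test=ordered.iloc[:k_test],
        validation=ordered.iloc[k_test : k_test + k_val],
        train=ordered.iloc[k_test + k_val :],
    )


# ---------------------------------------------------------------------------
# convolutional model


class _ConvNet:
    """Parameter container + forward pass for the block architecture."""

    def __init__(self, spec: CNNSpec, rng: np.random.Generator):
        self.spec = spec
        self.convs: list[tuple[Conv1DSame, Conv1DSame]] = []
        c_in = 4
        length = spec.input_length
        for b in range(1, spec.n_blocks + 1):
            f = spec.block_filters(b)
            if length < 2:
                raise ValueError(
                    f"input length {spec.input_length} too short for {spec.n_blocks} pooling blocks"
                )
            self.convs.append((
                Conv1DSame(rng, c_in, f, spec.kernel_size),
                Conv1DSame(rng, f, f, spec.kernel_size),
            ))
            c_in = f
            length //= 2
        self.flat_dim = length * c_in
        self.dense = Dense(rng, self.flat_dim, spec.dense_units)
        self.head = Dense(rng, spec.dense_units, 1)

    @property
    def params(self) -> list[Tensor]:
        out = []
        for c1, c2 in self.convs:
            out += c1.params + c2.params
        return out + self.dense.params + self.head.params

    def forward(self, x: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        spec = self.spec
        h = x
        for c1, c2 in self.convs:
            h = c2(c1(h).relu()).relu()
            h = max_pool2(h)
            if training:
                h = dropout(h, spec.conv_dropout, rng, training)
        n = h.shape[0]
        h = h.reshape(n, self.flat_dim)
        h = self.dense(h).relu()
        if training:
            h = dropout(h, spec.dense_dropout, rng, training)
        return self.head(h).reshape(n)

    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        shapes = []
        for b, (c1, c2) in enumerate(self.convs, start=1):
            shapes.append((f"block{b}_conv1", tuple(c1.W.shape)))
            shapes.append((f"block{b}_conv2", tuple(c2.W.shape)))
            shapes.append((f"block{b}_pool", (2,)))
        shapes.append(("dense", tuple(self.dense.W.shape)))
        shapes.append(("output", tuple(self.head.W.shape)))
        return shapes


class ConvolutionalMRLRegression:
    """Convolutional MRL predictor built from sequences and measured MRLs.

    Parameters
    ----------
    sequences, mrl : training data (variable regions; left zero-padded to
        ``spec.input_length``).
    val_sequences, val_mrl : held-out data for early stopping.
    spec : CNNSpec architecture description.
    """

    def __init__(self, sequences: Sequence[str], mrl: Sequence[float],
                 val_sequences: Sequence[str], val_mrl: Sequence[float],
                 spec: CNNSpec = CNNSpec()):
        self.spec = spec
        self.X = encode_batch(sequences, spec.input_length)
        self.y = np.asarray(mrl, dtype=float)
        self.X_val = encode_batch(val_sequences, spec.input_length)
        self.y_val = np.asarray(val_mrl, dtype=float)
        if len(self.X) != len(self.y) or len(self.X_val) != len(self.y_val):
            raise ValueError("sequences and targets must have equal lengths")

    @classmethod
    def from_split(cls, split: TrainSplit, spec: CNNSpec = CNNSpec()) -> "ConvolutionalMRLRegression":
        return cls(split.train["sequence"], split.train["mrl"],
                   split.validation["sequence"], split.validation["mrl"], spec=spec)

    def fit(self, max_epochs: int = 50, patience: int = 5, batch_size: int = 128,
            lr: float = 1e-3, seed: int = 0) -> "ConvNetResults":
        rng = np.random.default_rng(seed)
        net = _ConvNet(self.spec, rng)
        opt = Adam(net.params, lr=lr)
        n = len(self.X)
        history: list[dict] = []
        best_val = np.inf
        best_params = [p.data.copy() for p in net.params]
        best_epoch = 0
        stale = 0
        for epoch in range(1, max_epochs + 1):
            order = rng.permutation(n)
            train_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb = Tensor(self.X[idx])
                pred = net.forward(xb, training=True, rng=rng)
                resid = pred - Tensor(self.y[idx])
                loss = (resid * resid).mean()
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                train_loss += loss.item() * len(idx)
            train_loss /= n
            val_pred = self._predict_array(net, self.X_val)
            val_loss = float(np.mean((val_pred - self.y_val) ** 2))
            if not np.isfinite(val_loss):
                raise FloatingPointError(f"non-finite validation loss at epoch {epoch}")
            history.append({"epoch": epoch, "train_mse": train_loss, "val_mse": val_loss})
            if val_loss < best_val:
                best_val = val_loss
                best_params = [p.data.copy() for p in net.params]
                best_epoch = epoch
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
        for p, saved in zip(net.params, best_params):
            p.data = saved
        return ConvNetResults(model=self, net=net,
                              history=pd.DataFrame(history),
                              best_epoch=best_epoch, best_val_mse=best_val)

    @staticmethod
    def _predict_array(net: _ConvNet, X: np.ndarray, chunk: int = 1024) -> np.ndarray:
        out = []
        for start in range(0, len(X), chunk):
            out.append(net.forward(Tensor(X[start : start + chunk])).data)
        return np.concatenate(out) if out else np.zeros(0)


@dataclass
class ConvNetResults:
    model: ConvolutionalMRLRegression
    net: _ConvNet
    history: pd.DataFrame
    best_epoch: int
    best_val_mse: float

    @property
    def spec(self) -> CNNSpec:
        return self.model.spec

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        """Predicted MRL per sequence (order-preserving, deterministic)."""
        X = encode_batch(sequences, self.spec.input_length)
        return ConvolutionalMRLRegression._predict_array(self.net, X)

    def forward(self, x: Tensor) -> Tensor:
        """Differentiable forward pass on an (N, L, 4) relaxed input."""
        return self.net.forward(x, training=False)

    def layer_shapes(self) -> list[tuple[str, tuple[int, ...]]]:
        return self.net.layer_shapes()

    def save(self, path) -> None:
        """Serialize spec + weights + training history to an .npz container."""
        import json

        arrays = {f"param_{i}": p.data for i, p in enumerate(self.net.params)}
        meta = {
            "spec": self.spec.__dict__,
            "best_epoch": self.best_epoch,
            "best_val_mse": self.best_val_mse,
            "history": self.history.to_dict(orient="list"),
            "format_version": 1,
        }
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "ConvNetResults":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            spec = CNNSpec(**meta["spec"])
            net = _ConvNet(spec, np.random.default_rng(0))
            for i, p in enumerate(net.params):
                p.data = data[f"param_{i}"]
        dummy = ConvolutionalMRLRegression.__new__(ConvolutionalMRLRegression)
        dummy.spec = spec
        return cls(model=dummy, net=net, history=pd.DataFrame(meta["history"]),
                   best_epoch=meta["best_epoch"], best_val_mse=meta["best_val_mse"])

    def summary(self) -> str:
        buf = io.StringIO()
        s = self.spec
        buf.write("Convolutional MRL regression\n")
        buf.write(f"  input length {s.input_length}, {s.n_blocks} blocks, "
                  f"kernel {s.kernel_size}, base filters {s.base_filters}\n")
        for name, shape in self.layer_shapes():
            buf.write(f"  {name:<16} {shape}\n")
        buf.write(f"  epochs run {len(self.history)}, best epoch {self.best_epoch}, "
                  f"best val MSE {self.best_val_mse:.4f}\n")
        return buf.getvalue()


def random_search_cnn(split: TrainSplit, n_trials: int, seed: int = 0,
                      fit_kwargs: dict | None = None) -> pd.DataFrame:
    """Local random search over the architecture ranges.

    Samples (n_blocks 1-5 as the input length allows, kernel 2-7, base
    filters 16-128, dropouts 0-0.5, dense units 10-100), trains each
    candidate, and returns a trial table sorted by validation MSE.
    """
    rng = np.random.default_rng(seed)
    fit_kwargs = fit_kwargs or {}
    length = len(split.train["sequence"].iloc[0])
    max_blocks = min(5, int(np.log2(length)))
    rows = []
    for trial in range(n_trials):
        spec = CNNSpec(
            input_length=length,
            n_blocks=int(rng.integers(1, max_blocks + 1)),
            kernel_size=int(rng.integers(2, 8)),
            base_filters=int(rng.integers(16, 129)),
            conv_dropout=float(rng.uniform(0, 0.5)),
            dense_units=int(rng.integers(10, 101)),
            dense_dropout=float(rng.uniform(0, 0.5)),
        )
        res = ConvolutionalMRLRegression.from_split(split, spec=spec).fit(
            seed=int(rng.integers(2**31)), **fit_kwargs
        )
        rows.append({"trial": trial, "spec": spec, "val_mse": res.best_val_mse,
                     "best_epoch": res.best_epoch})
    return pd.DataFrame(rows).sort_values("val_mse").reset_index(drop=True)


# ---------------------------------------------------------------------------
# positional 3-mer linear model


class PositionalTrimerRegression:
    """Linear MRL model on (offset, 3-mer) indicator features."""

    def __init__(self, sequences: Sequence[str], mrl: Sequence[float]):
        lengths = {len(s) for s in sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences must share one length, got {sorted(lengths)}")
        self.length = lengths.pop()
        self.X = positional_3mer_features(list(sequences))
        self.y = np.asarray(mrl, dtype=float)

    def fit(self, stabilizer: float = 1e-6) -> "PositionalTrimerResults":
        ridge = Ridge(alpha=stabilizer, solver="cholesky")
        ridge.fit(self.X, self.y)
        weights = ridge.coef_.reshape(self.length - 2, 64)
        return PositionalTrimerResults(
            length=self.length, weights=weights, intercept=float(ridge.intercept_)
        )


@dataclass
class PositionalTrimerResults:
    length: int
    weights: np.ndarray  # (L-2, 64)
    intercept: float

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        X = positional_3mer_features(list(sequences))
        return X @ self.weights.ravel() + self.intercept

    def weight_correlation(self, other: "PositionalTrimerResults") -> float:
        """Pearson correlation of flattened weight matrices (replicate
        agreement diagnostic)."""
        return float(stats.pearsonr(self.weights.ravel(), other.weights.ravel())[0])

    def summary(self) -> str:
        top = np.unravel_index(np.argsort(np.abs(self.weights), axis=None)[::-1][:5],
                               self.weights.shape)
        names = kmer_feature_names(3, 3)
        lines = ["Positional 3-mer linear regression",
                 f"  sequence length {self.length}, {self.weights.size} weights, "
                 f"intercept {self.intercept:.4f}", "  largest |weights|:"]
        for off, kid in zip(*top):
            lines.append(f"    offset {off:>2} {names[kid]}  {self.weights[off, kid]:+.4f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# k-mer oracle


@dataclass(frozen=True)
class KmerFilterSpec:
    """Training-set filters for the oracle: depth, no uAUGs, no initial UG
    (which would complete an AUG with a fixed region ending in A)."""

    min_reads: int = 250
    exclude_uaug: bool = True
    exclude_initial_ug: bool = True


class KmerOracleRegression:
    """Lasso-selected, least-squares-refit k-mer model of MRL.

    ``table`` is indexed by variant id with ``sequence``, ``mrl`` and
    ``reads`` columns.  The fit pipeline filters the table, featurizes
    with log2(1+count) k-mer counts, runs Lasso on a seeded random subset
    for support selection, then refits the selected features without
    penalty on the full filtered set.
    """

    def __init__(self, table: pd.DataFrame,
                 filter_spec: KmerFilterSpec = KmerFilterSpec(),
                 architecture: Architecture | str = Architecture.FIXED_END_50,
                 k_min: int = 2, k_max: int = 6):
        self.filter_spec = filter_spec
        self.architecture = Architecture(architecture)
        self.k_min, self.k_max = k_min, k_max
        self.table = self.apply_filters(table, filter_spec)

    @staticmethod
    def apply_filters(table: pd.DataFrame, spec: KmerFilterSpec) -> pd.DataFrame:
        keep = table["reads"] >= spec.min_reads
        if spec.exclude_uaug:
            has_uaug = table["sequence"].map(lambda s: "ATG" in s.upper().replace("U", "T"))
            keep &= ~has_uaug
        if spec.exclude_initial_ug:
            keep &= ~table["sequence"].str.upper().str.replace("U", "T").str.startswith("TG")
        return table[keep]

    def fit(self, lasso_alpha: float = 0.001, n_train_subset: int = 50_000,
            seed: int = 0, test_table: pd.DataFrame | None = None,
            lasso_max_iter: int = 3000) -> "KmerOracleResults":
        if lasso_alpha <= 0:
            raise ValueError("lasso_alpha must be > 0")
        rng = np.random.default_rng(seed)
        df = self.table
        if len(df) == 0:
            raise ValueError("no sequences pass the oracle filters")
        n_sub = min(n_train_subset, len(df))
        if n_sub < n_train_subset:
            import warnings

            warnings.warn(
                f"only {len(df)} filtered sequences; Lasso subset reduced to {n_sub}"
            )
        subset = df.iloc[np.sort(rng.choice(len(df), size=n_sub, replace=False))]
        X_sub = kmer_log_features(list(subset["sequence"]), self.k_min, self.k_max)
        lasso = Lasso(alpha=lasso_alpha, max_iter=lasso_max_iter)
        lasso.fit(X_sub, subset["mrl"].to_numpy())
        support = np.flatnonzero(lasso.coef_ != 0)
        if support.size == 0:
            raise ValueError(
                f"Lasso(alpha={lasso_alpha}) selected no features; try a smaller alpha"
            )
        X_full = kmer_log_features(list(df["sequence"]), self.k_min, self.k_max)[:, support]
        refit = LinearRegression()
        refit.fit(X_full, df["mrl"].to_numpy())
        names = kmer_feature_names(self.k_min, self.k_max)
        test_r = np.nan
        if test_table is not None and len(test_table) > 1:
            Xt = kmer_log_features(list(test_table["sequence"]), self.k_min, self.k_max)[:, support]
            pred = refit.predict(Xt)
            test_r = float(stats.pearsonr(pred, test_table["mrl"].to_numpy())[0])
        return KmerOracleResults(
            model=self,
            support=support,
            selected_features=[names[i] for i in support],
            weights=refit.coef_.copy(),
            intercept=float(refit.intercept_),
            lasso_alpha=lasso_alpha,
            n_lasso_subset=n_sub,
            test_pearson_r=test_r,
        )


@dataclass
class KmerOracleResults:
    model: KmerOracleRegression
    support: np.ndarray
    selected_features: list[str]
    weights: np.ndarray
    intercept: float
    lasso_alpha: float
    n_lasso_subset: int
    test_pearson_r: float

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        X = kmer_log_features(list(sequences), self.model.k_min, self.model.k_max)
        return X[:, self.support] @ self.weights + self.intercept

    def summary(self) -> str:
        lines = [
            "k-mer oracle (Lasso selection + least-squares refit)",
            f"  Lasso alpha {self.lasso_alpha} on {self.n_lasso_subset} sequences "
            f"-> {len(self.selected_features)} features",
            f"  refit on {len(self.model.table)} filtered sequences, "
            f"intercept {self.intercept:.4f}",
        ]
        if np.isfinite(self.test_pearson_r):
            lines.append(f"  test Pearson r {self.test_pearson_r:.4f}")
        order = np.argsort(np.abs(self.weights))[::-1][:5]
        lines.append("  largest |weights|: "
                     + ", ".join(f"{self.selected_features[i]} {self.weights[i]:+.3f}"
                                 for i in order))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------


def evaluate_r2(predicted: Sequence[float], measured: Sequence[float]) -> float:
    """Squared Pearson correlation between predictions and measurements."""
    p = np.asarray(predicted, dtype=float)
    m = np.asarray(measured, dtype=float)
    if p.shape != m.shape or p.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.std(p) == 0 or np.std(m) == 0:
        raise ValueError("correlation undefined: zero variance input")
    return float(stats.pearsonr(p, m)[0] ** 2)
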