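"""Neural-network layers built on the autodiff engine.

Layers follow the usual conventions: sequence inputs are (N, L, C)
arrays with C=4 one-hot channels, dense inputs are (N, D).  All
randomness (initialization, dropout, sampling) flows through an explicit
``numpy.random.Generator`` so training runs are reproducible bit-for-bit
on a single thread.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .autodiff import Adam, Tensor, softmax

__all__ = ["Dense", "Conv1DSame", "max_pool2", "dropout", "straight_through_sample", "Adam"]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        self.W = Tensor(_glorot(rng, n_in, n_out, (n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


class Conv1DSame:
    """1-D convolution with 'same' zero padding along the length axis."""

    def __init__(self, rng: np.random.Generator, c_in: int, filters: int, kernel_size: int):
        self.kernel_size = int(kernel_size)
        self.c_in = int(c_in)
        self.filters = int(filters)
        fan_in = c_in * kernel_size
        self.W = Tensor(_glorot(rng, fan_in, filters, (fan_in, filters)), requires_grad=True)
        self.b = Tensor(np.zeros(filters), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, L, c = x.shape
        k = self.kernel_size
        left = (k - 1) // 2
        right = k - 1 - left
        xp = x.pad_axis1(left, right)
        idx = np.arange(L)[:, None] + np.arange(k)[None, :]
        cols = xp.take_axis1(idx)                      # (N, L, k, C)
        cols = cols.reshape(n, L, k * c)
        return cols @ self.W + self.b                   # (N, L, F)

    @property
    def params(self) -> list[Tensor]:
        return [self.W, self.b]


def max_pool2(x: Tensor) -> Tensor:
    """Max pooling with size and stride 2; trailing odd position dropped."""
    n, L, c = x.shape
    L2 = L // 2
    if L2 * 2 != L:
        x = x[:, : L2 * 2, :]
    return x.reshape(n, L2, 2, c).max(axis=2)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def straight_through_sample(probs: Tensor, rng: np.random.Generator) -> Tensor:
    """Sample a discrete one-hot per position; gradients pass to the probabilities.

    ``probs`` is (N, L, 4) (or (L, 4)); the forward value is the sampled
    one-hot matrix while the backward pass treats the sampling as the
    identity (straight-through estimator).
    """
    p = probs.data
    flat = p.reshape(-1, p.shape[-1])
    cum = np.cumsum(flat, axis=1)
    u = rng.random((flat.shape[0], 1)) * cum[:, -1:]
    choice = (u > cum).sum(axis=1)
    onehot = np.zeros_like(flat)
    onehot[np.arange(flat.shape[0]), choice] = 1.0
    onehot = onehot.reshape(p.shape)
    return probs + Tensor(onehot - p)
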