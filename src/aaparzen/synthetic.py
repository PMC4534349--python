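"""Synthetic labeled binary fingerprint datasets with controllable structure.

Each class ``j`` has a vector of per-bit Bernoulli on-probabilities
``p[j, l]``; pattern bits are drawn independently (no within-pattern
correlation -- sufficient for exercising the estimators, and a documented
extension point).  A single named pseudo-random stream per ``generate``
call makes every dataset reproducible from its seed.

Presets:

- ``disjoint-blocks`` -- each class is dense inside its own contiguous bit
  block and near-silent elsewhere; a separable benchmark on which the
  classifier must score near-perfectly.
- ``overlapping`` -- class blocks overlap by half a block width, giving a
  harder, partially confusable problem.
- ``iid-uniform`` -- all probabilities equal; classes are indistinguishable
  (a null benchmark).
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exact import LabeledDataset

__all__ = [
    "GeneratorConfig",
    "generate",
    "disjoint_block_preset",
    "overlapping_preset",
    "iid_uniform_preset",
]


def _default_labels(J: int) -> tuple:
    if J <= 26:
        return tuple(string.ascii_uppercase[:J])
    return tuple(f"C{j}" for j in range(J))


@dataclass(frozen=True)
class GeneratorConfig:
    """Bernoulli bit-occurrence profiles for ``J`` classes over ``L`` bits."""

    J: int
    L: int
    n_per_class: tuple
    bit_probs: np.ndarray  # shape (J, L), entries in [0, 1]
    seed: int
    preset: str = "custom"
    labels: tuple = ()

    def __post_init__(self) -> None:
        probs = np.asarray(self.bit_probs, dtype=float)
        if probs.shape != (self.J, self.L):
            raise ValueError(
                f"bit_probs must have shape (J, L)=({self.J}, {self.L}); got {probs.shape}"
            )
        if ((probs < 0) | (probs > 1)).any():
            raise ValueError("bit_probs entries must lie in [0, 1]")
        n = tuple(int(v) for v in self.n_per_class)
        if len(n) != self.J:
            raise ValueError(f"n_per_class must have J={self.J} entries; got {len(n)}")
        if any(v < 1 for v in n):
            raise ValueError("every class must have at least one pattern")
        labels = tuple(self.labels) or _default_labels(self.J)
        if len(labels) != self.J:
            raise ValueError(f"labels must have J={self.J} entries; got {len(labels)}")
        object.__setattr__(self, "bit_probs", probs)
        object.__setattr__(self, "n_per_class", n)
        object.__setattr__(self, "labels", labels)


def generate(config: GeneratorConfig) -> LabeledDataset:
    """Draw a dataset: bit ``l`` of a class-``j`` pattern is Bernoulli(p[j, l]).

    Deterministic for a fixed config (one ``default_rng(seed)`` stream,
    consumed class by class in label order).
    """
    rng = np.random.default_rng(config.seed)
    blocks, labels = [], []
    for j in range(config.J):
        n = config.n_per_class[j]
        block = (rng.random((n, config.L)) < config.bit_probs[j]).astype(np.int64)
        blocks.append(block)
        labels.extend([config.labels[j]] * n)
    return LabeledDataset(np.vstack(blocks), labels)


def _block_slices(J: int, L: int):
    # contiguous blocks of floor/ceil(L/J) bits covering [0, L)
    edges = np.linspace(0, L, J + 1).round().astype(int)
    return [slice(edges[j], edges[j + 1]) for j in range(J)]


def disjoint_block_preset(
    J: int,
    L: int,
    block_density: float = 0.9,
    n_per_class: int | Sequence[int] = 100,
    seed: int = 0,
    off_density: float = 0.01,
) -> GeneratorConfig:
    """Separable benchmark: class ``j`` is active only on its own L/J block.

    With ``J=2, L=8``: class A's block is bits 0-3, class B's bits 4-7.
    When ``J`` does not divide ``L`` the blocks differ by at most one bit.
    """
    if L < J:
        raise ValueError(f"need L >= J to assign each class a block; got L={L}, J={J}")
    probs = np.full((J, L), off_density)
    for j, sl in enumerate(_block_slices(J, L)):
        probs[j, sl] = block_density
    n = (n_per_class,) * J if np.isscalar(n_per_class) else tuple(n_per_class)
    return GeneratorConfig(
        J=J, L=L, n_per_class=n, bit_probs=probs, seed=seed, preset="disjoint-blocks"
    )


def overlapping_preset(
    J: int,
    L: int,
    block_density: float = 0.9,
    n_per_class: int | Sequence[int] = 100,
    seed: int = 0,
    off_density: float = 0.05,
) -> GeneratorConfig:
    """Harder benchmark: adjacent class blocks overlap by half a block width."""
    if L < J:
        raise ValueError(f"need L >= J; got L={L}, J={J}")
    probs = np.full((J, L), off_density)
    width = max(1, L // J)
    shift = max(1, width // 2)
    for j in range(J):
        start = min(j * shift, L - width)
        probs[j, start : start + width] = block_density
    n = (n_per_class,) * J if np.isscalar(n_per_class) else tuple(n_per_class)
    return GeneratorConfig(
        J=J, L=L, n_per_class=n, bit_probs=probs, seed=seed, preset="overlapping"
    )


def iid_uniform_preset(
    J: int,
    L: int,
    density: float = 0.5,
    n_per_class: int | Sequence[int] = 100,
    seed: int = 0,
) -> GeneratorConfig:
    """Null benchmark: every class has identical iid bit probabilities."""
    probs = np.full((J, L), density)
    n = (n_per_class,) * J if np.isscalar(n_per_class) else tuple(n_per_class)
    return GeneratorConfig(
        J=J, L=L, n_per_class=n, bit_probs=probs, seed=seed, preset="iid-uniform"
    )
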