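"""Brute-force Parzen window estimator and Bayes classifier.

The class-conditional density of a query ``x`` given class ``w`` is the mean
AA-kernel value over the class's prototypes::

    p_hat(x | w) = (1 / N_w) * sum_i K(x, x_i; lambda)

Combined with class priors (empirical frequencies or uniform) via Bayes'
rule this yields posteriors ``p(w | x)``; the classifier assigns the class
with maximal posterior, breaking exact ties toward the lexicographically
smallest class label.

This module is the correctness oracle for the compressed backend: it keeps
every prototype in memory and sums kernels directly.  Densities are
evaluated in the log domain throughout (``lam^L`` underflows for ``L`` in
the hundreds) with log-sum-exp normalization for the posteriors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
from scipy.special import logsumexp

from .kernels import KernelParams, as_bit_vector

__all__ = [
    "LabeledDataset",
    "PriorVector",
    "PosteriorResult",
    "EvidenceUnderflowError",
    "class_priors",
    "class_conditional_exact",
    "log_class_conditional_exact",
    "posterior",
    "classify",
]


class EvidenceUnderflowError(FloatingPointError):
    """Raised when every class-conditional is zero even in the log domain."""


@dataclass(frozen=True)
class LabeledDataset:
    """Training set of binary patterns with class labels.

    Parameters
    ----------
    patterns
        Array of shape ``(N, L)`` with entries in {0, 1}.
    labels
        Sequence of ``N`` class labels (opaque, hashable; strings in file
        formats).  Class membership is kept as an index list per class --
        the 0/1 membership indicator is never materialized as a matrix.
    """

    patterns: np.ndarray
    labels: tuple

    def __init__(self, patterns, labels):
        arr = np.asarray(patterns)
        if arr.ndim != 2:
            raise ValueError(f"patterns must be a 2-D array, got ndim {arr.ndim}")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("patterns contain a non-binary entry")
        arr = np.ascontiguousarray(arr, dtype=np.int64)
        labels = tuple(labels)
        if len(labels) != arr.shape[0]:
            raise ValueError(
                f"got {arr.shape[0]} patterns but {len(labels)} labels"
            )
        if arr.shape[0] < 1:
            raise ValueError("dataset must contain at least one pattern")
        object.__setattr__(self, "patterns", arr)
        object.__setattr__(self, "labels", labels)

    @property
    def N(self) -> int:
        return self.patterns.shape[0]

    @property
    def L(self) -> int:
        return self.patterns.shape[1]

    @property
    def classes(self) -> tuple:
        """Class labels present, in sorted order."""
        return tuple(sorted(set(self.labels), key=str))

    @property
    def J(self) -> int:
        return len(self.classes)

    def class_indices(self, cls) -> np.ndarray:
        idx = np.array([i for i, y in enumerate(self.labels) if y == cls], dtype=np.intp)
        if idx.size == 0:
            raise KeyError(f"class {cls!r} not present in dataset")
        return idx

    def class_patterns(self, cls) -> np.ndarray:
        return self.patterns[self.class_indices(cls)]


@dataclass(frozen=True)
class PriorVector:
    """Class prior probabilities, summing to 1."""

    priors: Mapping
    mode: str

    def __post_init__(self) -> None:
        vals = np.array(list(self.priors.values()), dtype=float)
        if not ((vals > 0) & (vals <= 1)).all():
            raise ValueError("priors must lie in (0, 1]")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"priors must sum to 1; got {vals.sum()!r}")

    def __getitem__(self, cls) -> float:
        return self.priors[cls]

    @property
    def classes(self) -> tuple:
        return tuple(sorted(self.priors, key=str))


@dataclass(frozen=True)
class PosteriorResult:
    """Per-class densities, priors, evidence and posteriors for one query."""

    log_conditionals: Mapping
    priors: PriorVector
    log_evidence: float
    posteriors: Mapping
    predicted: object

    @property
    def class_conditionals(self) -> dict:
        return {c: math.exp(v) for c, v in self.log_conditionals.items()}

    @property
    def evidence(self) -> float:
        return math.exp(self.log_evidence)


def class_priors(dataset: LabeledDataset, mode: str = "uniform") -> PriorVector:
    """Empirical (class frequency ``N_w / N``) or uniform (``1/J``) priors."""
    classes = dataset.classes
    if mode == "empirical":
        counts = {c: 0 for c in classes}
        for y in dataset.labels:
            counts[y] += 1
        priors = {c: counts[c] / dataset.N for c in classes}
    elif mode == "uniform":
        priors = {c: 1.0 / dataset.J for c in classes}
    else:
        raise ValueError(f"prior mode must be 'empirical' or 'uniform'; got {mode!r}")
    return PriorVector(priors=priors, mode=mode)


def _log_mean_kernel(x: np.ndarray, prototypes: np.ndarray, params: KernelParams) -> float:
    # log of (1/n) sum_i lam^L ((1-lam)/lam)^d(x, x_i); d via inner products.
    pop_x = int(x @ x)
    pops = prototypes.sum(axis=1)
    cross = prototypes @ x
    d = pop_x + pops - 2 * cross
    return float(
        params.L * params.log_lam
        + logsumexp(-params.alpha * d.astype(float))
        - math.log(prototypes.shape[0])
    )


def log_class_conditional_exact(x, dataset: LabeledDataset, cls, params: KernelParams) -> float:
    """Log of :func:`class_conditional_exact`."""
    xv = as_bit_vector(x, params.L)
    if dataset.L != params.L:
        raise ValueError(f"dataset has L={dataset.L} but params have L={params.L}")
    return _log_mean_kernel(xv, dataset.class_patterns(cls), params)


def class_conditional_exact(x, dataset: LabeledDataset, cls, params: KernelParams) -> float:
    """Mean AA-kernel value over the prototypes of ``cls`` (the Parzen estimate).

    Lies in ``(0, lam^L]``, attaining ``lam^L`` iff every prototype equals
    ``x``; sums to 1 over the whole pattern space.
    """
    return math.exp(log_class_conditional_exact(x, dataset, cls, params))


LogDensityBackend = Callable[[np.ndarray, object], float]


def posterior(
    x,
    dataset: LabeledDataset | None,
    params: KernelParams,
    priors: PriorVector,
    backend: str | LogDensityBackend = "exact",
    *,
    r_max: int = 60,
    model=None,
) -> PosteriorResult:
    """Bayes posterior ``p(w | x) = p_hat(x | w) p(w) / p(x)`` over all classes.

    ``backend`` selects the density estimator: ``"exact"`` (this module),
    ``"truncated"`` (series truncated at ``r_max``), ``"compressed"``
    (requires ``model``), or any callable ``(x, cls) -> log density``.
    Posteriors are normalized in the log domain via max-subtraction, so
    underflowing densities remain usable as long as one class-conditional
    is representable in log scale.
    """
    xv = as_bit_vector(x, params.L)
    log_fn = _resolve_backend(backend, dataset, params, r_max=r_max, model=model)
    classes = priors.classes
    log_cond = {c: log_fn(xv, c) for c in classes}
    log_num = np.array([log_cond[c] + math.log(priors[c]) for c in classes])
    if not np.isfinite(log_num).any():
        raise EvidenceUnderflowError(
            "evidence is zero in the log domain: every class-conditional "
            "density underflowed; check lambda and the feature dimension"
        )
    log_ev = float(logsumexp(log_num))
    post = np.exp(log_num - log_ev)
    post /= post.sum()
    posteriors = {c: float(p) for c, p in zip(classes, post)}
    best = max(post)
    predicted = next(c for c, p in zip(classes, post) if p == best)
    return PosteriorResult(
        log_conditionals=log_cond,
        priors=priors,
        log_evidence=log_ev,
        posteriors=posteriors,
        predicted=predicted,
    )


def classify(
    x,
    dataset: LabeledDataset | None,
    params: KernelParams,
    priors: PriorVector,
    backend: str | LogDensityBackend = "exact",
    *,
    r_max: int = 60,
    model=None,
):
    """Class label with maximal posterior; exact ties break to the
    lexicographically smallest label."""
    return posterior(
        x, dataset, params, priors, backend, r_max=r_max, model=model
    ).predicted


def _resolve_backend(backend, dataset, params, *, r_max, model) -> LogDensityBackend:
    if callable(backend):
        return backend
    if backend == "exact":
        if dataset is None:
            raise ValueError("exact backend requires a dataset")
        return lambda xv, c: log_class_conditional_exact(xv, dataset, c, params)
    if backend == "truncated":
        from .compressed import class_conditional_truncated

        if dataset is None:
            raise ValueError("truncated backend requires a dataset")

        def log_trunc(xv, c):
            val = class_conditional_truncated(xv, dataset.class_patterns(c), params, r_max)
            return math.log(val) if val > 0 else -math.inf

        return log_trunc
    if backend == "compressed":
        from .compressed import log_class_conditional_compressed

        if model is None:
            raise ValueError("compressed backend requires a fitted model")
        return lambda xv, c: log_class_conditional_compressed(xv, model.summaries[c], params)
    raise ValueError(
        f"backend must be 'exact', 'truncated', 'compressed' or a callable; got {backend!r}"
    )
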