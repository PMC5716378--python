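"""Hilbert-Schmidt independence criterion and the distance-correlation index.

HSIC is the squared Hilbert-Schmidt norm of the cross-covariance operator
between kernel embeddings of two variables; with universal kernels (rbf,
laplace) it vanishes iff the variables are independent, which makes it a
dependence-based sensitivity measure that sees non-linear, non-monotone
relations the variance decomposition misses.  The biased n-sample
estimator is

    HSIC_n(X, U) = (1/n^2) Tr(K_X H K_U H),

with Gram matrices K and the centering matrix H = I - (1/n) 11'.  The
sensitivity index reported per factor is the kernel distance correlation

    R(X, U) = HSIC(X, U) / sqrt(HSIC(X, X) HSIC(U, U))  in [0, 1].

Bandwidths default to the median heuristic (median pairwise distance,
Euclidean for rbf, L1 for laplace).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDataError, InputError
from .estimates import SensitivityEstimate

__all__ = [
    "KernelSpec",
    "GramPair",
    "gram_matrix",
    "centering_matrix",
    "median_heuristic_bandwidth",
    "hsic",
    "hsic_index",
    "hsic_permutation_test",
]

_FAMILIES = ("linear", "rbf", "laplace")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family plus bandwidth (a positive scale, or the median heuristic)."""

    family: str
    bandwidth: Union[float, str] = "median-heuristic"

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise InputError(f"kernel family must be one of {_FAMILIES}, got {self.family!r}")
        if isinstance(self.bandwidth, str):
            if self.bandwidth != "median-heuristic":
                raise InputError(f"unknown bandwidth rule {self.bandwidth!r}")
        elif not self.bandwidth > 0:
            raise InputError("numeric bandwidth must be positive")


@dataclass
class GramPair:
    """Gram matrices for an input factor and the output, plus the centering
    matrix they share."""

    K_x: np.ndarray
    K_u: np.ndarray
    H: np.ndarray


def _as_2d(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise InputError("samples must be a vector or an (n, p) matrix")
    return x


def median_heuristic_bandwidth(samples, metric: str = "euclidean") -> float:
    """Median of the pairwise distances of the sample (excluding self-pairs).

    ``metric`` is ``euclidean`` for the rbf kernel and ``cityblock`` (L1) for
    the laplace kernel.  Falls back to the smallest positive distance when
    ties at zero push the median to zero.
    """
    x = _as_2d(samples)
    if x.shape[0] < 2:
        raise InputError("median heuristic needs at least two samples")
    d = pdist(x, metric=metric)
    positive = d[d > 0]
    if positive.size == 0:
        raise DegenerateDataError("all samples identical; bandwidth undefined")
    med = float(np.median(d))
    return med if med > 0 else float(positive.min())


def _resolve_bandwidth(x: np.ndarray, spec: KernelSpec) -> float:
    if isinstance(spec.bandwidth, str):
        metric = "cityblock" if spec.family == "laplace" else "euclidean"
        return median_heuristic_bandwidth(x, metric=metric)
    return float(spec.bandwidth)


def gram_matrix(samples, spec: KernelSpec) -> np.ndarray:
    """Symmetric n x n kernel matrix for 1-D or multivariate samples.

    rbf: k(x,y) = exp(-||x-y||^2 / (2 sigma^2));
    laplace: k(x,y) = exp(-||x-y||_1 / sigma);
    linear: k(x,y) = <x, y>.
    """
    x = _as_2d(samples)
    n = x.shape[0]
    if n < 2:
        raise InputError("gram_matrix needs at least two samples")
    if spec.family == "linear":
        return x @ x.T
    sigma = _resolve_bandwidth(x, spec)
    if spec.family == "rbf":
        sq = squareform(pdist(x, metric="sqeuclidean"))
        return np.exp(-sq / (2.0 * sigma**2))
    l1 = squareform(pdist(x, metric="cityblock"))
    return np.exp(-l1 / sigma)


def centering_matrix(n: int) -> np.ndarray:
    """H(i, j) = delta_ij - 1/n; idempotent, annihilates constants."""
    if n < 1:
        raise InputError("n must be >= 1")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def _center_gram(K: np.ndarray) -> np.ndarray:
    # H K H via rank-1 corrections; O(n^2) instead of two matmuls
    row = K.mean(axis=1, keepdims=True)
    col = K.mean(axis=0, keepdims=True)
    return K - row - col + K.mean()


def _hsic_from_grams(K_x: np.ndarray, K_u: np.ndarray) -> float:
    n = K_x.shape[0]
    return float(np.sum(_center_gram(K_x) * K_u)) / n**2


def hsic(x, u, spec_x: KernelSpec, spec_u: KernelSpec) -> float:
    """Biased HSIC estimator (1/n^2) Tr(K_x H K_u H); non-negative."""
    xv, uv = _as_2d(x), _as_2d(u)
    if xv.shape[0] != uv.shape[0]:
        raise InputError("x and u must have the same number of samples")
    if xv.shape[0] < 4:
        raise InputError("HSIC needs at least 4 paired samples")
    return _hsic_from_grams(gram_matrix(xv, spec_x), gram_matrix(uv, spec_u))


def hsic_index(
    x_k,
    u,
    spec_x: KernelSpec,
    spec_u: KernelSpec | None = None,
    factor: str = "x",
) -> SensitivityEstimate:
    """Distance-correlation sensitivity index R(X_k, U) in [0, 1].

    The output kernel defaults to the same family as the input kernel.
    Raises on constant input or output (zero self-HSIC).
    """
    if spec_u is None:
        spec_u = spec_x
    xv, uv = _as_2d(x_k), _as_2d(u)
    if xv.shape[0] != uv.shape[0]:
        raise InputError("x_k and u must have the same number of samples")
    if xv.shape[0] < 4:
        raise InputError("HSIC needs at least 4 paired samples")
    K_x = gram_matrix(xv, spec_x)
    K_u = gram_matrix(uv, spec_u)
    h_xx = _hsic_from_grams(K_x, K_x)
    h_uu = _hsic_from_grams(K_u, K_u)
    if h_xx <= 0 or h_uu <= 0:
        raise DegenerateDataError("constant variable: self-HSIC is zero, R undefined")
    h_xu = _hsic_from_grams(K_x, K_u)
    R = h_xu / np.sqrt(h_xx * h_uu)
    return SensitivityEstimate(
        factor=factor,
        method=f"hsic:{spec_x.family}",
        order="first",
        value=float(R),
        n=xv.shape[0],
        out_of_range=not (0.0 <= R <= 1.0),
    )


def hsic_indices_matrix(
    X,
    u,
    spec_x: KernelSpec,
    spec_u: KernelSpec | None = None,
    factor_names=None,
) -> list:
    """Distance-correlation index of every column of X against u.

    Equivalent to calling :func:`hsic_index` per column, but the output
    Gram matrix and its self-HSIC are computed once -- the hot path of the
    bootstrap/time-course pipelines.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise InputError("X must be an (n, d) matrix of factor columns")
    if spec_u is None:
        spec_u = spec_x
    names = list(factor_names) if factor_names is not None else [f"x{j + 1}" for j in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise InputError("factor_names length must match the number of columns")
    uv = _as_2d(u)
    if uv.shape[0] != X.shape[0] or X.shape[0] < 4:
        raise InputError("need >= 4 rows and matching sample counts")
    K_u = gram_matrix(uv, spec_u)
    h_uu = _hsic_from_grams(K_u, K_u)
    if h_uu <= 0:
        raise DegenerateDataError("constant output: self-HSIC is zero, R undefined")
    out = []
    n = X.shape[0]
    for j, name in enumerate(names):
        K_x = gram_matrix(X[:, j], spec_x)
        Kxc = _center_gram(K_x)
        h_xx = float(np.sum(Kxc * K_x)) / n**2
        if h_xx <= 0:
            raise DegenerateDataError(f"constant factor {name!r}: self-HSIC is zero")
        R = (float(np.sum(Kxc * K_u)) / n**2) / np.sqrt(h_xx * h_uu)
        out.append(
            SensitivityEstimate(
                factor=name,
                method=f"hsic:{spec_x.family}",
                order="first",
                value=float(R),
                n=n,
                out_of_range=not (0.0 <= R <= 1.0),
            )
        )
    return out


def hsic_permutation_test(
    x,
    u,
    spec_x: KernelSpec,
    spec_u: KernelSpec | None = None,
    n_permutations: int = 200,
    rng_seed: int = 0,
) -> dict:
    """Permutation null for the distance-correlation index (diagnostic only).

    Permutes the pairing of u against x ``n_permutations`` times, recomputing
    R each time from the cached Gram matrices.  Returns the observed R, the
    null 95th percentile and a one-sided p-value.  Index magnitudes are
    scale-bound, so this calibrates "how large is large"; it never gates
    pipeline output.
    """
    if spec_u is None:
        spec_u = spec_x
    xv, uv = _as_2d(x), _as_2d(u)
    if xv.shape[0] != uv.shape[0] or xv.shape[0] < 4:
        raise InputError("need >= 4 equally paired samples")
    K_x = gram_matrix(xv, spec_x)
    K_u = gram_matrix(uv, spec_u)
    Kxc = _center_gram(K_x)
    n = xv.shape[0]
    h_xx = float(np.sum(Kxc * K_x)) / n**2
    h_uu = _hsic_from_grams(K_u, K_u)
    if h_xx <= 0 or h_uu <= 0:
        raise DegenerateDataError("constant variable: permutation test undefined")
    denom = np.sqrt(h_xx * h_uu)
    observed = (float(np.sum(Kxc * K_u)) / n**2) / denom
    rng = np.random.default_rng(rng_seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        p = rng.permutation(n)
        null[b] = (float(np.sum(Kxc * K_u[np.ix_(p, p)])) / n**2) / denom
    p_value = float((np.sum(null >= observed) + 1) / (n_permutations + 1))
    return {
        "R": observed,
        "null_q95": float(np.quantile(null, 0.95)),
        "p_value": p_value,
        "n_permutations": n_permutations,
    }
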