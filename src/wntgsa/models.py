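"""Output models and psychophysical-law primitives.

Two pieces live here.  The first is the Sobol g-function

    f(x) = prod_i (|4 x_i - 2| + a_i) / (1 + a_i),   x in [0,1]^d,  a_i >= 0,

a non-linear, non-monotone benchmark whose ANOVA variance decomposition is
known in closed form, which makes it the standard model for validating
global sensitivity estimators.  Smaller a_i means factor i matters more; a
factor with a_i = 0 is maximally influential.  In the expression-analysis
pipelines the gene columns (mapped into the unit cube) play the role of x
and a random coefficient vector a defines the model whose output the
indices interrogate.

The second piece is the Bernoulli/Weber psychophysics: sensation grows with
the logarithm of the stimulus, gamma = b log(beta/alpha), so the sensation
increment produced by a stimulus step depends only on the relative step
delta_beta/beta.  That ratio (the Weber ratio k_r) is what motivates
analysing *deviations* in fold change between consecutive time points
rather than the fold-change levels themselves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .errors import DomainError, InputError

__all__ = [
    "GFunctionModel",
    "WeberRecord",
    "g_function",
    "draw_importance_coefficients",
    "g_function_analytic_indices",
    "bernoulli_sensation",
    "sensation_increment",
    "weber_ratio_from_increment",
]


@dataclass(frozen=True)
class GFunctionModel:
    """The g-function with importance coefficients ``a`` (length d)."""

    a: np.ndarray

    def __post_init__(self):
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        if a.ndim != 1 or a.size < 1:
            raise InputError("a must be a non-empty 1-D coefficient vector")
        if np.any(a < 0):
            raise DomainError("every importance coefficient a_i must be >= 0")
        object.__setattr__(self, "a", a)

    @property
    def d(self) -> int:
        return int(self.a.size)

    def __call__(self, x) -> np.ndarray:
        return g_function(x, self)


@dataclass
class WeberRecord:
    """A stimulus/sensation bookkeeping record for one Weber-law evaluation.

    beta is the stimulus magnitude, delta_beta its increment, b the
    logarithmic gain, alpha the sensation threshold.  k_r is the Weber
    ratio delta_beta / beta.
    """

    beta: float
    delta_beta: Optional[float] = None
    b: Optional[float] = None
    alpha: Optional[float] = None
    gamma: Optional[float] = None
    delta_gamma: Optional[float] = None
    k_r: Optional[float] = None

    def __post_init__(self):
        if self.beta <= 0:
            raise DomainError("beta must be positive")
        if self.alpha is not None and self.alpha <= 0:
            raise DomainError("alpha must be positive")
        if self.k_r is None and self.delta_beta is not None:
            self.k_r = self.delta_beta / self.beta
        if self.k_r is not None and self.delta_beta is not None:
            if not math.isclose(self.k_r, self.delta_beta / self.beta, rel_tol=1e-9, abs_tol=1e-12):
                raise InputError("k_r must equal delta_beta / beta")


def g_function(x, model: GFunctionModel) -> np.ndarray:
    """Evaluate the g-function at one point or at rows of a matrix.

    ``x`` may be a length-d point or an (n, d) array of points; the result
    is a scalar or a length-n vector accordingly.  Points must lie in the
    closed unit cube.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    pts = np.atleast_2d(x)
    if pts.shape[-1] != model.d:
        raise InputError(f"x has {pts.shape[-1]} components, model expects {model.d}")
    if np.any(pts < 0.0) or np.any(pts > 1.0):
        raise DomainError("g_function is defined only on the closed unit cube [0,1]^d")
    vals = np.prod((np.abs(4.0 * pts - 2.0) + model.a) / (1.0 + model.a), axis=-1)
    return float(vals[0]) if scalar else vals


def draw_importance_coefficients(d: int, rng_seed: int) -> np.ndarray:
    """Draw the coefficient vector a ~ Uniform[0,1]^d, reproducibly.

    Every pipeline run draws a exactly once from its ``a_seed`` and records
    both in the run log; d is 18 for the static dataset and 71 for the
    time-course dataset by default.
    """
    if d < 1:
        raise InputError("d must be >= 1")
    rng = np.random.default_rng(rng_seed)
    return rng.uniform(0.0, 1.0, size=d)


def g_function_analytic_indices(model: GFunctionModel) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form first-order and total Sobol indices of the g-function.

    Each factor contributes partial variance V_i = (1/3)/(1+a_i)^2 and the
    multiplicative ANOVA structure gives total variance D = prod(1+V_j) - 1.
    Returns ``(S, T)`` with S_i = V_i / D and T_i = 1 - (prod_{j!=i}(1+V_j) - 1)/D.
    Used as the oracle against which the Monte Carlo estimators are judged;
    itself validated against brute-force quadrature in the test suite.
    """
    a = model.a
    V = (1.0 / 3.0) / (1.0 + a) ** 2
    prod_all = np.prod(1.0 + V)
    D = prod_all - 1.0
    S = V / D
    # complement-group variance: prod over j != i of (1+V_j), minus 1
    D_complement = prod_all / (1.0 + V) - 1.0
    T = 1.0 - D_complement / D
    return S, T


def bernoulli_sensation(beta: float, alpha: float, b: float) -> float:
    """Sensation magnitude gamma = b * log(beta / alpha) (natural log)."""
    if beta <= 0 or alpha <= 0:
        raise DomainError("beta and alpha must be positive")
    return b * math.log(beta / alpha)


def sensation_increment(beta: float, delta_beta: float, b: float) -> float:
    """Sensation increment for a stimulus step beta -> beta + delta_beta.

    delta_gamma = b * log(1 + delta_beta/beta); the threshold alpha cancels,
    so the increment depends on the stimulus only through the relative step.
    """
    if beta <= 0:
        raise DomainError("beta must be positive")
    if beta + delta_beta <= 0:
        raise DomainError("beta + delta_beta must be positive")
    return b * math.log1p(delta_beta / beta)


def weber_ratio_from_increment(delta_gamma: float, b: float) -> float:
    """Invert the sensation increment back to the Weber ratio.

    k_r = exp(delta_gamma)^(1/b) - 1; composed with
    :func:`sensation_increment` this recovers delta_beta/beta exactly.
    """
    if b == 0:
        raise DomainError("b must be non-zero")
    return math.expm1(delta_gamma / b)
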