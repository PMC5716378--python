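"""Variance-based (Sobol) sensitivity indices via pick-freeze Monte Carlo.

The ANOVA decomposition of a square-integrable model f on the unit cube
splits its variance D into per-factor and interaction terms; the
first-order index S_i = D_i / D measures the share of variance a factor
explains alone, the total index T_i the share it explains including all
its interactions.  Pick-freeze estimation evaluates f on two independent
sample matrices A and B plus, per factor, the hybrid AB_i (A with column i
taken from B), at a total cost of (d+2) n evaluations.  Because f(B) and
f(AB_i) share exactly column i, their covariance estimates D_i; f(A) and
f(AB_i) share everything *but* column i, giving the complement variance
behind T_i.

Five classical estimator variants are provided under the tags
``sobol1993``, ``saltelli2002`` (output centered first), ``mauntz2007``,
``jansen`` and ``martinez`` (correlation-coefficient forms).  Estimates may
come out slightly negative or above one by Monte Carlo noise; they are
reported unclipped with ``out_of_range`` set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Sequence

import numpy as np

from .errors import DegenerateDataError, InputError
from .estimates import SOBOL_METHODS, SensitivityEstimate

__all__ = [
    "PickFreezeDesign",
    "build_design",
    "center_output",
    "estimate_sobol",
    "estimate_sobol_order",
    "estimate_sobol_from_data",
]


@dataclass
class PickFreezeDesign:
    """Paired sample matrices A, B plus lazily materialised column swaps.

    ``ab(i)`` returns A with column i replaced by column i of B.
    """

    A: np.ndarray
    B: np.ndarray
    rng_seed: int | None = None

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if A.ndim != 2 or B.ndim != 2 or A.shape != B.shape:
            raise InputError("A and B must be two equally shaped (n, d) matrices")
        if A.shape[0] < 2 or A.shape[1] < 1:
            raise InputError("need n >= 2 samples and d >= 1 factors")
        self.A, self.B = A, B

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def d(self) -> int:
        return self.A.shape[1]

    def ab(self, i: int) -> np.ndarray:
        if not 0 <= i < self.d:
            raise InputError(f"factor index {i} outside 0..{self.d - 1}")
        M = self.A.copy()
        M[:, i] = self.B[:, i]
        return M

    def ab_group(self, group: Sequence[int]) -> np.ndarray:
        idx = list(group)
        if not idx:
            raise InputError("group must be a non-empty subset of factors")
        if any(not 0 <= i < self.d for i in idx):
            raise InputError("group contains factor indices outside the design")
        M = self.A.copy()
        M[:, idx] = self.B[:, idx]
        return M


def build_design(n: int, d: int, rng_seed: int) -> PickFreezeDesign:
    """Draw independent uniform A and B on [0,1]^d, reproducibly per seed."""
    if n < 2 or d < 1:
        raise InputError("build_design needs n >= 2 and d >= 1")
    rng = np.random.default_rng(rng_seed)
    A = rng.uniform(size=(n, d))
    B = rng.uniform(size=(n, d))
    return PickFreezeDesign(A=A, B=B, rng_seed=rng_seed)


def center_output(u) -> np.ndarray:
    """Subtract the sample mean.  Required before the saltelli2002 form,
    which is ill-conditioned for largely non-centered output."""
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise InputError("cannot center an empty output vector")
    return u - u.mean()


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def estimate_sobol(
    model: Callable[[np.ndarray], np.ndarray],
    design: PickFreezeDesign,
    method: str,
    factor_names: Sequence[str] | None = None,
) -> List[SensitivityEstimate]:
    """First-order and total indices for every factor, one method.

    ``model`` is applied to whole (n, d) matrices and must return length-n
    outputs.  Total variance D is estimated from the pooled A/B evaluations.
    Returns 2 d estimates (first + total per factor).
    """
    if method not in SOBOL_METHODS:
        raise InputError(f"unknown Sobol method {method!r}; choose from {SOBOL_METHODS}")
    names = list(factor_names) if factor_names is not None else [f"x{i + 1}" for i in range(design.d)]
    if len(names) != design.d:
        raise InputError("factor_names length must equal the number of design columns")

    fA = np.asarray(model(design.A), dtype=float)
    fB = np.asarray(model(design.B), dtype=float)
    if fA.shape != (design.n,) or fB.shape != (design.n,):
        raise InputError("model must map an (n, d) matrix to a length-n output vector")

    # Output is centered before every variant, not just saltelli2002: the
    # covariance-form estimators are badly conditioned for non-centered
    # output (their f0^2 correction then dominates the signal), and the
    # difference-based jansen/mauntz forms are unaffected by the shift.
    mu = float(np.concatenate([fA, fB]).mean())
    fA = fA - mu
    fB = fB - mu

    pooled = np.concatenate([fA, fB])
    D = float(pooled.var())
    if D <= 0.0:
        raise DegenerateDataError("model output has zero variance; indices undefined")
    # residual-mean correction: (pooled mean)^2 for the 1993 form, the
    # cross-product of the per-matrix means for the 2002 form
    f0sq_1993 = float(pooled.mean() ** 2)
    f0sq_2002 = float(fA.mean() * fB.mean())

    out: List[SensitivityEstimate] = []
    n = design.n
    for i, name in enumerate(names):
        fABi = np.asarray(model(design.ab(i)), dtype=float) - mu
        if method in ("sobol1993", "saltelli2002"):
            f0sq = f0sq_1993 if method == "sobol1993" else f0sq_2002
            S = (float(np.mean(fB * fABi)) - f0sq) / D
            T = 1.0 - (float(np.mean(fA * fABi)) - f0sq) / D
        elif method == "mauntz2007":
            S = float(np.mean(fB * (fABi - fA))) / D
            T = float(np.mean(fA * (fA - fABi))) / D
        elif method == "jansen":
            T = float(np.mean((fA - fABi) ** 2)) / (2.0 * D)
            S = 1.0 - float(np.mean((fB - fABi) ** 2)) / (2.0 * D)
        else:  # martinez
            S = _corr(fB, fABi)
            T = 1.0 - _corr(fA, fABi)
        for order, value in (("first", S), ("total", T)):
            out.append(
                SensitivityEstimate(
                    factor=name,
                    method=method,
                    order=order,
                    value=value,
                    n=n,
                    out_of_range=not (0.0 <= value <= 1.0),
                )
            )
    return out


def estimate_sobol_order(
    model: Callable[[np.ndarray], np.ndarray],
    design: PickFreezeDesign,
    group: Sequence[int],
    name: str | None = None,
) -> SensitivityEstimate:
    """Closed (grouped) first-order index for a subset of factors.

    All group columns are swapped together; a single-factor group reduces to
    that factor's first-order index, the full set gives ~1 by normalisation.
    """
    idx = list(group)
    if not idx:
        raise InputError("group must be non-empty")
    fA = np.asarray(model(design.A), dtype=float)
    fB = np.asarray(model(design.B), dtype=float)
    mu = float(np.concatenate([fA, fB]).mean())
    fA, fB = fA - mu, fB - mu
    pooled = np.concatenate([fA, fB])
    D = float(pooled.var())
    if D <= 0.0:
        raise DegenerateDataError("model output has zero variance; indices undefined")
    fABg = np.asarray(model(design.ab_group(idx)), dtype=float) - mu
    f0sq = float(fA.mean() * fB.mean())
    S = (float(np.mean(fB * fABg)) - f0sq) / D
    label = name if name is not None else "{" + ",".join(str(i) for i in idx) + "}"
    return SensitivityEstimate(
        factor=label,
        method="sobol1993",
        order="first",
        value=S,
        n=design.n,
        out_of_range=not (0.0 <= S <= 1.0),
    )


def design_from_empirical_marginals(
    matrix: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> PickFreezeDesign:
    """Pick-freeze design whose factor marginals are the data's.

    Each column of A and B is drawn independently (with replacement) from
    the corresponding column of ``matrix``, so the design carries the
    empirical marginal of every factor while the columns are mutually
    independent -- the sampling assumption behind the variance
    decomposition.  This is how a small expression sample (8-24 patients)
    feeds the estimators at a Monte Carlo size large enough to resolve the
    indices.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise InputError("need a 2-D sample matrix with at least 2 rows")
    if n < 2:
        raise InputError("Monte Carlo size n must be >= 2")
    d = X.shape[1]
    A = np.empty((n, d))
    B = np.empty((n, d))
    for j in range(d):
        draws = rng.choice(X[:, j], size=2 * n, replace=True)
        A[:, j], B[:, j] = draws[:n], draws[n:]
    return PickFreezeDesign(A=A, B=B)


def estimate_sobol_from_data(
    matrix: np.ndarray,
    model: Callable[[np.ndarray], np.ndarray],
    method: str,
    factor_names: Sequence[str] | None = None,
) -> List[SensitivityEstimate]:
    """Pick-freeze indices driven by an empirical sample matrix.

    The rows of ``matrix`` (samples x factors, already mapped into the unit
    cube) are split in half into the A and B design matrices, mirroring how
    bootstrapped expression samples feed the estimators in the pipelines.
    Needs at least 4 rows; an odd trailing row is dropped.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise InputError("need a 2-D sample matrix with at least 4 rows")
    half = X.shape[0] // 2
    design = PickFreezeDesign(A=X[:half], B=X[half : 2 * half])
    return estimate_sobol(model, design, method, factor_names=factor_names)
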