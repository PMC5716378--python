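"""Density-based sensitivity indices via Csiszar f-divergences.

The impact of an input factor X_k on the model output U is measured as the
expected f-divergence between the output density and the conditional
output density given X_k.  Rewriting the conditional in terms of the
density ratio

    r(x, u) = p_{X_k,U}(x, u) / (p_{X_k}(x) p_U(u))

turns the index into a plain Monte Carlo average over the observed pairs:

    S^F_{X_k} = E_{(X_k,U)} [ F(1 / r(X_k, U)) ],

for a convex F with F(1) = 0.  Supported divergences: Kullback-Leibler,
Hellinger, total variation, Pearson chi^2 and Neyman chi^2.  The index is
zero when X_k and U are independent and, unlike variance-based indices
(invariant only under linear output transformations), is invariant under
any smooth uniquely invertible transformation of either variable.

Densities are estimated by Gaussian kernel density estimation with a
product kernel for the 2-D joint.  Because the index feeds the *ratio* of
joint to marginal densities through an unbounded F, the bandwidths are
chosen once for the pair and shared between the joint and the marginals:
h = 1.2 min(sd, IQR/1.34) n^(-1/6) per variable (the two-dimensional
Silverman exponent, mildly oversmoothed).  Sharing the bandwidths makes the
leading KDE biases cancel inside the ratio, and the oversmoothing keeps the
noise of F(1/r) small enough that the index is calibrated near zero under
independence -- with the classical 1-D n^(-1/5) rule the total-variation
index reads ~0.08 on independent data purely from estimation noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import DegenerateDataError, InputError
from .estimates import SensitivityEstimate

__all__ = [
    "FDivergenceSpec",
    "DensityRatioEstimate",
    "csiszar_F",
    "estimate_density_ratio",
    "fdiv_index",
]

#: Divergences clamped at zero when estimation noise yields a tiny negative
#: reading (the raw value is retained in ``raw_value``).  The Neyman form is
#: excluded: its F is unbounded below near t = 0 by construction.
_CLAMPED = ("KL", "Hellinger", "TV", "PearsonChi2")

_ALIASES = {
    "kl": "KL",
    "kullback-leibler": "KL",
    "hellinger": "Hellinger",
    "tv": "TV",
    "totalvariation": "TV",
    "pearson": "PearsonChi2",
    "pearsonchi2": "PearsonChi2",
    "neyman": "NeymanChi2",
    "neymanchi2": "NeymanChi2",
}

_F_FUNCS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "KL": lambda t: -np.log(t),
    "Hellinger": lambda t: (np.sqrt(t) - 1.0) ** 2,
    "TV": lambda t: np.abs(t - 1.0),
    "PearsonChi2": lambda t: t**2 - 1.0,
    "NeymanChi2": lambda t: (1.0 - t**2) / t,
}


def _canonical_name(name: str) -> str:
    key = name.replace(" ", "").replace("_", "").lower()
    if key not in _ALIASES:
        raise InputError(
            f"unknown divergence {name!r}; choose from {sorted(set(_ALIASES.values()))}"
        )
    return _ALIASES[key]


def csiszar_F(name: str) -> Callable[[np.ndarray], np.ndarray]:
    """The convex function F (with F(1)=0) naming a supported divergence."""
    return _F_FUNCS[_canonical_name(name)]


@dataclass(frozen=True)
class FDivergenceSpec:
    """A named Csiszar divergence and its convex function F."""

    name: str
    F: Callable[[np.ndarray], np.ndarray] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        canonical = _canonical_name(self.name)
        object.__setattr__(self, "name", canonical)
        if self.F is None:
            object.__setattr__(self, "F", _F_FUNCS[canonical])


@dataclass
class DensityRatioEstimate:
    """Density-ratio values r(x_i, u_i) at the sample pairs, with the
    bandwidths used and the positive floor applied."""

    r: np.ndarray
    floor: float
    bandwidth_x: float
    bandwidth_u: float


def _ratio_bandwidth(v: np.ndarray) -> float:
    """1.2 min(sd, IQR/1.34) n^(-1/6); falls back to sd when the IQR is zero.

    The n^(-1/6) exponent is Silverman's rate for a 2-D density; the same
    bandwidth is reused for the 1-D marginals so the KDE biases cancel in
    the joint/marginal ratio (see module docstring).
    """
    n = v.size
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        raise DegenerateDataError("constant sample: KDE bandwidth undefined")
    return 1.2 * spread * n ** (-1.0 / 6.0)


def _marginal_kde_at_samples(v: np.ndarray, h: float, chunk: int = 512) -> np.ndarray:
    n = v.size
    out = np.empty(n)
    inv = 1.0 / (h * np.sqrt(2.0 * np.pi))
    for start in range(0, n, chunk):
        block = v[start : start + chunk, None]  # (b, 1)
        z = (block - v[None, :]) / h
        out[start : start + chunk] = np.exp(-0.5 * z**2).mean(axis=1) * inv
    return out


def estimate_density_ratio(x_k, u, floor: float = 1e-12) -> DensityRatioEstimate:
    """Estimate r(x, u) = p_joint / (p_x p_u) at the observed sample pairs.

    Gaussian product-kernel KDE with one shared bandwidth per variable
    (see module docstring).  Values are clamped below at ``floor``.  Needs
    at least 30 paired samples.
    """
    x = np.asarray(x_k, dtype=float).ravel()
    uu = np.asarray(u, dtype=float).ravel()
    if x.size != uu.size:
        raise InputError("x_k and u must have equal length")
    if x.size < 30:
        raise InputError("density-ratio estimation needs at least 30 paired samples")
    h_x = _ratio_bandwidth(x)
    h_u = _ratio_bandwidth(uu)

    p_x = _marginal_kde_at_samples(x, h_x)
    p_u = _marginal_kde_at_samples(uu, h_u)

    n = x.size
    p_joint = np.empty(n)
    inv = 1.0 / (2.0 * np.pi * h_x * h_u)
    chunk = 512
    for start in range(0, n, chunk):
        zx = (x[start : start + chunk, None] - x[None, :]) / h_x
        zu = (uu[start : start + chunk, None] - uu[None, :]) / h_u
        p_joint[start : start + chunk] = np.exp(-0.5 * (zx**2 + zu**2)).mean(axis=1) * inv

    r = np.maximum(p_joint / np.maximum(p_x * p_u, floor), floor)
    return DensityRatioEstimate(r=r, floor=floor, bandwidth_x=h_x, bandwidth_u=h_u)


def fdiv_index(
    x_k,
    u,
    spec: FDivergenceSpec | str,
    factor: str = "x",
    floor: float = 1e-12,
) -> SensitivityEstimate:
    """Sample-mean f-divergence sensitivity index S^F_{X_k} = mean F(1/r).

    For KL/Hellinger/TV/Pearson a tiny negative reading (pure estimation
    noise; the population index is non-negative) is clamped at zero with
    the raw value kept in ``raw_value``.
    """
    if isinstance(spec, str):
        spec = FDivergenceSpec(spec)
    ratio = estimate_density_ratio(x_k, u, floor=floor)
    t = 1.0 / ratio.r
    raw = float(np.mean(spec.F(t)))
    value = raw
    clamped = False
    if spec.name in _CLAMPED and raw < 0.0:
        value = 0.0
        clamped = True
    return SensitivityEstimate(
        factor=factor,
        method=f"fdiv:{spec.name}",
        order="first",
        value=value,
        n=int(np.asarray(x_k).size),
        raw_value=raw if clamped else None,
        out_of_range=clamped,
    )
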