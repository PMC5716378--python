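"""Method-tag registry shared by the static and time-course pipelines.

A method tag is one of the pick-freeze variants (``jansen``,
``saltelli2002``, ...), ``hsic:<family>`` or ``fdiv:<name>``.  Given a
sample matrix mapped into the unit cube (the g-function's domain), the
dependence-measure inputs and the evaluated model output, the dispatcher
returns per-factor estimates for one tag.
"""

from __future__ import annotations

from typing import Callable, List, Sequence

import numpy as np

from .errors import InputError
from .estimates import SOBOL_METHODS, SensitivityEstimate
from .fdiv import fdiv_index
from .hsic import KernelSpec, hsic_indices_matrix
from .sobol import design_from_empirical_marginals, estimate_sobol


def validate_methods(methods: Sequence[str]) -> List[str]:
    if not methods:
        raise InputError("at least one method tag is required")
    for m in methods:
        parse_method(m)  # raises on unknown tags
    return list(methods)


def parse_method(tag: str):
    """Split a tag into (kind, detail); raises InputError on unknown tags."""
    if tag in SOBOL_METHODS:
        return "sobol", tag
    if tag.startswith("hsic:"):
        family = tag.split(":", 1)[1]
        KernelSpec(family)  # validation
        return "hsic", family
    if tag.startswith("fdiv:"):
        from .fdiv import FDivergenceSpec

        name = tag.split(":", 1)[1]
        return "fdiv", FDivergenceSpec(name).name
    raise InputError(
        f"unknown method tag {tag!r}; use one of {SOBOL_METHODS}, 'hsic:<kernel>' or 'fdiv:<F>'"
    )


def compute_indices(
    unit_matrix: np.ndarray,
    dep_matrix: np.ndarray,
    u: np.ndarray,
    model: Callable[[np.ndarray], np.ndarray],
    method: str,
    factor_names: Sequence[str],
    mc_rng: np.random.Generator | None = None,
    n_mc: int = 1000,
) -> List[SensitivityEstimate]:
    """Per-factor estimates for one method tag.

    ``unit_matrix`` (samples x factors, inside [0,1]) supplies the empirical
    factor marginals from which the pick-freeze Sobol design is drawn at
    Monte Carlo size ``n_mc`` (evaluating the model directly on the handful
    of data rows would leave the variance estimates noise-bound);
    ``dep_matrix`` provides the factor columns paired with the output ``u``
    for the dependence measures (HSIC, f-divergence).
    """
    kind, detail = parse_method(method)
    if kind == "sobol":
        rng = mc_rng if mc_rng is not None else np.random.default_rng(0)
        design = design_from_empirical_marginals(unit_matrix, n_mc, rng)
        return estimate_sobol(model, design, method, factor_names=factor_names)
    if kind == "hsic":
        spec = KernelSpec(detail)
        return hsic_indices_matrix(dep_matrix, u, spec, factor_names=factor_names)
    return [
        fdiv_index(dep_matrix[:, j], u, detail, factor=name)
        for j, name in enumerate(factor_names)
    ]
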