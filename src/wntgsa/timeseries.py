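"""Time-course experiments: fold changes and deviations in fold changes.

For every recorded fold change a measurement distribution is generated
(Normal around the recorded value, sd 0.005, plus jitter), giving a sample
matrix of genes at each time point; the g-function output is evaluated over
that matrix and per-gene sensitivity indices are computed.  The *deviation*
experiment does the same per consecutive time interval <t_i, t_{i+1}>, the
deviation samples being differences of independent draws at the two
endpoints -- the quantity Weber's law ties to the relative stimulus step.

Mapping data into the g-function's unit-cube domain: in scaled mode each
gene column is min-max scaled on its own; in non-scaled mode (the mode the
source analysis reports) one affine map over the *whole* matrix sends the
global minimum to 0 and maximum to 1, so cross-gene geometry -- which gene
sits where relative to the others, and how wide its measurement
distribution is -- survives.  With the multiplicative g-function this is
what lets the index of a gene vary over time: a factor whose mapped values
sit near the kink at 0.5 (where |4x-2| is small) has a large relative
effect on the product, while one parked near the cube faces contributes an
almost constant factor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._dispatch import compute_indices, validate_methods
from .errors import DegenerateDataError, InputError, PipelineError
from .models import GFunctionModel, draw_importance_coefficients, g_function
from .synthetic import NoiseConfig, TimeCourse, perturb_measurement

__all__ = [
    "IntervalLabel",
    "deviation_series",
    "sign_pattern",
    "two_fold_filter",
    "fold_change_experiment",
    "deviation_experiment",
]


@dataclass(frozen=True)
class IntervalLabel:
    """A consecutive time interval, displayed as ``<t_i,t_{i+1}>`` in hours."""

    from_hour: float
    to_hour: float

    def __post_init__(self):
        if not self.from_hour < self.to_hour:
            raise InputError("from_hour must be earlier than to_hour")

    @property
    def display(self) -> str:
        def fmt(h: float) -> str:
            return f"{h:g}"

        return f"<{fmt(self.from_hour)},{fmt(self.to_hour)}>"


def deviation_series(tc: TimeCourse) -> np.ndarray:
    """Consecutive deviations Delta_i = fc(t_{i+1}) - fc(t_i)."""
    if len(tc.hours) < 2:
        raise InputError("deviation series needs at least 2 time points")
    return np.diff(tc.fold_change)


def sign_pattern(deviations) -> str:
    """One character per deviation: '+' / '-' / '0' for exact zeros."""
    dev = np.asarray(deviations, dtype=float)
    if dev.size == 0:
        raise InputError("sign_pattern needs at least one deviation")
    return "".join("+" if d > 0 else "-" if d < 0 else "0" for d in dev)


def two_fold_filter(courses: Sequence[TimeCourse]) -> List[TimeCourse]:
    """Keep genes whose |fold change| exceeds 2 at one or more time points."""
    return [tc for tc in courses if float(np.max(np.abs(tc.fold_change))) > 2.0]


def _common_grid(courses: Sequence[TimeCourse]) -> Tuple[float, ...]:
    if not courses:
        raise InputError("need at least one time course")
    hours = courses[0].hours
    for tc in courses[1:]:
        if tc.hours != hours:
            raise InputError(
                f"time grid mismatch: {tc.gene} has {tc.hours}, expected {hours}"
            )
    return hours


def _unit_cube_map(raw: np.ndarray, scaled: bool) -> np.ndarray:
    """Map a samples-x-genes matrix into [0,1]^d for the g-function."""
    if scaled:
        lo = raw.min(axis=0, keepdims=True)
        hi = raw.max(axis=0, keepdims=True)
        span = hi - lo
        if np.any(span <= 0):
            raise DegenerateDataError("constant sample column: per-gene scaling undefined")
        return (raw - lo) / span
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        raise DegenerateDataError("constant sample matrix: affine map undefined")
    return (raw - lo) / (hi - lo)


def _run_units(
    sample_blocks: List[Tuple[str, np.ndarray]],
    genes: List[str],
    methods: Sequence[str],
    model: GFunctionModel,
    scaled: bool,
    unit_key: str,
    mc_seed_base: int = 0,
) -> Tuple[pd.DataFrame, List[dict]]:
    """Shared core: indices per analysis unit (a time point or an interval)."""
    records: List[dict] = []
    failures: List[dict] = []
    for block_idx, (label, raw) in enumerate(sample_blocks):
        try:
            X = _unit_cube_map(raw, scaled)
            u = g_function(X, model)
            mc_rng = np.random.default_rng([mc_seed_base, block_idx, 0x50B01])
            for method in methods:
                try:
                    for est in compute_indices(X, X, u, model, method, genes,
                                               mc_rng=mc_rng):
                        records.append(
                            {
                                "gene": est.factor,
                                unit_key: label,
                                "method": est.method,
                                "order": est.order,
                                "value": est.value,
                            }
                        )
                except (DegenerateDataError, InputError) as exc:
                    failures.append({unit_key: label, "method": method, "error": str(exc)})
        except DegenerateDataError as exc:
            failures.append({unit_key: label, "method": "*", "error": str(exc)})
    if not records:
        raise PipelineError("no analysis unit produced any estimate")
    return pd.DataFrame(records), failures


def _prepare(courses, methods, noise, a_seed, a_coefficients):
    methods = validate_methods(methods)
    hours = _common_grid(courses)
    genes = [tc.gene for tc in courses]
    if len(set(genes)) != len(genes):
        raise InputError("duplicate gene names in the time courses")
    d = len(courses)
    a = (
        np.asarray(a_coefficients, dtype=float)
        if a_coefficients is not None
        else draw_importance_coefficients(d, a_seed)
    )
    if a.shape != (d,):
        raise InputError(f"a_coefficients must have length {d}")
    fc = np.vstack([tc.fold_change for tc in courses])  # genes x time
    return methods, hours, genes, GFunctionModel(a), a, fc


def fold_change_experiment(
    courses: Sequence[TimeCourse],
    methods: Sequence[str],
    noise: Optional[NoiseConfig] = None,
    a_seed: int = 0,
    scaled: bool = False,
    a_coefficients: Optional[np.ndarray] = None,
    sd_overrides: Optional[Dict[Tuple[str, float], float]] = None,
) -> Tuple[pd.DataFrame, Dict]:
    """Per-gene sensitivity indices at every time point.

    At each time point, ``noise.n_samples`` perturbed draws per gene form
    the sample matrix.  ``sd_overrides`` maps (gene, hour) to a replacement
    measurement sd, which is how tests plant genes with inflated or
    suppressed dependence at chosen time points.  Returns a tidy table
    keyed by (gene, hour, method, order) and a run log.
    """
    noise = noise if noise is not None else NoiseConfig()
    methods, hours, genes, model, a, fc = _prepare(courses, methods, noise, a_seed, a_coefficients)
    overrides = dict(sd_overrides or {})
    rng = np.random.default_rng(noise.rng_seed)

    blocks = []
    for t, hour in enumerate(hours):
        raw = np.empty((noise.n_samples, len(genes)))
        for j, gene in enumerate(genes):
            cfg = noise
            sd = overrides.get((gene, hour))
            if sd is not None:
                cfg = NoiseConfig(sd=sd, jitter_factor=noise.jitter_factor,
                                  n_samples=noise.n_samples, rng_seed=noise.rng_seed)
            raw[:, j] = perturb_measurement(fc[j, t], cfg, rng)
        blocks.append((float(hour), raw))

    result, failures = _run_units(blocks, genes, methods, model, scaled, "hour",
                                  mc_seed_base=noise.rng_seed)
    result = result.sort_values(["method", "order", "hour", "gene"], kind="stable").reset_index(drop=True)
    run_log = {
        "experiment": "fold_change",
        "methods": list(methods),
        "hours": list(hours),
        "noise": {"sd": noise.sd, "jitter_factor": noise.jitter_factor,
                  "n_samples": noise.n_samples, "rng_seed": noise.rng_seed},
        "a_seed": a_seed,
        "a": a.tolist(),
        "scaled": scaled,
        "genes": genes,
        "failures": failures,
    }
    return result, run_log


def deviation_experiment(
    courses: Sequence[TimeCourse],
    methods: Sequence[str],
    noise: Optional[NoiseConfig] = None,
    a_seed: int = 0,
    scaled: bool = False,
    a_coefficients: Optional[np.ndarray] = None,
    sd_overrides: Optional[Dict[Tuple[str, float], float]] = None,
) -> Tuple[pd.DataFrame, Dict]:
    """Per-gene sensitivity indices for every consecutive time interval.

    Each gene's deviation sample at interval <t_i, t_{i+1}> is the
    difference of independent perturbed draws at the two endpoints (the
    measurement distributions are generated per time snapshot, not with
    common random numbers).  Needs at least 3 time points.  Returns a tidy
    table keyed by (gene, interval, method, order) and a run log.
    """
    noise = noise if noise is not None else NoiseConfig()
    methods, hours, genes, model, a, fc = _prepare(courses, methods, noise, a_seed, a_coefficients)
    if len(hours) < 3:
        raise InputError("deviation experiment needs at least 3 time points")
    overrides = dict(sd_overrides or {})
    rng = np.random.default_rng(noise.rng_seed)

    def draws(gene_idx: int, t: int) -> np.ndarray:
        gene, hour = genes[gene_idx], hours[t]
        cfg = noise
        sd = overrides.get((gene, hour))
        if sd is not None:
            cfg = NoiseConfig(sd=sd, jitter_factor=noise.jitter_factor,
                              n_samples=noise.n_samples, rng_seed=noise.rng_seed)
        return perturb_measurement(fc[gene_idx, t], cfg, rng)

    blocks = []
    for t in range(len(hours) - 1):
        label = IntervalLabel(hours[t], hours[t + 1]).display
        raw = np.empty((noise.n_samples, len(genes)))
        for j in range(len(genes)):
            raw[:, j] = draws(j, t + 1) - draws(j, t)
        blocks.append((label, raw))

    result, failures = _run_units(blocks, genes, methods, model, scaled, "interval",
                                  mc_seed_base=noise.rng_seed)
    result = result.sort_values(["method", "order", "gene"], kind="stable").reset_index(drop=True)
    run_log = {
        "experiment": "deviation",
        "methods": list(methods),
        "hours": list(hours),
        "intervals": [IntervalLabel(a_, b_).display for a_, b_ in zip(hours, hours[1:])],
        "noise": {"sd": noise.sd, "jitter_factor": noise.jitter_factor,
                  "n_samples": noise.n_samples, "rng_seed": noise.rng_seed},
        "a_seed": a_seed,
        "a": a.tolist(),
        "scaled": scaled,
        "genes": genes,
        "failures": failures,
    }
    return result, run_log
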