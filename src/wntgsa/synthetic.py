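"""Synthetic expression data with the structure the analyses assume.

Two datasets are emulated.  The *static* dataset mimics a colorectal-cancer
expression panel: 18 Wnt-related genes (secreted antagonists of the SFRP,
DKK, WIF1 and DACT families plus pathway target genes) measured in 24
normal-mucosa and 24 tumor samples.  Expression is log-normal (positive,
right-skewed) with a per-gene activation/repression contrast between the
two conditions expressed in units of the log-scale noise sd.

The *time-course* dataset mimics a WNT3A-stimulation qPCR experiment:
signed fold changes for 71 genes at hours 1, 3, 6, 12 and 24 relative to
the unstimulated 0-hour baseline (positive = up-regulation).  Trajectories
are built deviation-first so that requested sign patterns of consecutive
deviations (e.g. "+-++") are realised exactly, and trajectory magnitudes
are scaled so a configurable fraction of genes clears the more-than-two-fold
significance filter.

The measurement-noise model turns one recorded value into a sample:
Normal(value, sd = 0.005) draws plus uniform jitter whose half-width is
factor * range/50 (the convention of R's ``jitter``, with its degenerate
fallbacks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "DEFAULT_STATIC_GENES",
    "DEFAULT_HOURS",
    "ExpressionTable",
    "TimeCourse",
    "NoiseConfig",
    "generate_static_dataset",
    "generate_timecourse_dataset",
    "perturb_measurement",
    "jitter",
    "normalize_pattern",
]

DEFAULT_STATIC_GENES = (
    "SFRP1", "SFRP2", "SFRP3", "SFRP4", "SFRP5",
    "DKK1", "DKK2", "DKK3-1", "DKK3-2", "DKK4",
    "WIF1", "DACT1", "DACT2", "DACT3",
    "LEF1", "MYC", "CD44", "CCND1",
)

DEFAULT_HOURS = (1.0, 3.0, 6.0, 12.0, 24.0)

CONDITIONS = ("normal", "tumor")


def normalize_pattern(pattern: str) -> str:
    """Map typographic sign characters (U+2212 minus) to ASCII '+'/'-'/'0'."""
    out = pattern.replace("−", "-").replace("–", "-")
    if any(ch not in "+-0" for ch in out):
        raise InputError(f"malformed sign pattern {pattern!r}: only +, - (or U+2212), 0 allowed")
    return out


@dataclass
class ExpressionTable:
    """Static samples x genes matrix with a normal/tumor label per sample.

    ``data`` is indexed by sample id with one column per gene; ``condition``
    shares the index and takes values in {normal, tumor}.
    """

    data: pd.DataFrame
    condition: pd.Series

    def __post_init__(self):
        if self.data.shape[1] < 1:
            raise InputError("expression table needs at least one gene")
        if self.data.columns.duplicated().any():
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise InputError(f"duplicate gene names: {dupes}")
        if self.data.isna().any().any():
            raise InputError("expression table contains missing values")
        if not self.data.index.equals(self.condition.index):
            raise InputError("condition labels must be indexed like the sample rows")
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise InputError(f"unknown condition labels {sorted(bad)}; allowed: {CONDITIONS}")

    @property
    def genes(self) -> List[str]:
        return list(self.data.columns)

    @property
    def d(self) -> int:
        return self.data.shape[1]

    def subset(self, condition: str) -> pd.DataFrame:
        if condition not in CONDITIONS:
            raise InputError(f"condition must be one of {CONDITIONS}")
        return self.data.loc[self.condition == condition]


@dataclass
class TimeCourse:
    """Signed fold changes of one gene over ordered time points (hours)."""

    gene: str
    hours: Tuple[float, ...]
    fold_change: np.ndarray
    planted_pattern: Optional[str] = None

    def __post_init__(self):
        hours = tuple(float(h) for h in self.hours)
        if any(b <= a for a, b in zip(hours, hours[1:])):
            raise InputError(f"hours must be strictly increasing, got {hours}")
        fc = np.asarray(self.fold_change, dtype=float)
        if fc.shape != (len(hours),):
            raise InputError(
                f"{self.gene}: fold_change length {fc.size} != number of hours {len(hours)}"
            )
        self.hours = hours
        self.fold_change = fc
        if self.planted_pattern is not None:
            self.planted_pattern = normalize_pattern(self.planted_pattern)


@dataclass
class NoiseConfig:
    """Measurement-noise model: Normal(value, sd) plus uniform jitter.

    ``sd`` defaults to 0.005 expression units, ``n_samples`` to 1000 draws
    per recorded measurement.
    """

    sd: float = 0.005
    jitter_factor: float = 1.0
    n_samples: int = 1000
    rng_seed: int = 0

    def __post_init__(self):
        if not self.sd > 0:
            raise InputError("sd must be positive")
        if self.n_samples < 30:
            raise InputError("n_samples must be at least 30")
        if self.jitter_factor < 0:
            raise InputError("jitter_factor must be non-negative")


def generate_static_dataset(
    n_normal: int = 24,
    n_tumor: int = 24,
    effect_profile: Optional[Dict[str, float]] = None,
    rng_seed: int = 0,
    genes: Sequence[str] = DEFAULT_STATIC_GENES,
    log_sd: float = 0.25,
) -> ExpressionTable:
    """Log-normal expression for two conditions with per-gene contrasts.

    ``effect_profile`` maps gene -> contrast, the normal-vs-tumor difference
    of log-scale means in units of ``log_sd`` (positive = higher in tumor,
    i.e. activation; negative = repression).  Genes absent from the profile
    get zero contrast, so an empty/None profile yields a null dataset in
    which the two conditions are statistically indistinguishable.
    """
    if n_normal < 2 or n_tumor < 2:
        raise InputError("need at least 2 samples per condition")
    genes = list(genes)
    if len(genes) < 1:
        raise InputError("need at least one gene")
    effect_profile = dict(effect_profile or {})
    unknown = set(effect_profile) - set(genes)
    if unknown:
        raise InputError(f"effect_profile names unknown genes: {sorted(unknown)}")

    rng = np.random.default_rng(rng_seed)
    base_mu = rng.normal(2.0, 0.5, size=len(genes))  # per-gene baseline log-expression
    contrast = np.array([effect_profile.get(g, 0.0) for g in genes])

    log_normal = rng.normal(base_mu, log_sd, size=(n_normal, len(genes)))
    log_tumor = rng.normal(base_mu + contrast * log_sd, log_sd, size=(n_tumor, len(genes)))

    ids = [f"N{i + 1:02d}" for i in range(n_normal)] + [f"T{i + 1:02d}" for i in range(n_tumor)]
    data = pd.DataFrame(
        np.exp(np.vstack([log_normal, log_tumor])), index=pd.Index(ids, name="sample_id"),
        columns=genes,
    )
    condition = pd.Series(["normal"] * n_normal + ["tumor"] * n_tumor, index=data.index,
                          name="condition")
    return ExpressionTable(data=data, condition=condition)


def _trajectory_from_signs(signs: str, rng: np.random.Generator) -> np.ndarray:
    """Fold-change series whose consecutive deviations carry the given signs."""
    dev = np.empty(len(signs))
    for i, s in enumerate(signs):
        if s == "+":
            dev[i] = rng.uniform(0.2, 1.2)
        elif s == "-":
            dev[i] = -rng.uniform(0.2, 1.2)
        else:
            dev[i] = 0.0
    start = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
    return start + np.concatenate([[0.0], np.cumsum(dev)])


def generate_timecourse_dataset(
    n_genes: int = 71,
    hours: Sequence[float] = DEFAULT_HOURS,
    pattern_book: Optional[Dict[str, str]] = None,
    rng_seed: int = 0,
    two_fold_fraction: float = 0.5,
) -> List[TimeCourse]:
    """Fold-change trajectories with exact planted sign patterns.

    Genes named in ``pattern_book`` come first and realise their requested
    deviation sign strings exactly (strings of length len(hours)-1 over
    +/-, typographic minus accepted).  Remaining genes get random patterns.
    round(two_fold_fraction * n_genes) genes are scaled to exceed the
    two-fold filter (|fold change| > 2 somewhere); pattern signs survive the
    scaling because it is positive.
    """
    if n_genes < 1:
        raise InputError("n_genes must be >= 1")
    hours = tuple(float(h) for h in hours)
    if any(b <= a for a, b in zip(hours, hours[1:])):
        raise InputError("hours must be strictly increasing")
    if not 0.0 <= two_fold_fraction <= 1.0:
        raise InputError("two_fold_fraction must lie in [0, 1]")
    n_dev = len(hours) - 1
    book = {g: normalize_pattern(p) for g, p in (pattern_book or {}).items()}
    for g, p in book.items():
        if len(p) != n_dev:
            raise InputError(f"{g}: pattern {p!r} must have length {n_dev}")
    if len(book) > n_genes:
        raise InputError("pattern_book has more genes than n_genes")

    rng = np.random.default_rng(rng_seed)
    names = list(book)
    names += [f"GENE{i + 1:03d}" for i in range(n_genes - len(names))]

    n_pass = int(round(two_fold_fraction * n_genes))
    pass_flags = np.zeros(n_genes, dtype=bool)
    pass_flags[rng.choice(n_genes, size=n_pass, replace=False)] = True

    courses: List[TimeCourse] = []
    for j, name in enumerate(names):
        signs = book.get(name)
        if signs is None:
            signs = "".join(rng.choice(["+", "-"]) for _ in range(n_dev))
        fc = _trajectory_from_signs(signs, rng)
        peak = np.max(np.abs(fc))
        target = rng.uniform(2.2, 4.0) if pass_flags[j] else rng.uniform(0.3, 1.8)
        fc = fc * (target / peak)
        courses.append(TimeCourse(gene=name, hours=hours, fold_change=fc,
                                  planted_pattern=signs if name in book else None))
    return courses


def jitter(values, factor: float = 1.0, rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Add uniform noise on +/- amount, amount = factor * (max - min) / 50.

    Degenerate fallbacks follow R's ``jitter``: for a zero range the amount
    is factor * |value| / 50, or 0.0002 when the value itself is zero.
    A factor of 0 returns the values unchanged.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise InputError("jitter needs a non-empty value array")
    if factor == 0:
        return v.copy()
    rng = rng if rng is not None else np.random.default_rng()
    span = float(v.max() - v.min())
    if span > 0:
        amount = factor * span / 50.0
    else:
        value = float(v.flat[0])
        amount = factor * abs(value) / 50.0 if value != 0 else 0.0002
    return v + rng.uniform(-amount, amount, size=v.shape)


def perturb_measurement(
    value: float,
    cfg: NoiseConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Sample ``cfg.n_samples`` noisy replicates of one recorded value.

    Draws Normal(value, sd) and adds jitter; the jitter half-width scales
    with the realised spread of the draws, so the sample sd stays close to
    (slightly above) the configured sd.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    draws = rng.normal(value, cfg.sd, size=cfg.n_samples)
    return jitter(draws, cfg.jitter_factor, rng)
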