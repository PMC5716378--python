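"""Result container for sensitivity indices.

Every estimator in the package (variance-based, density-based and
kernel-based) reports its result as a :class:`SensitivityEstimate`, so
pipelines can aggregate heterogeneous methods into one tidy table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import InputError

#: Variance-based estimator tags (pick-freeze Monte Carlo variants).
SOBOL_METHODS = ("sobol1993", "saltelli2002", "mauntz2007", "jansen", "martinez")

_ORDERS = ("first", "total")


@dataclass
class SensitivityEstimate:
    """One sensitivity index for one factor.

    ``method`` is a registry tag: one of :data:`SOBOL_METHODS`, or
    ``"fdiv:<F>"`` / ``"hsic:<kernel>"`` for the density- and kernel-based
    measures (those carry a single index and are tagged order ``first``).
    ``raw_value`` keeps the pre-clamp value when estimation noise produced
    an out-of-range reading; ``out_of_range`` flags it.
    """

    factor: str
    method: str
    order: str
    value: float
    n: int
    band_low: Optional[float] = None
    band_high: Optional[float] = None
    raw_value: Optional[float] = None
    out_of_range: bool = field(default=False)

    def __post_init__(self):
        if self.order not in _ORDERS:
            raise InputError(f"order must be one of {_ORDERS}, got {self.order!r}")
        if self.band_low is not None and self.band_high is not None:
            if not (self.band_low <= self.value <= self.band_high):
                raise InputError(
                    "confidence band must bracket the value: "
                    f"{self.band_low} <= {self.value} <= {self.band_high} fails"
                )


def estimates_to_frame(estimates: Iterable[SensitivityEstimate]) -> pd.DataFrame:
    """Flatten estimates into a tidy DataFrame (one row per index)."""
    rows = [
        {
            "factor": e.factor,
            "method": e.method,
            "order": e.order,
            "value": e.value,
            "band_low": e.band_low,
            "band_high": e.band_high,
            "n": e.n,
            "out_of_range": e.out_of_range,
        }
        for e in estimates
    ]
    return pd.DataFrame(rows)
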