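"""CSV readers/writers, run configuration and reporting.

The on-disk dialect is fixed: comma-separated, dot decimal, UTF-8, header
mandatory, numbers written with 10 significant digits so that write/read
round trips are bit-identical at that precision.

Static table:   ``sample_id,condition,<gene>,...`` with condition in
                {normal, tumor}.
Time course:    ``gene,h<hour>,...`` with strictly increasing hours
                (default ``gene,h1,h3,h6,h12,h24``).
Pattern book:   ``gene,pattern``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._dispatch import validate_methods
from .errors import InputError, ParseError
from .static_pipeline import BootstrapConfig
from .synthetic import CONDITIONS, ExpressionTable, NoiseConfig, TimeCourse, normalize_pattern

__all__ = [
    "RunConfig",
    "read_expression_csv",
    "write_expression_csv",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_pattern_book_csv",
    "write_pattern_book_csv",
    "write_indices_csv",
    "write_manifest",
    "run_report",
]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """A validated pipeline configuration; everything needed to reproduce a run."""

    methods: List[str]
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    a_seed: int = 0
    scaled: bool = False
    output_dir: Optional[Path] = None

    def __post_init__(self):
        self.methods = validate_methods(self.methods)
        if self.output_dir is not None:
            self.output_dir = Path(self.output_dir)

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "noise": vars(self.noise).copy(),
            "bootstrap": {
                "sizes": list(self.bootstrap.sizes),
                "n_boot": self.bootstrap.n_boot,
                "ci_level": self.bootstrap.ci_level,
                "rng_seed": self.bootstrap.rng_seed,
            },
            "a_seed": self.a_seed,
            "scaled": self.scaled,
            "output_dir": str(self.output_dir) if self.output_dir else None,
        }


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\r\n").split(",")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except ParseError:
        raise
    except Exception as exc:  # malformed CSV structure
        raise ParseError(f"cannot parse CSV: {exc}", path=path) from exc
    if len(set(header)) != len(header):  # pandas silently renames duplicates
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise ParseError(f"duplicate columns in header: {dupes}", path=path, row=1)
    return df


def _parse_float(raw: str, path, row: int, column: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"non-numeric cell {raw!r}", path=path, row=row, column=column) from None


def read_expression_csv(path) -> ExpressionTable:
    """Read and validate a static expression table."""
    df = _read_csv(path)
    cols = list(df.columns)
    if cols[:2] != ["sample_id", "condition"]:
        raise ParseError(
            f"header must start with 'sample_id,condition', got {cols[:2]}", path=path, row=1
        )
    genes = cols[2:]
    if not genes:
        raise ParseError("no gene columns found", path=path, row=1)
    if len(set(genes)) != len(genes):
        raise ParseError("duplicate gene columns in header", path=path, row=1)
    values = np.empty((len(df), len(genes)))
    for i in range(len(df)):
        row_no = i + 2  # header is row 1
        cond = df.iat[i, 1]
        if cond not in CONDITIONS:
            raise ParseError(
                f"unknown condition label {cond!r} (allowed: {'/'.join(CONDITIONS)})",
                path=path, row=row_no, column="condition",
            )
        for j, g in enumerate(genes):
            values[i, j] = _parse_float(df.iat[i, 2 + j], path, row_no, g)
    data = pd.DataFrame(values, index=pd.Index(df["sample_id"], name="sample_id"), columns=genes)
    condition = pd.Series(df["condition"].to_numpy(), index=data.index, name="condition")
    try:
        return ExpressionTable(data=data, condition=condition)
    except InputError as exc:
        raise ParseError(str(exc), path=path) from exc


def write_expression_csv(table: ExpressionTable, path) -> None:
    out = table.data.copy()
    out.insert(0, "condition", table.condition)
    out.to_csv(path, float_format=_FLOAT_FMT)


def read_timecourse_csv(path) -> List[TimeCourse]:
    """Read time courses on a shared, strictly increasing hour grid."""
    df = _read_csv(path)
    cols = list(df.columns)
    if not cols or cols[0] != "gene":
        raise ParseError("header must start with 'gene'", path=path, row=1)
    hour_cols = cols[1:]
    if not hour_cols:
        raise ParseError("no hour columns found", path=path, row=1)
    hours = []
    for c in hour_cols:
        if not c.startswith("h"):
            raise ParseError(f"hour column {c!r} must look like 'h<hours>'", path=path, row=1, column=c)
        try:
            hours.append(float(c[1:]))
        except ValueError:
            raise ParseError(f"hour column {c!r} is not numeric", path=path, row=1, column=c) from None
    if any(b <= a for a, b in zip(hours, hours[1:])):
        raise ParseError(f"hour columns must strictly increase, got {hours}", path=path, row=1)
    courses = []
    seen = set()
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        gene = rec.gene
        if gene in seen:
            raise ParseError(f"duplicate gene {gene!r}", path=path, row=i, column="gene")
        seen.add(gene)
        fc = [_parse_float(v, path, i, c) for v, c in zip(rec[1:], hour_cols)]
        courses.append(TimeCourse(gene=gene, hours=tuple(hours), fold_change=np.array(fc)))
    if not courses:
        raise ParseError("file contains no time courses", path=path)
    return courses


def write_timecourse_csv(courses: Sequence[TimeCourse], path) -> None:
    if not courses:
        raise InputError("nothing to write")
    hours = courses[0].hours
    cols = ["gene"] + [f"h{h:g}" for h in hours]
    rows = [[tc.gene] + [_FLOAT_FMT % v for v in tc.fold_change] for tc in courses]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_pattern_book_csv(path) -> Dict[str, str]:
    df = _read_csv(path)
    if list(df.columns) != ["gene", "pattern"]:
        raise ParseError("header must be 'gene,pattern'", path=path, row=1)
    book = {}
    for i, rec in enumerate(df.itertuples(index=False), start=2):
        try:
            book[rec.gene] = normalize_pattern(rec.pattern)
        except InputError as exc:
            raise ParseError(str(exc), path=path, row=i, column="pattern") from exc
    return book


def write_pattern_book_csv(book: Dict[str, str], path) -> None:
    pd.DataFrame({"gene": list(book), "pattern": list(book.values())}).to_csv(path, index=False)


def write_indices_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _config_hash(payload: dict) -> str:
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(run_log: dict, path, extra: Optional[dict] = None) -> dict:
    """Write the machine-readable run manifest (config, seeds, versions).

    The manifest together with the package version is sufficient to
    reproduce every output bit-identically.
    """
    from . import __version__

    manifest = {
        "package": "wntgsa",
        "version": __version__,
        "run_log": run_log,
        **(extra or {}),
    }
    manifest["config_hash"] = _config_hash(
        {k: v for k, v in manifest.items() if k != "config_hash"}
    )
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def run_report(results: pd.DataFrame, top_k: int = 3) -> str:
    """Human-readable summary: top-k factors per method and analysis unit.

    ``results`` is any tidy index table with a 'gene' (or 'factor') column,
    a 'method' column, one unit column among condition/hour/interval, and a
    'value' or 'mean' column.
    """
    if results is None or len(results) == 0:
        raise InputError("cannot report on empty results")
    df = results.copy()
    factor_col = "gene" if "gene" in df.columns else "factor"
    value_col = "mean" if "mean" in df.columns else "value"
    unit_col = next((c for c in ("condition", "hour", "interval") if c in df.columns), None)
    if factor_col not in df.columns or value_col not in df.columns or unit_col is None:
        raise InputError("results table lacks the expected tidy columns")
    lines = []
    group_cols = ["method", unit_col] + (["order"] if "order" in df.columns else [])
    for key, sub in df.groupby(group_cols, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        top = sub.sort_values(value_col, ascending=False).head(top_k)
        ranked = ", ".join(f"{r[factor_col]}={r[value_col]:.4g}" for _, r in top.iterrows())
        lines.append(f"{' / '.join(str(k) for k in key)}: {ranked}")
    return "\n".join(lines)
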