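"""Delimited-text feature tables, preprocessing, and run configuration.

Feature tables are plain TSV/CSV with sample ids in the first column by
default (samples as rows, features as columns); the transposed layout is
selected with ``orientation="features_by_samples"``.  Declared NA tokens
map to missing; everything else must parse as a number.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["DEFAULT_NA_TOKENS", "RunConfig", "read_matrix", "write_results", "pqn_log2"]

DEFAULT_NA_TOKENS: tuple[str, ...] = ("NA", "NaN", "nan", "")

Orientation = Literal["samples_by_features", "features_by_samples"]


@dataclass
class RunConfig:
    """Resolved configuration of a command-line run, echoed with results."""

    command: str
    input: Optional[str] = None
    output: Optional[str] = None
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS
    orientation: Orientation = "samples_by_features"
    mode: str = "auto"
    outcome: Optional[str] = None
    covariates: Sequence[str] = field(default_factory=list)
    seed: Optional[int] = None
    alpha: float = 0.05
    correction: str = "bonferroni"
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["na_tokens"] = list(self.na_tokens)
        d["covariates"] = list(self.covariates)
        return json.dumps(d, indent=2, sort_keys=True)


def _infer_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: Union[str, Path],
    na_tokens: Sequence[str] = DEFAULT_NA_TOKENS,
    orientation: Orientation = "samples_by_features",
    sep: Optional[str] = None,
) -> pd.DataFrame:
    """Read a delimited feature table into a samples x features DataFrame.

    Missing entries (any declared NA token, matched after stripping
    whitespace) become NaN.  Duplicate sample or feature ids and cells
    that are neither numeric nor an NA token raise, naming the location.
    """
    path = Path(path)
    if sep is None:
        sep = _infer_sep(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in {path.name}: {dups}")
    if raw.columns.has_duplicates:
        dups = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate column ids in {path.name}: {dups}")
    tokens = {t.strip() for t in na_tokens}
    out = pd.DataFrame(index=raw.index.copy(), columns=raw.columns.copy(), dtype=float)
    for col in raw.columns:
        cells = raw[col].astype(str).str.strip()
        is_na = cells.isin(tokens)
        numeric = pd.to_numeric(cells.where(~is_na), errors="coerce")
        bad = ~is_na & numeric.isna()
        if bad.any():
            row = raw.index[bad.to_numpy()][0]
            raise ValueError(
                f"non-numeric cell at row {row!r}, column {col!r}: "
                f"{raw.loc[row, col]!r} (not a declared NA token)"
            )
        out[col] = numeric
    if orientation == "features_by_samples":
        out = out.T
    elif orientation != "samples_by_features":
        raise ValueError(f"unknown orientation {orientation!r}")
    return out


def write_results(
    df: pd.DataFrame,
    path: Union[str, Path],
    config: Optional[RunConfig] = None,
) -> None:
    """Write a results table as TSV; if a config is given, write the
    resolved-run JSON next to it (same stem, ``.json``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True)
    if config is not None:
        summary = path.with_suffix(".json")
        summary.write_text(config.to_json() + "\n")


def pqn_log2(
    matrix: pd.DataFrame, max_missing_for_reference: float = 0.20
) -> pd.DataFrame:
    """Probabilistic-quotient normalization followed by log2.

    The reference profile is the per-feature median over samples, using
    only features with a missing fraction below
    ``max_missing_for_reference``.  Each sample is divided by the median
    ratio of its values to the reference (its dilution quotient), then
    all observed values are log2-transformed.  Missingness is untouched.
    Raw intensities must be positive.
    """
    if not isinstance(matrix, pd.DataFrame):
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
    vals = matrix.to_numpy(dtype=float)
    if np.any(vals[~np.isnan(vals)] <= 0):
        raise ValueError("PQN + log2 requires strictly positive observed intensities")
    miss_frac = matrix.isna().mean(axis=0)
    eligible = miss_frac < max_missing_for_reference
    if not eligible.any():
        raise ValueError(
            f"no feature has missingness below {max_missing_for_reference:.0%}; "
            "cannot build a PQN reference"
        )
    ref = matrix.loc[:, eligible].median(axis=0, skipna=True)
    quotients = matrix.loc[:, eligible].div(ref, axis=1).median(axis=1, skipna=True)
    if quotients.isna().any() or (quotients <= 0).any():
        raise ValueError("PQN quotient undefined for at least one sample")
    normalized = matrix.div(quotients, axis=0)
    return np.log2(normalized)
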