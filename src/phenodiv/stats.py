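"""Per-trait descriptive statistics and coefficients of variation.

The trait-diversity table reports, per trait, the minimum, maximum, mean,
sample standard deviation and coefficient of variation (CV = sd/mean × 100),
plus the unweighted panel-mean CV across all traits.  The CV is the
field's standard unit-free dispersion measure for comparing variability
across traits with incommensurate units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TraitMatrix

__all__ = ["TraitSummary", "summarize", "rank_cv", "mean_cv_percent"]


@dataclass
class TraitSummary:
    """Per-trait min/max/mean/sd/CV table plus the panel-mean CV."""

    table: pd.DataFrame  # index: trait; columns: minimum, maximum, mean, sd, cv_percent
    mean_cv_percent: float

    def row(self, trait: str) -> pd.Series:
        return self.table.loc[trait]


def summarize(matrix: TraitMatrix, *, ddof: int = 1) -> TraitSummary:
    """Descriptive statistics per trait (sample SD by default, ``ddof=1``).

    A trait whose mean is not positive gets ``cv_percent = NaN`` (the CV is
    undefined for non-positive means); such traits are excluded from the
    panel-mean CV, and the run continues.
    """
    X = matrix.values
    if X.shape[0] < 2:
        raise ValueError("summarize requires at least 2 accessions")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean * 100.0, np.nan)
    table = pd.DataFrame(
        {
            "minimum": X.min(axis=0),
            "maximum": X.max(axis=0),
            "mean": mean,
            "sd": sd,
            "cv_percent": cv,
        },
        index=pd.Index(matrix.trait_names, name="trait"),
    )
    return TraitSummary(table=table, mean_cv_percent=float(np.nanmean(cv)))


def mean_cv_percent(cv_values) -> float:
    """Unweighted mean of a collection of per-trait CVs (percent)."""
    return float(np.mean(np.asarray(list(cv_values), dtype=float)))


def rank_cv(summary: TraitSummary) -> list[tuple[str, float]]:
    """Traits ordered by descending CV; ties keep catalog order."""
    items = list(summary.table["cv_percent"].items())
    # stable sort preserves catalog order within ties
    return sorted(items, key=lambda kv: -kv[1])
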