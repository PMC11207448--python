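"""Pairwise Pearson correlation among traits with significance stars.

Every trait pair gets a Pearson r and a two-sided p-value from the exact
t-transform ``t = r * sqrt((n-2) / (1-r^2))`` on ``n-2`` degrees of
freedom.  Significance stars follow the strict thresholds p < 0.05 (*),
p < 0.01 (**) and p < 0.001 (***); a p exactly equal to a threshold earns
no star.  No multiple-testing correction is applied by default, matching
common practice in germplasm-screening tables; a Holm adjustment can be
switched on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .simulate import TraitMatrix, UnknownTraitError

__all__ = ["CorrelationResult", "correlate", "extract_anchors", "stars_for_p",
           "pearson_with_p"]


def stars_for_p(p: float) -> str:
    """Map a p-value to its significance stars (strict thresholds)."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p via the t-transform on n-2 df.

    Returns ``(nan, nan)`` if either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p)


@dataclass
class CorrelationResult:
    """Trait × trait Pearson r, p-values and star labels."""

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def cell(self, trait_a: str, trait_b: str) -> tuple[float, float, str]:
        for t in (trait_a, trait_b):
            if t not in self.r.index:
                raise UnknownTraitError(t)
        return (
            float(self.r.loc[trait_a, trait_b]),
            float(self.p.loc[trait_a, trait_b]),
            str(self.stars.loc[trait_a, trait_b]),
        )

    def to_long(self) -> pd.DataFrame:
        """Long-format table (trait_a, trait_b, r, p, stars), upper triangle."""
        names = list(self.r.index)
        rows = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                rows.append(
                    (a, b, self.r.loc[a, b], self.p.loc[a, b], self.stars.loc[a, b])
                )
        return pd.DataFrame(rows, columns=["trait_a", "trait_b", "r", "p", "stars"])


def correlate(matrix: TraitMatrix, *, holm: bool = False) -> CorrelationResult:
    """All-pairs Pearson correlation of the panel's traits.

    Constant columns yield NaN (flagged-undefined) in every cell involving
    them rather than a silent zero.  With ``holm=True`` the off-diagonal
    p-values are Holm-adjusted before star assignment.
    """
    X = matrix.values
    n, p_traits = X.shape
    if n < 3:
        raise ValueError("correlate requires at least 3 accessions")
    names = list(matrix.trait_names)

    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.clip(R, -1.0, 1.0)
    R = (R + R.T) / 2.0  # corrcoef is symmetric only to rounding; make it exact
    R[constant, :] = np.nan
    R[:, constant] = np.nan
    np.fill_diagonal(R, np.where(constant, np.nan, 1.0))

    with np.errstate(invalid="ignore", divide="ignore"):
        T = R * np.sqrt((n - 2) / (1.0 - R * R))
    P = 2.0 * sps.t.sf(np.abs(T), df=n - 2)
    P[np.abs(R) == 1.0] = 0.0
    np.fill_diagonal(P, 0.0)
    P[np.isnan(R)] = np.nan

    if holm:
        iu = np.triu_indices(p_traits, k=1)
        flat = P[iu]
        ok = ~np.isnan(flat)
        if ok.any():
            adj = flat.copy()
            adj[ok] = multipletests(flat[ok], method="holm")[1]
            P[iu] = adj
            P.T[iu] = adj

    S = np.frompyfunc(stars_for_p, 1, 1)(P).astype(object)
    idx = pd.Index(names, name="trait")
    return CorrelationResult(
        r=pd.DataFrame(R, index=idx, columns=names),
        p=pd.DataFrame(P, index=idx, columns=names),
        stars=pd.DataFrame(S, index=idx, columns=names),
    )


def extract_anchors(
    result: CorrelationResult, pairs: list[tuple[str, str]]
) -> list[tuple[tuple[str, str], float, str]]:
    """Report (pair, r, stars) for the requested trait pairs."""
    out = []
    for a, b in pairs:
        r, _p, s = result.cell(a, b)
        out.append(((a, b), r, s))
    return out
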