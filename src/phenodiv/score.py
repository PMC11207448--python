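"""Membership-function composite scoring (D-value) of accessions.

Each retained principal-component score column is rescaled to [0, 1] by
the fuzzy membership function

    mu(x_j) = (x_j - x_min) / (x_max - x_min)

with the minimum and maximum taken panel-wise across accessions.  The
component weights are the retained components' contribution rates
normalized over their own sum, W_i = P_i / sum(P_i), and the composite
score of accession j is the weighted sum D_j = sum_i mu_ji W_i in [0, 1].
Higher D means a better all-round phenotype; accessions are ranked by
descending D with competition ranking (ties share the smallest rank and
subsequent ranks skip, the "1-2-2-4" convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlation import pearson_with_p, stars_for_p
from .pca import PCAResult, pca, retain, select_key_traits, standardize
from .simulate import TraitMatrix

__all__ = [
    "MembershipEvaluation",
    "membership",
    "compute_weights",
    "d_value",
    "rank_competition",
    "d_trait_correlation",
    "evaluate",
]


def membership(scores: np.ndarray) -> np.ndarray:
    """Column-wise min-max normalization of component scores to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be 2-D (accessions × components)")
    if scores.shape[0] < 2:
        raise ValueError("membership needs at least 2 accessions (min = max otherwise)")
    lo = scores.min(axis=0)
    hi = scores.max(axis=0)
    span = hi - lo
    if np.any(span == 0):
        bad = list(np.nonzero(span == 0)[0])
        raise ValueError(f"constant score column(s) {bad}: membership undefined")
    return (scores - lo) / span


def compute_weights(contribution_percent) -> np.ndarray:
    """Normalize contribution rates to weights summing to 1."""
    p = np.asarray(list(contribution_percent), dtype=float)
    if p.size == 0 or np.any(p <= 0):
        raise ValueError("contribution rates must be positive")
    return p / p.sum()


def d_value(mu: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted sum of membership values per accession: D_j = sum mu_ji W_i."""
    mu = np.asarray(mu, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if mu.shape[1] != weights.size:
        raise ValueError(
            f"mu has {mu.shape[1]} columns but {weights.size} weights given"
        )
    return mu @ weights


def rank_competition(values) -> np.ndarray:
    """Descending competition ranks ("1-2-2-4"): ties share the smallest rank."""
    v = np.asarray(list(values), dtype=float)
    order = np.argsort(-v, kind="stable")
    ranks = np.empty(v.size, dtype=int)
    prev_val: float | None = None
    prev_rank = 0
    for pos, idx in enumerate(order, start=1):
        if prev_val is not None and v[idx] == prev_val:
            ranks[idx] = prev_rank
        else:
            ranks[idx] = pos
            prev_rank = pos
            prev_val = v[idx]
    return ranks


def d_trait_correlation(d_values: np.ndarray, matrix: TraitMatrix) -> pd.DataFrame:
    """Pearson r of the composite D against each raw trait, with stars."""
    rows = []
    for trait in matrix.trait_names:
        r, p = pearson_with_p(d_values, matrix.column(trait))
        rows.append((trait, r, p, stars_for_p(p)))
    return pd.DataFrame(rows, columns=["trait", "r", "p", "stars"]).set_index("trait")


@dataclass
class MembershipEvaluation:
    """Full composite evaluation: mu matrix, weights, D-values and ranks."""

    mu: np.ndarray
    weights: np.ndarray
    d_values: np.ndarray
    ranks: np.ndarray
    retained: list[int]
    key_traits: list[str]
    pca_result: PCAResult

    def table(self, matrix: TraitMatrix, decimals: int = 3) -> pd.DataFrame:
        """Accession / D / rank report (D rounded for display only)."""
        return pd.DataFrame(
            {
                "accession": matrix.accession_ids,
                "D": np.round(self.d_values, decimals),
                "rank": self.ranks,
            }
        )


def evaluate(matrix: TraitMatrix, *, eigenvalue_threshold: float = 1.0) -> MembershipEvaluation:
    """Run standardize → PCA → retain → membership → weights → D → rank."""
    z = standardize(matrix)
    res = pca(z, matrix.trait_names)
    kept = retain(res, eigenvalue_threshold)
    if not kept:
        raise ValueError("no components retained; lower the eigenvalue threshold")
    scores = res.scores[:, kept]
    mu = membership(scores)
    weights = compute_weights(res.contribution_percent[kept])
    d = d_value(mu, weights)
    selection = select_key_traits(res, kept)
    return MembershipEvaluation(
        mu=mu,
        weights=weights,
        d_values=d,
        ranks=rank_competition(d),
        retained=kept,
        key_traits=selection.key_traits,
        pca_result=res,
    )
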