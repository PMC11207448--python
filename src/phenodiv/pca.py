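"""Correlation-matrix PCA and key-trait screening.

Traits are z-scored (sample SD), the principal components are the
eigenpairs of the trait correlation matrix, and components are retained
by the Kaiser rule (eigenvalue strictly greater than 1).  Contribution
rates are eigenvalue / p × 100, so all p components sum to 100 %.

Key-trait screening condenses the retained components to named traits:
for each retained component in order, take the trait with the largest
absolute loading; a trait already claimed by an earlier component is
skipped, so k components can yield fewer than k distinct traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TraitMatrix

__all__ = [
    "PCAResult",
    "KeyTraitSelection",
    "standardize",
    "pca",
    "retain",
    "cumulative_contribution",
    "select_key_traits",
]


def standardize(matrix: TraitMatrix | np.ndarray) -> np.ndarray:
    """Z-score each trait column (mean 0, sample SD 1, ``ddof=1``)."""
    X = matrix.values if isinstance(matrix, TraitMatrix) else np.asarray(matrix, float)
    if X.shape[0] < 2:
        raise ValueError("standardize requires at least 2 rows")
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        names = (
            list(matrix.trait_names)
            if isinstance(matrix, TraitMatrix)
            else [str(j) for j in range(X.shape[1])]
        )
        bad = [names[j] for j in np.nonzero(sd == 0)[0]]
        raise ValueError(f"constant column(s) cannot be standardized: {bad}")
    return (X - X.mean(axis=0)) / sd


@dataclass
class PCAResult:
    """Eigenpairs of the trait correlation matrix with contribution rates."""

    eigenvalues: np.ndarray            # descending, length p
    loadings: pd.DataFrame             # traits × components, unit-norm eigenvectors
    contribution_percent: np.ndarray   # lambda_i / p * 100
    cumulative_percent: np.ndarray     # running sum of contribution_percent
    scores: np.ndarray                 # n × p projections of the z-scored data

    @property
    def n_traits(self) -> int:
        return self.loadings.shape[0]


def pca(z: np.ndarray, trait_names: list[str] | tuple[str, ...] | None = None) -> PCAResult:
    """Eigen-decomposition of the sample correlation matrix of ``z``.

    ``z`` is expected to be the standardized panel (then its sample
    covariance is the trait correlation matrix).  Eigenvalues come out
    descending; each eigenvector's sign is fixed so its largest-magnitude
    element is positive, making loadings tables reproducible.
    """
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    if n < 2:
        raise ValueError("pca requires at least 2 rows")
    if trait_names is None:
        trait_names = [f"T{j}" for j in range(p)]
    corr = np.cov(z, rowvar=False, ddof=1)
    corr = np.atleast_2d(corr)
    w, v = np.linalg.eigh(corr)
    order = np.argsort(w)[::-1]
    w = w[order]
    v = v[:, order]
    # deterministic sign: largest-|.| element of each column positive,
    # catalog order breaking exact magnitude ties
    for j in range(p):
        col = v[:, j]
        imax = int(np.argmax(np.abs(np.round(col, 12))))
        if col[imax] < 0:
            v[:, j] = -col
    w = np.clip(w, 0.0, None)
    contrib = w / p * 100.0
    comp_names = [f"PC{j + 1}" for j in range(p)]
    loadings = pd.DataFrame(v, index=pd.Index(trait_names, name="trait"),
                            columns=comp_names)
    return PCAResult(
        eigenvalues=w,
        loadings=loadings,
        contribution_percent=contrib,
        cumulative_percent=np.cumsum(contrib),
        scores=z @ v,
    )


def retain(result: PCAResult | np.ndarray, threshold: float = 1.0) -> list[int]:
    """Indices of components whose eigenvalue strictly exceeds ``threshold``."""
    w = result.eigenvalues if isinstance(result, PCAResult) else np.asarray(result)
    return [int(i) for i in np.nonzero(w > threshold)[0]]


def cumulative_contribution(eigenvalues, p: int) -> float:
    """Total contribution (%) of a set of eigenvalues out of ``p`` traits."""
    w = np.asarray(list(eigenvalues), dtype=float)
    if w.size == 0:
        return 0.0
    return float(w.sum() / p * 100.0)


@dataclass
class KeyTraitSelection:
    """Per-component top trait and the deduplicated key-trait list."""

    per_component: list[tuple[int, str]]  # (component index, top trait by |loading|)
    key_traits: list[str]                 # deduplicated, component order


def select_key_traits(result: PCAResult, retained: list[int]) -> KeyTraitSelection:
    """Pick each retained component's max-|loading| trait, deduplicated.

    Ties in |loading| break toward the earlier catalog position.
    """
    if not retained:
        raise ValueError("no retained components to select key traits from")
    traits = list(result.loadings.index)
    per_component: list[tuple[int, str]] = []
    key: list[str] = []
    for idx in retained:
        col = np.abs(result.loadings.iloc[:, idx].to_numpy())
        top = traits[int(np.argmax(col))]  # argmax returns first max: catalog order
        per_component.append((idx, top))
        if top not in key:
            key.append(top)
    return KeyTraitSelection(per_component=per_component, key_traits=key)
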