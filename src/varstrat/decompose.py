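"""Principal component analysis of the polished matrix and per-variable
contribution decomposition.

The input matrix is already column-standardized, so eigendecomposition of its
sample covariance is equivalent to correlation-matrix PCA; standardization
lives in the polishing step and the decomposition stays pure.  A fixed sign
convention (each loading vector flipped so its largest-magnitude entry is
positive, ties broken by first position) makes output deterministic across
runs and platforms.

Per-component variable contributions are ``100 x squared loading`` (unit-norm
loading columns, so each component's contributions sum to 100).  The overall
contribution pools the retained components weighted by their variance shares
— the package's formalization of the usual "which variable drives the
structure" reading of a contribution bar chart.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .polish import PolishedMatrix

__all__ = [
    "PCADecomposition",
    "ContributionTable",
    "ContributionPCA",
    "pca",
    "select_components",
    "variable_contributions",
]


@dataclass
class PCADecomposition:
    """Scores (variant x component), unit-norm loadings (variable x
    component) and non-increasing variance shares summing to one."""

    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_share: np.ndarray
    eigenvalues: np.ndarray

    @property
    def n_variants(self) -> int:
        return self.scores.shape[0]

    @property
    def n_variables(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _as_frame(matrix: PolishedMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.values if isinstance(matrix, PolishedMatrix) else matrix


class ContributionPCA(BaseEstimator, TransformerMixin):
    """Deterministic covariance-PCA transformer for standardized matrices.

    Fitted attributes: ``components_`` (component x variable), ``loadings_``
    (variable x component frame), ``explained_variance_``,
    ``explained_variance_ratio_``, ``feature_names_in_``.
    """

    def fit(self, X: PolishedMatrix | pd.DataFrame, y=None) -> "ContributionPCA":
        frame = _as_frame(X)
        if frame.shape[0] < 2:
            raise ValueError("PCA requires at least 2 rows")
        values = np.asarray(frame, dtype=float)
        sds = values.std(axis=0, ddof=1)
        if np.any(sds <= 0):
            constant = [str(c) for c, s in zip(frame.columns, sds) if s <= 0]
            raise ValueError(f"constant column(s): {', '.join(constant)}")
        cov = np.cov(values, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        eigval, eigvec = np.linalg.eigh(cov)
        order = np.argsort(eigval)[::-1]  # ties keep original column order via stable reverse
        eigval = np.clip(eigval[order], 0.0, None)
        eigvec = eigvec[:, order]
        # Sign convention: largest-|entry| of each loading vector positive.
        for j in range(eigvec.shape[1]):
            i = int(np.argmax(np.abs(eigvec[:, j])))
            if eigvec[i, j] < 0:
                eigvec[:, j] = -eigvec[:, j]
        names = [f"PC{j + 1}" for j in range(eigvec.shape[1])]
        self.feature_names_in_ = list(frame.columns)
        self.components_ = eigvec.T
        self.loadings_ = pd.DataFrame(eigvec, index=frame.columns, columns=names)
        self.explained_variance_ = eigval
        self.explained_variance_ratio_ = eigval / eigval.sum()
        return self

    def transform(self, X: PolishedMatrix | pd.DataFrame) -> pd.DataFrame:
        frame = _as_frame(X)
        scores = np.asarray(frame, dtype=float) @ self.components_.T
        return pd.DataFrame(scores, index=frame.index, columns=self.loadings_.columns)

    def decomposition(self, X: PolishedMatrix | pd.DataFrame) -> PCADecomposition:
        return PCADecomposition(
            scores=self.transform(X),
            loadings=self.loadings_.copy(),
            variance_share=self.explained_variance_ratio_.copy(),
            eigenvalues=self.explained_variance_.copy(),
        )


def pca(matrix: PolishedMatrix | pd.DataFrame) -> PCADecomposition:
    """Fit-and-decompose in one call (thin wrapper over ContributionPCA)."""
    return ContributionPCA().fit(matrix).decomposition(matrix)


def select_components(decomp: PCADecomposition, threshold: float = 0.85) -> int:
    """Smallest component count whose cumulative variance share exceeds
    ``threshold``; ``threshold=1.0`` keeps every nonzero-share component."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    shares = decomp.variance_share
    cumulative = np.cumsum(shares)
    exceeding = np.nonzero(cumulative > threshold)[0]
    if len(exceeding):
        return int(exceeding[0]) + 1
    return int(np.sum(shares > 1e-12))


@dataclass
class ContributionTable:
    """Per-(variable, component) and pooled variable contributions in %."""

    per_component: pd.DataFrame  # variable x component, columns sum to 100
    overall: pd.Series           # variance-share-weighted over retained PCs
    n_components: int


def variable_contributions(decomp: PCADecomposition, n_components: int) -> ContributionTable:
    if not 1 <= n_components <= decomp.n_components:
        raise ValueError(
            f"n_components must be in 1..{decomp.n_components}, got {n_components}"
        )
    sq = decomp.loadings**2 * 100.0
    retained = sq.iloc[:, :n_components]
    shares = decomp.variance_share[:n_components]
    overall = (retained * shares).sum(axis=1) / shares.sum()
    overall.name = "overall_pct"
    return ContributionTable(per_component=sq, overall=overall, n_components=n_components)
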