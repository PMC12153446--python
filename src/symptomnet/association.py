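"""Nonparametric association matrix feeding the network estimator.

Ordinal 4-category items carry massive ties, so associations are
Spearman rank correlations with average ranks. A pairwise rank
correlation matrix need not be positive semidefinite; an eigenvalue
clipping step restores PSD before the matrix enters the graphical
lasso.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ItemResponseMatrix:
    """Complete n-by-p matrix of ordinal responses with node metadata."""

    values: np.ndarray
    node_labels: list[str]
    community_of: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (respondents x items)")
        if self.values.shape[1] != len(self.node_labels):
            raise ValueError("node_labels length must match column count")
        if np.isnan(self.values).any():
            raise ValueError("item response matrix must be complete")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        node_labels: Sequence[str],
        community_of: Mapping[str, str],
    ) -> "ItemResponseMatrix":
        cols = [lab.lower() for lab in node_labels]
        return cls(
            values=frame[cols].to_numpy(dtype=float),
            node_labels=list(node_labels),
            community_of=dict(community_of),
        )

    def subset(self, rows: np.ndarray) -> "ItemResponseMatrix":
        return ItemResponseMatrix(
            self.values[rows], list(self.node_labels), dict(self.community_of)
        )


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal association matrix plus the n it came from."""

    values: np.ndarray
    n_effective: int
    node_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        p = self.values.shape[0]
        if self.values.shape != (p, p):
            raise ValueError("correlation matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not self.node_labels:
            self.node_labels = [f"V{i+1}" for i in range(p)]

    @property
    def p(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.values, index=self.node_labels, columns=self.node_labels
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, n_effective: int) -> "CorrelationMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(), n_effective, list(df.columns))


def spearman_matrix(data: ItemResponseMatrix) -> CorrelationMatrix:
    """Pairwise Spearman correlations (average ranks for ties).

    Raises if any item has zero variance, naming the item: a rank
    correlation with a constant column is undefined.
    """
    if data.n < 3:
        raise ValueError("Spearman matrix requires at least 3 observations")
    variances = data.values.var(axis=0)
    dead = [lab for lab, v in zip(data.node_labels, variances) if v == 0]
    if dead:
        raise ValueError(f"zero-variance item(s): {', '.join(dead)}")
    rho = stats.spearmanr(data.values).statistic
    if data.p == 2:  # scipy returns a scalar for two columns
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho = np.asarray(rho, dtype=float)
    rho = (rho + rho.T) / 2.0
    np.fill_diagonal(rho, 1.0)
    return CorrelationMatrix(rho, data.n, list(data.node_labels))


def nearest_psd(S: CorrelationMatrix, tol: float = 1e-8) -> CorrelationMatrix:
    """Eigenvalue-clipping PSD repair with unit diagonal restored.

    A matrix that is already PSD is returned unchanged (same object),
    so the repair is a no-op on well-behaved inputs.
    """
    vals = np.linalg.eigvalsh(S.values)
    if vals.min() >= 0:
        return S
    w, V = np.linalg.eigh(S.values)
    w = np.clip(w, 0.0, None)
    A = (V * w) @ V.T
    d = np.sqrt(np.diag(A))
    # clipping cannot zero a diagonal of a matrix with unit diagonal
    A = A / np.outer(d, d)
    A = (A + A.T) / 2.0
    np.fill_diagonal(A, 1.0)
    if np.linalg.eigvalsh(A).min() < -tol:
        raise RuntimeError("PSD repair failed to reach the tolerance")
    return CorrelationMatrix(A, S.n_effective, list(S.node_labels))
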