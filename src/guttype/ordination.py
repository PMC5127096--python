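"""PCA biplot coordinates/loadings and PCoA (classical MDS) coordinates.

PCA operates on the column-centered (not scaled) sample x taxon matrix, so
axis loadings are directly interpretable as taxon contributions to sample
placement.  PCoA applies Gower double-centering to squared distances and
keeps positive-eigenvalue axes only; for Euclidean input it reproduces the
original configuration exactly, while for sqrt-JSD (metric but not
necessarily Euclidean) the dropped negative eigenvalue mass is recorded.

Axis signs are fixed so the largest-magnitude loading (PCA) or coordinate
(PCoA) on each axis is positive, which makes outputs reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .abundance import AbundanceTable
from .clustering import DistanceMatrix

__all__ = ["OrdinationResult", "pca_biplot", "pcoa"]


@dataclass
class OrdinationResult:
    """Sample coordinates, per-axis variance fractions and (PCA) loadings."""

    sample_coords: pd.DataFrame
    axis_contributions: np.ndarray
    method: str
    loadings: pd.DataFrame | None = None
    negative_eigenvalue_fraction: float = 0.0

    def contributions_percent(self, n_axes: int = 2) -> list[float]:
        """Leading axis contributions as percentages rounded to one decimal."""
        return [round(100.0 * c, 1) for c in self.axis_contributions[:n_axes]]

    def write_coords(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            pct = ", ".join(
                f"{ax}: {100 * c:.1f}%"
                for ax, c in zip(self.sample_coords.columns, self.axis_contributions)
            )
            fh.write(f"# axis contributions: {pct}\n")
            self.sample_coords.to_csv(fh, sep="\t")

    def write_loadings(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        if self.loadings is None:
            raise ValueError(f"{self.method} ordination has no loadings")
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.loadings.to_csv(fh, sep="\t")


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    flips = np.sign(vectors[np.argmax(np.abs(vectors), axis=0), np.arange(vectors.shape[1])])
    flips[flips == 0] = 1.0
    return flips


def pca_biplot(table: AbundanceTable) -> OrdinationResult:
    """Principal component analysis of the centered relative-abundance matrix."""
    if table.kind != "relative":
        raise ValueError("pca_biplot expects a relative-abundance table")
    x = table.values
    n, p = x.shape
    if n < 3 or p < 2:
        raise ValueError("PCA needs at least 3 samples and 2 taxa")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    total = eigval.sum()
    if total <= 0:
        raise ValueError("zero-variance matrix: all samples identical")
    flips = _fix_signs(eigvec)
    eigvec = eigvec * flips
    scores = centered @ eigvec
    axes = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    return OrdinationResult(
        sample_coords=pd.DataFrame(scores, index=table.sample_ids, columns=axes),
        axis_contributions=eigval / total,
        loadings=pd.DataFrame(eigvec, index=table.taxon_ids, columns=axes),
        method="pca",
    )


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinate analysis via Gower double-centering."""
    d = dist.values
    n = d.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 samples")
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    scale = max(abs(eigval[0]), abs(eigval[-1]), 1.0)
    tol = 1e-8 * scale
    positive = eigval > tol
    if not positive.any():
        raise ValueError("zero-variance distances: no positive eigenvalues")
    neg_mass = float(-eigval[eigval < -tol].sum())
    pos_sum = float(eigval[positive].sum())
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    coords = coords * _fix_signs(coords)
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        sample_coords=pd.DataFrame(coords, index=dist.sample_ids, columns=axes),
        axis_contributions=eigval[positive] / pos_sum,
        method="pcoa",
        negative_eigenvalue_fraction=neg_mass / (pos_sum + neg_mass),
    )
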