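"""PCA of morphological descriptor tables with biplot coordinate export.

Descriptors are CPVO/UPOV-style ordinal scores with heterogeneous ranges,
so the default standardizes each descriptor to unit variance before the
decomposition (``scale=True``); raw covariance PCA is available with
``scale=False``.

The decomposition is a singular value decomposition of the centered (and
optionally scaled) matrix.  Component signs are fixed so the
largest-magnitude loading of each component is positive, making outputs
comparable across runs and implementations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import DescriptorTable


@dataclass
class PCAResult:
    """Scores, loadings and variance decomposition of a descriptor PCA."""

    accessions: list[str]
    descriptors: list[str]
    scores: np.ndarray  # (n_accessions, n_components)
    loadings: np.ndarray  # (n_descriptors, n_components)
    singular_values: np.ndarray
    var_explained: np.ndarray  # fractions, non-increasing, sums to 1

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(table: DescriptorTable, scale: bool = True) -> PCAResult:
    """Principal component analysis of the descriptor matrix.

    Columns are centered (and unit-scaled when ``scale``); the variance
    explained by component i is sigma_i^2 / sum(sigma^2).  Zero-variance
    descriptors are an error under scaling.
    """
    x = table.values.astype(float)
    x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if zero.size:
            names = [table.descriptors[i] for i in zero]
            raise ValueError(f"zero-variance descriptor(s) under scaling: {names}")
        x = x / sd
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # fix sign: largest-|loading| entry of each component made positive
    for j in range(vt.shape[0]):
        k = int(np.argmax(np.abs(vt[j])))
        if vt[j, k] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    scores = u * s
    total = float((s**2).sum())
    var_explained = s**2 / total if total > 0 else np.zeros_like(s)
    return PCAResult(
        accessions=list(table.accessions),
        descriptors=list(table.descriptors),
        scores=scores,
        loadings=vt.T,
        singular_values=s,
        var_explained=var_explained,
    )


def biplot_coordinates(
    result: PCAResult, pcs: tuple[int, int] = (0, 1), arrow_scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Accession scores and descriptor arrows for a two-component biplot.

    Arrows are loadings scaled by the singular values raised to
    ``arrow_scale`` (1 gives covariance-biplot arrows, 0 raw loadings).
    Returns (scores[:, pcs], arrows[:, pcs]).
    """
    for p in pcs:
        if not (0 <= p < result.n_components):
            raise IndexError(f"component index {p} out of range")
    cols = list(pcs)
    scores = result.scores[:, cols]
    arrows = result.loadings[:, cols] * (result.singular_values[cols] ** arrow_scale)
    return scores, arrows


def variance_table(result: PCAResult) -> list[tuple[str, float, float]]:
    """(component, pct variance, cumulative pct) rows for reporting."""
    rows = []
    cum = 0.0
    for i, v in enumerate(result.var_explained, start=1):
        cum += float(v)
        rows.append((f"PC{i}", round(100 * float(v), 4), round(100 * cum, 4)))
    return rows
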