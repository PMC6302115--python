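"""Population-structure PCA on variance-standardized genotypes.

Columns are standardized as (g - 2p) / sqrt(2p(1-p)) (the PLINK ``--pca``
convention), missing dosages are mean-imputed (0 after centering), and the
samples x samples covariance of the standardized matrix, scaled by 1/#markers,
is eigendecomposed.  Variance fractions are taken over ALL components so
"PC1+PC2 explain X%" statements are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypePanel

logger = logging.getLogger(__name__)


def standardize_genotypes(panel: GenotypePanel):
    """Variance-standardized dosage matrix.

    Returns (X, kept_idx): X is samples x polymorphic-markers with column
    means 0 (exactly, given mean imputation); monomorphic columns are dropped
    with a warning.
    """
    d = panel.dosages_float()
    mask = ~np.isnan(d)
    n_obs = mask.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.nansum(d, axis=0) / (2.0 * n_obs)
    poly = (n_obs > 0) & (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if n_dropped:
        logger.warning("standardize_genotypes: dropped %d monomorphic/empty column(s)",
                       n_dropped)
    kept = np.nonzero(poly)[0]
    d = d[:, kept]
    p = p[kept]
    x = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x = np.where(np.isnan(x), 0.0, x)    # mean imputation after centering
    return x, kept


@dataclass
class PCAResult:
    """Principal components of a genotype panel.

    coordinates : samples x k PC scores (eigenvector * sqrt(eigenvalue)).
    eigenvalues : all sample-covariance eigenvalues, descending.
    pct_variance : percent of total variance per retained component.
    population_labels : one label per sample.
    """

    coordinates: np.ndarray
    eigenvalues: np.ndarray
    pct_variance: np.ndarray
    population_labels: list
    sample_ids: list

    def to_frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        df = pd.DataFrame(self.coordinates,
                          columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "population", self.population_labels)
        return df


def pca(panel: GenotypePanel, k: int = 10,
        population_labels: list | None = None) -> PCAResult:
    """PCA of a (possibly multi-population) genotype panel.

    Eigendecomposition of G = X X^T / m over the standardized matrix X; the
    top-k coordinates are returned with variance fractions computed over all
    components.  Deterministic sign convention: in each component the
    largest-magnitude sample loading is made positive.  ``k`` beyond the
    matrix rank is truncated with a warning.
    """
    if panel.n_samples < 2:
        raise ValueError("need at least two samples")
    x, kept = standardize_genotypes(panel)
    if kept.size < 2:
        raise ValueError("need at least two polymorphic markers")
    m = x.shape[1]
    g = (x @ x.T) / m
    evals, evecs = np.linalg.eigh(g)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    total = evals.sum()
    rank = int(np.sum(evals > 1e-12 * max(total, 1.0)))
    if k > rank:
        logger.warning("pca: k=%d exceeds rank %d; truncating", k, rank)
        k = rank
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    for j in range(k):
        i_max = np.argmax(np.abs(coords[:, j]))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    pct = 100.0 * evals[:k] / total
    labels = population_labels if population_labels is not None \
        else [panel.population_name] * panel.n_samples
    return PCAResult(coordinates=coords, eigenvalues=evals, pct_variance=pct,
                     population_labels=list(labels),
                     sample_ids=list(panel.sample_ids))
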