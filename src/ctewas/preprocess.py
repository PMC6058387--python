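"""Probe filtering, quantile normalization and principal components.

The PC scores computed here supply the batch covariate used by the
per-probe association regressions: the array is run on the combined
sorted matrix (both cell fractions together) and the per-sample PC1
scores are then passed into the per-fraction models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ContractError, ValidationError

log = logging.getLogger(__name__)


@dataclass
class PCScores:
    """Sample scores on the top principal components.

    ``scores``: samples x components DataFrame (columns PC1, PC2, ...),
    centered per component; ``explained_variance``: fraction of total
    variance per component, in decreasing order; ``loadings``: probes x
    components.
    """

    scores: pd.DataFrame
    explained_variance: np.ndarray
    loadings: pd.DataFrame


def filter_probes_by_detection(
    beta: pd.DataFrame, detection_p: pd.DataFrame | None, threshold: float = 0.01
) -> pd.DataFrame:
    """Keep probes with detection p <= threshold in every sample.

    ``detection_p`` may be None (no detection values available, e.g.
    synthetic data); the matrix then passes through unchanged.
    """
    if detection_p is None:
        log.info("no detection-p matrix supplied; probe filter is a pass-through")
        return beta
    if detection_p.shape != beta.shape:
        raise ValidationError(
            f"detection-p shape {detection_p.shape} != beta shape {beta.shape}"
        )
    detp = detection_p.reindex(index=beta.index, columns=beta.columns)
    if detp.isna().any().any():
        raise ValidationError("detection-p matrix does not cover the beta matrix")
    keep = (detp.to_numpy() <= threshold).all(axis=1)
    log.info("detection filter: %d of %d probes retained", int(keep.sum()), len(keep))
    return beta.loc[keep]


def drop_incomplete_probes(beta: pd.DataFrame) -> pd.DataFrame:
    """Drop probes with any missing beta (required before QN / PCA)."""
    keep = beta.notna().all(axis=1)
    if not keep.all():
        log.info("dropping %d probes with missing values", int((~keep).sum()))
    return beta.loc[keep]


def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Force every sample onto the mean empirical distribution.

    After normalization each column's sorted values equal the per-rank
    means across columns; ties receive the value at their average rank
    (linear interpolation between adjacent rank means).  Idempotent.
    """
    if beta.isna().any().any():
        raise ValidationError("quantile normalization requires a missing-free matrix")
    X = beta.to_numpy(dtype=float)
    n = X.shape[0]
    rank_means = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    grid = np.arange(n, dtype=float)
    for j in range(X.shape[1]):
        r = stats.rankdata(X[:, j], method="average") - 1.0
        out[:, j] = np.interp(r, grid, rank_means)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


def compute_principal_components(beta: pd.DataFrame, n_components: int) -> PCScores:
    """PCA of samples on probe-centered data.

    Sign convention: for each component the loading with the largest
    absolute value is forced positive, making scores reproducible.
    """
    if beta.isna().any().any():
        raise ValidationError("PCA requires a missing-free matrix")
    n_samples = beta.shape[1]
    if n_samples < 2:
        raise ContractError("PCA needs at least 2 samples")
    if n_components > n_samples - 1:
        raise ContractError(
            f"n_components={n_components} exceeds n_samples-1={n_samples - 1}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(beta.to_numpy(dtype=float).T)
    loadings = pca.components_.T  # probes x components
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1.0
            scores[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCScores(
        scores=pd.DataFrame(scores, index=beta.columns, columns=cols),
        explained_variance=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=beta.index, columns=cols),
    )


_CONTINUOUS = ("age", "braak", "true_neuron_prop")


def correlate_pcs_with_covariates(pcs: PCScores, sheet: pd.DataFrame) -> pd.DataFrame:
    """Associate each PC with each sample covariate.

    Continuous covariates: Pearson correlation test; categorical: one-way
    ANOVA F test.  Returns a long table (pc, covariate, kind, statistic,
    p) sorted by ascending p within each PC.  Single-level covariates are
    skipped with a warning.
    """
    aligned = sheet.reindex(pcs.scores.index)
    if aligned.isna().all(axis=1).any():
        raise ValidationError("sample sheet does not cover all scored samples")
    records = []
    for pc in pcs.scores.columns:
        x = pcs.scores[pc].to_numpy()
        for cov in aligned.columns:
            col = aligned[cov]
            if col.nunique(dropna=True) < 2:
                log.warning("covariate %r has a single level; skipped", cov)
                continue
            if cov in _CONTINUOUS:
                r, p = stats.pearsonr(x, col.to_numpy(dtype=float))
                records.append((pc, cov, "pearson", r, p))
            else:
                groups = [x[(col == level).to_numpy()] for level in col.unique()]
                f, p = stats.f_oneway(*groups)
                records.append((pc, cov, "anova", f, p))
    out = pd.DataFrame(records, columns=["pc", "covariate", "kind", "statistic", "p"])
    return out.sort_values(["pc", "p"], kind="stable").reset_index(drop=True)
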