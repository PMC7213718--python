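"""Convergence analytics for GA runs.

Population snapshots (organisms x 13 multipliers, slow-variable genes
excluded) are projected onto two principal components; cluster position
and spread relative to the known truth are summarised by the Mean Cluster
Error (centroid-to-truth distance) and the Standard Distance (RMS spread
about the centroid).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = ["PopulationSnapshot", "pca_project", "mce", "sdist",
           "recovery_report"]


@dataclass
class PopulationSnapshot:
    parameters: np.ndarray          # (organisms, n_params) multipliers
    generation: int = 0
    reference: np.ndarray | None = None   # true parameter vector

    def __post_init__(self):
        self.parameters = np.atleast_2d(
            np.asarray(self.parameters, dtype=float))
        if not np.all(np.isfinite(self.parameters)):
            raise ValueError("snapshot contains missing values")


def pca_project(snapshots, reference=None, baseline=None):
    """Project one or several snapshots onto a common 2-PC plane.

    The PCA is fitted on the pooled snapshots, baseline-normalised and
    mean-centred (no unit-variance scaling: multipliers are already
    dimensionless and commensurate).  Returns (scores list, loadings,
    explained variance ratio, reference score or None).
    """
    if isinstance(snapshots, PopulationSnapshot):
        snapshots = [snapshots]
    mats = [s.parameters for s in snapshots]
    X = np.vstack(mats)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 organisms for a PCA")
    if baseline is None:
        baseline = np.ones(X.shape[1])
    Xn = X / baseline
    if np.linalg.matrix_rank(Xn - Xn.mean(axis=0)) < 1:
        raise ValueError("degenerate population (zero variance)")
    pca = PCA(n_components=2)
    pca.fit(Xn)
    scores = []
    i = 0
    for m in mats:
        scores.append(pca.transform(m / baseline))
        i += m.shape[0]
    if reference is None:
        refs = [s.reference for s in snapshots if s.reference is not None]
        reference = refs[0] if refs else None
    ref_score = None
    if reference is not None:
        ref_score = pca.transform(
            np.asarray(reference, dtype=float)[None, :] / baseline)[0]
    if len(scores) == 1:
        scores = scores[0]
    return scores, pca.components_, pca.explained_variance_ratio_, ref_score


def mce(scores, reference_score) -> float:
    """Mean Cluster Error: distance from the cluster centroid to the truth
    point in PC space."""
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    centroid = s.mean(axis=0)
    return float(np.linalg.norm(
        centroid - np.asarray(reference_score, dtype=float)))


def sdist(scores) -> float:
    """Standard Distance: sqrt of the summed per-axis mean squared
    deviations about the centroid (RMS cluster radius)."""
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    c = s.mean(axis=0)
    return float(np.sqrt(np.sum(np.mean((s - c) ** 2, axis=0))))


def recovery_report(best_genomes, true_genome, names=None) -> pd.DataFrame:
    """Per-parameter relative errors |estimate - truth| / truth across runs.

    Returns a DataFrame with one row per parameter: mean and SD of the
    error in percent, plus the per-run errors (box-plot ready).
    """
    truth = np.asarray(true_genome, dtype=float)
    if np.any(truth == 0):
        raise ValueError("true parameter vector contains zeros")
    G = np.atleast_2d(np.asarray(best_genomes, dtype=float))[:, :truth.size]
    err = np.abs(G - truth) / np.abs(truth) * 100.0
    if names is None:
        names = [f"p{i}" for i in range(truth.size)]
    return pd.DataFrame({
        "parameter": list(names),
        "mean_error_pct": err.mean(axis=0),
        "sd_error_pct": err.std(axis=0, ddof=1) if err.shape[0] > 1
        else np.zeros(truth.size),
        "errors_pct": [err[:, j].tolist() for j in range(truth.size)],
    }).set_index("parameter")
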