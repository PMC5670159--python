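"""Trait-profile views: Z-scores, high/low clustering and PCA ordination.

Z-scores use the sample (n-1) standard deviation.  The high/low split is an
average-linkage agglomerative clustering on Euclidean distance cut at two
clusters; the cluster with the larger grand-mean Z-score is labelled
``high``.  PCA runs on ln(1+x)-transformed, column-centered (unscaled) trait
values via SVD.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .core_io import (
    DegenerateDesignError,
    InsufficientDataError,
    IsolateRecord,
    RhizotraitsError,
    TraitMatrix,
)


@dataclass
class ZScoreMatrix:
    """Per-trait standardized matrix; constant traits become all-zero."""

    values: pd.DataFrame

    @property
    def isolate_ids(self) -> list[str]:
        return list(self.values.index)


def zscore(matrix: TraitMatrix | ZScoreMatrix) -> ZScoreMatrix:
    frame = matrix.values
    if len(frame) < 2:
        raise InsufficientDataError("Z-scores need >=2 isolates")
    mean = frame.mean(axis=0)
    sd = frame.std(axis=0, ddof=1)
    out = (frame - mean).div(sd.where(sd > 0, 1.0), axis=1)
    out.loc[:, sd == 0] = 0.0
    return ZScoreMatrix(out)


@dataclass
class ClusterAssignment:
    assignment: dict[str, str]  # isolate_id -> "high" | "low"
    linkage: str = "average"
    metric: str = "euclidean"

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"isolate_id": list(self.assignment), "cluster": list(self.assignment.values())}
        )


def cluster_high_low(
    z: ZScoreMatrix, columns: Sequence[str] | None = None
) -> ClusterAssignment:
    """Two-cluster average-linkage split; larger grand-mean cluster = high."""
    frame = z.values if columns is None else z.values[list(columns)]
    if len(frame) < 2:
        raise InsufficientDataError("clustering needs >=2 isolates")
    data = frame.to_numpy(dtype=float)
    if np.allclose(data, data[0]):
        raise DegenerateDesignError("all isolates identical; high/low split undefined")
    tree = linkage(data, method="average", metric="euclidean")
    labels = fcluster(tree, t=2, criterion="maxclust")
    means = {lab: data[labels == lab].mean() for lab in np.unique(labels)}
    high_label = max(means, key=lambda lab: means[lab])
    assignment = {
        iso: ("high" if lab == high_label else "low")
        for iso, lab in zip(frame.index, labels)
    }
    return ClusterAssignment(assignment)


def treatment_proportions(
    assignment: ClusterAssignment, isolates: Sequence[IsolateRecord]
) -> pd.DataFrame:
    """Count and fraction of high/low isolates per treatment."""
    by_iso = assignment.assignment
    rows = []
    for iso in isolates:
        if iso.isolate_id not in by_iso:
            raise RhizotraitsError(f"isolate {iso.isolate_id!r} not assigned")
        rows.append(
            {
                "stage_years": iso.stage_years,
                "plant_species": iso.plant_species.value,
                "compartment": iso.compartment.value,
                "cluster": by_iso[iso.isolate_id],
            }
        )
    frame = pd.DataFrame(rows)
    counts = (
        frame.groupby(["stage_years", "plant_species", "compartment", "cluster"])
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(["stage_years", "plant_species", "compartment"])["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts


@dataclass
class PcaResult:
    scores: pd.DataFrame  # isolates x components
    loadings: pd.DataFrame  # traits x components
    explained_variance_ratio: np.ndarray

    def variance_pct(self, n_components: int = 2) -> float:
        return float(100.0 * self.explained_variance_ratio[:n_components].sum())


def pca_traits(matrix: TraitMatrix, log_offset: float = 1.0) -> PcaResult:
    """PCA of ln(offset + x) trait values, centered, unscaled.

    With ``log_offset=1`` the transform is ln(1+x), defined at the exact
    zeros that abundance weighting can produce.
    """
    frame = matrix.values
    if len(frame) < 3 or frame.shape[1] < 2:
        raise InsufficientDataError("PCA needs >=3 isolates and >=2 traits")
    data = frame.to_numpy(dtype=float)
    if (data < 0).any():
        raise RhizotraitsError("PCA input must be nonnegative before log transform")
    logged = np.log(log_offset + data)
    centered = logged - logged.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # deterministic sign: largest-magnitude loading positive per component
    for k in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    var = s**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    comp_names = [f"PC{k+1}" for k in range(len(s))]
    scores = pd.DataFrame(u * s, index=frame.index, columns=comp_names)
    loadings = pd.DataFrame(vt.T, index=frame.columns, columns=comp_names)
    return PcaResult(scores, loadings, ratio)
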