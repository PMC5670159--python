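"""Functional diversity: mean pairwise Bray-Curtis distance per treatment.

The diversity statistic pools the strains belonging to one treatment group
(successional stage, plant species, compartment, or a stage crossing) and
averages the Bray-Curtis distances over all within-group pairs.  Groups with
fewer than two strains have no pair and are reported as N.A.

Group comparisons use the Kruskal-Wallis rank test on the pooled pairwise
distances followed by the Nemenyi all-pairs post hoc on the studentized
range distribution.  The pairwise distances entering these tests share
strains and are therefore not independent observations; the procedure is
applied to them regardless because that is exactly how the field uses it,
and the type-I behaviour under this dependence is characterised in the test
suite rather than silently assumed nominal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .core_io import (
    ConfigError,
    InsufficientDataError,
    IsolateRecord,
    MatrixState,
    RhizotraitsError,
    TraitMatrix,
)

GROUPINGS = ("stage", "plant", "compartment", "stage_by_compartment", "stage_by_plant")

#: Rendered value for groups whose diversity is undefined (<2 members).
NA = "N.A."


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) on nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise RhizotraitsError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise RhizotraitsError("Bray-Curtis requires nonnegative entries")
    denom = float(np.sum(u + v))
    if denom == 0:
        raise RhizotraitsError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(u - v)) / denom)


@dataclass
class DistanceMatrix:
    isolate_ids: list[str]
    values: np.ndarray
    metric: str = "bray_curtis"

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        idx = [self.isolate_ids.index(i) for i in ids]
        return self.values[np.ix_(idx, idx)]

    def pair_distances(self, ids: Sequence[str]) -> list[float]:
        sub = self.submatrix(ids)
        iu = np.triu_indices(len(ids), k=1)
        return [float(x) for x in sub[iu]]


def pairwise_distances(matrix: TraitMatrix) -> DistanceMatrix:
    """Full symmetric Bray-Curtis matrix over the isolates."""
    if matrix.state not in (MatrixState.NORMALIZED, MatrixState.WEIGHTED):
        raise RhizotraitsError(
            f"distance input must be normalized or weighted, got {matrix.state.value}"
        )
    values = matrix.values.to_numpy(dtype=float)
    if (values < 0).any():
        raise RhizotraitsError("trait matrix has negative entries")
    if (values.sum(axis=1) == 0).any():
        raise RhizotraitsError("all-zero trait row makes Bray-Curtis undefined")
    if len(values) == 1:
        dm = np.zeros((1, 1))
    else:
        dm = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(matrix.isolate_ids, dm)


# ---------------------------------------------------------------------------
# Treatment pooling
# ---------------------------------------------------------------------------


@dataclass
class DiversityResult:
    grouping: str
    group: str
    n_species: int
    pair_distances: list[float] = field(default_factory=list)

    @property
    def defined(self) -> bool:
        return self.n_species >= 2

    @property
    def mean(self) -> float | None:
        return float(np.mean(self.pair_distances)) if self.defined else None

    @property
    def sd(self) -> float | None:
        if not self.defined:
            return None
        return float(np.std(self.pair_distances, ddof=1)) if len(self.pair_distances) > 1 else 0.0

    def render_mean_sd(self) -> str:
        if not self.defined:
            return NA
        return f"{self.mean:.2f} ± {self.sd:.2f}"


def _group_key(iso: IsolateRecord, grouping: str) -> str:
    if grouping == "stage":
        return f"{iso.stage_years}y"
    if grouping == "plant":
        return iso.plant_species.value
    if grouping == "compartment":
        return iso.compartment.value
    if grouping == "stage_by_compartment":
        return f"{iso.stage_years}y:{iso.compartment.value}"
    if grouping == "stage_by_plant":
        return f"{iso.stage_years}y:{iso.plant_species.value}"
    raise ConfigError(f"unknown grouping {grouping!r}; expected one of {GROUPINGS}")


def treatment_diversity(
    dm: DistanceMatrix,
    isolates: Sequence[IsolateRecord],
    grouping: str,
) -> list[DiversityResult]:
    """Mean pairwise distance per group under the chosen grouping."""
    members: dict[str, list[str]] = {}
    for iso in isolates:
        if iso.isolate_id in dm.isolate_ids:
            members.setdefault(_group_key(iso, grouping), []).append(iso.isolate_id)
    results = []
    for group in sorted(members, key=_stage_sort_key):
        ids = members[group]
        pairs = dm.pair_distances(ids) if len(ids) >= 2 else []
        results.append(DiversityResult(grouping, group, len(ids), pairs))
    return results


def _stage_sort_key(label: str):
    head = label.split(":")[0]
    if head.endswith("y") and head[:-1].isdigit():
        return (0, int(head[:-1]), label)
    return (1, 0, label)


def diversity_table(results: Sequence[DiversityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "grouping": r.grouping,
                "group": r.group,
                "n_species": r.n_species,
                "n_pairs": len(r.pair_distances),
                "mean": r.mean if r.defined else NA,
                "sd": r.sd if r.defined else NA,
            }
            for r in results
        ]
    )


# ---------------------------------------------------------------------------
# Nonparametric comparisons
# ---------------------------------------------------------------------------


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise InsufficientDataError("Kruskal-Wallis needs >=2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise InsufficientDataError("Kruskal-Wallis needs >=3 total observations")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


@dataclass
class PosthocResult:
    groups: list[str]
    kw_statistic: float
    kw_p: float
    nemenyi_p: pd.DataFrame


def nemenyi_posthoc(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> PosthocResult:
    """All-pairs Nemenyi test on mean rank differences.

    The statistic for groups i, j is

        q_ij = |Rbar_i - Rbar_j| / sqrt(S * (1/n_i + 1/n_j))

    with S = N(N+1)/12 - sum(t^3 - t)/(12(N-1)) the tie-corrected rank
    variance term, referred to the studentized range distribution with k
    groups and infinite degrees of freedom (p = P(Q_k >= q*sqrt(2))), the
    convention of the R routine ``posthoc.kruskal.nemenyi.test``.
    """
    data = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in data) or len(data) < 2:
        raise InsufficientDataError("Nemenyi needs >=2 non-empty groups")
    if labels is None:
        labels = [f"g{i+1}" for i in range(len(data))]
    labels = list(labels)
    kw_h, kw_p = kruskal_wallis(data)

    pooled = np.concatenate(data)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in data]
    bounds = np.cumsum([0, *sizes])
    mean_ranks = [
        float(np.mean(ranks[bounds[i]:bounds[i + 1]])) for i in range(len(data))
    ]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    s_var = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        s_var -= tie_term / (12.0 * (n_total - 1))

    k = len(data)
    pmat = np.eye(k)
    np.fill_diagonal(pmat, 1.0)
    for i, j in itertools.combinations(range(k), 2):
        if s_var <= 0:
            p = 1.0
        else:
            q = abs(mean_ranks[i] - mean_ranks[j]) / np.sqrt(
                s_var * (1.0 / sizes[i] + 1.0 / sizes[j])
            )
            p = float(stats.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
        pmat[i, j] = pmat[j, i] = min(1.0, p)
    frame = pd.DataFrame(pmat, index=labels, columns=labels)
    return PosthocResult(labels, kw_h, kw_p, frame)


def compare_groups(
    results: Sequence[DiversityResult], min_pairs: int = 1
) -> PosthocResult | None:
    """KW + Nemenyi over the defined groups of one diversity run."""
    defined = [r for r in results if r.defined and len(r.pair_distances) >= min_pairs]
    if len(defined) < 2:
        return None
    return nemenyi_posthoc(
        [r.pair_distances for r in defined], [r.group for r in defined]
    )
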