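"""Statistics on the activity matrix A: differential activation and clustering.

Differential iModulon activation (DiMA) compares the absolute difference in
mean activity between two condition groups against a null distribution built
from biological replicates: within-replicate-group absolute activity
differences are pooled across the compendium and fit with a two-parameter
log-normal. An iModulon is called differentially activated only when the
difference exceeds a practical threshold (default 5 activity units) AND the
BH-adjusted tail probability falls below alpha.

Activity rows cluster into stimulons (groups of iModulons with coordinated
activities); replicate-averaged activity columns cluster samples by the
similarity of their whole-transcriptome response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .compendium_io import SampleMetadata
from .enrichment import bh_adjust

__all__ = [
    "DimaNull",
    "StimulonClustering",
    "fit_dima_null",
    "fit_dima_nulls",
    "dima",
    "count_dima_per_condition",
    "activity_correlation_clusters",
    "sample_profile_clusters",
]

DEFAULT_MIN_DELTA = 5.0
DEFAULT_ALPHA = 0.05
_EPS = 1e-6


@dataclass
class DimaNull:
    """Log-normal null for one iModulon's replicate-level activity noise."""

    component_id: str
    shape: float  # log-space sigma
    scale: float  # exp(log-space mu)
    n_pairs: int

    def sf(self, delta: float) -> float:
        """Upper-tail probability of an absolute activity difference."""
        return float(stats.lognorm.sf(delta + _EPS, self.shape, loc=0.0, scale=self.scale))


def _replicate_pairs(meta: SampleMetadata, sample_ids) -> list[tuple[str, str]]:
    pairs = []
    available = set(sample_ids)
    for _, members in meta.replicate_groups().items():
        members = [m for m in members if m in available]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                pairs.append((members[i], members[j]))
    return pairs


def fit_dima_null(
    a_row: pd.Series,
    meta: SampleMetadata,
    min_pairs: int = 10,
    component_id: str = "",
    extra_diffs: np.ndarray | None = None,
) -> DimaNull:
    """Fit the log-normal replicate-noise null for one activity row.

    Collects |activity difference| over every within-replicate-group sample
    pair in the compendium, adds a small epsilon so identical replicates do
    not produce zeros, and fits a two-parameter log-normal (location fixed
    at 0). ``extra_diffs`` allows pooling differences across iModulons when a
    single row has too few pairs.
    """
    pairs = _replicate_pairs(meta, a_row.index)
    diffs = np.array([abs(a_row[i] - a_row[j]) for i, j in pairs], dtype=float)
    if extra_diffs is not None:
        diffs = np.concatenate([diffs, np.asarray(extra_diffs, dtype=float)])
    if diffs.size < min_pairs:
        raise ValueError(
            f"only {diffs.size} replicate pairs for component {component_id or '<?>'} "
            f"(need >= {min_pairs}); consider pooling differences across iModulons"
        )
    shape, _, scale = stats.lognorm.fit(diffs + _EPS, floc=0.0)
    return DimaNull(component_id=component_id, shape=float(shape), scale=float(scale), n_pairs=int(diffs.size))


def fit_dima_nulls(
    A: pd.DataFrame,
    meta: SampleMetadata,
    min_pairs: int = 10,
    pooled: bool = False,
) -> dict[str, DimaNull]:
    """Fit the replicate-noise null for every activity row.

    With ``pooled=True`` the absolute replicate differences of all iModulons
    are concatenated into one shared null (useful when replicate pairs are
    scarce).
    """
    pairs = _replicate_pairs(meta, A.columns)
    if pooled:
        diffs = np.abs(
            A.loc[:, [p[0] for p in pairs]].to_numpy() - A.loc[:, [p[1] for p in pairs]].to_numpy()
        ).ravel()
        if diffs.size < min_pairs:
            raise ValueError("too few replicate pairs even when pooled across iModulons")
        shape, _, scale = stats.lognorm.fit(diffs + _EPS, floc=0.0)
        return {
            str(c): DimaNull(str(c), float(shape), float(scale), int(diffs.size)) for c in A.index
        }
    return {
        str(c): fit_dima_null(A.loc[c], meta, min_pairs=min_pairs, component_id=str(c))
        for c in A.index
    }


def dima(
    A: pd.DataFrame,
    group1: list[str],
    group2: list[str],
    nulls: dict[str, DimaNull],
    min_delta: float = DEFAULT_MIN_DELTA,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Differential iModulon activation between two sample groups.

    delta = |mean activity in group1 - mean in group2| per iModulon; the
    p-value is the upper tail of that iModulon's replicate-noise log-normal;
    q is BH across iModulons; a call is significant only when delta exceeds
    ``min_delta`` AND q < alpha.
    """
    if not group1 or not group2:
        raise ValueError("both sample groups must be non-empty")
    rows = []
    for comp in A.index:
        key = str(comp)
        if key not in nulls:
            warnings.warn(f"no null for component {key}; skipped", stacklevel=2)
            continue
        delta = abs(A.loc[comp, group1].mean() - A.loc[comp, group2].mean())
        rows.append({"component_id": key, "delta": float(delta), "p": nulls[key].sf(delta)})
    result = pd.DataFrame(rows)
    if result.empty:
        return result.assign(q=[], significant=[])
    result["q"] = bh_adjust(result["p"])
    result["significant"] = (result["delta"] > min_delta) & (result["q"] < alpha)
    return result


def count_dima_per_condition(
    A: pd.DataFrame,
    meta: SampleMetadata,
    nulls: dict[str, DimaNull],
    min_delta: float = DEFAULT_MIN_DELTA,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, float]:
    """Differentially activated iModulon counts for every condition vs. its baseline.

    Every non-reference condition is compared against its project's baseline
    (reference) condition; returns per-condition counts and their median.
    """
    table = meta.table[meta.table["sample_id"].isin(A.columns)]
    rows = []
    for project in table["project"].unique():
        ref = [s for s in meta.reference_samples(project) if s in A.columns]
        if not ref:
            continue
        sub = table[table["project"] == project]
        ref_conditions = set(sub.loc[sub["sample_id"].isin(ref), "condition"])
        for condition in sub["condition"].unique():
            if condition in ref_conditions:
                continue
            group = sub.loc[sub["condition"] == condition, "sample_id"].tolist()
            if not group:
                continue
            res = dima(A, group, ref, nulls, min_delta=min_delta, alpha=alpha)
            rows.append(
                {
                    "project": project,
                    "condition": condition,
                    "n_differential": int(res["significant"].sum()) if not res.empty else 0,
                }
            )
    counts = pd.DataFrame(rows)
    median = float(counts["n_differential"].median()) if not counts.empty else 0.0
    return counts, median


@dataclass
class StimulonClustering:
    correlation: pd.DataFrame
    linkage: np.ndarray
    assignments: pd.Series
    cluster_mean_abs_r: pd.Series


def _correlation_clusters(
    frame: pd.DataFrame,
    linkage_method: str,
    threshold: float,
    axis_name: str,
) -> StimulonClustering:
    """Hierarchical clustering of rows of ``frame`` on the distance 1 - Pearson r."""
    values = frame.to_numpy(dtype=float)
    keep = values.std(axis=1) > 0
    dropped = frame.index[~keep].tolist()
    if dropped:
        warnings.warn(f"constant {axis_name} excluded from clustering: {dropped}", stacklevel=3)
    frame = frame.loc[keep]
    if frame.shape[0] < 2:
        raise ValueError(f"need at least 2 non-constant {axis_name} to cluster")
    corr = pd.DataFrame(
        np.corrcoef(frame.to_numpy()), index=frame.index, columns=frame.index
    )
    dist = np.clip(1.0 - corr.to_numpy(), 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=linkage_method)
    flat = hierarchy.fcluster(Z, t=threshold, criterion="distance")
    assignments = pd.Series(flat, index=frame.index, name="cluster")
    means = {}
    for lab in np.unique(flat):
        idx = assignments.index[assignments == lab]
        if len(idx) == 1:
            means[int(lab)] = 1.0
            continue
        sub = corr.loc[idx, idx].to_numpy()
        off = sub[np.triu_indices_from(sub, k=1)]
        means[int(lab)] = float(np.abs(off).mean())
    return StimulonClustering(
        correlation=corr,
        linkage=Z,
        assignments=assignments,
        cluster_mean_abs_r=pd.Series(means, name="mean_abs_r"),
    )


def activity_correlation_clusters(
    A: pd.DataFrame,
    linkage_method: str = "average",
    threshold: float = 0.5,
) -> StimulonClustering:
    """Cluster iModulons by correlated activities (stimulon detection)."""
    return _correlation_clusters(A, linkage_method, threshold, "activity rows")


def sample_profile_clusters(
    A: pd.DataFrame,
    meta: SampleMetadata,
    linkage_method: str = "average",
    threshold: float = 0.5,
) -> StimulonClustering:
    """Cluster samples by their replicate-averaged activity profiles.

    Activity columns are first averaged within replicate groups, then
    clustered by the Pearson correlation between profiles.
    """
    groups = meta.replicate_groups()
    averaged = {}
    for group, members in groups.items():
        members = [m for m in members if m in A.columns]
        if members:
            averaged[group] = A.loc[:, members].mean(axis=1)
    avg = pd.DataFrame(averaged)
    return _correlation_clusters(avg.T, linkage_method, threshold, "sample profiles")
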