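"""Binarization of component gene weights into discrete iModulon memberships.

Most genes in a component's weight vector form a near-Gaussian background;
the genes that the component actually regulates sit far out in the tails. The
threshold for each component is found by iteratively peeling off the
largest-magnitude gene until the remaining weights no longer reject normality
under D'Agostino's K-squared test. The peeled genes are the iModulon members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeightThreshold",
    "MembershipStats",
    "dagostino_k2",
    "compute_weight_threshold",
    "binarize_m",
    "membership_stats",
    "select_map_subset",
    "calibrate_k2_cutoff",
]

DEFAULT_K2_CUTOFF = 550.0


@dataclass
class WeightThreshold:
    """Per-component binarization record.

    ``threshold`` is in absolute-weight units: members are exactly the genes
    with |weight| strictly greater than it (it equals the largest
    non-member's |weight|).
    """

    component_id: str
    k2_cutoff: float
    threshold: float
    n_members: int
    members: list[str]


@dataclass
class MembershipStats:
    n_genes_in_any: int
    n_genes_universe: int
    fraction_in_any: float
    multiplicity_histogram: dict[int, int]
    median_size: float
    largest: tuple[str, int]
    smallest_nonempty: tuple[str, int]
    sizes: pd.Series


def dagostino_k2(sample: np.ndarray | pd.Series) -> tuple[float, float]:
    """D'Agostino's K-squared omnibus normality statistic and its p-value.

    K2 is the sum of the squared normal-transformed skewness and kurtosis
    statistics; under normality it is chi-squared with 2 degrees of freedom.
    Requires at least 8 observations.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 8:
        raise ValueError(f"sample too small for K2 (n={x.size}, need >= 8)")
    with warnings.catch_warnings():
        # the small-n kurtosis approximation warning is irrelevant at n >= 8
        warnings.filterwarnings("ignore", message="kurtosistest")
        stat, p = stats.normaltest(x)
    return float(stat), float(p)


def compute_weight_threshold(
    weights: pd.Series,
    k2_cutoff: float = DEFAULT_K2_CUTOFF,
    component_id: str = "",
    stability_window: int = 5,
) -> WeightThreshold:
    """Find the absolute-weight threshold separating members from background.

    Iteratively removes the gene(s) of largest |weight| (ties removed
    together, so the result is order-independent) and re-evaluates K2 on the
    remainder; removal stops once the statistic falls below ``k2_cutoff`` and
    stays below it for ``stability_window`` consecutive removals. The
    stability window matters because K2 is not monotone along the removal
    path: deleting a single extreme gene can transiently cancel the skewness
    term while strong outliers remain, so a first-crossing stop would
    truncate the membership; on monotone paths the two rules coincide.

    Members are the genes removed before the statistic stably entered the
    background regime. If the weights pass the normality gate immediately —
    including the degenerate all-equal case — membership is empty and the
    threshold is max|weight|.
    """
    w = weights.astype(float)
    if w.size < 8:
        raise ValueError("component has too few genes for K2 thresholding")
    abs_w = w.abs().sort_values(ascending=False)
    if np.isclose(abs_w.iloc[0], abs_w.iloc[-1]):
        return WeightThreshold(component_id, k2_cutoff, float(abs_w.iloc[0]), 0, [])

    # peel genes largest-|weight| first, recording each removal batch
    batches: list[list[str]] = []
    remaining = abs_w.copy()
    below_run = 0
    stop_batch = None
    while remaining.size >= 8:
        stat, _ = dagostino_k2(w.loc[remaining.index])
        if np.isfinite(stat) and stat >= k2_cutoff:
            below_run = 0
        else:
            if below_run == 0:
                stop_batch = len(batches)
            below_run += 1
            if below_run >= stability_window:
                break
        top = remaining.iloc[0]
        tied = remaining.index[np.isclose(remaining.to_numpy(), top)].tolist()
        batches.append(tied)
        remaining = remaining.drop(tied)
    if below_run == 0:
        stop_batch = len(batches)  # never reached background before running out

    members = [g for batch in batches[:stop_batch] for g in batch]
    if not members:
        return WeightThreshold(component_id, k2_cutoff, float(abs_w.iloc[0]), 0, [])
    n_removed = len(members)
    threshold = float(abs_w.iloc[n_removed]) if n_removed < abs_w.size else 0.0
    members = [g for g in w.index if g in set(members)]  # original gene order
    return WeightThreshold(component_id, k2_cutoff, threshold, len(members), members)


def binarize_m(
    M: pd.DataFrame,
    k2_cutoff: float = DEFAULT_K2_CUTOFF,
) -> tuple[pd.DataFrame, dict[str, WeightThreshold]]:
    """Apply K2 thresholding per component; returns the boolean gene x component matrix."""
    thresholds: dict[str, WeightThreshold] = {}
    binary = pd.DataFrame(False, index=M.index, columns=M.columns)
    for comp in M.columns:
        thr = compute_weight_threshold(M[comp], k2_cutoff=k2_cutoff, component_id=str(comp))
        thresholds[str(comp)] = thr
        binary.loc[thr.members, comp] = True
    return binary, thresholds


def thresholds_to_frame(thresholds: dict[str, WeightThreshold]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component_id": t.component_id,
                "k2_cutoff": t.k2_cutoff,
                "threshold": t.threshold,
                "n_members": t.n_members,
            }
            for t in thresholds.values()
        ]
    )


def membership_stats(Mb: pd.DataFrame) -> MembershipStats:
    """Census of the binarized membership matrix.

    Reports how many genes belong to at least one iModulon, the multiplicity
    histogram (genes in exactly 1, 2, 3, ... components), and component size
    statistics (median over non-empty components).
    """
    if Mb.size == 0:
        raise ValueError("empty membership matrix")
    mult = Mb.sum(axis=1).astype(int)
    in_any = mult[mult > 0]
    histogram = in_any.value_counts().sort_index().to_dict()
    sizes = Mb.sum(axis=0).astype(int)
    nonempty = sizes[sizes > 0]
    if nonempty.empty:
        largest = smallest = ("", 0)
        median = 0.0
    else:
        largest = (str(nonempty.idxmax()), int(nonempty.max()))
        smallest = (str(nonempty.idxmin()), int(nonempty.min()))
        median = float(nonempty.median())
    return MembershipStats(
        n_genes_in_any=int(len(in_any)),
        n_genes_universe=int(Mb.shape[0]),
        fraction_in_any=float(len(in_any) / Mb.shape[0]),
        multiplicity_histogram={int(k): int(v) for k, v in histogram.items()},
        median_size=median,
        largest=largest,
        smallest_nonempty=smallest,
        sizes=sizes,
    )


def select_map_subset(Mb: pd.DataFrame, min_multiplicity: int = 3) -> list[str]:
    """Components containing at least one gene found in >= min_multiplicity components.

    This is the rule used to pick the most interconnected part of the network
    for the graphical map.
    """
    if min_multiplicity < 2:
        raise ValueError("min_multiplicity must be >= 2")
    mult = Mb.sum(axis=1)
    hub_genes = mult.index[mult >= min_multiplicity]
    if hub_genes.empty:
        return []
    mask = Mb.loc[hub_genes].any(axis=0)
    return Mb.columns[mask].tolist()


def calibrate_k2_cutoff(
    M: pd.DataFrame,
    planted_members: dict[str, set[str]],
    cutoffs: list[float],
) -> tuple[float, pd.DataFrame]:
    """Sweep K2 cutoffs and pick the one maximizing mean F1 against known modules.

    Intended for calibrating the cutoff on synthetic data (or against curated
    regulons) before applying it to a real compendium.
    """
    from .enrichment import precision_recall

    rows = []
    planted_sets = list(planted_members.values())
    for cutoff in cutoffs:
        Mb, _ = binarize_m(M, k2_cutoff=cutoff)
        f1s = []
        for comp in Mb.columns:
            members = set(Mb.index[Mb[comp]])
            if not members:
                f1s.append(0.0)
                continue
            best = max(precision_recall(members, ps)[2] for ps in planted_sets if ps)
            f1s.append(best)
        rows.append({"k2_cutoff": cutoff, "mean_f1": float(np.mean(f1s)) if f1s else 0.0})
    table = pd.DataFrame(rows)
    best_cutoff = float(table.loc[table["mean_f1"].idxmax(), "k2_cutoff"])
    return best_cutoff, table
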