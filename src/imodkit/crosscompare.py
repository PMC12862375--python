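"""Comparison of two iModulon structures over their shared gene space.

Components from two decompositions (e.g. knowledgebases built from different
sample collections) are matched by the Pearson correlation of their gene
weights on the intersection of the two gene sets; a component "has a match"
when some component on the other side correlates above a cutoff (default
r > 0.5). Differential iModulon membership (DiMM) tables classify each shared
gene as a member of both, either, or neither of a matched component pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .membership import WeightThreshold

__all__ = ["MatchCensus", "align_genes", "match_imodulons", "dimm"]

DIMM_CLASSES = ("both", "only_A", "only_B", "neither")


@dataclass
class MatchCensus:
    """Per-component best partners plus the matched/unmatched counts."""

    matches: pd.DataFrame  # component_id_A, best_partner, r, matched
    r_matrix: pd.DataFrame  # components_A x components_B
    n_matched: int
    n_total: int

    @property
    def matched_fraction(self) -> float:
        return self.n_matched / self.n_total if self.n_total else 0.0


def align_genes(M_A: pd.DataFrame, M_B: pd.DataFrame) -> tuple[pd.Index, float, float]:
    """Shared genes of two weight matrices in sorted order, with coverage fractions."""
    shared = M_A.index.intersection(M_B.index).sort_values()
    if shared.empty:
        raise ValueError("no shared genes between the two weight matrices")
    return shared, len(shared) / len(M_A.index), len(shared) / len(M_B.index)


def match_imodulons(
    M_A: pd.DataFrame,
    M_B: pd.DataFrame,
    min_r: float = 0.5,
    use_absolute: bool = False,
    categories: pd.Series | None = None,
) -> MatchCensus:
    """Match components of A to components of B by gene-weight correlation.

    Pearson r is computed on the shared gene set for every cross pair. With
    ``use_absolute`` the magnitude |r| is compared against ``min_r``
    (sign conventions can differ between independently fit decompositions).
    Components with constant weights on the shared genes are skipped with a
    warning. ``categories`` (indexed by A's component ids) adds a per-category
    census column.
    """
    shared, _, _ = align_genes(M_A, M_B)
    A_vals = M_A.loc[shared].to_numpy(dtype=float)
    B_vals = M_B.loc[shared].to_numpy(dtype=float)

    const_a = A_vals.std(axis=0) == 0
    const_b = B_vals.std(axis=0) == 0
    if const_a.any():
        warnings.warn(
            f"constant weight vectors in A skipped: {M_A.columns[const_a].tolist()}", stacklevel=2
        )
    if const_b.any():
        warnings.warn(
            f"constant weight vectors in B skipped: {M_B.columns[const_b].tolist()}", stacklevel=2
        )

    Az = (A_vals - A_vals.mean(axis=0)) / np.where(const_a, 1.0, A_vals.std(axis=0))
    Bz = (B_vals - B_vals.mean(axis=0)) / np.where(const_b, 1.0, B_vals.std(axis=0))
    R = (Az.T @ Bz) / len(shared)
    R[const_a, :] = np.nan
    R[:, const_b] = np.nan
    r_matrix = pd.DataFrame(R, index=M_A.columns, columns=M_B.columns)

    score = r_matrix.abs() if use_absolute else r_matrix
    rows = []
    for comp in M_A.columns:
        row = score.loc[comp]
        if row.isna().all():
            rows.append({"component_id_A": comp, "best_partner": "", "r": np.nan, "matched": False})
            continue
        partner = row.idxmax()
        best = float(r_matrix.loc[comp, partner])
        rows.append(
            {
                "component_id_A": comp,
                "best_partner": partner,
                "r": best,
                "matched": bool(row.max() > min_r),
            }
        )
    matches = pd.DataFrame(rows)
    if categories is not None:
        matches["category"] = matches["component_id_A"].map(categories).fillna("")
    return MatchCensus(
        matches=matches,
        r_matrix=r_matrix,
        n_matched=int(matches["matched"].sum()),
        n_total=len(matches),
    )


def dimm(
    weights_A: pd.Series,
    weights_B: pd.Series,
    threshold_A: WeightThreshold | float,
    threshold_B: WeightThreshold | float,
) -> pd.DataFrame:
    """Differential iModulon membership table for one pair of components.

    Each shared gene is classified by its membership on either side
    (|weight| above the component's threshold): "both", "only_A", "only_B",
    or "neither" — the red/pink/orange/gray convention of DiMM plots.
    """
    thr_a = threshold_A.threshold if isinstance(threshold_A, WeightThreshold) else float(threshold_A)
    thr_b = threshold_B.threshold if isinstance(threshold_B, WeightThreshold) else float(threshold_B)
    shared = weights_A.index.intersection(weights_B.index).sort_values()
    if shared.empty:
        raise ValueError("no shared genes for DiMM")
    wa = weights_A.loc[shared].astype(float)
    wb = weights_B.loc[shared].astype(float)
    in_a = wa.abs() > thr_a
    in_b = wb.abs() > thr_b
    cls = np.where(
        in_a & in_b, "both", np.where(in_a, "only_A", np.where(in_b, "only_B", "neither"))
    )
    return pd.DataFrame(
        {
            "gene": shared,
            "weight_A": wa.to_numpy(),
            "weight_B": wb.to_numpy(),
            "member_A": in_a.to_numpy(),
            "member_B": in_b.to_numpy(),
            "class": cls,
        }
    ).set_index("gene")
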