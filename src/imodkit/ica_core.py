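"""Robust independent component analysis of a centered expression compendium.

The centered log2(TPM) matrix X (genes x samples) is decomposed as X ~ M.A,
where the columns of M are statistically independent gene-weight signatures
and the rows of A are their activities across samples. Because FastICA is a
stochastic algorithm, the decomposition is made robust by pooling components
from many restarts, clustering them by the distance 1 - |Pearson r| between
gene-weight vectors, and retaining only clusters reproduced in a minimum
fraction of runs. Dimensionality is chosen by scanning a grid and keeping the
smallest dimension that maximizes the number of reproducible multi-gene
components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .compendium_io import ExpressionMatrix

__all__ = [
    "IcaDecomposition",
    "OpticaScanResult",
    "run_single_ica",
    "robust_decompose",
    "optica_select",
    "explained_variance",
]


@dataclass
class IcaDecomposition:
    """Gene-weight matrix M (genes x k, unit-norm columns) and activities A (k x samples)."""

    M: pd.DataFrame
    A: pd.DataFrame
    dimensionality_used: int
    n_runs: int
    seeds: list[int] = field(default_factory=list)

    @property
    def component_ids(self) -> pd.Index:
        return self.M.columns

    @property
    def n_components(self) -> int:
        return self.M.shape[1]


@dataclass
class OpticaScanResult:
    """Per-dimension census of robust components and the selected dimension."""

    table: pd.DataFrame  # columns: dimension, n_robust, n_single_gene, n_multi_gene
    selected_dimension: int
    decompositions: dict[int, IcaDecomposition] = field(default_factory=dict, repr=False)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ExpressionMatrix):
        return X.data
    return X


def _orient_and_normalize(S: np.ndarray, A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-normalize gene-weight columns, carry scale into A, and fix signs.

    Sign convention: each component is oriented so its largest-magnitude gene
    weight is positive; stable under small perturbations.
    """
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    S = S / norms
    A = A * norms[:, None]
    flip = np.sign(S[np.argmax(np.abs(S), axis=0), np.arange(S.shape[1])])
    flip[flip == 0] = 1.0
    return S * flip, A * flip[:, None]


def run_single_ica(
    X: ExpressionMatrix | pd.DataFrame,
    dimension: int,
    seed: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> tuple[pd.DataFrame, pd.DataFrame, bool]:
    """One FastICA restart.

    Returns (S, A, converged): S the genes x dimension weight matrix with
    unit-L2 columns, A the matching dimension x samples activity rows, and a
    convergence flag (non-converged runs are excluded from robust pooling).
    """
    data = _as_frame(X)
    n_genes, n_samples = data.shape
    if dimension > min(n_genes, n_samples):
        raise ValueError(
            f"dimension {dimension} exceeds min(genes, samples) = {min(n_genes, n_samples)}"
        )
    ica = FastICA(
        n_components=dimension,
        random_state=int(seed),
        max_iter=max_iter,
        tol=tol,
        whiten="unit-variance",
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        S = ica.fit_transform(data.to_numpy())
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    A = ica.mixing_.T  # k x samples
    S, A = _orient_and_normalize(S, A)
    comp_ids = [f"run{seed}_c{i}" for i in range(dimension)]
    S_df = pd.DataFrame(S, index=data.index, columns=comp_ids)
    A_df = pd.DataFrame(A, index=comp_ids, columns=data.columns)
    return S_df, A_df, converged


def _component_ids(k: int) -> list[str]:
    width = max(2, len(str(k)))
    return [f"C{i + 1:0{width}d}" for i in range(k)]


def robust_decompose(
    X: ExpressionMatrix | pd.DataFrame,
    dimension: int,
    n_runs: int = 100,
    cluster_eps: float = 0.1,
    min_frequency: float = 0.5,
    seed: int = 0,
    max_iter: int = 1000,
) -> IcaDecomposition:
    """Pool FastICA restarts and keep only reproducible components.

    Components from all converged runs are clustered with DBSCAN on the
    precomputed distance 1 - |Pearson r| between gene-weight vectors; a
    cluster is retained when it contains components from at least
    ``min_frequency`` of the runs. The retained component is the centrotype
    (member with maximal mean |r| to the rest of its cluster). Activities are
    recomputed by pseudoinverse projection, A = M+ . X, so X ~ M.A holds for
    the retained set.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2 for robustness pooling")
    data = _as_frame(X)
    rng = np.random.default_rng(seed)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_runs)]

    pooled: list[np.ndarray] = []
    run_of: list[int] = []
    n_good = 0
    for run_idx, run_seed in enumerate(seeds):
        S_df, _, converged = run_single_ica(data, dimension, run_seed, max_iter=max_iter)
        if not converged:
            continue
        n_good += 1
        pooled.append(S_df.to_numpy())
        run_of.extend([run_idx] * dimension)

    if n_good == 0:
        warnings.warn("no FastICA run converged; empty decomposition", stacklevel=2)
        return _empty_decomposition(data, dimension, n_runs, seeds)

    W = np.hstack(pooled)  # genes x (n_good * dimension)
    run_ids = np.asarray(run_of)
    with np.errstate(invalid="ignore"):
        R = np.abs(np.corrcoef(W.T))
    np.fill_diagonal(R, 1.0)
    R = np.nan_to_num(R, nan=0.0)
    D = np.clip(1.0 - R, 0.0, None)

    min_runs = max(2, int(np.ceil(min_frequency * n_good)))
    labels = DBSCAN(eps=cluster_eps, min_samples=min_runs, metric="precomputed").fit_predict(D)

    centrotypes: list[np.ndarray] = []
    keys: list[tuple[int, int]] = []  # (-cluster size, first index) for deterministic ordering
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        if len(np.unique(run_ids[idx])) < min_runs:
            continue
        sub = R[np.ix_(idx, idx)]
        centro = idx[np.argmax(sub.mean(axis=1))]
        centrotypes.append(W[:, centro])
        keys.append((-len(idx), int(idx[0])))

    if not centrotypes:
        warnings.warn("no robust component cluster retained; empty decomposition", stacklevel=2)
        return _empty_decomposition(data, dimension, n_runs, seeds)

    # deterministic component order: larger clusters first, ties by pool position
    sort_idx = np.lexsort((np.array([k[1] for k in keys]), np.array([k[0] for k in keys])))
    M = np.column_stack([centrotypes[i] for i in sort_idx])
    A = np.zeros((M.shape[1], data.shape[1]))
    M, A = _orient_and_normalize(M, A)
    A = np.linalg.pinv(M) @ data.to_numpy()

    ids = _component_ids(M.shape[1])
    M_df = pd.DataFrame(M, index=data.index, columns=ids)
    A_df = pd.DataFrame(A, index=ids, columns=data.columns)
    return IcaDecomposition(M=M_df, A=A_df, dimensionality_used=dimension, n_runs=n_runs, seeds=seeds)


def _empty_decomposition(data, dimension, n_runs, seeds) -> IcaDecomposition:
    M_df = pd.DataFrame(index=data.index, columns=pd.Index([], dtype=object), dtype=float)
    A_df = pd.DataFrame(index=pd.Index([], dtype=object), columns=data.columns, dtype=float)
    return IcaDecomposition(M=M_df, A=A_df, dimensionality_used=dimension, n_runs=n_runs, seeds=seeds)


def optica_select(
    X: ExpressionMatrix | pd.DataFrame,
    dimension_grid: list[int],
    n_runs: int = 100,
    k2_cutoff: float = 550.0,
    cluster_eps: float = 0.1,
    min_frequency: float = 0.5,
    seed: int = 0,
    keep_decompositions: bool = True,
) -> OpticaScanResult:
    """Scan ICA dimensionalities and select by the multi-gene component census.

    At each grid dimension a robust decomposition is computed and each robust
    component is classified as single-gene (at most one gene survives its K2
    binarization threshold) or multi-gene. The selected dimension is the
    smallest grid point at which the multi-gene component count attains its
    maximum over the grid.
    """
    from .membership import binarize_m

    if not dimension_grid:
        raise ValueError("dimension grid must be non-empty")
    grid = sorted(int(d) for d in dimension_grid)
    data = _as_frame(X)
    rng = np.random.default_rng(seed)
    records = []
    decomps: dict[int, IcaDecomposition] = {}
    for dim in grid:
        dim_seed = int(rng.integers(0, 2**31 - 1))
        dec = robust_decompose(
            data, dim, n_runs=n_runs, cluster_eps=cluster_eps,
            min_frequency=min_frequency, seed=dim_seed,
        )
        if dec.n_components:
            membership, _ = binarize_m(dec.M, k2_cutoff=k2_cutoff)
            sizes = membership.sum(axis=0)
            n_single = int((sizes <= 1).sum())
        else:
            n_single = 0
        n_robust = dec.n_components
        records.append(
            {
                "dimension": dim,
                "n_robust": n_robust,
                "n_single_gene": n_single,
                "n_multi_gene": n_robust - n_single,
            }
        )
        if keep_decompositions:
            decomps[dim] = dec
    table = pd.DataFrame(records)
    best = table["n_multi_gene"].max()
    selected = int(table.loc[table["n_multi_gene"] == best, "dimension"].iloc[0])
    return OpticaScanResult(table=table, selected_dimension=selected, decompositions=decomps)


def explained_variance(
    X: ExpressionMatrix | pd.DataFrame,
    M: pd.DataFrame,
    A: pd.DataFrame,
    component_subset: list[str] | None = None,
) -> float:
    """Fraction of variance in X captured by a component subset.

    Computed as 1 - ||X - M_S.A_S||_F^2 / ||X||_F^2 with the subset's
    activities re-fit by pseudoinverse projection; clipped to [0, 1]. The
    empty subset is 0 by definition.
    """
    data = _as_frame(X).to_numpy()
    if component_subset is not None:
        subset = list(component_subset)
        if not subset:
            return 0.0
        M_S = M.loc[:, subset].to_numpy()
    else:
        if M.shape[1] == 0:
            return 0.0
        M_S = M.to_numpy()
    A_S = np.linalg.pinv(M_S) @ data
    resid = data - M_S @ A_S
    total = float(np.sum(data**2))
    if total == 0:
        return 0.0
    return float(np.clip(1.0 - np.sum(resid**2) / total, 0.0, 1.0))
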