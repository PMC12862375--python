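"""Reading, validation, quality filtering, and reference centering of expression compendia.

The compendium is a gene x sample matrix of log2(TPM) values together with a
sample metadata table describing the project / condition / replicate design.
Quality control follows two numeric gates — a minimum number of reads mapped to
coding sequences, and a minimum Pearson correlation between biological
replicates — and batch effects are removed by centering every project against
the mean expression of its reference-condition samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_metadata",
    "write_sample_metadata",
    "tpm_to_log2",
    "filter_low_coverage",
    "filter_replicate_correlation",
    "center_to_reference",
    "combine_qc",
]

METADATA_COLUMNS = [
    "sample_id",
    "project",
    "condition",
    "replicate_group",
    "is_reference",
    "fallback_reference_project",
]


@dataclass
class ExpressionMatrix:
    """A gene x sample expression table in log2(TPM) units.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as columns. Values are log2(TPM), or centered log2(TPM) when
        ``centered`` is True.
    centered
        Whether the values have been centered to per-project reference
        conditions (the X of the X = M.A decomposition).
    """

    data: pd.DataFrame
    centered: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if not all(np.issubdtype(dt, np.number) for dt in self.data.dtypes):
            raise ValueError("expression values must be numeric")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in samples: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], centered=self.centered)


@dataclass
class SampleMetadata:
    """Sample design table: project, condition, replicate group, reference flag.

    Every project must resolve to a reference condition — either its own
    samples flagged ``is_reference`` or, for single-condition/miscellaneous
    projects, a ``fallback_reference_project`` whose reference samples are
    borrowed for centering.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS[:5] if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        if "fallback_reference_project" not in self.table.columns:
            self.table = self.table.assign(fallback_reference_project=pd.NA)
        if self.table["sample_id"].duplicated().any():
            dups = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample_id in metadata: {dups}")
        self.table = self.table.set_index("sample_id", drop=False)

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def samples_of_project(self, project: str) -> list[str]:
        return self.table.index[self.table["project"] == project].tolist()

    def reference_samples(self, project: str) -> list[str]:
        """Reference samples for a project, following the fallback if needed.

        Raises ``ValueError`` naming the project when no reference resolves.
        """
        sub = self.table[self.table["project"] == project]
        if sub.empty:
            raise ValueError(f"unknown project: {project!r}")
        own = sub.index[sub["is_reference"].astype(bool)].tolist()
        if own:
            return own
        fallback = sub["fallback_reference_project"].dropna().unique().tolist()
        if fallback:
            fb = fallback[0]
            fsub = self.table[self.table["project"] == fb]
            fref = fsub.index[fsub["is_reference"].astype(bool)].tolist()
            if fref:
                return fref
        raise ValueError(f"project {project!r} has no resolvable reference condition")

    def replicate_groups(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for sid, grp in self.table["replicate_group"].items():
            groups.setdefault(str(grp), []).append(sid)
        return groups

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = set(expr.sample_ids) - set(self.sample_ids)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    def subset(self, sample_ids) -> "SampleMetadata":
        table = self.table.loc[list(sample_ids)].reset_index(drop=True)
        return SampleMetadata(table)


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows TSV expression matrix (first column gene IDs)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(header) != len(set(header)):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"duplicate sample identifiers in header: {dups}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.any().any():
        gene = bad.index[bad.any(axis=1)][0]
        col = bad.columns[bad.loc[gene]][0]
        raise ValueError(
            f"malformed numeric value at gene {gene!r}, sample {col!r}: {raw.loc[gene, col]!r}"
        )
    return ExpressionMatrix(numeric.astype(float))


def write_expression_matrix(expr: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV with full float precision so write/read round-trips exactly."""
    out = expr.data.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format=None)


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "is_reference" in table.columns:
        table["is_reference"] = table["is_reference"].astype(bool)
    return SampleMetadata(table)


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.reset_index(drop=True).to_csv(path, sep="\t", index=False)


def tpm_to_log2(tpm: pd.DataFrame, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Entry-wise log2(TPM + pseudocount).

    The pseudocount (default 1, so TPM of zero maps to zero) guards against
    log of zero while preserving the zero point of the scale.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    values = tpm.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("TPM values must be nonnegative")
    return ExpressionMatrix(pd.DataFrame(np.log2(values + pseudocount), index=tpm.index, columns=tpm.columns))


def filter_low_coverage(
    read_counts: Mapping[str, int] | pd.Series,
    min_reads: int = 500_000,
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples with fewer than ``min_reads`` reads mapped to coding sequences.

    The comparison is strict: a sample with exactly ``min_reads`` is kept.
    Returns the kept sample list and a per-sample QC report.
    """
    counts = pd.Series(read_counts, dtype=float)
    if counts.isna().any():
        missing = counts.index[counts.isna()].tolist()
        raise ValueError(f"missing mapped-read count for samples: {missing}")
    passed = counts >= min_reads
    report = pd.DataFrame(
        {
            "sample_id": counts.index,
            "mapped_reads": counts.astype(int).to_numpy(),
            "min_reads_pass": passed.to_numpy(),
        }
    )
    return counts.index[passed].tolist(), report


def filter_replicate_correlation(
    expr: ExpressionMatrix,
    meta: SampleMetadata,
    min_r: float = 0.95,
) -> tuple[list[str], pd.DataFrame]:
    """Drop samples without a replicate or with poor replicate agreement.

    Singleton replicate groups are discarded outright. In groups with more
    than one sample, a sample is kept when its best Pearson correlation (on
    log2[TPM]) against any other member of its group reaches ``min_r``.
    """
    meta.validate_against(expr)
    records = []
    kept: list[str] = []
    for group, members in meta.replicate_groups().items():
        members = [m for m in members if m in expr.sample_ids]
        if not members:
            raise ValueError(f"replicate group {group!r} has no samples in the matrix")
        if len(members) == 1:
            records.append((members[0], group, np.nan, False))
            continue
        sub = expr.data.loc[:, members]
        corr = sub.corr(method="pearson")
        for sid in members:
            best = corr.loc[sid].drop(sid).max()
            ok = bool(best >= min_r)
            records.append((sid, group, float(best), ok))
            if ok:
                kept.append(sid)
    report = pd.DataFrame(
        records, columns=["sample_id", "replicate_group", "replicate_pearson_r", "replicate_r_pass"]
    )
    # keep original sample order
    order = {s: i for i, s in enumerate(expr.sample_ids)}
    kept.sort(key=order.get)
    return kept, report


def combine_qc(*reports: pd.DataFrame) -> pd.DataFrame:
    """Merge per-gate QC reports; a sample passes overall iff every gate passes."""
    merged: pd.DataFrame | None = None
    for rep in reports:
        merged = rep if merged is None else merged.merge(rep, on="sample_id", how="outer")
    if merged is None:
        raise ValueError("no QC reports given")
    gate_cols = [c for c in merged.columns if c.endswith("_pass")]
    merged["pass"] = merged[gate_cols].fillna(False).all(axis=1)
    return merged


def center_to_reference(expr: ExpressionMatrix, meta: SampleMetadata) -> ExpressionMatrix:
    """Center each project against the mean of its reference-condition samples.

    For every project, the per-gene arithmetic mean over that project's
    reference samples (own, or the fallback project's when the project has
    none) is subtracted from all of the project's samples. After centering,
    the mean over a project's own reference replicates is the zero vector.
    """
    meta.validate_against(expr)
    centered = expr.data.copy()
    for project in meta.table["project"].unique():
        samples = [s for s in meta.samples_of_project(project) if s in expr.sample_ids]
        if not samples:
            continue
        ref = [s for s in meta.reference_samples(project) if s in expr.sample_ids]
        if not ref:
            raise ValueError(f"project {project!r}: reference samples absent from matrix")
        ref_mean = expr.data.loc[:, ref].mean(axis=1)
        centered.loc[:, samples] = expr.data.loc[:, samples].sub(ref_mean, axis=0)
    if expr.centered:
        warnings.warn("centering an already-centered matrix", stacklevel=2)
    return ExpressionMatrix(centered, centered=True)
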