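"""Synthetic compendium generator with planted ground truth.

Generates everything the pipeline consumes — an expression matrix with the
structure X = M.A + noise, sample metadata with a project / condition /
replicate design, and a regulon table concordant with the planted modules —
so every stage can be tested against a known answer.

The planted structure emulates the statistical features the method assumes:
a sparse gene-weight matrix whose modules are mostly disjoint (with a
controllable fraction of multi-module genes), heavy-tailed member weights
(ICA requires non-Gaussian sources), condition-level activities with
project/replicate block structure and an all-zero reference condition per
project (mimicking reference-centered data), optional stimulon groups that
share an additive latent activity factor, and i.i.d. Gaussian expression
noise. It does not emulate count-level RNA-seq noise or library-size effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .compendium_io import (
    ExpressionMatrix,
    SampleMetadata,
    write_expression_matrix,
    write_sample_metadata,
)
from .enrichment import RegulonTable, write_regulon_table

__all__ = [
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_modules",
    "generate_activities",
    "compose_expression",
    "noise_sd_for_fraction",
    "generate_trn",
    "simulate",
    "recovery_report",
    "write_bundle",
]

# distinct fixed streams per stage so each generate_* call is independently
# reproducible from the spec seed alone
_STAGE_MODULES = 1
_STAGE_ACTIVITIES = 2
_STAGE_EXPRESSION = 3
_STAGE_TRN = 4


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic compendium.

    Defaults plant 10 modules of 8-25 genes in a 1000-gene universe over a
    10-project x 3-condition x 4-replicate design (120 samples), with
    condition activities of scale 10, replicate noise of sd 1, and expression
    noise at 10% of the signal variance.
    """

    n_genes: int = 1000
    n_modules: int = 10
    module_size_min: int = 8
    module_size_max: int = 25
    multi_module_gene_fraction: float = 0.0
    n_projects: int = 10
    conditions_per_project: int = 3
    replicates_per_condition: int = 4
    activity_scale: float = 10.0
    stimulon_groups: tuple[tuple[tuple[int, ...], float], ...] = ()
    replicate_noise_sd: float = 1.0
    expression_noise_sd: float | None = None  # None: 10% of signal variance
    trn_false_positive_rate: float = 0.0
    trn_false_negative_rate: float = 0.0
    weight_floor: float = 0.25
    weight_tail_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_modules <= 0:
            raise ValueError("n_genes and n_modules must be positive")
        if not (0 < self.module_size_min <= self.module_size_max <= self.n_genes):
            raise ValueError("module sizes must satisfy 0 < min <= max <= n_genes")
        if not 0 <= self.multi_module_gene_fraction <= 1:
            raise ValueError("multi_module_gene_fraction must be in [0, 1]")
        if self.n_projects <= 0 or self.replicates_per_condition <= 0:
            raise ValueError("project and replicate counts must be positive")
        if self.conditions_per_project <= 0:
            raise ValueError("conditions_per_project must be positive")
        for rate in (self.trn_false_positive_rate, self.trn_false_negative_rate):
            if not 0 <= rate <= 1:
                raise ValueError("TRN error rates must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_projects * self.conditions_per_project * self.replicates_per_condition

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def module_ids(self) -> list[str]:
        return [f"mod{i + 1:02d}" for i in range(self.n_modules)]


@dataclass
class SyntheticTruth:
    """Planted ground truth: M, A, metadata, regulon table, member lists."""

    spec: SyntheticSpec
    M: pd.DataFrame
    A: pd.DataFrame
    metadata: SampleMetadata
    members: dict[str, list[str]]
    trn: RegulonTable | None = None


def _rng(spec: SyntheticSpec, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, stage)))


def generate_modules(spec: SyntheticSpec) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Plant the sparse gene-weight matrix M.

    Module sizes are uniform in [size_min, size_max]. A
    ``multi_module_gene_fraction`` of each module's members is re-drawn from
    genes already used by earlier modules (when any exist), producing
    multi-module genes; the rest come from unused genes. Member weights are
    heavy-tailed — random sign, magnitude floor plus an exponential tail — and
    each column is normalized to unit L2 norm.
    """
    rng = _rng(spec, _STAGE_MODULES)
    genes = spec.gene_ids
    unused = list(genes)
    used: list[str] = []
    M = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=spec.module_ids)
    members: dict[str, list[str]] = {}
    for mod in spec.module_ids:
        size = int(rng.integers(spec.module_size_min, spec.module_size_max + 1))
        n_shared = int(round(spec.multi_module_gene_fraction * size))
        n_shared = min(n_shared, len(used))
        n_fresh = size - n_shared
        if n_fresh > len(unused):
            raise ValueError(
                f"module {mod}: needs {n_fresh} fresh genes but only {len(unused)} remain"
            )
        shared = list(rng.choice(used, size=n_shared, replace=False)) if n_shared else []
        fresh_idx = rng.choice(len(unused), size=n_fresh, replace=False)
        fresh = [unused[i] for i in sorted(fresh_idx)]
        for g in fresh:
            unused.remove(g)
            used.append(g)
        chosen = fresh + shared
        magnitudes = spec.weight_floor + rng.exponential(spec.weight_tail_scale, size=size)
        signs = rng.choice([-1.0, 1.0], size=size)
        M.loc[chosen, mod] = magnitudes * signs
        members[mod] = sorted(chosen)
    norms = np.linalg.norm(M.to_numpy(), axis=0)
    M = M / norms
    return M, members


def generate_activities(spec: SyntheticSpec) -> tuple[pd.DataFrame, SampleMetadata]:
    """Plant the activity matrix A and the sample design.

    Each project's first condition is its reference and has condition-level
    activity 0 for every module (the compendium is generated already centered
    to reference). Other conditions draw module activities N(0, scale^2);
    stimulon groups add a shared per-condition latent factor scaled by their
    mixing coefficient. Replicate columns add N(0, replicate_noise_sd^2).
    """
    rng = _rng(spec, _STAGE_ACTIVITIES)
    module_ids = spec.module_ids
    k = spec.n_modules
    columns: list[str] = []
    meta_rows = []
    activity_cols = []
    for p in range(spec.n_projects):
        project = f"P{p + 1:02d}"
        for c in range(spec.conditions_per_project):
            condition = f"{project}_c{c}"
            is_ref = c == 0
            if is_ref:
                cond_activity = np.zeros(k)
            else:
                cond_activity = rng.normal(0.0, spec.activity_scale, size=k)
                for group, mixing in spec.stimulon_groups:
                    latent = rng.normal(0.0, spec.activity_scale)
                    for mod_idx in group:
                        cond_activity[mod_idx] += mixing * latent
            for r in range(spec.replicates_per_condition):
                sid = f"{condition}_r{r + 1}"
                columns.append(sid)
                noise = rng.normal(0.0, spec.replicate_noise_sd, size=k)
                activity_cols.append(cond_activity + noise)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "project": project,
                        "condition": condition,
                        "replicate_group": condition,
                        "is_reference": is_ref,
                        "fallback_reference_project": pd.NA,
                    }
                )
    A = pd.DataFrame(np.column_stack(activity_cols), index=module_ids, columns=columns)
    return A, SampleMetadata(pd.DataFrame(meta_rows))


def noise_sd_for_fraction(M: pd.DataFrame, A: pd.DataFrame, fraction: float) -> float:
    """Expression-noise sd giving noise variance = ``fraction`` x signal variance."""
    signal = M.to_numpy() @ A.to_numpy()
    return float(np.sqrt(fraction * signal.var()))


def compose_expression(
    truth: SyntheticTruth,
    expression_noise_sd: float | None = None,
) -> ExpressionMatrix:
    """Realize X = M.A + i.i.d. Gaussian noise; deterministic for the spec seed."""
    spec = truth.spec
    if expression_noise_sd is None:
        expression_noise_sd = spec.expression_noise_sd
    if expression_noise_sd is None:
        expression_noise_sd = noise_sd_for_fraction(truth.M, truth.A, 0.10)
    rng = _rng(spec, _STAGE_EXPRESSION)
    signal = truth.M.to_numpy() @ truth.A.to_numpy()
    noise = rng.normal(0.0, expression_noise_sd, size=signal.shape) if expression_noise_sd > 0 else 0.0
    X = pd.DataFrame(signal + noise, index=truth.M.index, columns=truth.A.columns)
    return ExpressionMatrix(X, centered=True)


def generate_trn(
    truth: SyntheticTruth,
    fpr: float | None = None,
    fnr: float | None = None,
) -> RegulonTable:
    """Regulon table concordant with the planted modules, with controlled error.

    One regulator per module; each member is dropped with probability ``fnr``
    and each non-member gene added with probability ``fpr``. Regulons emptied
    by dropout are removed with a warning.
    """
    spec = truth.spec
    fpr = spec.trn_false_positive_rate if fpr is None else fpr
    fnr = spec.trn_false_negative_rate if fnr is None else fnr
    rng = _rng(spec, _STAGE_TRN)
    all_genes = set(truth.M.index)
    rows = []
    for mod, members in truth.members.items():
        regulator = f"R_{mod}"
        kept = [g for g in members if fnr == 0 or rng.random() >= fnr]
        non_members = sorted(all_genes - set(members))
        added = [g for g in non_members if fpr > 0 and rng.random() < fpr]
        regulon = sorted(set(kept) | set(added))
        if not regulon:
            warnings.warn(f"regulon for {regulator} empty after dropout; dropped", stacklevel=2)
            continue
        for g in regulon:
            rows.append({"regulator": regulator, "gene": g, "effect": "+", "evidence": "planted"})
    return RegulonTable(pd.DataFrame(rows, columns=["regulator", "gene", "effect", "evidence"]))


def simulate(spec: SyntheticSpec) -> tuple[SyntheticTruth, ExpressionMatrix]:
    """Full synthetic bundle: truth (M, A, metadata, TRN) plus the expression matrix."""
    M, members = generate_modules(spec)
    A, meta = generate_activities(spec)
    truth = SyntheticTruth(spec=spec, M=M, A=A, metadata=meta, members=members)
    truth.trn = generate_trn(truth)
    expr = compose_expression(truth)
    return truth, expr


def recovery_report(
    truth: SyntheticTruth,
    M_recovered: pd.DataFrame,
    membership: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Score recovered components against the planted modules.

    Per planted module: the maximum |Pearson r| between its weight vector and
    any recovered column, and (when a binarized membership is given) the best
    Jaccard index between its member set and any recovered member set.
    """
    rows = []
    for mod in truth.M.columns:
        planted_w = truth.M[mod].to_numpy()
        best_r = 0.0
        if M_recovered.shape[1]:
            rec = M_recovered.loc[truth.M.index].to_numpy()
            pw = planted_w - planted_w.mean()
            rc = rec - rec.mean(axis=0)
            denom = np.linalg.norm(pw) * np.linalg.norm(rc, axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                rs = np.abs(pw @ rc) / denom
            best_r = float(np.nanmax(rs)) if rs.size else 0.0
        best_j = np.nan
        if membership is not None and membership.shape[1]:
            planted = set(truth.members[mod])
            jaccards = []
            for comp in membership.columns:
                rec_members = set(membership.index[membership[comp]])
                union = planted | rec_members
                jaccards.append(len(planted & rec_members) / len(union) if union else 0.0)
            best_j = float(max(jaccards))
        rows.append({"module": mod, "max_abs_r": best_r, "best_jaccard": best_j})
    return pd.DataFrame(rows).set_index("module")


def write_bundle(truth: SyntheticTruth, expr: ExpressionMatrix, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the TSV formats the pipeline consumes, plus the truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "trn": outdir / "trn.tsv",
        "planted_M": outdir / "planted_M.tsv",
        "planted_A": outdir / "planted_A.tsv",
        "spec": outdir / "spec.yaml",
    }
    write_expression_matrix(expr, paths["expression"])
    write_sample_metadata(truth.metadata, paths["metadata"])
    if truth.trn is not None:
        write_regulon_table(truth.trn, paths["trn"])
    M_out = truth.M.copy()
    M_out.index.name = "gene_id"
    M_out.to_csv(paths["planted_M"], sep="\t")
    A_out = truth.A.copy()
    A_out.index.name = "component_id"
    A_out.to_csv(paths["planted_A"], sep="\t")
    import yaml

    spec_dict = asdict(truth.spec)
    spec_dict["stimulon_groups"] = [
        {"modules": list(group), "mixing": mixing} for group, mixing in truth.spec.stimulon_groups
    ]
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(spec_dict, fh, sort_keys=True)
    return paths
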