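"""Regulon enrichment and categorization of iModulons.

Each iModulon's gene membership is tested for over-representation of curated
regulons (regulator -> gene sets from a TRN table) with the one-sided Fisher
exact (hypergeometric) test, Benjamini-Hochberg adjusted across the candidate
family of single regulators and pairwise regulator combinations. iModulons
with a significant enrichment are "Regulatory"; the rest fall to "Technical"
(a single dominant gene, usually noise), "Biological" (manually annotated
function), or "Uncharacterized".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RegulonTable",
    "EnrichmentResult",
    "IModulonAnnotation",
    "fisher_enrichment",
    "bh_adjust",
    "precision_recall",
    "enrich_imodulon",
    "categorize",
    "read_regulon_table",
    "write_regulon_table",
    "build_imodulon_table",
]

REGULON_COLUMNS = ["regulator", "gene", "effect", "evidence"]
CATEGORIES = ("Regulatory", "Biological", "Technical", "Uncharacterized")


@dataclass
class RegulonTable:
    """Regulator -> gene associations with effect sign and evidence level."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REGULON_COLUMNS[:2] if c not in self.table.columns]
        if missing:
            raise ValueError(f"regulon table missing columns: {missing}")
        for col in REGULON_COLUMNS[2:]:
            if col not in self.table.columns:
                self.table = self.table.assign(**{col: "unknown"})
        if self.table.duplicated(subset=["regulator", "gene"]).any():
            raise ValueError("duplicate (regulator, gene) pairs in regulon table")

    @property
    def regulators(self) -> list[str]:
        return sorted(self.table["regulator"].unique())

    def regulon(self, regulator: str) -> frozenset[str]:
        return frozenset(self.table.loc[self.table["regulator"] == regulator, "gene"])

    def to_mapping(self) -> dict[str, frozenset[str]]:
        return {r: frozenset(g["gene"]) for r, g in self.table.groupby("regulator")}

    def filter_evidence(self, levels: set[str]) -> "RegulonTable":
        return RegulonTable(self.table[self.table["evidence"].isin(levels)].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.table)


def read_regulon_table(path: str | Path) -> RegulonTable:
    return RegulonTable(pd.read_csv(path, sep="\t", dtype=str))


def write_regulon_table(trn: RegulonTable, path: str | Path) -> None:
    trn.table.to_csv(path, sep="\t", index=False)


@dataclass
class EnrichmentResult:
    component_id: str
    regulator_set: tuple[str, ...]
    combination: str  # "single", "intersection", or "union"
    p: float
    q: float
    overlap: int
    precision: float
    recall: float
    f1: float

    @property
    def regulator_label(self) -> str:
        joiner = {"single": "", "intersection": "+", "union": "/"}[self.combination]
        return joiner.join(self.regulator_set) if len(self.regulator_set) > 1 else self.regulator_set[0]


@dataclass
class IModulonAnnotation:
    component_id: str
    category: str
    name: str = ""
    functional_category: str = ""
    enrichment: EnrichmentResult | None = None


def fisher_enrichment(members: set[str], regulon: set[str], universe: int) -> float:
    """One-sided over-representation p-value for a gene-set overlap.

    The upper-tail hypergeometric probability of drawing at least the
    observed overlap when |members| genes are sampled from a universe
    containing |regulon| successes. Empty member set returns 1 by convention.
    """
    if universe <= 0:
        raise ValueError("universe must be positive")
    if len(members) > universe or len(regulon) > universe:
        raise ValueError("gene sets exceed the declared universe")
    if not members:
        return 1.0
    overlap = len(members & regulon)
    return float(stats.hypergeom.sf(overlap - 1, universe, len(regulon), len(members)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def precision_recall(members: set[str], regulon: set[str]) -> tuple[float, float, float]:
    """Precision (overlap/|members|), recall (overlap/|regulon|), and their F1."""
    if not members:
        raise ValueError("empty member set")
    if not regulon:
        raise ValueError("empty regulon")
    overlap = len(members & regulon)
    prec = overlap / len(members)
    rec = overlap / len(regulon)
    f1 = 0.0 if overlap == 0 else 2 * prec * rec / (prec + rec)
    return prec, rec, f1


def enrich_imodulon(
    members: set[str],
    trn: RegulonTable,
    universe: int,
    max_regulators: int = 2,
    q_threshold: float = 1e-5,
    component_id: str = "",
) -> EnrichmentResult | None:
    """Best regulon enrichment for one iModulon, or None if nothing is significant.

    Candidates are every single regulon with at least one member overlap plus
    the pairwise intersections and unions of those regulators (bounding the
    combination size keeps the BH family from exploding). p-values are
    BH-adjusted within the candidate family; the winner has the lowest q,
    ties broken by highest F1.
    """
    if not members or len(trn) == 0:
        return None
    mapping = trn.to_mapping()
    singles = {r: g for r, g in mapping.items() if g and members & g}
    if not singles:
        return None

    candidates: list[tuple[tuple[str, ...], str, frozenset[str]]] = [
        ((r,), "single", g) for r, g in sorted(singles.items())
    ]
    if max_regulators >= 2:
        for r1, r2 in combinations(sorted(singles), 2):
            inter = singles[r1] & singles[r2]
            if inter and members & inter:
                candidates.append(((r1, r2), "intersection", inter))
            union = singles[r1] | singles[r2]
            candidates.append(((r1, r2), "union", union))

    pvals = [fisher_enrichment(members, set(genes), universe) for _, _, genes in candidates]
    qvals = bh_adjust(pvals)

    results = []
    for (regs, combo, genes), p, q in zip(candidates, pvals, qvals):
        prec, rec, f1 = precision_recall(members, set(genes))
        results.append(
            EnrichmentResult(
                component_id=component_id,
                regulator_set=regs,
                combination=combo,
                p=float(p),
                q=float(q),
                overlap=len(members & genes),
                precision=prec,
                recall=rec,
                f1=f1,
            )
        )
    best = min(results, key=lambda r: (r.q, -r.f1))
    if best.q >= q_threshold:
        return None
    return best


def categorize(
    component_id: str,
    members: list[str],
    weights: pd.Series,
    enrichment: EnrichmentResult | None,
    manual_annotations: pd.DataFrame | None = None,
    dominance_ratio: float = 5.0,
) -> IModulonAnnotation:
    """Assign one of the four iModulon categories.

    Precedence: Regulatory (significant regulon enrichment) > Technical
    (exactly one member, or the top |weight| dominates the runner-up by
    ``dominance_ratio``) > Biological (a manual functional annotation
    exists) > Uncharacterized.
    """
    manual = None
    if manual_annotations is not None and component_id in manual_annotations.index:
        manual = manual_annotations.loc[component_id]

    if enrichment is not None:
        name = manual["name"] if manual is not None and "name" in manual else enrichment.regulator_label
        func = manual["functional_category"] if manual is not None and "functional_category" in manual else ""
        return IModulonAnnotation(component_id, "Regulatory", str(name), str(func), enrichment)

    abs_w = weights.abs().sort_values(ascending=False)
    single_gene = len(members) == 1 or (
        len(abs_w) >= 2 and abs_w.iloc[1] > 0 and abs_w.iloc[0] / abs_w.iloc[1] >= dominance_ratio
    ) or (len(abs_w) >= 2 and abs_w.iloc[1] == 0 and abs_w.iloc[0] > 0)
    if single_gene:
        name = str(abs_w.index[0]) if len(abs_w) else component_id
        return IModulonAnnotation(component_id, "Technical", name, "single gene", None)

    if manual is not None:
        return IModulonAnnotation(
            component_id,
            "Biological",
            str(manual.get("name", component_id)),
            str(manual.get("functional_category", "")),
            None,
        )
    return IModulonAnnotation(component_id, "Uncharacterized", component_id, "", None)


def build_imodulon_table(
    membership: pd.DataFrame,
    M: pd.DataFrame,
    trn: RegulonTable,
    universe: int | None = None,
    max_regulators: int = 2,
    q_threshold: float = 1e-5,
    manual_annotations: pd.DataFrame | None = None,
    dominance_ratio: float = 5.0,
) -> pd.DataFrame:
    """Annotate every component; returns the consolidated iModulon table.

    Columns mirror the standard knowledgebase layout: identity, category,
    winning regulator set with its statistics, and membership size. The gene
    universe defaults to the genes present in the weight matrix.
    """
    if universe is None:
        universe = M.shape[0]
    rows = []
    for comp in membership.columns:
        members = membership.index[membership[comp]].tolist()
        enr = None
        if members:
            enr = enrich_imodulon(
                set(members), trn, universe,
                max_regulators=max_regulators, q_threshold=q_threshold, component_id=str(comp),
            )
        elif len(trn):
            warnings.warn(f"component {comp} has no members; skipping enrichment", stacklevel=2)
        ann = categorize(str(comp), members, M[comp], enr, manual_annotations, dominance_ratio)
        rows.append(
            {
                "component_id": str(comp),
                "name": ann.name,
                "category": ann.category,
                "functional_category": ann.functional_category,
                "regulator_set": enr.regulator_label if enr else "",
                "p": enr.p if enr else np.nan,
                "q": enr.q if enr else np.nan,
                "overlap": enr.overlap if enr else 0,
                "precision": enr.precision if enr else np.nan,
                "recall": enr.recall if enr else np.nan,
                "f1": enr.f1 if enr else np.nan,
                "n_members": len(members),
            }
        )
    return pd.DataFrame(rows)
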