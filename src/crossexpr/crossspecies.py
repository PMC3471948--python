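"""Ortholog pairing and the similar/different expression-pattern heuristic.

Each ortholog pair gets, per stage comparison, the two species' log2 fold
changes (fc_a, fc_b). The pattern label is:

* ``similar``   — |fc_a − fc_b| < t_similar                       (default 0.2)
* ``different`` — |fc_a − fc_b| > t_different and |fc_a| > t_min
                  and |fc_b| > t_min                              (defaults 0.4, 0.2)
* ``neither``   — everything else (including the (t_similar, t_different] gap
                  and pairs driven by a single species).

All thresholds are on the log2 scale with strict inequalities; boundary
values fall to ``neither``. On scatterplots similar/different/neither map to
red/green/black.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import (
    FoldChangeTable,
    GeneSetCollection,
    OrthologMap,
    ValidationError,
)

__all__ = [
    "ClassificationParams",
    "LABELS",
    "pair_fold_changes",
    "classify_pair",
    "classify_table",
    "restrict_to_gene_set",
    "gene_set_summary",
]

LABELS = ("similar", "different", "neither")


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the pattern heuristic, all on the log2 scale."""

    t_similar: float = 0.2
    t_different: float = 0.4
    t_min: float = 0.2

    def __post_init__(self) -> None:
        if not (self.t_different >= self.t_similar >= 0):
            raise ValidationError("require t_different >= t_similar >= 0")
        if self.t_min < 0:
            raise ValidationError("t_min must be >= 0")


def pair_fold_changes(
    fc_a: FoldChangeTable, fc_b: FoldChangeTable, omap: OrthologMap
) -> tuple[pd.DataFrame, dict]:
    """Join the two species' fold changes through the ortholog map.

    Returns a (paired table, coverage report) tuple. The paired table has one
    row per ortholog pair per shared comparison when both genes are measured;
    many-to-many links expand to all pairs. Pairs with either gene unmeasured
    are dropped and counted in the coverage report.
    """
    comparisons = [c.name for c in fc_a.comparisons if c.name in fc_b.fold_changes.columns]
    if not comparisons:
        raise ValidationError("fold-change tables share no comparisons")
    genes_a = set(fc_a.gene_ids)
    genes_b = set(fc_b.gene_ids)
    rows = []
    n_paired = n_unpaired = 0
    for gene_a, gene_b in sorted(omap.pairs):
        if gene_a in genes_a and gene_b in genes_b:
            n_paired += 1
            for comp in comparisons:
                rows.append(
                    (
                        gene_a,
                        gene_b,
                        comp,
                        float(fc_a.fold_changes.at[gene_a, comp]),
                        float(fc_b.fold_changes.at[gene_b, comp]),
                    )
                )
        else:
            n_unpaired += 1
    paired = pd.DataFrame(rows, columns=["gene_a", "gene_b", "comparison", "fc_a", "fc_b"])
    report = {
        "map_pairs": len(omap),
        "measured_a": len(genes_a),
        "measured_b": len(genes_b),
        "paired": n_paired,
        "unpaired": n_unpaired,
        "mapped_fraction_a": len(omap.genes_a & genes_a) / max(len(genes_a), 1),
        "mapped_fraction_b": len(omap.genes_b & genes_b) / max(len(genes_b), 1),
    }
    return paired, report


def classify_pair(fc_a: float, fc_b: float, params: ClassificationParams = ClassificationParams()) -> str:
    """Label one ortholog pair for one comparison; see module docstring."""
    if not (math.isfinite(fc_a) and math.isfinite(fc_b)):
        raise ValidationError("fold changes must be finite")
    diff = abs(fc_a - fc_b)
    if diff < params.t_similar:
        return "similar"
    if diff > params.t_different and abs(fc_a) > params.t_min and abs(fc_b) > params.t_min:
        return "different"
    return "neither"


def classify_table(
    paired: pd.DataFrame, params: ClassificationParams = ClassificationParams()
) -> pd.DataFrame:
    """Row-wise classification of a paired fold-change table (vectorized).

    Returns the paired table with a ``label`` column appended.
    """
    out = paired.copy()
    if out.empty:
        out["label"] = pd.Series(dtype=str)
        return out
    fa = out["fc_a"].to_numpy(dtype=float)
    fb = out["fc_b"].to_numpy(dtype=float)
    if not (np.isfinite(fa).all() and np.isfinite(fb).all()):
        raise ValidationError("fold changes must be finite")
    diff = np.abs(fa - fb)
    similar = diff < params.t_similar
    different = (
        (diff > params.t_different)
        & (np.abs(fa) > params.t_min)
        & (np.abs(fb) > params.t_min)
        & ~similar
    )
    labels = np.where(similar, "similar", np.where(different, "different", "neither"))
    out["label"] = labels
    return out


def label_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """Counts per comparison × label, all labels present (zero-filled)."""
    rows = []
    for comp, group in labeled.groupby("comparison", sort=True):
        counts = group["label"].value_counts()
        rows.append(
            {
                "comparison": comp,
                **{label: int(counts.get(label, 0)) for label in LABELS},
                "total": len(group),
            }
        )
    return pd.DataFrame(rows, columns=["comparison", *LABELS, "total"])


def restrict_to_gene_set(
    table: pd.DataFrame, gene_set: set, omap: OrthologMap
) -> tuple[pd.DataFrame, dict]:
    """Keep rows whose species-A gene belongs to the set; report coverage.

    Gene sets are defined on species-A identifiers (the mouse-anchored
    convention); rows translate through the ortholog map implicitly because
    the table is already paired.
    """
    if not gene_set:
        raise ValidationError("gene set is empty")
    mapped = {g for g in gene_set if g in omap.genes_a}
    measured = set(table["gene_a"]) & gene_set
    restricted = table[table["gene_a"].isin(gene_set)].reset_index(drop=True)
    report = {
        "set_size": len(gene_set),
        "mapped_size": len(mapped),
        "measured_size": len(measured),
    }
    return restricted, report


def gene_set_summary(
    labeled: pd.DataFrame, collection: GeneSetCollection, omap: OrthologMap
) -> pd.DataFrame:
    """Per-set × per-comparison label counts plus the 'different' gene list.

    One row per (set, comparison); the ``different_genes`` column lists the
    discordant species-A genes sorted by |fc_a − fc_b| descending (ties by
    identifier), comma-separated.
    """
    rows = []
    for name in collection.names():
        restricted, report = restrict_to_gene_set(labeled, collection.sets[name], omap)
        for comp in sorted(labeled["comparison"].unique()):
            sub = restricted[restricted["comparison"] == comp]
            counts = sub["label"].value_counts()
            diffs = sub[sub["label"] == "different"].copy()
            diffs["_gap"] = (diffs["fc_a"] - diffs["fc_b"]).abs()
            diffs = diffs.sort_values(["_gap", "gene_a"], ascending=[False, True], kind="mergesort")
            rows.append(
                {
                    "set": name,
                    "comparison": comp,
                    "set_size": report["set_size"],
                    "mapped_size": report["mapped_size"],
                    "measured_size": report["measured_size"],
                    **{label: int(counts.get(label, 0)) for label in LABELS},
                    "different_genes": ",".join(diffs["gene_a"]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["set", "comparison", "set_size", "mapped_size", "measured_size",
                 *LABELS, "different_genes"],
    )
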