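"""Stage means, log2 fold changes, threshold selection, Venn overlaps, top-N union.

Fold change is the difference between mean log2 signal values of two stages —
a log2 ratio. With two pooled replicates per stage, aggregation is the
unweighted arithmetic mean; no variance moderation is attempted. Selection
thresholds (canonically 1.5 and 3) apply to |FC| with strict inequality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    CANONICAL_COMPARISONS,
    ExpressionDataset,
    FoldChangeTable,
    StageComparison,
    ValidationError,
)

__all__ = [
    "SelectionParams",
    "VennCounts",
    "stage_means",
    "compute_fold_changes",
    "select_genes",
    "venn_counts",
    "top_n_union",
]


@dataclass(frozen=True)
class SelectionParams:
    """Fold-change selection rule: |FC| > threshold (log2 scale) by default."""

    threshold: float
    use_absolute: bool = True
    strict: bool = True

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("selection threshold must be positive")

    def passes(self, fc: np.ndarray) -> np.ndarray:
        value = np.abs(fc) if self.use_absolute else np.asarray(fc)
        return value > self.threshold if self.strict else value >= self.threshold


def stage_means(dataset: ExpressionDataset, stages=None) -> pd.DataFrame:
    """Per-gene arithmetic mean of log2 signals over each stage's replicates.

    Returns a genes × stages DataFrame. Raises naming the stage if a stage
    has no samples.
    """
    stages = tuple(stages) if stages is not None else tuple(
        dict.fromkeys(dataset.samples["stage"])
    )
    dataset.require_stages(stages)
    out = pd.DataFrame(index=dataset.values.index)
    for stage in stages:
        cols = dataset.samples_for_stage(stage)
        out[stage] = dataset.values[cols].mean(axis=1)
    return out


def compute_fold_changes(
    dataset: ExpressionDataset,
    comparisons: tuple[StageComparison, ...] = CANONICAL_COMPARISONS,
) -> FoldChangeTable:
    """Fold changes FC(gene, c) = mean(numerator stage) − mean(denominator stage).

    Stage means are computed once and reused across comparisons, so the
    additivity identity FC(ICM vs M) = FC(ICM vs B) + FC(B vs M) holds exactly.
    """
    needed = tuple(dict.fromkeys(
        s for c in comparisons for s in (c.numerator, c.denominator)
    ))
    means = stage_means(dataset, needed)
    fc = pd.DataFrame(index=means.index)
    for c in comparisons:
        fc[c.name] = means[c.numerator] - means[c.denominator]
    return FoldChangeTable(
        species_label=dataset.species_label,
        stage_means=means,
        fold_changes=fc,
        comparisons=tuple(comparisons),
    )


def select_genes(
    fc: FoldChangeTable, comparison: StageComparison | str, params: SelectionParams
) -> pd.DataFrame:
    """Genes passing the threshold for one comparison.

    Output columns ``gene_id``, ``fc`` (signed), sorted by |FC| descending
    with ties broken by gene identifier ascending.
    """
    name = comparison if isinstance(comparison, str) else comparison.name
    if name not in fc.fold_changes.columns:
        raise ValidationError(f"unknown comparison {name!r}")
    values = fc.fold_changes[name]
    mask = params.passes(values.to_numpy())
    selected = pd.DataFrame({"gene_id": values.index[mask], "fc": values[mask].to_numpy()})
    selected["_abs"] = selected["fc"].abs()
    selected = selected.sort_values(
        ["_abs", "gene_id"], ascending=[False, True], kind="mergesort"
    ).drop(columns="_abs")
    return selected.reset_index(drop=True)


#: The seven regions of a three-set Venn, as frozensets of member-list indices.
_REGIONS = (
    frozenset({0}), frozenset({1}), frozenset({2}),
    frozenset({0, 1}), frozenset({0, 2}), frozenset({1, 2}),
    frozenset({0, 1, 2}),
)


@dataclass
class VennCounts:
    """Exclusive region counts of a three-set Venn diagram."""

    labels: tuple[str, str, str]
    counts: dict = field(default_factory=dict)  # frozenset of labels -> int

    def region(self, *labels: str) -> int:
        """Count of elements in exactly the given sets (exclusive region)."""
        return self.counts[frozenset(labels)]

    def set_total(self, label: str) -> int:
        """Total size of one set = sum of its four regions."""
        return sum(n for region, n in self.counts.items() if label in region)

    def intersection(self, *labels: str) -> int:
        """Plain (inclusive) intersection size of the given sets."""
        want = frozenset(labels)
        return sum(n for region, n in self.counts.items() if want <= region)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for region in sorted(self.counts, key=lambda r: (len(r), sorted(r))):
            rows.append({"region": "&".join(sorted(region)), "count": self.counts[region]})
        return pd.DataFrame(rows)


def venn_counts(lists: dict) -> VennCounts:
    """Exact counts of the 7 exclusive regions of three named gene lists."""
    if len(lists) != 3:
        raise ValidationError("venn_counts needs exactly three named lists")
    labels = tuple(lists)
    if len(set(labels)) != 3:
        raise ValidationError("list names must be distinct")
    sets = [set(lists[name]) for name in labels]
    counts: dict = {}
    for region in _REGIONS:
        inside = set.intersection(*(sets[i] for i in region)) if region else set()
        for i in set(range(3)) - region:
            inside -= sets[i]
        counts[frozenset(labels[i] for i in region)] = len(inside)
    return VennCounts(labels=labels, counts=counts)


def top_n_union(fc: FoldChangeTable, n: int) -> tuple[dict, list]:
    """Top-n genes by |FC| per comparison and their ordered union.

    Ties break by gene identifier ascending. The union preserves first-seen
    order across comparisons taken in the table's comparison order — the gene
    list fed to the heatmap.
    """
    if n < 1:
        raise ValidationError("n must be a positive integer")
    if n > len(fc.gene_ids):
        raise ValidationError(f"n={n} exceeds gene count {len(fc.gene_ids)}")
    per_comparison: dict = {}
    union: list = []
    seen = set()
    for c in fc.comparisons:
        values = fc.fold_changes[c.name]
        order = sorted(values.index, key=lambda g: (-abs(values[g]), g))
        top = order[:n]
        per_comparison[c.name] = top
        for g in top:
            if g not in seen:
                seen.add(g)
                union.append(g)
    return per_comparison, union
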