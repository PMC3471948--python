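"""Figure builders: clustered heatmap, fold-change scatterplots, profile plots.

Every figure has a data-side spec object (and sidecar TSV) holding exactly
the numbers drawn, so tests assert on the spec tables rather than on image
bytes. Clustering is agglomerative with Euclidean distance and average
linkage on row-centered log2 values; this choice is recorded in the spec.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datamodel import (
    STAGE_CODES,
    ExpressionDataset,
    FoldChangeTable,
    ValidationError,
)
from .foldchange import VennCounts, top_n_union

logger = logging.getLogger(__name__)

__all__ = [
    "HeatmapSpec",
    "ScatterSpec",
    "ProfileSpec",
    "hierarchical_order",
    "build_heatmap",
    "build_scatter",
    "build_profile",
    "build_venn_figure",
]

#: Fixed column order of the heatmap: stage design order, replicates within stage.
_HEATMAP_STAGE_ORDER = ("morula", "blastocyst", "ICM")

#: Profile plots use the figure convention morula, ICM, blastocyst.
_PROFILE_STAGE_ORDER = ("morula", "ICM", "blastocyst")

_LABEL_COLORS = {"similar": "red", "different": "green", "neither": "black"}


def hierarchical_order(matrix: np.ndarray) -> tuple[list, np.ndarray]:
    """Leaf order and linkage of deterministic average-linkage clustering.

    Euclidean distances; SciPy's agglomerative algorithm is deterministic
    given row order, so identical inputs give identical leaf orders.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValidationError("clustering needs a 2-D matrix with >=2 rows")
    linkage = hierarchy.linkage(pdist(matrix, metric="euclidean"), method="average")
    leaves = hierarchy.leaves_list(linkage).tolist()
    return leaves, linkage


@dataclass
class HeatmapSpec:
    """Data behind one species' heatmap: row-centered values in plotted order."""

    species_label: str
    gene_order: list
    sample_order: list
    values: pd.DataFrame  # genes (plot order) x samples (plot order), row-centered
    linkage: np.ndarray
    union_genes: list
    per_comparison_top: dict
    distance_metric: str = "euclidean"
    linkage_method: str = "average"

    def to_frame(self) -> pd.DataFrame:
        out = self.values.copy()
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)


def build_heatmap(
    fc: FoldChangeTable,
    dataset: ExpressionDataset,
    n: int = 20,
    out: str | Path | None = None,
) -> HeatmapSpec:
    """Top-n-per-comparison union heatmap with hierarchically clustered rows.

    Rows are the union of the three top-n lists, centered per gene (row mean
    subtracted) so baselines vanish while fold-change magnitudes survive;
    columns stay in fixed design order (M1, M2, B1, B2, ICM1, ICM2).
    """
    per_comparison, union = top_n_union(fc, n)
    sample_order = []
    for stage in _HEATMAP_STAGE_ORDER:
        cols = dataset.samples[dataset.samples["stage"] == stage]
        cols = cols.sort_values("replicate")
        sample_order.extend(
            (sid, f"{STAGE_CODES[stage]}{rep}")
            for sid, rep in zip(cols["sample_id"], cols["replicate"])
        )
    sample_ids = [sid for sid, _ in sample_order]
    sample_labels = [lab for _, lab in sample_order]

    sub = dataset.values.loc[union, sample_ids]
    centered = sub.sub(sub.mean(axis=1), axis=0)
    leaves, linkage = hierarchical_order(centered.to_numpy())
    gene_order = [union[i] for i in leaves]
    values = centered.loc[gene_order]
    values.columns = sample_labels

    spec = HeatmapSpec(
        species_label=fc.species_label,
        gene_order=gene_order,
        sample_order=sample_labels,
        values=values,
        linkage=linkage,
        union_genes=union,
        per_comparison_top=per_comparison,
    )
    if out is not None:
        _render_heatmap(spec, Path(out))
    return spec


def _render_heatmap(spec: HeatmapSpec, out: Path) -> None:
    n_rows = len(spec.gene_order)
    fig, ax = plt.subplots(figsize=(4.5, max(3.0, 0.14 * n_rows + 1.2)))
    limit = np.abs(spec.values.to_numpy()).max() or 1.0
    im = ax.imshow(
        spec.values.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-limit, vmax=limit
    )
    ax.set_xticks(range(len(spec.sample_order)), spec.sample_order, rotation=45)
    ax.set_yticks(range(n_rows), spec.gene_order, fontsize=5)
    ax.set_title(f"{spec.species_label}: top-gene heatmap (row-centered log2)")
    fig.colorbar(im, ax=ax, label="log2 signal − row mean")
    _save(fig, out)


@dataclass
class ScatterSpec:
    """Points of one cross-species fold-change scatterplot with label colors."""

    comparison: str
    points: pd.DataFrame  # gene_a, gene_b, fc_a, fc_b, label, color
    highlighted: list = field(default_factory=list)
    xlabel: str = "species A log2 fold change"
    ylabel: str = "species B log2 fold change"

    def color_counts(self) -> dict:
        return self.points["color"].value_counts().to_dict()


def build_scatter(
    labeled: pd.DataFrame,
    comparison: str,
    highlight: list | None = None,
    out: str | Path | None = None,
    species_labels: tuple[str, str] = ("species A", "species B"),
) -> ScatterSpec:
    """Scatter of (fc_a, fc_b) per ortholog pair, colored by pattern label.

    Red = similar, green = different, black = neither; a grey diagonal marks
    perfect concordance. Highlight genes absent from the table are skipped
    with a warning.
    """
    sub = labeled[labeled["comparison"] == comparison]
    if sub.empty:
        raise ValidationError(f"comparison {comparison!r} not present in labeled table")
    points = sub[["gene_a", "gene_b", "fc_a", "fc_b", "label"]].copy()
    points["color"] = points["label"].map(_LABEL_COLORS)

    highlighted = []
    for gene in highlight or []:
        if gene in set(points["gene_a"]):
            highlighted.append(gene)
        else:
            warnings.warn(f"highlight gene {gene!r} not in scatter table; skipped")

    spec = ScatterSpec(
        comparison=comparison,
        points=points.reset_index(drop=True),
        highlighted=highlighted,
        xlabel=f"{species_labels[0]} log2 fold change ({comparison})",
        ylabel=f"{species_labels[1]} log2 fold change ({comparison})",
    )
    if out is not None:
        _render_scatter(spec, Path(out))
    return spec


def _render_scatter(spec: ScatterSpec, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    pts = spec.points
    span = float(np.abs(pts[["fc_a", "fc_b"]].to_numpy()).max() or 1.0) * 1.05
    ax.plot([-span, span], [-span, span], color="0.8", lw=0.8, zorder=0)
    for label, color in _LABEL_COLORS.items():
        sel = pts[pts["label"] == label]
        ax.scatter(sel["fc_a"], sel["fc_b"], s=8, c=color, label=label, alpha=0.7)
    lookup = pts.set_index("gene_a")
    for gene in spec.highlighted:
        row = lookup.loc[[gene]].iloc[0]
        ax.annotate(gene, (row["fc_a"], row["fc_b"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlim(-span, span)
    ax.set_ylim(-span, span)
    ax.set_xlabel(spec.xlabel)
    ax.set_ylabel(spec.ylabel)
    ax.legend(fontsize=7)
    ax.set_title(f"Cross-species fold changes: {spec.comparison}")
    _save(fig, out)


@dataclass
class ProfileSpec:
    """Stage-ordered mean log2 signals for one ortholog pair, both species."""

    gene_a: str
    gene_b: str
    stages: tuple = _PROFILE_STAGE_ORDER
    means_a: list = field(default_factory=list)
    means_b: list = field(default_factory=list)
    species_labels: tuple[str, str] = ("species A", "species B")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": list(self.stages),
                f"mean_{self.species_labels[0]}": self.means_a,
                f"mean_{self.species_labels[1]}": self.means_b,
            }
        )


def build_profile(
    gene_a: str,
    gene_b: str,
    dataset_a: ExpressionDataset,
    dataset_b: ExpressionDataset,
    out: str | Path | None = None,
) -> ProfileSpec:
    """Expression-signal profile of an ortholog pair over morula, ICM, blastocyst.

    The y values are mean log2 signals per stage (the unit is log2 of
    measured expression). Raises naming the gene and species if unmeasured.
    """
    from .foldchange import stage_means  # local import avoids cycle at module load

    for gene, ds in ((gene_a, dataset_a), (gene_b, dataset_b)):
        if gene not in ds.values.index:
            raise ValidationError(f"gene {gene!r} not measured in {ds.species_label!r}")
    means_a = stage_means(dataset_a, _PROFILE_STAGE_ORDER).loc[gene_a]
    means_b = stage_means(dataset_b, _PROFILE_STAGE_ORDER).loc[gene_b]
    spec = ProfileSpec(
        gene_a=gene_a,
        gene_b=gene_b,
        means_a=[float(means_a[s]) for s in _PROFILE_STAGE_ORDER],
        means_b=[float(means_b[s]) for s in _PROFILE_STAGE_ORDER],
        species_labels=(dataset_a.species_label, dataset_b.species_label),
    )
    if out is not None:
        _render_profile(spec, Path(out))
    return spec


def _render_profile(spec: ProfileSpec, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(4.0, 3.2))
    x = range(len(spec.stages))
    ax.plot(x, spec.means_a, "o-", color="blue", label=f"{spec.species_labels[0]} {spec.gene_a}")
    ax.plot(x, spec.means_b, "s-", color="red", label=f"{spec.species_labels[1]} {spec.gene_b}")
    ax.set_xticks(list(x), [STAGE_CODES[s] if s != "ICM" else "ICM" for s in spec.stages])
    ax.set_ylabel("log2 of measured expression")
    ax.legend(fontsize=7)
    ax.set_title(f"Expression profile: {spec.gene_a} / {spec.gene_b}")
    _save(fig, out)


def build_venn_figure(counts: VennCounts, out: str | Path) -> None:
    """Three-circle Venn drawing annotated with the exclusive region counts."""
    fig, ax = plt.subplots(figsize=(4.5, 4.0))
    centers = {0: (-0.5, 0.3), 1: (0.5, 0.3), 2: (0.0, -0.55)}
    for idx, label in enumerate(counts.labels):
        circle = plt.Circle(centers[idx], 0.85, fill=False, lw=1.4, color=f"C{idx}")
        ax.add_patch(circle)
        cx, cy = centers[idx]
        ax.text(cx * 2.0, cy * 2.0, label, ha="center", fontsize=9, color=f"C{idx}")
    positions = {
        frozenset({counts.labels[0]}): (-0.85, 0.45),
        frozenset({counts.labels[1]}): (0.85, 0.45),
        frozenset({counts.labels[2]}): (0.0, -1.0),
        frozenset({counts.labels[0], counts.labels[1]}): (0.0, 0.55),
        frozenset({counts.labels[0], counts.labels[2]}): (-0.55, -0.3),
        frozenset({counts.labels[1], counts.labels[2]}): (0.55, -0.3),
        frozenset(counts.labels): (0.0, 0.0),
    }
    for region, (x, y) in positions.items():
        ax.text(x, y, str(counts.counts[region]), ha="center", va="center", fontsize=10)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.8, 1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    _save(fig, Path(out))


def _save(fig, out: Path) -> None:
    """Write PNG and SVG next to each other for one output stem."""
    out.parent.mkdir(parents=True, exist_ok=True)
    stem = out.with_suffix("")
    for ext in (".png", ".svg"):
        fig.savefig(stem.with_suffix(ext), dpi=150, bbox_inches="tight")
    plt.close(fig)
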