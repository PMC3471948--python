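"""Synthetic two-species, three-stage expression data with planted truth.

The generator emulates the study design end to end: two species, three cell
populations (morula, blastocyst, ICM), two pooled replicate samples per
stage, RMA-scale log2 intensities. Each ortholog pair is planted in one of
four classes:

* ``null``             — no stage effects in either species;
* ``concordant``       — identical stage-effect vector in both species
                         (magnitude ``effect_size``);
* ``discordant``       — stage effects engineered so every canonical
                         comparison satisfies the "different" heuristic with
                         margin: both true |FC| ≥ ``min_abs_fc`` and the
                         inter-species FC gap ≥ ``discordant_gap``;
* ``species_specific`` — effects in one species only, flat in the other.

Expected labels are defined on the NOISE-FREE fold changes, so ground truth
is unambiguous; misclassification of noisy estimates is the measured
quantity. All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crossspecies import ClassificationParams, classify_pair
from .datamodel import (
    CANONICAL_COMPARISONS,
    ExpressionDataset,
    GeneSetCollection,
    OrthologMap,
    STAGE_CODES,
    ValidationError,
)

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate", "evaluate_recovery"]

_CLASSES = ("null", "concordant", "discordant", "species_specific")
_STAGE_ORDER = ("morula", "blastocyst", "ICM")


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults mirror the emulated study design.

    ``n_replicates=2`` matches the two pooled replicate samples per stage;
    baseline 8 ± 2 and ``noise_sd=0.15`` log2 units resemble RMA-summarized
    microarray intensities. Class fractions, ``effect_size``,
    ``discordant_gap`` and ``min_abs_fc`` (the minimum planted true |FC| of
    discordant genes) control the planted structure.
    """

    n_pairs: int = 2000
    fraction_null: float = 0.7
    fraction_concordant: float = 0.1
    fraction_discordant: float = 0.1
    fraction_species_specific: float = 0.1
    effect_size: float = 1.0
    discordant_gap: float = 1.0
    min_abs_fc: float = 0.5
    noise_sd: float = 0.15
    n_replicates: int = 2
    baseline_mean: float = 8.0
    baseline_sd: float = 2.0
    unpaired_fraction: float = 0.05
    many_to_many_fraction: float = 0.02
    seed: int = 0
    species_a: str = "mouse"
    species_b: str = "rat"

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (
            self.fraction_null,
            self.fraction_concordant,
            self.fraction_discordant,
            self.fraction_species_specific,
        )

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("class fractions must sum to 1")
        if min(self.fractions) < 0:
            raise ValidationError("class fractions must be non-negative")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if not (0 <= self.unpaired_fraction < 1):
            raise ValidationError("unpaired_fraction must be in [0, 1)")
        if self.many_to_many_fraction < 0:
            raise ValidationError("many_to_many_fraction must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted classes, noise-free fold changes, and expected labels.

    ``table`` is long-format: one row per ortholog pair per canonical
    comparison with columns ``gene_a, gene_b, class, in_map, comparison,
    true_fc_a, true_fc_b, expected_label``. ``pair_classes`` has one row per
    pair. Expected labels are ``classify_pair`` applied to the true FCs.
    """

    table: pd.DataFrame
    pair_classes: pd.DataFrame
    params: ClassificationParams = field(default_factory=ClassificationParams)

    def mapped(self) -> pd.DataFrame:
        return self.table[self.table["in_map"]].reset_index(drop=True)


def _fc_from_effects(effects: dict) -> dict:
    return {
        c.name: effects[c.numerator] - effects[c.denominator]
        for c in CANONICAL_COMPARISONS
    }


def _plant_effects(cls: str, cfg: SimulationConfig, rng: np.random.Generator):
    """Per-species stage-effect vectors (morula is the zero reference)."""
    zero = {s: 0.0 for s in _STAGE_ORDER}
    if cls == "null":
        return dict(zero), dict(zero)
    if cls == "concordant":
        s1, s2 = rng.choice([-1.0, 1.0], size=2)
        e = {"morula": 0.0, "blastocyst": s1 * cfg.effect_size, "ICM": s2 * cfg.effect_size}
        return dict(e), dict(e)
    if cls == "discordant":
        s = float(rng.choice([-1.0, 1.0]))
        m, g = cfg.min_abs_fc, cfg.discordant_gap
        e_a = {"morula": 0.0, "blastocyst": s * m, "ICM": s * 2 * m}
        e_b = {"morula": 0.0, "blastocyst": s * (m + g), "ICM": s * 2 * (m + g)}
        return e_a, e_b
    # species_specific: effect in exactly one species
    s1, s2 = rng.choice([-1.0, 1.0], size=2)
    affected_a = bool(rng.integers(0, 2))
    e = {"morula": 0.0, "blastocyst": s1 * cfg.effect_size, "ICM": s2 * cfg.effect_size}
    return (dict(e), dict(zero)) if affected_a else (dict(zero), dict(e))


def _assemble_dataset(
    species: str, gene_ids: list, effects: list, cfg: SimulationConfig,
    rng: np.random.Generator,
) -> ExpressionDataset:
    baselines = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(gene_ids))
    sample_rows = []
    for stage in _STAGE_ORDER:
        for rep in range(1, cfg.n_replicates + 1):
            sample_rows.append(
                {
                    "sample_id": f"{species}_{STAGE_CODES[stage]}{rep}",
                    "species": species,
                    "stage": stage,
                    "replicate": rep,
                }
            )
    samples = pd.DataFrame(sample_rows)
    signal = np.empty((len(gene_ids), len(sample_rows)))
    for j, row in samples.iterrows():
        stage_effect = np.array([e[row["stage"]] for e in effects])
        signal[:, j] = baselines + stage_effect
    if cfg.noise_sd > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sd, size=signal.shape)
    values = pd.DataFrame(signal, index=pd.Index(gene_ids, name="gene_id"),
                          columns=samples["sample_id"])
    return ExpressionDataset(species_label=species, values=values, samples=samples)


def simulate(
    config: SimulationConfig,
    params: ClassificationParams = ClassificationParams(),
) -> tuple[ExpressionDataset, ExpressionDataset, OrthologMap, GeneSetCollection, SyntheticTruth]:
    """Generate the full synthetic bundle for one seeded configuration.

    Returns (dataset A, dataset B, ortholog map, gene sets, truth). The
    ortholog map covers ``1 − unpaired_fraction`` of the base pairs and adds
    ``many_to_many_fraction`` extra species-A genes that duplicate an
    existing species-B partner with identical planted truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_pairs
    width = max(5, len(str(n)))

    classes = rng.choice(len(_CLASSES), size=n, p=list(cfg.fractions))
    class_names = [_CLASSES[i] for i in classes]

    genes_a = [f"{cfg.species_a[0]}gene{i:0{width}d}" for i in range(1, n + 1)]
    genes_b = [f"{cfg.species_b[0]}gene{i:0{width}d}" for i in range(1, n + 1)]
    effects_a, effects_b = [], []
    for cls in class_names:
        e_a, e_b = _plant_effects(cls, cfg, rng)
        effects_a.append(e_a)
        effects_b.append(e_b)

    # many-to-many: extra species-A genes re-linked to existing species-B partners
    n_mm = int(round(cfg.many_to_many_fraction * n))
    mm_targets = rng.choice(n, size=n_mm, replace=False) if n_mm else np.array([], dtype=int)
    mm_genes_a = [f"{cfg.species_a[0]}geneX{j:04d}" for j in range(1, n_mm + 1)]
    mm_rows = []
    for new_gene, k in zip(mm_genes_a, mm_targets):
        genes_a.append(new_gene)
        effects_a.append(dict(effects_a[k]))
        mm_rows.append((new_gene, genes_b[k], class_names[k]))

    # ortholog map drops unpaired_fraction of the base pairs (genes stay measured)
    n_unpaired = int(round(cfg.unpaired_fraction * n))
    unpaired_idx = set(
        rng.choice(n, size=n_unpaired, replace=False).tolist() if n_unpaired else []
    )
    pairs = [(genes_a[i], genes_b[i]) for i in range(n) if i not in unpaired_idx]
    pairs += [(a, b) for a, b, _ in mm_rows]
    omap = OrthologMap.from_pairs(pairs)

    dataset_a = _assemble_dataset(cfg.species_a, genes_a, effects_a, cfg, rng)
    dataset_b = _assemble_dataset(cfg.species_b, genes_b, effects_b, cfg, rng)

    truth_rows = []
    pair_rows = []

    def add_truth(gene_a, gene_b, cls, e_a, e_b, in_map):
        fcs_a = _fc_from_effects(e_a)
        fcs_b = _fc_from_effects(e_b)
        pair_rows.append({"gene_a": gene_a, "gene_b": gene_b, "class": cls, "in_map": in_map})
        for c in CANONICAL_COMPARISONS:
            fa, fb = fcs_a[c.name], fcs_b[c.name]
            truth_rows.append(
                {
                    "gene_a": gene_a,
                    "gene_b": gene_b,
                    "class": cls,
                    "in_map": in_map,
                    "comparison": c.name,
                    "true_fc_a": fa,
                    "true_fc_b": fb,
                    "expected_label": classify_pair(fa, fb, params),
                }
            )

    for i in range(n):
        add_truth(genes_a[i], genes_b[i], class_names[i], effects_a[i], effects_b[i],
                  i not in unpaired_idx)
    for j, ((new_gene, gene_b, cls), k) in enumerate(zip(mm_rows, mm_targets)):
        add_truth(new_gene, gene_b, cls, effects_a[n + j], effects_b[k], True)

    truth = SyntheticTruth(
        table=pd.DataFrame(truth_rows),
        pair_classes=pd.DataFrame(pair_rows),
        params=params,
    )
    gene_sets = _bundle_gene_sets(genes_a[:n], class_names, rng)
    return dataset_a, dataset_b, omap, gene_sets, truth


def _bundle_gene_sets(
    base_genes_a: list, class_names: list, rng: np.random.Generator
) -> GeneSetCollection:
    """Two bundled sets: one enriched in discordant genes, one random draw."""
    discordant = [g for g, c in zip(base_genes_a, class_names) if c == "discordant"]
    others = [g for g, c in zip(base_genes_a, class_names) if c != "discordant"]
    n_disc = min(30, len(discordant)) or 0
    enriched = list(rng.choice(discordant, size=n_disc, replace=False)) if n_disc else []
    enriched += list(rng.choice(others, size=min(10, len(others)), replace=False))
    if not enriched:
        enriched = base_genes_a[:1]
    n_rand = min(40, len(base_genes_a))
    random_set = list(rng.choice(base_genes_a, size=n_rand, replace=False))
    return GeneSetCollection(
        sets={"discordant_enriched": set(enriched), "random_set": set(random_set)},
        provenance={
            "discordant_enriched": "synthetic: planted-discordant genes plus background",
            "random_set": "synthetic: uniform random draw of species-A genes",
        },
    )


def evaluate_recovery(labeled: pd.DataFrame, truth: SyntheticTruth) -> dict:
    """Confusion table and per-class sensitivity/specificity of the labels.

    Aligns on (gene_a, gene_b, comparison) over the mapped truth rows; raises
    if the keys disagree. Sensitivity of class k = P(predicted k | expected
    k); specificity = P(predicted ≠ k | expected ≠ k).
    """
    key = ["gene_a", "gene_b", "comparison"]
    expected = truth.mapped()[key + ["expected_label", "class"]]
    merged = expected.merge(labeled[key + ["label"]], on=key, how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        n_bad = int((merged["_merge"] != "both").sum())
        raise ValidationError(f"label and truth tables misaligned on {n_bad} rows")
    merged = merged.drop(columns="_merge")

    labels = ("similar", "different", "neither")
    confusion = pd.crosstab(merged["expected_label"], merged["label"]).reindex(
        index=labels, columns=labels, fill_value=0
    )
    confusion.index.name = "expected"
    confusion.columns.name = "predicted"

    sensitivity, specificity = {}, {}
    total = len(merged)
    for lab in labels:
        actual = merged["expected_label"] == lab
        pred = merged["label"] == lab
        sensitivity[lab] = float((actual & pred).sum() / actual.sum()) if actual.any() else float("nan")
        negatives = total - int(actual.sum())
        specificity[lab] = (
            float((~actual & ~pred).sum() / negatives) if negatives else float("nan")
        )
    return {
        "confusion": confusion,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "accuracy": float((merged["expected_label"] == merged["label"]).mean()) if total else float("nan"),
        "n": total,
    }
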