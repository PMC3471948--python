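"""Core data types for cross-species expression comparison.

The pipeline operates on gene-level log2 expression matrices for two species
sampled at three preimplantation stages (morula, blastocyst, inner cell mass),
an ortholog translation table linking the two gene-identifier namespaces, and
gene-set collections defined on species-A identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "STAGE_CODES",
    "CANONICAL_COMPARISONS",
    "ExpressionDataset",
    "StageComparison",
    "OrthologMap",
    "GeneSetCollection",
    "FoldChangeTable",
    "ValidationError",
    "FormatError",
]

#: Closed vocabulary of developmental stages.
STAGES: tuple[str, ...] = ("morula", "blastocyst", "ICM")

#: Short codes used in comparison names and sample labels.
STAGE_CODES: dict[str, str] = {"morula": "M", "blastocyst": "B", "ICM": "ICM"}


class ValidationError(ValueError):
    """A structurally well-formed input violates a semantic invariant."""


class FormatError(ValueError):
    """An input file does not conform to the documented dialect."""


@dataclass(frozen=True)
class StageComparison:
    """A pairwise stage contrast; fold change = numerator mean − denominator mean."""

    name: str
    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        for stage in (self.numerator, self.denominator):
            if stage not in STAGES:
                raise ValidationError(f"unknown stage {stage!r}; expected one of {STAGES}")
        if self.numerator == self.denominator:
            raise ValidationError("comparison numerator and denominator must differ")

    def reversed(self) -> "StageComparison":
        code_n = STAGE_CODES[self.denominator]
        code_d = STAGE_CODES[self.numerator]
        return StageComparison(f"{code_n}_vs_{code_d}", self.denominator, self.numerator)


#: The three canonical contrasts of the study design.
CANONICAL_COMPARISONS: tuple[StageComparison, ...] = (
    StageComparison("B_vs_M", "blastocyst", "morula"),
    StageComparison("ICM_vs_B", "ICM", "blastocyst"),
    StageComparison("ICM_vs_M", "ICM", "morula"),
)


@dataclass
class ExpressionDataset:
    """One species' log2 gene × sample matrix plus stage/replicate annotations.

    Parameters
    ----------
    species_label
        Free-text species name (e.g. ``"mouse"``).
    values
        DataFrame of finite log2 intensities; index = gene identifiers,
        columns = sample identifiers.
    samples
        DataFrame with columns ``sample_id``, ``stage``, ``replicate``,
        one row per column of ``values``, in matrix column order.
    """

    species_label: str
    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        required = {"sample_id", "stage", "replicate"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        if list(self.samples["sample_id"]) != list(self.values.columns):
            raise ValidationError("sample sheet order must match matrix column order")
        bad = set(self.samples["stage"]) - set(STAGES)
        if bad:
            raise ValidationError(f"unknown stage label(s) {sorted(bad)}; expected {STAGES}")
        if (self.samples["replicate"].astype(int) < 1).any():
            raise ValidationError("replicate numbers must be positive integers")
        key = list(zip(self.samples["stage"], self.samples["replicate"]))
        if len(set(key)) != len(key):
            raise ValidationError("duplicate (stage, replicate) pair in sample sheet")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def samples_for_stage(self, stage: str) -> list[str]:
        if stage not in STAGES:
            raise ValidationError(f"unknown stage {stage!r}")
        mask = self.samples["stage"] == stage
        return list(self.samples.loc[mask, "sample_id"])

    def require_stages(self, stages=STAGES) -> None:
        """Raise if any requested stage has no samples, naming the stage."""
        for stage in stages:
            if not self.samples_for_stage(stage):
                raise ValidationError(
                    f"dataset {self.species_label!r} has no samples for stage {stage!r}"
                )


@dataclass(frozen=True)
class OrthologMap:
    """Cross-species gene-identifier pairs; many-to-many links are allowed."""

    pairs: frozenset

    @classmethod
    def from_pairs(cls, pairs) -> "OrthologMap":
        return cls(frozenset((str(a), str(b)) for a, b in pairs))

    @property
    def genes_a(self) -> set:
        return {a for a, _ in self.pairs}

    @property
    def genes_b(self) -> set:
        return {b for _, b in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)

    def one_to_one(self) -> "OrthologMap":
        """Restrict to pairs whose genes each occur exactly once in the map."""
        count_a: dict[str, int] = {}
        count_b: dict[str, int] = {}
        for a, b in self.pairs:
            count_a[a] = count_a.get(a, 0) + 1
            count_b[b] = count_b.get(b, 0) + 1
        kept = {(a, b) for a, b in self.pairs if count_a[a] == 1 and count_b[b] == 1}
        return OrthologMap(frozenset(kept))

    def partners_of_a(self, gene_a: str) -> set:
        return {b for a, b in self.pairs if a == gene_a}

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.pairs)
        return pd.DataFrame(rows, columns=["gene_a", "gene_b"])


@dataclass
class GeneSetCollection:
    """Named gene sets on the species-A identifier namespace (GMT semantics)."""

    sets: dict[str, set]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class FoldChangeTable:
    """Per-gene stage means and log2 fold changes for a set of comparisons.

    ``stage_means``: genes × stages; ``fold_changes``: genes × comparison names.
    Fold change is the difference of mean log2 signals (a log2 ratio).
    """

    species_label: str
    stage_means: pd.DataFrame
    fold_changes: pd.DataFrame
    comparisons: tuple[StageComparison, ...] = CANONICAL_COMPARISONS

    def __post_init__(self) -> None:
        if not self.stage_means.index.equals(self.fold_changes.index):
            raise ValidationError("stage_means and fold_changes must share a gene index")
        if not np.isfinite(self.fold_changes.to_numpy(dtype=float)).all():
            raise ValidationError("fold changes must be finite")
        names = {c.name for c in self.comparisons}
        if set(self.fold_changes.columns) != names:
            raise ValidationError("fold_changes columns must match comparison names")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.fold_changes.index)

    def comparison(self, name: str) -> StageComparison:
        for c in self.comparisons:
            if c.name == name:
                return c
        raise ValidationError(f"unknown comparison {name!r}")

    def to_frame(self) -> pd.DataFrame:
        """Flat table: gene_id, per-stage means, per-comparison fold changes."""
        out = pd.DataFrame(index=self.fold_changes.index)
        for stage in self.stage_means.columns:
            out[f"mean_{stage}"] = self.stage_means[stage]
        for c in self.comparisons:
            out[f"fc_{c.name}"] = self.fold_changes[c.name]
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)
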