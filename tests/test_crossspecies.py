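"""Ortholog pairing and the similar/different pattern heuristic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import crossexpr as cx
from crossexpr.crossspecies import (
    ClassificationParams,
    classify_pair,
    classify_table,
    gene_set_summary,
    label_counts,
    pair_fold_changes,
    restrict_to_gene_set,
)


def oracle_label(fa: float, fb: float, p: ClassificationParams) -> str:
    """Independent re-evaluation of the two defining inequalities."""
    similar = abs(fa - fb) < p.t_similar
    different = (
        abs(fa - fb) > p.t_different and abs(fa) > p.t_min and abs(fb) > p.t_min
    )
    if similar:
        return "similar"
    if different:
        return "different"
    return "neither"


class TestClassifyPair:
    @pytest.mark.parametrize(
        "fa, fb, expected",
        [
            (1.00, 0.95, "similar"),    # |diff| 0.05 < 0.2
            (1.0, 0.3, "different"),    # diff 0.7 > 0.4, both |fc| > 0.2
            (0.5, -0.1, "neither"),     # one species not differentially expressed
            (0.5, 0.2, "neither"),      # diff 0.3 in the (0.2, 0.4] gap
            (0.2, 0.0, "neither"),      # strict: |diff| = 0.2 is not similar
        ],
    )
    def test_reference_points(self, fa, fb, expected):
        assert classify_pair(fa, fb) == expected

    def test_boundaries_fall_to_neither(self):
        p = ClassificationParams()
        assert classify_pair(0.0, p.t_similar) == "neither"
        # gap exactly t_different with both fc above t_min: strict -> neither
        assert classify_pair(0.8, 0.4) == "neither"
        # fc exactly at t_min: strict -> neither
        assert classify_pair(0.2, 1.0) == "neither"

    def test_non_finite_rejected(self):
        with pytest.raises(cx.ValidationError):
            classify_pair(float("nan"), 0.0)

    def test_grid_matches_brute_force_oracle(self):
        p = ClassificationParams()
        grid = np.round(np.arange(-2.0, 2.0001, 0.05), 10)
        for fa in grid:
            for fb in grid:
                assert classify_pair(fa, fb, p) == oracle_label(fa, fb, p)

    @settings(max_examples=300, derandomize=True)
    @given(
        fa=st.floats(-5, 5, allow_nan=False),
        fb=st.floats(-5, 5, allow_nan=False),
    )
    def test_species_swap_symmetry(self, fa, fb):
        assert classify_pair(fa, fb) == classify_pair(fb, fa)

    def test_monotonicity_in_thresholds(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(-2, 2, size=(500, 2))
        for loose_sim, tight_sim in [(0.3, 0.2)]:
            n_loose = sum(
                classify_pair(a, b, ClassificationParams(t_similar=loose_sim, t_different=0.4)) == "similar"
                for a, b in pts
            )
            n_tight = sum(
                classify_pair(a, b, ClassificationParams(t_similar=tight_sim, t_different=0.4)) == "similar"
                for a, b in pts
            )
            assert n_loose >= n_tight
        n_low = sum(
            classify_pair(a, b, ClassificationParams(t_different=0.4)) == "different" for a, b in pts
        )
        n_high = sum(
            classify_pair(a, b, ClassificationParams(t_different=0.8)) == "different" for a, b in pts
        )
        assert n_low >= n_high

    def test_degenerate_zero_similar_threshold(self):
        p = ClassificationParams(t_similar=0.0, t_different=0.4)
        # strict inequality: even exact equality is excluded
        assert classify_pair(1.0, 1.0, p) == "neither"

    def test_default_gap_band_is_nonempty_neither(self):
        p = ClassificationParams()
        band = [(1.0, 1.0 - d) for d in (0.22, 0.25, 0.3, 0.35, 0.38)]
        assert all(classify_pair(a, b, p) == "neither" for a, b in band)


def _fc_table(species, fcs: dict) -> cx.FoldChangeTable:
    index = pd.Index(list(fcs), name="gene_id")
    frame = pd.DataFrame(
        fcs.values(), index=index, columns=["B_vs_M", "ICM_vs_B", "ICM_vs_M"]
    )
    means = pd.DataFrame(0.0, index=index, columns=["morula", "blastocyst", "ICM"])
    return cx.FoldChangeTable(species, means, frame)


class TestPairing:
    def test_single_pair_expands_to_three_comparisons(self):
        fa = _fc_table("mouse", {"mA": (1.0, 0.5, 1.5)})
        fb = _fc_table("rat", {"rA": (0.9, 0.6, 1.5)})
        paired, report = pair_fold_changes(fa, fb, cx.OrthologMap.from_pairs([("mA", "rA")]))
        assert len(paired) == 3
        assert set(paired["comparison"]) == {"B_vs_M", "ICM_vs_B", "ICM_vs_M"}
        row = paired[paired["comparison"] == "B_vs_M"].iloc[0]
        assert row["fc_a"] == pytest.approx(1.0) and row["fc_b"] == pytest.approx(0.9)
        assert report["paired"] == 1 and report["unpaired"] == 0

    def test_many_to_many_expansion(self):
        fa = _fc_table("mouse", {"mA": (1.0, 0.0, 1.0)})
        fb = _fc_table("rat", {"rA": (1.0, 0.0, 1.0), "rB": (0.0, 0.0, 0.0)})
        omap = cx.OrthologMap.from_pairs([("mA", "rA"), ("mA", "rB")])
        paired, report = pair_fold_changes(fa, fb, omap)
        assert len(paired) == 6
        assert (paired["gene_a"] == "mA").all()
        assert report["paired"] == 2

    def test_unmeasured_gene_dropped_and_reported(self):
        fa = _fc_table("mouse", {"mA": (1.0, 0.0, 1.0)})
        fb = _fc_table("rat", {"rB": (0.0, 0.0, 0.0)})
        paired, report = pair_fold_changes(fa, fb, cx.OrthologMap.from_pairs([("mA", "rA")]))
        assert paired.empty
        assert report["unpaired"] == 1


class TestClassifyTable:
    def test_empty_table_all_counts_zero(self):
        empty = pd.DataFrame(columns=["gene_a", "gene_b", "comparison", "fc_a", "fc_b"])
        labeled = classify_table(empty)
        assert labeled.empty
        assert label_counts(labeled).empty

    def test_label_conservation_and_oracle_tally(self):
        rng = np.random.default_rng(6)
        k = 400
        paired = pd.DataFrame(
            {
                "gene_a": [f"m{i}" for i in range(k)],
                "gene_b": [f"r{i}" for i in range(k)],
                "comparison": rng.choice(["B_vs_M", "ICM_vs_B", "ICM_vs_M"], size=k),
                "fc_a": rng.uniform(-2, 2, size=k),
                "fc_b": rng.uniform(-2, 2, size=k),
            }
        )
        p = ClassificationParams()
        labeled = classify_table(paired, p)
        assert len(labeled) == k
        expected = [oracle_label(a, b, p) for a, b in zip(paired["fc_a"], paired["fc_b"])]
        assert list(labeled["label"]) == expected
        counts = label_counts(labeled)
        assert counts["total"].sum() == k
        assert (counts[["similar", "different", "neither"]].sum(axis=1) == counts["total"]).all()


class TestGeneSetRestriction:
    @pytest.fixture()
    def labeled(self):
        rng = np.random.default_rng(7)
        genes = [f"m{i:03d}" for i in range(60)]
        rows = []
        for g in genes:
            for comp in ("B_vs_M", "ICM_vs_B", "ICM_vs_M"):
                rows.append((g, g.replace("m", "r"), comp,
                             rng.uniform(-2, 2), rng.uniform(-2, 2)))
        paired = pd.DataFrame(rows, columns=["gene_a", "gene_b", "comparison", "fc_a", "fc_b"])
        return classify_table(paired)

    @pytest.fixture()
    def omap(self, labeled):
        return cx.OrthologMap.from_pairs(set(zip(labeled["gene_a"], labeled["gene_b"])))

    def test_restriction_keeps_only_member_rows(self, labeled, omap):
        sub, report = restrict_to_gene_set(labeled, {"m000", "m001"}, omap)
        assert set(sub["gene_a"]) == {"m000", "m001"}
        assert report["set_size"] == 2 and report["mapped_size"] == 2

    def test_unmapped_set_yields_empty_result(self, labeled, omap):
        sub, report = restrict_to_gene_set(labeled, {"zzz"}, omap)
        assert sub.empty and report["mapped_size"] == 0

    def test_partition_union_recovers_full_table(self, labeled, omap):
        genes = sorted(set(labeled["gene_a"]))
        parts = [set(genes[:20]), set(genes[20:45]), set(genes[45:])]
        pieces = [restrict_to_gene_set(labeled, p, omap)[0] for p in parts]
        combined = pd.concat(pieces).sort_values(["gene_a", "comparison"]).reset_index(drop=True)
        full = labeled.sort_values(["gene_a", "comparison"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(combined, full)

    def test_summary_counts_match_brute_force(self, labeled, omap):
        rng = np.random.default_rng(8)
        genes = sorted(set(labeled["gene_a"]))
        sets = cx.GeneSetCollection(
            sets={
                "setA": set(rng.choice(genes, size=15, replace=False)),
                "setB": set(rng.choice(genes, size=25, replace=False)),
            }
        )
        summary = gene_set_summary(labeled, sets, omap)
        assert len(summary) == 2 * 3
        for _, row in summary.iterrows():
            sub = labeled[
                labeled["gene_a"].isin(sets.sets[row["set"]])
                & (labeled["comparison"] == row["comparison"])
            ]
            for label in ("similar", "different", "neither"):
                assert row[label] == (sub["label"] == label).sum()
            listed = row["different_genes"].split(",") if row["different_genes"] else []
            assert set(listed) == set(sub.loc[sub["label"] == "different", "gene_a"])

    def test_whole_universe_set_equals_global_counts(self, labeled, omap):
        sets = cx.GeneSetCollection(sets={"all": set(labeled["gene_a"])})
        summary = gene_set_summary(labeled, sets, omap)
        global_counts = label_counts(labeled).set_index("comparison")
        for _, row in summary.iterrows():
            for label in ("similar", "different", "neither"):
                assert row[label] == global_counts.at[row["comparison"], label]
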