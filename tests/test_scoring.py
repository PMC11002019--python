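"""Directed rank scores, signature construction, immunophenogram, overlap."""

import numpy as np
import pandas as pd
import pytest
from ayamel.expression import ExpressionMatrix
from ayamel.scoring import (
    DirectedGeneSet,
    EmptySignatureError,
    UndefinedScoreError,
    build_composite_signature,
    build_directed_signature,
    directed_rank_score,
    immunophenogram_scores,
    read_gmt,
    score_cohort,
    signature_overlap,
    stratify_by_immunogenicity,
    write_gmt,
)
from oracles import brute_force_directed_score


def matrix_from(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestDirectedGeneSet:
    def test_needs_genes_and_valid_weights(self):
        with pytest.raises(ValueError):
            DirectedGeneSet(name="x", weights={})
        with pytest.raises(ValueError):
            DirectedGeneSet(name="x", weights={"A": 2})


class TestDirectedRankScore:
    sample = {"A": 1.0, "B": 2.0, "C": 3.0}

    def test_top_gene_up_weighted(self):
        res = directed_rank_score(self.sample, DirectedGeneSet("s", {"C": +1}))
        assert res.score == 3.0
        assert res.n_used == 1

    def test_bottom_gene_down_weighted(self):
        # decreasing-abundance rank of the lowest-expressed gene is G = 3
        res = directed_rank_score(self.sample, DirectedGeneSet("s", {"A": -1}))
        assert res.score == 3.0

    def test_absent_genes_excluded_from_numerator_and_n(self):
        res = directed_rank_score(
            self.sample, DirectedGeneSet("s", {"C": +1, "A": -1, "D": +1})
        )
        assert res.score == 3.0
        assert res.n_used == 2

    def test_no_overlap_raises_with_sample_name(self):
        with pytest.raises(UndefinedScoreError, match="sm1"):
            directed_rank_score(self.sample, DirectedGeneSet("s", {"Z": +1}), sample="sm1")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            g = int(rng.integers(3, 51))
            genes = [f"g{i}" for i in range(g)]
            # integer values to exercise ties
            values = dict(zip(genes, rng.integers(0, 20, size=g).astype(float)))
            k = int(rng.integers(1, g + 1))
            chosen = rng.choice(genes, size=k, replace=False)
            weights = {x: int(rng.choice([-1, 1])) for x in chosen}
            expected, n_expected = brute_force_directed_score(values, weights)
            res = directed_rank_score(values, DirectedGeneSet("r", weights))
            assert res.score == pytest.approx(expected)
            assert res.n_used == n_expected

    def test_all_genes_up_scores_midpoint(self):
        rng = np.random.default_rng(11)
        g = 37
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=g))}
        gene_set = DirectedGeneSet("all", {k: +1 for k in values})
        assert directed_rank_score(values, gene_set).score == pytest.approx((g + 1) / 2)

    def test_sign_reversal_reflects_score(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            g = 50
            # tie-free values
            values = {f"g{i}": float(v) for i, v in enumerate(rng.permutation(g))}
            chosen = rng.choice(list(values), size=10, replace=False)
            weights = {x: int(rng.choice([-1, 1])) for x in chosen}
            flipped = {x: -w for x, w in weights.items()}
            s = directed_rank_score(values, DirectedGeneSet("a", weights)).score
            s_rev = directed_rank_score(values, DirectedGeneSet("b", flipped)).score
            assert s_rev == pytest.approx(g + 1 - s)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(13)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 5, size=30))}
        weights = {"g0": +1, "g5": -1, "g7": +1}
        cubed = {k: v**3 for k, v in values.items()}
        s1 = directed_rank_score(values, DirectedGeneSet("s", weights)).score
        s2 = directed_rank_score(cubed, DirectedGeneSet("s", weights)).score
        assert s1 == s2

    def test_raising_an_up_gene_never_decreases_score(self):
        rng = np.random.default_rng(14)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.uniform(size=20))}
        weights = {"g3": +1, "g8": -1}
        base = directed_rank_score(values, DirectedGeneSet("s", weights)).score
        for bump in (0.1, 1.0, 10.0):
            bumped = dict(values, g3=values["g3"] + bump)
            assert directed_rank_score(bumped, DirectedGeneSet("s", weights)).score >= base

    def test_normalized_variant_in_unit_interval(self):
        res = directed_rank_score(self.sample, DirectedGeneSet("s", {"C": +1}), normalized=True)
        assert res.score == pytest.approx(1.0)  # (3 - 1) / (3 - 1)

    def test_two_block_variant_sums_block_means(self):
        res = directed_rank_score(
            self.sample, DirectedGeneSet("s", {"C": +1, "A": -1}), two_block=True
        )
        assert res.score == pytest.approx(3.0 + 3.0)


class TestScoreCohort:
    def test_consistent_with_per_sample_calls(self):
        rng = np.random.default_rng(15)
        genes = [f"g{i}" for i in range(25)]
        m = matrix_from(rng.integers(0, 100, size=(25, 3)), genes, ["a", "b", "c"])
        gene_set = DirectedGeneSet("s", {"g0": +1, "g5": -1, "g9": +1})
        cohort = score_cohort(m, gene_set)
        for res in cohort:
            solo = directed_rank_score(m.counts[res.sample].astype(float), gene_set)
            assert res.score == solo.score

    def test_sample_permutation_preserves_scores(self):
        rng = np.random.default_rng(16)
        genes = [f"g{i}" for i in range(25)]
        m = matrix_from(rng.integers(0, 100, size=(25, 4)), genes, list("abcd"))
        perm = matrix_from(m.counts[["c", "a", "d", "b"]].values, genes, list("cadb"))
        gene_set = DirectedGeneSet("s", {"g1": +1, "g2": -1})
        by_sample = {r.sample: r.score for r in score_cohort(m, gene_set)}
        by_sample_perm = {r.sample: r.score for r in score_cohort(perm, gene_set)}
        assert by_sample == by_sample_perm

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            score_cohort(ExpressionMatrix(pd.DataFrame(dtype=int)), DirectedGeneSet("s", {"A": 1}))


class TestBuildSignature:
    de = pd.DataFrame(
        {
            "log2fc": [2.0, -2.0, 3.0, 0.5],
            "padj": [0.01, 0.01, 0.2, 0.04],
        },
        index=["up_gene", "down_gene", "ns_gene", "weak_up"],
    )

    def test_weights_follow_fold_change_sign(self):
        sig = build_directed_signature(self.de, alpha=0.05)
        assert sig.weights == {"up_gene": +1, "down_gene": -1, "weak_up": +1}

    def test_nonsignificant_gene_excluded(self):
        sig = build_directed_signature(self.de, alpha=0.05)
        assert "ns_gene" not in sig.weights

    def test_no_passing_gene_raises(self):
        with pytest.raises(EmptySignatureError):
            build_directed_signature(self.de, alpha=1e-6)


class TestCompositeSignature:
    def test_composite_equals_scoring_merged_signed_set(self):
        effectors = {"chemokine": ["A", "B"], "ifng": ["C"]}
        suppressive = {"tgfb": ["D"], "immunosuppression": ["E"]}
        composite = build_composite_signature(effectors, suppressive, name="IMMU")
        merged = DirectedGeneSet(
            "manual", {"A": +1, "B": +1, "C": +1, "D": -1, "E": -1}
        )
        rng = np.random.default_rng(17)
        values = {g: float(v) for g, v in zip("ABCDEFGH", rng.uniform(size=8))}
        assert (
            directed_rank_score(values, composite).score
            == directed_rank_score(values, merged).score
        )

    def test_conflicting_gene_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="both effector and suppressive"):
            composite = build_composite_signature({"e": ["A", "B"]}, {"s": ["B", "C"]})
        assert composite.weights == {"A": +1, "C": -1}


class TestImmunophenogram:
    def test_constant_gene_z_zero_and_hand_z(self):
        m = matrix_from([[0, 2], [5, 5]], ["v", "const"], ["s1", "s2"])
        profiles = immunophenogram_scores(m, {"cat": ["v"], "flat": ["const"]})
        by = {p.sample: p.category_scores for p in profiles}
        # n-1 SD of (0, 2) is sqrt(2): z = -1/sqrt(2), +1/sqrt(2)
        assert by["s1"]["cat"] == pytest.approx(-0.70710678)
        assert by["s2"]["cat"] == pytest.approx(+0.70710678)
        assert by["s1"]["flat"] == 0.0

    def test_category_mean_of_member_z_scores(self):
        rng = np.random.default_rng(18)
        m = matrix_from(rng.integers(1, 50, size=(3, 4)), ["a", "b", "c"], list("wxyz"))
        both = immunophenogram_scores(m, {"ab": ["a", "b"]})
        single = immunophenogram_scores(m, {"a": ["a"], "b": ["b"]})
        for p_both, p_single in zip(both, single):
            expected = (p_single.category_scores["a"] + p_single.category_scores["b"]) / 2
            assert p_both.category_scores["ab"] == pytest.approx(expected)

    def test_missing_category_flagged_not_raised(self):
        m = matrix_from([[1, 2]], ["a"], ["s1", "s2"])
        profiles = immunophenogram_scores(m, {"ghost": ["zz"]})
        assert np.isnan(profiles[0].category_scores["ghost"])

    def test_needs_two_samples(self):
        m = matrix_from([[1]], ["a"], ["s1"])
        with pytest.raises(ValueError):
            immunophenogram_scores(m, {"c": ["a"]})

    def test_stratification_splits_on_mean_category_score(self):
        m = matrix_from([[0, 10], [1, 9]], ["a", "b"], ["lo", "hi"])
        profiles = immunophenogram_scores(m, {"c": ["a", "b"]})
        groups = stratify_by_immunogenicity(profiles)
        assert groups == {"lo": "low", "hi": "high"}


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = DirectedGeneSet("a", {"A": 1, "B": -1})
        assert signature_overlap(a, a).fraction == 1.0
        b = DirectedGeneSet("b", {"C": 1})
        assert signature_overlap(a, b).fraction == 0.0

    def test_hand_counts(self):
        a = DirectedGeneSet("a", {g: 1 for g in "ABCD"})
        b = DirectedGeneSet("b", {"D": 1, "E": -1})
        res = signature_overlap(a, b)
        assert res.fraction == 0.25
        assert res.jaccard == pytest.approx(0.2)


class TestGmtIO:
    def test_signed_round_trip(self, tmp_path):
        sig = DirectedGeneSet("YIM", {"A": +1, "B": -1}, provenance="demo")
        path = tmp_path / "sets.gmt"
        write_gmt([sig], path)
        back = read_gmt(path)[0]
        assert back.name == "YIM"
        assert back.weights == sig.weights

    def test_plain_gmt_defaults_to_up(self, tmp_path):
        path = tmp_path / "plain.gmt"
        path.write_text("IPRES\tequal weights\tA\tB\tC\n")
        back = read_gmt(path)[0]
        assert back.weights == {"A": +1, "B": +1, "C": +1}
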