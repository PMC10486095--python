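import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genehmm import evaluation as ev
from genehmm.assign import MISSING


# ---------------------------------------------------------------------------
# AUROC

class TestAuroc:
    def test_perfect_separation(self):
        assert ev.tie_aware_auroc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_hand_worked_tied_case(self):
        assert ev.tie_aware_auroc([1, 1, 0, 0], [0.9, 0.5, 0.5, 0.1]) == \
            pytest.approx(0.875)

    def test_constant_scores_give_half(self):
        assert ev.tie_aware_auroc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3]) == \
            pytest.approx(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(),
                              st.integers(min_value=0, max_value=5)),
                    min_size=2, max_size=50))
    def test_matches_all_pairs_estimator(self, items):
        labels = np.array([l for l, _ in items])
        scores = np.array([s for _, s in items], dtype=float)
        if labels.all() or not labels.any():
            return
        pos = scores[labels]
        neg = scores[~labels]
        pairs = [(1.0 if p > n else 0.5 if p == n else 0.0)
                 for p in pos for n in neg]
        assert ev.tie_aware_auroc(labels, scores) == pytest.approx(np.mean(pairs))


# ---------------------------------------------------------------------------
# binomial comparison

class TestBinomialComparison:
    def test_all_wins_closed_form(self):
        a = np.ones(127)
        b = np.zeros(127)
        assert ev.compare_methods_binomial(a, b) == pytest.approx(2.0 ** -127)

    def test_no_wins_gives_exactly_one(self):
        assert ev.compare_methods_binomial(np.zeros(10), np.ones(10)) == 1.0

    def test_half_wins_is_above_half(self):
        a = np.r_[np.ones(5), np.zeros(5)]
        b = np.r_[np.zeros(5), np.ones(5)]
        assert ev.compare_methods_binomial(a, b) > 0.5

    def test_ties_count_against_the_first_method(self):
        p_tied = ev.compare_methods_binomial(np.ones(6), np.ones(6))
        assert p_tied == 1.0

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            ev.compare_methods_binomial([], [])


# ---------------------------------------------------------------------------
# mutual information

class TestMutualInformation:
    def test_independent_labels_have_zero_mi(self):
        x = [0, 0, 1, 1] * 10
        y = [0, 1, 0, 1] * 10
        assert ev.mutual_information(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_bijection_of_two_equiprobable_bins_is_one_bit(self):
        x = [0, 1] * 20
        y = [5, 7] * 20
        assert ev.mutual_information(x, y) == pytest.approx(1.0)

    def test_four_bins_mapped_two_to_one_is_one_bit(self):
        bins = [0, 1, 2, 3] * 10
        annot = [b // 2 for b in bins]
        assert ev.mutual_information(annot, bins) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3)),
                    min_size=2, max_size=60))
    def test_bounded_by_marginal_entropies_and_relabel_invariant(self, pairs):
        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        mi = ev.mutual_information(x, y)

        def entropy(v):
            p = np.bincount(v) / len(v)
            p = p[p > 0]
            return -(p * np.log2(p)).sum()

        assert -1e-9 <= mi <= min(entropy(x), entropy(y)) + 1e-9
        relabeled = (x + 2) % 4  # a permutation of the label alphabet
        assert ev.mutual_information(relabeled, y) == pytest.approx(mi, abs=1e-12)

    def test_per_cell_type_series(self):
        labels = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        lengths = [1000, 1000, 100_000, 100_000]
        mi = ev.mutual_information_with_length(labels, lengths)
        assert mi.iloc[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# confusion / contingency / co-assignment

def block_assignments():
    """3 cell types; first two replicates with identical assignments."""
    labels = np.array([[0, 0, 1],
                       [0, 0, 0],
                       [1, 1, 1],
                       [1, 1, 0],
                       [2, 2, 2]])
    pairs = ev.PairedCellTypes(replicate_pairs=[("a", "b")],
                               cell_types=["a", "b", "c"])
    return labels, pairs


class TestConfusionContingency:
    def test_identical_replicates_give_identity_confusion(self):
        labels, pairs = block_assignments()
        confusion, contingency, spec = ev.confusion_and_contingency(labels, pairs)
        np.testing.assert_array_equal(confusion, np.eye(3))
        assert np.nansum(np.abs(confusion.sum(axis=1) - 1)) < 1e-12

    def test_rows_are_stochastic(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(50, 6))
        pairs = ev.PairedCellTypes(replicate_pairs=[(0, 1), (2, 3)],
                                   cell_types=list(range(6)))
        confusion, contingency, _ = ev.confusion_and_contingency(labels, pairs)
        np.testing.assert_allclose(confusion.sum(axis=1), 1.0)
        np.testing.assert_allclose(contingency.sum(axis=1), 1.0)

    def test_specificity_from_printed_diagonals(self):
        # with replicate concordance 0.811 and non-replicate 0.571 the score
        # is 1 - 0.571/0.811 ~ 0.296
        assert 1 - 0.571 / 0.811 == pytest.approx(0.2959, abs=1e-4)
        labels, pairs = block_assignments()
        *_, specificity = ev.confusion_and_contingency(labels, pairs)
        assert specificity.shape == (3,)

    def test_invalid_pairs_rejected(self):
        with pytest.raises(ValueError):
            ev.PairedCellTypes(replicate_pairs=[("a", "a")], cell_types=["a"])
        with pytest.raises(ValueError):
            ev.PairedCellTypes(replicate_pairs=[("a", "z")], cell_types=["a", "b"])


class TestCoassignment:
    def test_single_component_gives_zero_matrix(self):
        labels = np.zeros((30, 3), dtype=int)
        pairs = ev.PairedCellTypes(replicate_pairs=[], cell_types=[0, 1, 2])
        enr = ev.coassignment_enrichment(labels, pairs)
        np.testing.assert_allclose(enr, 0.0, atol=1e-12)

    def test_matrix_is_symmetric(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 3, size=(80, 5))
        pairs = ev.PairedCellTypes(replicate_pairs=[(0, 1)],
                                   cell_types=list(range(5)))
        enr = ev.coassignment_enrichment(labels, pairs)
        np.testing.assert_allclose(enr, enr.T, atol=1e-12, equal_nan=True)

    def test_independent_assignments_give_near_zero_enrichment(self):
        rng = np.random.default_rng(2)
        pi = np.array([0.5, 0.3, 0.2])
        labels = rng.choice(3, size=(20_000, 5), p=pi)
        pairs = ev.PairedCellTypes(replicate_pairs=[], cell_types=list(range(5)))
        enr = ev.coassignment_enrichment(labels, pairs)
        assert np.nanmax(np.abs(enr)) < 0.1


# ---------------------------------------------------------------------------
# hypergeometric enrichment

class TestGeneSetEnrichment:
    def test_exact_small_case(self):
        # universe 10, set 5, component 4, overlap 4: p = C(5,4)C(5,0)/C(10,4)
        labels = np.array([[0]] * 4 + [[1]] * 6)
        gene_set = [0, 1, 2, 3, 4]
        results, fold, median_p = ev.gene_set_enrichment(labels, gene_set, 0)
        assert median_p == pytest.approx(5 / 210)

    def test_fold_is_proportion_over_prior(self):
        # component 0 holds 4/16 entries (prior 0.25); 3/4 of them in the set
        labels = np.array([[0]] * 4 + [[1]] * 12)
        gene_set = [0, 1, 2, 8]
        _, fold, _ = ev.gene_set_enrichment(labels, gene_set, 0)
        assert fold == pytest.approx(0.75 / 0.25)

    def test_saturated_set(self):
        labels = np.array([[0]] * 3 + [[1]] * 5)
        results, fold, median_p = ev.gene_set_enrichment(labels, list(range(8)), 0)
        assert median_p == pytest.approx(1.0)
        assert fold == pytest.approx(1.0)

    def test_set_outside_universe_rejected(self):
        labels = np.array([[0], [1]])
        with pytest.raises(ValueError):
            ev.gene_set_enrichment(labels, [99], 0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(4, 20), st.data())
    def test_matches_exhaustive_enumeration(self, N, data):
        n_set = data.draw(st.integers(1, N))
        n_comp = data.draw(st.integers(1, N))
        from scipy.stats import hypergeom
        set_ids = set(range(n_set))
        comp_genes = set(data.draw(st.permutations(range(N)))[:n_comp])
        overlap = len(set_ids & comp_genes)
        # exhaustive: over all C(N, n_comp) draws, fraction with >= overlap hits
        count = sum(1 for combo in itertools.combinations(range(N), n_comp)
                    if len(set(combo) & set_ids) >= overlap)
        exact = count / math.comb(N, n_comp)
        assert hypergeom.sf(overlap - 1, N, n_set, n_comp) == \
            pytest.approx(exact, rel=1e-9)

    def test_bonferroni_caps_at_one(self):
        assert ev.bonferroni(0.3, 10) == 1.0
        assert ev.bonferroni(0.001, 10) == pytest.approx(0.01)


class TestRandomSplitComparison:
    def make_inputs(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        labels = pd.Series(rng.integers(0, 2, 200), index=genes)
        # gene sets aligned with annotation 0
        aligned = [g for g in genes if labels[g] == 0][:60]
        gene_sets = {"aligned": aligned,
                     "noise": list(rng.choice(genes, 40, replace=False))}
        return labels, genes, gene_sets

    def test_aligned_sets_beat_random_splits(self):
        labels, genes, gene_sets = self.make_inputs()
        n_true, mean_rand = ev.random_split_enrichment_comparison(
            labels, genes, gene_sets, annotation_order=[0, 1], n_rand=20, seed=0)
        assert n_true >= 1
        assert n_true > mean_rand

    def test_seeded_reproducibility(self):
        labels, genes, gene_sets = self.make_inputs()
        a = ev.random_split_enrichment_comparison(
            labels, genes, gene_sets, annotation_order=[0, 1], n_rand=1, seed=5)
        b = ev.random_split_enrichment_comparison(
            labels, genes, gene_sets, annotation_order=[0, 1], n_rand=1, seed=5)
        assert a == b

    def test_no_signal_gives_zero_zero(self):
        genes = [f"g{i}" for i in range(40)]
        labels = pd.Series([0, 1] * 20, index=genes)
        gene_sets = {"tiny": genes[:2]}
        n_true, mean_rand = ev.random_split_enrichment_comparison(
            labels, genes, gene_sets, annotation_order=[0, 1], n_rand=5, seed=1)
        assert (n_true, mean_rand) == (0, 0.0)


# ---------------------------------------------------------------------------
# permutation test

class TestVariancePermutation:
    def test_all_equal_medians_give_p_one(self):
        res = ev.variance_permutation_test(np.full((3, 4), 2.5), n_perm=200, seed=0)
        assert res.p_value == 1.0

    def test_disjoint_ranges_below_resolution(self):
        vals = np.array([[0.0, 0.01, 0.02, 0.03],
                         [10.0, 10.01, 10.02, 10.03],
                         [20.0, 20.01, 20.02, 20.03]])
        res = ev.variance_permutation_test(vals, n_perm=500, seed=0)
        assert res.below_resolution
        assert "<" in str(res)

    def test_calibrated_under_exchangeability(self):
        rng = np.random.default_rng(7)
        pvals = [ev.variance_permutation_test(rng.normal(size=(3, 5)),
                                              n_perm=60, seed=s).p_value
                 for s in range(120)]
        # roughly uniform: mean near 1/2, mass spread over [0, 1]
        assert 0.4 < np.mean(pvals) < 0.6
        assert np.mean(np.array(pvals) < 0.25) == pytest.approx(0.25, abs=0.12)


# ---------------------------------------------------------------------------
# expression analyses

class TestExpressionPrediction:
    def make_case(self):
        genes = [f"g{i}" for i in range(40)]
        chroms = pd.Series(["chr1"] * 20 + ["chr2"] * 20, index=genes)
        labels = np.array([[0]] * 10 + [[1]] * 10 + [[0]] * 10 + [[1]] * 10)
        rpkm = np.where(labels[:, 0] == 0, 0.01, 50.0)
        expr = pd.DataFrame({"ct0": rpkm}, index=genes)
        return labels, expr, chroms

    def test_perfectly_separating_annotations_reach_auroc_one(self):
        labels, expr, chroms = self.make_case()
        perf = ev.expression_prediction_eval(labels, expr, chroms)
        assert perf.loc["ct0", "auroc"] == 1.0
        assert perf.loc["ct0", "mse"] < 0.1
        assert perf.loc["ct0", "pearson_r"] > 0.99

    def test_constant_predictions_fall_back_gracefully(self):
        genes = [f"g{i}" for i in range(20)]
        chroms = pd.Series(["chr1"] * 10 + ["chr2"] * 10, index=genes)
        labels = np.zeros((20, 1), dtype=int)
        # identical expression multisets per chromosome: the single
        # annotation's training median is the same in both folds, so the
        # prediction is exactly constant
        vals = [0.2, 0.5, 2.0, 5.0, 9.0] * 2
        expr = pd.DataFrame({"ct0": vals + vals}, index=genes)
        perf = ev.expression_prediction_eval(labels, expr, chroms)
        assert perf.loc["ct0", "auroc"] == pytest.approx(0.5)
        assert perf.loc["ct0", "pearson_r"] == 0.0

    def test_single_chromosome_rejected(self):
        genes = ["a", "b"]
        chroms = pd.Series(["chr1", "chr1"], index=genes)
        expr = pd.DataFrame({"ct0": [1.0, 2.0]}, index=genes)
        with pytest.raises(ValueError):
            ev.expression_prediction_eval(np.zeros((2, 1), int), expr, chroms)


class TestExpressionChangeMatrix:
    def test_identical_expression_gives_zero_matrix(self):
        labels = np.array([[0, 1], [1, 0], [0, 0]])
        expr = pd.DataFrame({"c1": [1.0, 2.0, 3.0], "c2": [1.0, 2.0, 3.0]},
                            index=["a", "b", "c"])
        mat = ev.expression_change_matrix(labels, expr)
        assert np.nanmax(np.abs(mat)) == 0.0

    def test_hand_computed_two_gene_case(self):
        labels = np.array([[0, 1], [1, 0]])
        expr = pd.DataFrame({"c1": [0.9, 1.9], "c2": [3.9, 0.9]},
                            index=["a", "b"])
        mat = ev.expression_change_matrix(labels, expr)
        # bin (0, 1) pools gene a's c1->c2 ratio log2(4/1) = 2 and gene b's
        # c2->c1 ratio log2(2/1) = 1; bin (1, 0) holds their negatives
        assert mat[0, 1] == pytest.approx(1.5)
        assert mat[1, 0] == pytest.approx(-1.5)
        # antisymmetric under swapping cell types together with bin indices
        np.testing.assert_allclose(mat, -mat.T, equal_nan=True)


class TestPli:
    def test_overall_proportion_counts(self):
        labels = np.array([[0], [0], [0]])
        pli = pd.Series([0.95, 0.2, 0.99], index=["a", "b", "c"])
        lengths = pd.Series([5000, 5000, 5000], index=["a", "b", "c"])
        expr = pd.DataFrame({"c1": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        res = ev.pli_analysis(labels, pli, lengths, expr)
        assert res.high_pli_proportion[0] == pytest.approx(2 / 3)

    def test_length_normalized_proportion_dot_product(self):
        # 2 active bins with proportions (0.5, 0.1), density (0.4, 0.6) -> 0.26
        prop = np.array([0.5, 0.1])
        density = np.array([0.4, 0.6])
        assert float(prop @ density) == pytest.approx(0.26)
        # uniform per-bin proportions reduce to that proportion
        res_prop = np.full(15, 0.3)
        density15 = np.random.default_rng(0).dirichlet(np.ones(15))
        assert float(res_prop @ density15) == pytest.approx(0.3)

    def test_uniform_proportions_are_fixed_point_of_normalization(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(300)]
        pli = pd.Series(rng.uniform(0, 1, 300), index=genes)
        lengths = pd.Series(10 ** rng.uniform(3.1, 5.9, 300), index=genes)
        expr = pd.DataFrame({"c1": 10 ** rng.uniform(-1, 2, 300)}, index=genes)
        labels = np.zeros((300, 1), dtype=int)
        res = ev.pli_analysis(labels, pli, lengths, expr)
        # single annotation: normalized proportion must equal plain proportion
        assert res.length_normalized_proportion[0] == \
            pytest.approx(res.high_pli_proportion[0], abs=0.05)
        assert -1 <= res.spearman_by_cell_type.iloc[0] <= 1

    def test_invalid_pli_rejected(self):
        labels = np.zeros((2, 1), dtype=int)
        pli = pd.Series([1.5, 0.2], index=["a", "b"])
        lengths = pd.Series([5000, 5000], index=["a", "b"])
        expr = pd.DataFrame({"c1": [1.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            ev.pli_analysis(labels, pli, lengths, expr)


# ---------------------------------------------------------------------------
# hyperparameters & distances

class TestHyperparameterMetrics:
    def test_identical_replicates_reproducibility_100(self, rng):
        from conftest import random_mixture
        labels = np.tile(rng.integers(0, 3, size=(30, 1)), (1, 2))
        pairs = ev.PairedCellTypes(replicate_pairs=[(0, 1)], cell_types=[0, 1])
        model = random_mixture(3, 2, 4, rng)
        df = ev.hyperparameter_metrics({(3, 2): model}, {(3, 2): labels}, pairs)
        assert df.loc[(3, 2), "reproducibility"] == 1.0

    def test_closest_state_distance_examples(self, rng):
        from genehmm.model import GeneMixtureModel
        emit = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        model = GeneMixtureModel(tau=np.array([[0.5, 0.5]]),
                                 trans=np.full((1, 2, 2), 0.475),
                                 emit=emit, exit_prob=np.full((1, 2), 0.05))
        assert ev.closest_state_distance(model) == pytest.approx(2.0)

    def test_min_over_state_pairs(self):
        from genehmm.model import GeneMixtureModel
        emit = np.array([[[0.0, 0.0], [0.3, 0.0], [0.9, 0.3]]])
        tau = np.full((1, 3), 1 / 3)
        model = GeneMixtureModel(tau=tau, trans=np.full((1, 3, 3), 0.95 / 3),
                                 emit=emit, exit_prob=np.full((1, 3), 0.05))
        assert ev.closest_state_distance(model) == pytest.approx(0.3)

    def test_single_state_distance_missing(self, rng):
        from conftest import random_mixture
        model = random_mixture(2, 1, 3, rng)
        assert np.isnan(ev.closest_state_distance(model))


class TestAssignmentDistances:
    def test_identical_and_discordant_rows(self):
        labels = np.array([[0, 1, 2], [0, 1, 2], [1, 2, 0]])
        d, idx = ev.assignment_distance_matrix(labels, n_sample=3, seed=0)
        from scipy.spatial.distance import squareform
        D = squareform(d)
        assert D[0, 1] == 0.0
        assert D[0, 2] == 1.0
        np.testing.assert_allclose(D, D.T)
        np.testing.assert_array_equal(np.diag(D), 0.0)

    def test_clustering_returns_a_leaf_order(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=(40, 6))
        d, idx = ev.assignment_distance_matrix(labels, n_sample=20, seed=1)
        order = ev.cluster_assignment_rows(d)
        assert sorted(order) == list(range(20))
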