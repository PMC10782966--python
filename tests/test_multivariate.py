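"""Clustering, PLS-DA, ROC AUC and the MCCV biomarker procedure."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from lipidome.multivariate import plsda, rf_biomarker_mccv, roc_auc, ward_cluster
from lipidome.preprocess import IntensityMatrix, log2_median_normalize
from lipidome.synthetic import simulate_two_group


def _logm(values, meta=None):
    df = pd.DataFrame(
        values,
        index=pd.Index([f"PG(16:{i}/18:1)" for i in range(values.shape[0])]),
        columns=[f"s{j}" for j in range(values.shape[1])],
    )
    return IntensityMatrix(
        df, pd.Series("negative", index=df.index), sample_meta=meta,
        state="log2_median",
    )


def brute_force_ward_d2(points):
    """Exhaustive Ward.D2 agglomeration (Lance-Williams on squared d)."""
    points = [np.asarray(p, dtype=float) for p in points]
    n = len(points)
    d2 = {
        frozenset((i, j)): float(((points[i] - points[j]) ** 2).sum())
        for i, j in itertools.combinations(range(n), 2)
    }
    sizes = {i: 1 for i in range(n)}
    active = set(range(n))
    heights = []
    next_id = n
    while len(active) > 1:
        (i, j) = min(
            (pair for pair in d2 if pair <= active), key=lambda p: d2[p]
        )
        i, j = sorted(i for i in (i, j))
        heights.append(np.sqrt(d2[frozenset((i, j))]))
        ni, nj, dij = sizes[i], sizes[j], d2[frozenset((i, j))]
        for k in active - {i, j}:
            nk = sizes[k]
            dik = d2[frozenset((i, k))]
            djk = d2[frozenset((j, k))]
            d2[frozenset((next_id, k))] = (
                (ni + nk) * dik + (nj + nk) * djk - nk * dij
            ) / (ni + nj + nk)
        sizes[next_id] = ni + nj
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return heights


class TestWardCluster:
    def test_two_samples_merge_at_their_euclidean_distance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 2))
        result = ward_cluster(_logm(x))
        expected = float(np.linalg.norm(x[:, 0] - x[:, 1]))
        assert result.heights == [pytest.approx(expected)]

    def test_heights_match_brute_force_on_six_samples(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(8, 6))  # 6 samples, 8 lipids
        result = ward_cluster(_logm(x))
        expected = brute_force_ward_d2(list(x.T))
        assert result.heights == pytest.approx(expected)

    def test_three_separated_groups_recovered_exactly(self):
        rng = np.random.default_rng(2)
        shift = np.repeat([0.0, 10.0, 20.0], 4)
        x = rng.normal(scale=1.0, size=(20, 12)) + shift
        result = ward_cluster(_logm(x))
        assignment = result.cut(3)
        found = [assignment[f"s{j}"] for j in range(12)]
        assert adjusted_rand_score(np.repeat([0, 1, 2], 4), found) == 1.0

    def test_heights_monotone_and_row_order_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10, 7))
        result = ward_cluster(_logm(x))
        assert all(a <= b for a, b in zip(result.heights, result.heights[1:]))
        shuffled = ward_cluster(_logm(x[::-1]))
        assert shuffled.heights == pytest.approx(result.heights)

    def test_newick_contains_all_samples(self):
        rng = np.random.default_rng(4)
        result = ward_cluster(_logm(rng.normal(size=(5, 4))))
        newick = result.to_newick()
        assert newick.endswith(";")
        assert all(f"s{j}" in newick for j in range(4))


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([1.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=10)
        scores[3] = scores[7]  # force a tie across classes
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1, 0, 1])
        total = 0.0
        for sp in scores[labels == 1]:
            for sn in scores[labels == 0]:
                total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        expected = total / (labels.sum() * (1 - labels).sum())
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_antisymmetry_under_score_negation(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=12)
        labels = rng.integers(0, 2, size=12)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(1 - roc_auc(-scores, labels))

    def test_single_class_is_error(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])


@pytest.fixture(scope="module")
def separable(catalog194):
    matrix, truth = simulate_two_group(
        n_lipids=120, n_per_group=9, planted_lipids=30,
        delta_log2=2.0, sigma=0.5, seed=21, catalog=catalog194[:120],
    )
    return log2_median_normalize(matrix), matrix.sample_meta["group"], truth


class TestPLSDA:
    def test_separable_classes_classified_and_predictive(self, separable):
        logm, labels, _ = separable
        report = plsda(logm, labels)
        assert report.n_components == 2
        assert report.accuracy >= 0.95
        assert report.q2 >= 0.8

    def test_q2_never_exceeds_r2(self, separable):
        logm, labels, _ = separable
        report = plsda(logm, labels)
        assert report.q2 <= report.r2 <= 1.0

    def test_permuted_labels_lose_predictivity(self, separable):
        logm, labels, _ = separable
        rng = np.random.default_rng(7)
        low = 0
        n_perm = 20
        for _ in range(n_perm):
            perm = pd.Series(
                rng.permutation(labels.to_numpy()), index=labels.index
            )
            if plsda(logm, perm).q2 <= 0.2:
                low += 1
        assert low >= int(0.9 * n_perm)

    def test_single_class_is_error(self, separable):
        logm, labels, _ = separable
        with pytest.raises(ValueError, match="2 classes"):
            plsda(logm, pd.Series("A", index=labels.index))


@pytest.fixture(scope="module")
def biomarker_data(catalog194):
    matrix, truth = simulate_two_group(
        n_lipids=194, n_per_group=18, planted_lipids=15,
        delta_log2=3.0, sigma=0.5, seed=11, catalog=catalog194,
    )
    return log2_median_normalize(matrix), matrix.sample_meta["group"], truth


class TestBiomarkerMCCV:
    def test_planted_lipids_dominate_ranking_with_high_auc(self, biomarker_data):
        logm, labels, truth = biomarker_data
        report = rf_biomarker_mccv(
            logm, labels, panel_sizes=(15,), n_rounds=15, seed=3, n_trees=150
        )
        top15 = set(report.ranking["lipid"].head(15))
        assert len(top15 & set(truth.planted_lipids)) >= 12
        assert report.panel_auc[15][0] >= 0.95
        assert 0.0 <= report.accuracy <= 1.0
        assert set(report.selected_panel) == top15

    def test_fixed_seed_reproduces_bit_identical_results(self, biomarker_data):
        logm, labels, _ = biomarker_data
        kwargs = dict(panel_sizes=(5,), panel_size=5, n_rounds=10, seed=8, n_trees=60)
        a = rf_biomarker_mccv(logm, labels, **kwargs)
        b = rf_biomarker_mccv(logm, labels, **kwargs)
        assert list(a.ranking["lipid"]) == list(b.ranking["lipid"])
        assert a.panel_auc == b.panel_auc
        assert a.full_model_auc == b.full_model_auc

    def test_ranking_stable_across_seeds(self, biomarker_data):
        logm, labels, _ = biomarker_data
        r1 = rf_biomarker_mccv(
            logm, labels, panel_sizes=(5,), panel_size=5,
            n_rounds=25, seed=1, n_trees=200,
        )
        r2 = rf_biomarker_mccv(
            logm, labels, panel_sizes=(5,), panel_size=5,
            n_rounds=25, seed=2, n_trees=200,
        )
        top30 = list(r1.ranking["lipid"].head(30))
        rank2 = {l: i for i, l in enumerate(r2.ranking["lipid"])}
        rho, _ = spearmanr(range(30), [rank2[l] for l in top30])
        assert rho >= 0.8

    def test_small_class_is_error_and_few_rounds_warn(self, biomarker_data):
        logm, labels, _ = biomarker_data
        tiny = labels.copy()
        tiny.iloc[:-2] = "A"
        with pytest.raises(ValueError, match="at least 3"):
            rf_biomarker_mccv(logm, tiny, n_rounds=10, seed=0)
        with pytest.warns(UserWarning, match="unstable"):
            rf_biomarker_mccv(
                logm, labels, panel_sizes=(3,), panel_size=3,
                n_rounds=4, seed=0, n_trees=20,
            )
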