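"""Error-correlation matrix, thresholded graph and cluster extraction."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from crowdcal.error_metrics import compute_metrics
from crowdcal.error_network import (
    build_graph,
    cluster_foods,
    error_correlation_matrix,
)
from crowdcal.quiz_model import Response
from crowdcal.synthetic_cohort import (
    SimulationConfig,
    perturb_duplicate_foods,
    simulate_block_cohort,
    simulate_cohort,
)


@pytest.fixture(scope="module")
def independent_noise_metrics(quiz):
    """Cohort whose errors are independent across foods (no shared
    participant or food intercepts)."""
    config = SimulationConfig(
        n_participants=150, n_experts=0, seed=33, sigma_noise=0.3,
        sd_participant=0.0, sd_food=0.0, p_invalid_bmi=0.0, p_missing_gender=0.0,
    )
    _, responses = simulate_cohort(quiz, config)
    return compute_metrics(responses, quiz)


class TestCorrelationMatrix:
    def test_symmetric_unit_diagonal_bounded(self, quiz, clean_metrics):
        corr = error_correlation_matrix(clean_metrics)
        vals = corr.to_numpy()
        assert np.allclose(vals, vals.T, equal_nan=True)
        assert np.allclose(np.diag(vals), 1.0)
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= -1.0 - 1e-12 and finite.max() <= 1.0 + 1e-12

    def test_duplicated_food_column_correlates_at_one(self, quiz, clean_cohort):
        _, responses = clean_cohort
        quiz2, responses2 = perturb_duplicate_foods(
            quiz, responses, "kiwi", copies=1, noise_sd=0.0
        )
        corr = error_correlation_matrix(compute_metrics(responses2, quiz2))
        assert corr.loc["kiwi", "kiwi__dup1"] == pytest.approx(1.0)

    def test_independent_noise_gives_small_correlations(self, independent_noise_metrics):
        """Null sampling bound: most |r| under 2/sqrt(n_participants)."""
        corr = error_correlation_matrix(independent_noise_metrics)
        n = independent_noise_metrics["participant_id"].nunique()
        off = corr.to_numpy()[np.triu_indices(len(corr), k=1)]
        frac_large = np.mean(np.abs(off) > 2 / np.sqrt(n))
        assert frac_large < 0.10

    def test_pairs_with_few_common_participants_are_missing(self, quiz):
        # p1,p2 answer kiwi+avocado; only p1 answers broccoli
        responses = [
            Response("p1", "kiwi", 100), Response("p1", "avocado", 120),
            Response("p1", "broccoli", 90),
            Response("p2", "kiwi", 110), Response("p2", "avocado", 130),
        ]
        corr = error_correlation_matrix(compute_metrics(responses, quiz))
        assert np.isnan(corr.loc["kiwi", "broccoli"])
        graph = build_graph(corr.fillna(np.nan), threshold=0.3)
        assert all("broccoli" not in (a, b) for a, b, _, _ in graph.edges)

    def test_invariant_to_participant_ordering(self, quiz, clean_cohort):
        _, responses = clean_cohort
        shuffled = list(responses)
        np.random.default_rng(1).shuffle(shuffled)
        a = error_correlation_matrix(compute_metrics(responses, quiz))
        b = error_correlation_matrix(compute_metrics(shuffled, quiz))
        pd.testing.assert_frame_equal(a, b)


class TestBuildGraph:
    def test_unreachable_threshold_gives_empty_graph(self, quiz, clean_metrics):
        corr = error_correlation_matrix(clean_metrics)
        graph = build_graph(corr, threshold=0.999)
        assert graph.edges == []
        assert len(graph.nodes) == 20

    def test_low_threshold_on_all_positive_matrix_is_complete(self, quiz):
        _, responses, _ = simulate_block_cohort(
            quiz, n_participants=150, n_blocks=1, block_sd=0.4, sigma_noise=0.1, seed=2
        )
        corr = error_correlation_matrix(compute_metrics(responses, quiz))
        graph = build_graph(corr, threshold=0.05)
        assert len(graph.edges) == 20 * 19 // 2

    def test_negative_correlations_never_edges(self):
        m = pd.DataFrame(
            [[1.0, -0.9], [-0.9, 1.0]], index=["a", "b"], columns=["a", "b"]
        )
        assert build_graph(m, threshold=0.3).edges == []

    def test_distance_is_one_minus_correlation(self, quiz, clean_metrics):
        corr = error_correlation_matrix(clean_metrics)
        graph = build_graph(corr, threshold=0.05)
        for a, b, r, d in graph.edges:
            assert d == pytest.approx(1.0 - r)
            assert r >= 0.05

    def test_threshold_out_of_range_rejected(self, clean_metrics):
        corr = error_correlation_matrix(clean_metrics)
        with pytest.raises(ValueError):
            build_graph(corr, threshold=1.5)


class TestClusterFoods:
    def test_two_disjoint_perfect_pairs_make_two_clusters(self):
        m = pd.DataFrame(
            [
                [1.0, 1.0, 0.0, 0.0],
                [1.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 1.0],
                [0.0, 0.0, 1.0, 1.0],
            ],
            index=list("abcd"),
            columns=list("abcd"),
        )
        labels = cluster_foods(m)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]
        assert len(set(labels.values())) == 2

    def test_single_food_is_singleton_cluster(self):
        m = pd.DataFrame([[1.0]], index=["only"], columns=["only"])
        assert cluster_foods(m) == {"only": 0}

    def test_all_missing_matrix_gives_all_singletons(self):
        m = pd.DataFrame(np.nan, index=list("abc"), columns=list("abc"))
        np.fill_diagonal(m.values, 1.0)
        labels = cluster_foods(m)
        assert len(set(labels.values())) == 3

    def test_planted_three_blocks_recovered(self, quiz):
        _, responses, planted = simulate_block_cohort(
            quiz, n_participants=200, n_blocks=3, block_sd=0.3, sigma_noise=0.15, seed=17
        )
        corr = error_correlation_matrix(compute_metrics(responses, quiz))
        labels = cluster_foods(corr)
        ari = adjusted_rand_score(
            [planted[f] for f in quiz.food_ids], [labels[f] for f in quiz.food_ids]
        )
        assert ari > 0.9

    def test_duplicate_family_clusters_together(self, quiz):
        config = SimulationConfig(
            n_participants=150, n_experts=0, seed=34, sigma_noise=0.3,
            sd_participant=0.0, sd_food=0.0, p_invalid_bmi=0.0, p_missing_gender=0.0,
        )
        _, responses = simulate_cohort(quiz, config)
        quiz2, responses2 = perturb_duplicate_foods(
            quiz, responses, "salami", copies=3, noise_sd=0.05
        )
        corr = error_correlation_matrix(compute_metrics(responses2, quiz2))
        labels = cluster_foods(corr)
        family = ["salami", "salami__dup1", "salami__dup2", "salami__dup3"]
        assert len({labels[f] for f in family}) == 1
        others = [f for f in labels if f not in family]
        assert all(labels[f] != labels["salami"] for f in others)


class TestGraphExport:
    def test_graphml_and_json_round_trip(self, tmp_path, quiz, clean_metrics):
        import json
        import networkx as nx

        corr = error_correlation_matrix(clean_metrics)
        graph = build_graph(corr, threshold=0.05)
        graph.clusters = cluster_foods(corr)
        gpath = tmp_path / "net.graphml"
        graph.write_graphml(gpath)
        loaded = nx.read_graphml(gpath)
        assert set(loaded.nodes) == set(graph.nodes)
        assert loaded.number_of_edges() == len(graph.edges)
        cpath = tmp_path / "clusters.json"
        graph.write_clusters_json(cpath)
        assert json.loads(cpath.read_text()) == {k: int(v) for k, v in graph.clusters.items()}
        edges = graph.edge_frame()
        assert list(edges.columns) == ["source", "target", "correlation", "distance"]
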