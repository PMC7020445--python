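"""Clustering, boundary naming/derivation, classification, subsampled
profiles and the condition comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from fluopop import (
    ClassBoundaries,
    classify_cell,
    classify_table,
    cluster_features,
    compare_conditions,
    derive_boundaries,
    name_clusters,
    subsample_profiles,
    summarize_profiles,
)
from fluopop.population import CLASS_ORDER, ActivityClass, _profile_from_classes


class TestClassifyCell:
    @pytest.mark.parametrize(
        "count,ca_max,expected",
        [
            (7, 1.2, ActivityClass.HYPERACTIVE),
            (3, 0.8, ActivityClass.MODERATE),
            (2, 0.3, ActivityClass.LOW),
            (0, 0.1, ActivityClass.SILENT),
            (6, 0.4, ActivityClass.LOW),   # boundary: 6 spikes is not hyperactive
            (0, 0.9, ActivityClass.SILENT),  # amplitude without spiking stays silent
        ],
    )
    def test_boundary_rules(self, count, ca_max, expected):
        assert classify_cell(count, ca_max) is expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_cell(-1, 0.5)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        count=st.integers(min_value=0, max_value=40),
        ca_max=st.floats(min_value=0, max_value=5, allow_nan=False),
    )
    def test_classification_is_total(self, count, ca_max):
        assert classify_cell(count, ca_max) in ActivityClass


class TestClusterFeatures:
    def test_separated_blobs_recovered_exactly(self, blob_features):
        feats, labels = blob_features
        model = cluster_features(feats, k=4, seed=0)
        ari = adjusted_rand_score([c.value for c in labels], model.assignments)
        assert ari == 1.0

    def test_identical_points_reduce_k(self):
        feats = pd.DataFrame(
            {"cell_id": range(10), "spike_count": [2] * 10, "ca_max": [0.5] * 10}
        )
        model = cluster_features(feats, k=4, seed=0)
        assert model.k == 1
        assert np.allclose(model.centroids[0], [2, 0.5])

    def test_deterministic_given_seed(self, blob_features):
        feats, _ = blob_features
        a = cluster_features(feats, k=4, seed=5)
        b = cluster_features(feats, k=4, seed=5)
        assert np.array_equal(a.assignments, b.assignments)
        assert np.allclose(a.centroids, b.centroids)


class TestNameClusters:
    def _model_with_centroids(self, centroids):
        from fluopop.population import ClusterModel

        c = np.asarray(centroids, dtype=float)
        return ClusterModel(
            k=len(c), centroids=c,
            scaling=((0.0, 10.0), (0.0, 1.5)),
            assignments=np.arange(len(c)), cell_ids=list(range(len(c))),
            inertia=0.0, seed=0, n_restarts=1,
        )

    def test_canonical_centroids(self):
        model = self._model_with_centroids([(9, 1.3), (3, 0.9), (2, 0.2), (0, 0.05)])
        named = name_clusters(model)
        assert [named[i] for i in range(4)] == [
            ActivityClass.HYPERACTIVE, ActivityClass.MODERATE,
            ActivityClass.LOW, ActivityClass.SILENT,
        ]

    def test_all_hyperactive_centroids_allowed(self, caplog):
        model = self._model_with_centroids([(8, 1.0), (9, 1.1), (12, 0.9), (20, 1.4)])
        named = name_clusters(model)
        assert all(c is ActivityClass.HYPERACTIVE for c in named.values())

    def test_blob_fixture_names_match_generating_classes(self, blob_features):
        feats, labels = blob_features
        model = cluster_features(feats, k=4, seed=1)
        named = name_clusters(model)
        agree = np.mean(
            [named[a] is c for a, c in zip(model.assignments, labels)]
        )
        assert agree == 1.0


class TestDeriveBoundaries:
    def test_midpoint_between_moderate_and_hyperactive(self, blob_features):
        feats, labels = blob_features
        model = cluster_features(feats, k=4, seed=1)
        named = name_clusters(model)
        b = derive_boundaries(model, named, features=feats)
        counts = feats["spike_count"].to_numpy()
        mod_max = max(c for c, l in zip(counts, labels) if l is ActivityClass.MODERATE)
        hyp_min = min(c for c, l in zip(counts, labels) if l is ActivityClass.HYPERACTIVE)
        assert b.spike_thr == pytest.approx((mod_max + hyp_min) / 2)

    def test_missing_class_falls_back_to_defaults(self):
        from fluopop.population import ClusterModel

        model = ClusterModel(
            k=2, centroids=np.array([[2.0, 0.2], [0.0, 0.05]]),
            scaling=((0.0, 5.0), (0.0, 1.0)), assignments=np.array([0, 1]),
            cell_ids=[1, 2], inertia=0.0, seed=0, n_restarts=1,
        )
        named = name_clusters(model)
        b = derive_boundaries(model, named)
        assert b.spike_thr == 6.0
        assert b.amp_thr == 0.5

    def test_boundary_classification_consistent_with_clustering(self, blob_features):
        feats, _ = blob_features
        model = cluster_features(feats, k=4, seed=2)
        named = name_clusters(model)
        b = derive_boundaries(model, named, features=feats)
        via_boundaries = classify_table(feats, b)
        via_clusters = [named[a] for a in model.assignments]
        agree = np.mean([x is y for x, y in zip(via_boundaries, via_clusters)])
        assert agree >= 0.95


class TestSubsampleProfiles:
    def test_homogeneous_population(self):
        feats = pd.DataFrame(
            {"cell_id": range(30), "spike_count": [10] * 30, "ca_max": [1.0] * 30,
             "condition": "x"}
        )
        profiles = subsample_profiles(feats, sample_size=20, n_repeats=5, seed=0)
        for p in profiles:
            assert p.percent[ActivityClass.HYPERACTIVE] == 100.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_percentages_sum_to_100(self, separated_processed, seed):
        profiles = subsample_profiles(
            separated_processed.features, sample_size=90, n_repeats=5, seed=seed
        )
        for p in profiles:
            assert sum(p.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_subsample_mean_matches_full_population(self, separated_processed):
        """Resampling consistency: over many draws the mean profile equals
        the full-population profile within 3 SE."""
        feats = separated_processed.features
        full = _profile_from_classes(
            list(classify_table(feats)), "full", "control"
        )
        profiles = subsample_profiles(feats, sample_size=90, n_repeats=200, seed=3)
        for cls in CLASS_ORDER:
            vals = np.array([p.percent[cls] for p in profiles])
            se = vals.std(ddof=1) / np.sqrt(len(vals))
            assert abs(vals.mean() - full.percent[cls]) <= max(3 * se, 0.5)

    def test_sample_larger_than_population_rejected(self):
        feats = pd.DataFrame(
            {"cell_id": [1, 2], "spike_count": [1, 2], "ca_max": [0.3, 0.4]}
        )
        with pytest.raises(ValueError):
            subsample_profiles(feats, sample_size=5)

    def test_summary_has_mean_and_sem(self, separated_processed):
        profiles = subsample_profiles(
            separated_processed.features, sample_size=90, n_repeats=5, seed=0
        )
        summary = summarize_profiles(profiles)
        assert set(summary["class"]) == {c.value for c in CLASS_ORDER}
        assert (summary["sem_pct"] >= 0).all()


class TestCompareConditions:
    def test_identical_profile_sets_not_significant(self):
        pcts = [
            {ActivityClass.HYPERACTIVE: 10.0, ActivityClass.MODERATE: 30.0,
             ActivityClass.LOW: 40.0, ActivityClass.SILENT: 20.0},
            {ActivityClass.HYPERACTIVE: 12.0, ActivityClass.MODERATE: 28.0,
             ActivityClass.LOW: 40.0, ActivityClass.SILENT: 20.0},
        ]
        from fluopop.population import SubpopulationProfile

        a = [SubpopulationProfile(f"a{i}", "a", p) for i, p in enumerate(pcts)]
        b = [SubpopulationProfile(f"b{i}", "b", p) for i, p in enumerate(pcts)]
        h, p = compare_conditions({"a": a, "b": b}, ActivityClass.HYPERACTIVE)
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_single_profile_condition_rejected(self):
        from fluopop.population import SubpopulationProfile

        pct = {ActivityClass.HYPERACTIVE: 100.0, ActivityClass.MODERATE: 0.0,
               ActivityClass.LOW: 0.0, ActivityClass.SILENT: 0.0}
        a = [SubpopulationProfile("a1", "a", pct)]
        b = [SubpopulationProfile("b1", "b", pct), SubpopulationProfile("b2", "b", pct)]
        with pytest.raises(ValueError):
            compare_conditions({"a": a, "b": b}, ActivityClass.HYPERACTIVE)


class TestBoundariesType:
    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ClassBoundaries(spike_thr=0.0)

    def test_round_trip_dict(self):
        b = ClassBoundaries(spike_thr=7.5, amp_thr=0.61)
        assert ClassBoundaries.from_dict(b.to_dict()) == b
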