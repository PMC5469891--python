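"""Baseline standardization, SVM categorization and rank-sum tests."""

import itertools

import numpy as np
import pandas as pd
import pytest

import hrv2d as h


def make_set(clusters, n=30, spread=0.5, seed=0, subjects=None):
    """Gaussian blobs in the feature plane, one per labeled cluster."""
    rng = np.random.default_rng(seed)
    frames = []
    for label, (cx, cy) in clusters.items():
        frames.append(
            pd.DataFrame(
                {
                    "LFiA_ms": rng.normal(cx, spread, n),
                    "HFiA_ms": rng.normal(cy, spread, n),
                    "label": label,
                    "subject": subjects.get(label, "s0") if subjects else "s0",
                }
            )
        )
    return h.LabeledFeatureSet(pd.concat(frames, ignore_index=True))


class TestStandardizeByBaseline:
    def test_baseline_median_maps_to_origin(self):
        fset = make_set({"Rest": (40, 50), "Math": (60, 20)})
        out = h.standardize_by_baseline(fset, "Rest")
        base = out.frame[out.frame["label"] == "Rest"]
        assert base["LFiA_ms"].median() == pytest.approx(0.0, abs=1e-12)
        assert base["HFiA_ms"].median() == pytest.approx(0.0, abs=1e-12)

    def test_constant_features_go_to_zero(self):
        df = pd.DataFrame(
            {"LFiA_ms": 5.0, "HFiA_ms": 7.0, "label": ["A"] * 4 + ["B"] * 4}
        )
        out = h.standardize_by_baseline(h.LabeledFeatureSet(df), "A")
        assert (out.frame[["LFiA_ms", "HFiA_ms"]] == 0).all().all()

    def test_subjects_centered_independently(self):
        rng = np.random.default_rng(1)
        rows = []
        for subj, offset in [("s1", 0.0), ("s2", 100.0)]:
            for label in ("Rest", "Math"):
                rows.append(
                    pd.DataFrame(
                        {
                            "LFiA_ms": offset + rng.normal(40, 1, 10),
                            "HFiA_ms": offset + rng.normal(50, 1, 10),
                            "label": label,
                            "subject": subj,
                        }
                    )
                )
        fset = h.LabeledFeatureSet(pd.concat(rows, ignore_index=True))
        out = h.standardize_by_baseline(fset, "Rest")
        for subj in ("s1", "s2"):
            sub = out.frame[
                (out.frame["subject"] == subj) & (out.frame["label"] == "Rest")
            ]
            assert sub["LFiA_ms"].median() == pytest.approx(0.0, abs=1e-9)

    def test_idempotent_after_first_application(self):
        fset = make_set({"Rest": (40, 50), "Math": (60, 20)})
        once = h.standardize_by_baseline(fset, "Rest")
        twice = h.standardize_by_baseline(once, "Rest")
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_missing_baseline_rejected(self):
        fset = make_set({"Rest": (40, 50), "Math": (60, 20)})
        with pytest.raises(ValueError):
            h.standardize_by_baseline(fset, "Yoga")


class TestFitCategorizer2D:
    def test_separable_clusters_resubstitution(self):
        fset = make_set({"A": (0, 0), "B": (10, 10)})
        model = h.fit_categorizer_2d(fset)
        assert h.categorization_accuracy(model, fset) == 100.0

    def test_three_region_layout(self):
        clusters = {"Rest": (10, 50), "Stress": (50, 10), "Mid": (30, 30)}
        fset = make_set(clusters, spread=2.0, seed=2)
        model = h.fit_categorizer_2d(fset)
        for label, centroid in clusters.items():
            assert model.predict(np.array([centroid]))[0] == label

    def test_refit_deterministic(self):
        fset = make_set({"A": (0, 0), "B": (5, 5), "C": (0, 5)}, spread=1.5)
        grid = np.random.default_rng(0).uniform(-3, 8, size=(50, 2))
        p1 = h.fit_categorizer_2d(fset).predict(grid)
        p2 = h.fit_categorizer_2d(fset).predict(grid)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_rejected(self):
        fset = make_set({"A": (0, 0)})
        with pytest.raises(ValueError):
            h.fit_categorizer_2d(fset)


class TestFitCategorizer1D:
    def test_separable_along_one_axis(self):
        fset = make_set({"A": (0, 0), "B": (10, 0)})
        model = h.fit_categorizer_1d(fset, "LFiA_ms")
        assert h.categorization_accuracy(model, fset) == 100.0

    def test_xor_layout_needs_both_features(self):
        # rest/exercise coincide on x, math/exercise on y: only 2D separates
        clusters = {"Rest": (40, 50), "Math": (60, 20), "Exercise": (40, 20)}
        fset = make_set(clusters, spread=1.5, seed=3)
        ca2 = h.categorization_accuracy(h.fit_categorizer_2d(fset), fset)
        ca1 = max(
            h.categorization_accuracy(h.fit_categorizer_1d(fset, w), fset)
            for w in fset.feature_pair
        )
        assert ca2 > ca1

    def test_predictions_ignore_pinned_coordinate(self):
        fset = make_set({"A": (0, 0), "B": (10, 0)})
        model = h.fit_categorizer_1d(fset, "LFiA_ms")
        x = np.linspace(-2, 12, 30)
        base = model.predict(np.column_stack([x, np.zeros_like(x)]))
        for const in (-100.0, 3.0, 1e4):
            shifted = model.predict(np.column_stack([x, np.full_like(x, const)]))
            np.testing.assert_array_equal(base, shifted)

    def test_unknown_feature_rejected(self):
        fset = make_set({"A": (0, 0), "B": (10, 0)})
        with pytest.raises(ValueError):
            h.fit_categorizer_1d(fset, "SDNN")


class TestCategorizationAccuracy:
    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(4)
        fset = make_set({"A": (0, 0), "B": (8, 0), "C": (4, 7)}, n=60, seed=4)
        df = fset.frame.copy()
        df["label"] = rng.permutation(df["label"].to_numpy())
        shuffled = h.LabeledFeatureSet(df)
        model = h.fit_categorizer_2d(shuffled)
        ca = h.categorization_accuracy(model, shuffled)
        assert 20.0 < ca < 55.0  # chance is 33.3% for 3 balanced classes

    def test_empty_set_rejected(self):
        fset = make_set({"A": (0, 0), "B": (5, 5)})
        model = h.fit_categorizer_2d(fset)
        empty = h.LabeledFeatureSet(fset.frame.iloc[:0], fset.feature_pair)
        with pytest.raises(ValueError):
            h.categorization_accuracy(model, empty)

    def test_kfold_mode_runs(self):
        fset = make_set({"A": (0, 0), "B": (10, 10)}, n=20)
        model = h.fit_categorizer_2d(fset)
        assert h.categorization_accuracy(model, fset, n_folds=4) == 100.0


def exact_ranksum_p(a, b):
    """Exhaustive oracle: enumerate all group assignments of the pooled
    ranks and count rank sums at least as extreme (two-sided)."""
    pooled = np.concatenate([a, b])
    ranks = pd.Series(pooled).rank().to_numpy()
    na = len(a)
    observed = ranks[:na].sum()
    sums = [
        sum(combo) for combo in itertools.combinations(ranks, na)
    ]
    mean = np.mean(sums)
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in sums)
    return extreme / len(sums)


class TestWilcoxonScenarios:
    def test_identical_groups(self):
        assert h.wilcoxon_scenarios([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_fully_separated_five_vs_five(self):
        a, b = [1, 2, 3, 4, 5], [10, 11, 12, 13, 14]
        p = h.wilcoxon_scenarios(a, b)
        assert p == pytest.approx(2 / 252, rel=1e-9)
        assert p == pytest.approx(exact_ranksum_p(np.array(a, float), np.array(b, float)))

    def test_singleton_in_middle_not_significant(self):
        p = h.wilcoxon_scenarios([3.0], [1.0, 2.0, 4.0, 5.0, 6.0])
        assert p > 0.05
        assert p == pytest.approx(
            exact_ranksum_p(np.array([3.0]), np.array([1, 2, 4, 5, 6.0]))
        )

    def test_matches_enumeration_oracle_random_groups(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            a = rng.normal(0, 1, 4)
            b = rng.normal(1, 1, 5)
            assert h.wilcoxon_scenarios(a, b) == pytest.approx(exact_ranksum_p(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            h.wilcoxon_scenarios([], [1.0])


class TestDecisionMap:
    def test_two_class_raster(self):
        fset = make_set({"A": (0, 0), "B": (10, 10)})
        model = h.fit_categorizer_2d(fset)
        raster, xg, yg = h.decision_map(model, (-3, 13, -3, 13), 40)
        assert set(np.unique(raster)) == {"A", "B"}
        assert raster.shape == (40, 40)

    def test_training_points_keep_their_predictions(self):
        fset = make_set({"A": (0, 0), "B": (10, 10)})
        model = h.fit_categorizer_2d(fset)
        pred = model.predict(fset.X)
        for (x, y), label in zip(fset.X, pred):
            r, xg, yg = h.decision_map(model, (x - 0.01, x + 0.01, y - 0.01, y + 0.01), 3)
            assert r[1, 1] == label

    def test_resolution_invariance_of_point_labels(self):
        fset = make_set({"A": (0, 0), "B": (10, 10)})
        model = h.fit_categorizer_2d(fset)
        bounds = (-3, 13, -3, 13)
        r1, *_ = h.decision_map(model, bounds, 20)
        r2, *_ = h.decision_map(model, bounds, 39)  # 39 = 2*20-1 nests the 20-grid
        np.testing.assert_array_equal(r1, r2[::2, ::2])

    def test_bad_inputs_rejected(self):
        fset = make_set({"A": (0, 0), "B": (10, 10)})
        model = h.fit_categorizer_2d(fset)
        with pytest.raises(ValueError):
            h.decision_map(model, (0, 1, 0, 1), 0)
        with pytest.raises(ValueError):
            h.decision_map(model, (1, 0, 0, 1), 10)
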