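"""ICI response modelling: merge, ComBat, split, centroids, AUC, benchmark."""

import itertools

import numpy as np
import pytest

from uvrsig import synthdata
from uvrsig.core import ExpressionMatrix, GeneSet, SignatureCollection
from uvrsig.ici_model import (
    CentroidModel,
    ResponseCohort,
    benchmark_signatures,
    combat_adjust,
    cross_validate,
    fit_centroid_model,
    merge_cohorts,
    predict_scores,
    roc_auc,
    split_cohort,
)


def small_cohort(genes, values, response):
    m = ExpressionMatrix(genes, [f"S{i}" for i in range(len(response))],
                         np.asarray(values, dtype=float))
    return ResponseCohort(m, response)


class TestMerge:
    def test_single_cohort_identity(self):
        c = small_cohort(["A", "B"], [[1, 2], [3, 4]], ["R", "NR"])
        merged = merge_cohorts([c])
        np.testing.assert_array_equal(merged.matrix.values, c.matrix.values)

    def test_gene_universe_is_intersection(self, rng):
        c1 = small_cohort(["A", "B", "C"], rng.normal(size=(3, 2)), ["R", "NR"])
        c2 = ResponseCohort(
            ExpressionMatrix(["B", "C", "D"], ["T0", "T1"], rng.normal(size=(3, 2))),
            ["R", "NR"],
        )
        merged = merge_cohorts([c1, c2])
        assert merged.matrix.gene_ids == ["B", "C"]
        assert merged.n_samples == 4
        assert merged.batch == merged.cohort  # cohort carried as batch

    def test_empty_intersection_rejected(self, rng):
        c1 = small_cohort(["A"], rng.normal(size=(1, 2)), ["R", "NR"])
        c2 = ResponseCohort(
            ExpressionMatrix(["B"], ["T0", "T1"], rng.normal(size=(1, 2))),
            ["R", "NR"],
        )
        with pytest.raises(ValueError, match="empty gene intersection"):
            merge_cohorts([c1, c2])


class TestCombat:
    def test_single_batch_is_identity(self, rng):
        m = ExpressionMatrix(
            [f"G{i}" for i in range(5)], [f"S{j}" for j in range(6)],
            rng.normal(size=(5, 6)),
        )
        adj = combat_adjust(m, ["b0"] * 6)
        np.testing.assert_allclose(adj.values, m.values, atol=1e-8)

    def test_constant_offset_equalizes_batch_levels(self, rng):
        X = rng.normal(size=(100, 40))
        X[:, 20:] += 3.0
        m = ExpressionMatrix(
            [f"G{i}" for i in range(100)], [f"S{j}" for j in range(40)], X
        )
        adj = combat_adjust(m, ["a"] * 20 + ["b"] * 20)
        gap = abs(adj.values[:, :20].mean() - adj.values[:, 20:].mean())
        assert gap < 0.05
        assert abs(X[:, :20].mean() - X[:, 20:].mean()) > 2.5  # was offset

    def test_grand_means_preserved(self, rng):
        X = rng.normal(size=(50, 30))
        m = ExpressionMatrix(
            [f"G{i}" for i in range(50)], [f"S{j}" for j in range(30)], X
        )
        adj = combat_adjust(m, ["a"] * 10 + ["b"] * 10 + ["c"] * 10)
        np.testing.assert_allclose(
            adj.values.mean(axis=1), X.mean(axis=1), atol=1e-6
        )

    def test_singleton_batch_needs_flag(self, rng, caplog):
        m = ExpressionMatrix(
            ["G0"], [f"S{j}" for j in range(3)], rng.normal(size=(1, 3))
        )
        with pytest.raises(ValueError, match="single sample"):
            combat_adjust(m, ["a", "a", "b"])
        with caplog.at_level("WARNING", logger="uvrsig"):
            adj = combat_adjust(m, ["a", "a", "b"], allow_singleton=True)
        np.testing.assert_array_equal(adj.values, m.values)

    def test_correction_improves_auc_under_batch_noise(self):
        from uvrsig.ici_model import fit_centroid_model, predict_scores, roc_auc

        before, after = [], []
        for seed in range(10):
            cohort, truth = synthdata.make_ici_cohort(
                n_samples=90, n_genes=200, effect_size=1.0,
                n_batches=3, batch_sd=2.0, seed=seed,
            )
            for corrected in (False, True):
                c = cohort
                if corrected:
                    c = ResponseCohort(
                        combat_adjust(cohort.matrix, cohort.batch),
                        cohort.response, cohort.batch, cohort.cohort,
                    )
                tr, val = split_cohort(c, 0.8, seed=seed)
                model = fit_centroid_model(tr, truth.effect_genes)
                auc = roc_auc(
                    predict_scores(model, val.matrix).to_numpy(), val.labels()
                )
                (after if corrected else before).append(auc)
        assert np.mean(after) >= np.mean(before)


class TestSplit:
    def test_even_split(self):
        cohort, _ = synthdata.make_ici_cohort(n_samples=20, n_genes=30, seed=0)
        tr, val = split_cohort(cohort, 0.5, seed=1)
        assert tr.n_samples == val.n_samples == 10

    def test_deterministic_and_partitioning(self):
        cohort, _ = synthdata.make_ici_cohort(n_samples=50, n_genes=30, seed=0)
        tr1, val1 = split_cohort(cohort, 0.8, seed=5)
        tr2, val2 = split_cohort(cohort, 0.8, seed=5)
        assert tr1.matrix.sample_ids == tr2.matrix.sample_ids
        ids = set(tr1.matrix.sample_ids) | set(val1.matrix.sample_ids)
        assert ids == set(cohort.matrix.sample_ids)
        assert not set(tr1.matrix.sample_ids) & set(val1.matrix.sample_ids)

    def test_train_retains_both_classes(self):
        cohort, _ = synthdata.make_ici_cohort(
            n_samples=20, n_genes=30, response_rate=0.1, seed=0
        )
        tr, _ = split_cohort(cohort, 0.8, seed=2)
        assert set(tr.response) == {"R", "NR"}


class TestCentroidModel:
    def test_centroids_are_class_means(self):
        c = small_cohort(
            ["A", "B"],
            [[1, 2, 3, 7, 8, 9], [2, 4, 6, 10, 12, 14]],
            ["R", "R", "R", "NR", "NR", "NR"],
        )
        model = fit_centroid_model(c, GeneSet("s", frozenset({"A", "B"})),
                                   distance="euclidean")
        np.testing.assert_allclose(model.centroid_r, [2.0, 4.0])
        np.testing.assert_allclose(model.centroid_nr, [8.0, 12.0])

    def test_duplicating_samples_leaves_centroids_unchanged(self, rng):
        values = rng.normal(size=(4, 8))
        resp = ["R"] * 4 + ["NR"] * 4
        c1 = small_cohort([f"G{i}" for i in range(4)], values, resp)
        dup = np.concatenate([values, values], axis=1)
        c2 = small_cohort([f"G{i}" for i in range(4)], dup, resp + resp)
        sig = GeneSet("s", frozenset(c1.matrix.gene_ids))
        m1 = fit_centroid_model(c1, sig)
        m2 = fit_centroid_model(c2, sig)
        np.testing.assert_allclose(m1.centroid_r, m2.centroid_r)
        np.testing.assert_allclose(m1.centroid_nr, m2.centroid_nr)

    def test_missing_class_rejected(self):
        c = small_cohort(["A", "B"], np.ones((2, 6)), ["R"] * 6)
        with pytest.raises(ValueError, match="per class"):
            fit_centroid_model(c, GeneSet("s", frozenset({"A", "B"})))


class TestPredictScores:
    @pytest.fixture
    def model(self):
        return CentroidModel(
            GeneSet("s", frozenset({"A", "B", "C"})),
            ["A", "B", "C"],
            np.array([1.0, 5.0, 2.0]),
            np.array([4.0, 1.0, 6.0]),
            "euclidean",
        )

    def test_centroid_identity_signs(self, model):
        m = ExpressionMatrix(
            ["A", "B", "C"], ["at_r", "at_nr", "mid"],
            np.column_stack(
                [model.centroid_r, model.centroid_nr,
                 (model.centroid_r + model.centroid_nr) / 2]
            ),
        )
        s = predict_scores(model, m)
        assert s["at_r"] < 0 < s["at_nr"]
        assert s["mid"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_sample_falls_back(self, model, caplog):
        model_p = CentroidModel(model.signature, model.genes, model.centroid_r,
                                model.centroid_nr, "pearson")
        m = ExpressionMatrix(["A", "B", "C"], ["flat"], [[2.0], [2.0], [2.0]])
        with caplog.at_level("WARNING", logger="uvrsig"):
            s = predict_scores(model_p, m)
        assert np.isfinite(s["flat"])
        assert any("fallback" in r.message for r in caplog.records)


class TestRocAuc:
    def test_perfect_and_tied(self):
        assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert roc_auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    def test_matches_pairwise_counting(self, rng):
        scores = rng.normal(size=6)
        labels = np.array([0, 1, 0, 1, 1, 0])
        pairs = [
            1.0 if scores[i] > scores[j] else 0.5 if scores[i] == scores[j] else 0.0
            for i, j in itertools.product(
                np.where(labels == 1)[0], np.where(labels == 0)[0]
            )
        ]
        assert roc_auc(scores, labels) == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_complement_identity(self, rng):
        scores = rng.normal(size=20)
        labels = rng.integers(0, 2, size=20)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1.0, 2.0], [1, 1])


class TestCrossValidate:
    def test_deterministic(self):
        cohort, truth = synthdata.make_ici_cohort(
            n_samples=40, n_genes=60, effect_size=1.5, seed=0
        )
        a = cross_validate(cohort, truth.effect_genes, k=2, repeats=1, seed=3)
        b = cross_validate(cohort, truth.effect_genes, k=2, repeats=1, seed=3)
        assert a == b

    def test_planted_effect_separates(self):
        cohort, truth = synthdata.make_ici_cohort(
            n_samples=80, n_genes=100, effect_size=2.0, seed=1
        )
        mean_auc, sd = cross_validate(cohort, truth.effect_genes, k=5, repeats=2,
                                      seed=0)
        assert mean_auc >= 0.85

    def test_small_class_reduces_k(self, caplog):
        cohort, truth = synthdata.make_ici_cohort(
            n_samples=20, n_genes=30, response_rate=0.2, seed=0
        )
        with caplog.at_level("WARNING", logger="uvrsig"):
            cross_validate(cohort, truth.effect_genes, k=10, repeats=1, seed=0)
        assert any("reducing k" in r.message for r in caplog.records)


class TestBenchmark:
    def test_true_signature_outranks_decoy(self, rng):
        cohort, truth = synthdata.make_ici_cohort(
            n_samples=100, n_genes=300, effect_size=2.0, seed=2
        )
        tr, val = split_cohort(cohort, 0.8, seed=2)
        decoy_pool = sorted(set(cohort.matrix.gene_ids) - truth.effect_genes.genes)
        sigs = SignatureCollection()
        sigs.add(GeneSet("true", truth.effect_genes.genes))
        sigs.add(GeneSet("decoy", frozenset(
            rng.choice(decoy_pool, size=len(truth.effect_genes.genes), replace=False)
        )))
        report = benchmark_signatures({"train": tr, "val": val}, sigs, "train")
        assert report.loc["true", "mean_auc"] > report.loc["decoy", "mean_auc"]

    def test_identical_signatures_identical_rows(self):
        cohort, truth = synthdata.make_ici_cohort(n_samples=40, n_genes=50, seed=3)
        sigs = SignatureCollection()
        sigs.add(GeneSet("a", truth.effect_genes.genes))
        sigs.add(GeneSet("b", truth.effect_genes.genes))
        report = benchmark_signatures({"c": cohort}, sigs, "c")
        np.testing.assert_allclose(report.loc["a"].to_numpy(),
                                   report.loc["b"].to_numpy())

    def test_disjoint_signature_yields_missing(self):
        cohort, _ = synthdata.make_ici_cohort(n_samples=40, n_genes=50, seed=4)
        sigs = SignatureCollection()
        sigs.add(GeneSet("alien", frozenset({"NOT1", "NOT2"})))
        report = benchmark_signatures({"c": cohort}, sigs, "c")
        assert report.loc["alien"].drop("mean_auc").isna().all()
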