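"""Labeling, IRLS logistic fitting, ROC/PR metrics and the window grid."""

import numpy as np
import pytest
from scipy.special import expit

from orthomap.candidates import CandidateTarget
from orthomap.intervals import GenomicInterval, PeakSet
from orthomap.training import (
    DEFAULT_WINDOW_GRID,
    LabeledCandidate,
    SeparationError,
    TrainingDataset,
    aupr,
    auroc,
    cross_validate,
    fit_logistic,
    label_candidates,
    window_grid,
    window_grid_search,
)

from conftest import auroc_brute_force


def simulate_labeled(rng, n, beta=(-3.0, 4.0, 5.0)):
    E = rng.uniform(0, 1, size=n)
    S = rng.uniform(0, 1, size=n)
    p = expit(beta[0] + beta[1] * E + beta[2] * S)
    y = (rng.uniform(size=n) < p).astype(int)
    return [LabeledCandidate(float(e), float(s), int(t)) for e, s, t in zip(E, S, y)]


class TestLabeling:
    def make_candidate(self, start, end):
        cand = CandidateTarget(
            query=GenomicInterval("q", 0, 100),
            target=GenomicInterval("chr1", start, end),
        )
        return cand.with_scores(0.5, 0.5, 0.5)

    def test_overlap_rule_including_half_open_boundary(self):
        gold = PeakSet([GenomicInterval("chr1", 1000, 1500)])
        inside = self.make_candidate(1100, 1300)
        outside = self.make_candidate(2000, 2200)
        abutting = self.make_candidate(1500, 1700)
        labels = [d.label for d in label_candidates([inside, outside, abutting], gold)]
        assert labels == [1, 0, 0]

    def test_similarities_copied_through(self):
        gold = PeakSet([GenomicInterval("chr1", 0, 10)])
        cand = self.make_candidate(0, 5)
        (labeled,) = label_candidates([cand], gold)
        assert (labeled.E, labeled.S) == (0.5, 0.5)

    def test_random_candidates_match_linear_scan(self):
        rng = np.random.default_rng(6)
        gold_ivs = [
            GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 300)))
            for s in rng.choice(50_000, size=40, replace=False)
        ]
        gold = PeakSet(gold_ivs)
        cands = [
            self.make_candidate(int(s), int(s) + 150)
            for s in rng.integers(0, 50_000, size=100)
        ]
        labeled = label_candidates(cands, gold)
        for cand, lab in zip(cands, labeled):
            expected = any(
                g.start < cand.target.end and cand.target.start < g.end
                for g in gold_ivs
            )
            assert lab.label == int(expected)


class TestFitLogistic:
    def test_parameter_recovery_within_three_standard_errors(self):
        """n=5000 simulated from the default coefficients refits closely."""
        rng = np.random.default_rng(100)
        data = simulate_labeled(rng, 5000)
        params = fit_logistic(data, ridge=0.0)
        X = np.column_stack(
            [np.ones(len(data)), [d.E for d in data], [d.S for d in data]]
        )
        beta = params.as_array()
        mu = expit(X @ beta)
        cov = np.linalg.inv(X.T @ (X * (mu * (1 - mu))[:, None]))
        se = np.sqrt(np.diag(cov))
        truth = np.array([-3.0, 4.0, 5.0])
        assert np.all(np.abs(beta - truth) <= 3 * se)

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check against scikit-learn's solver."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(7)
        data = simulate_labeled(rng, 2000)
        ours = fit_logistic(data, ridge=1e-6).as_array()
        X = np.column_stack([[d.E for d in data], [d.S for d in data]])
        y = [d.label for d in data]
        ref = LogisticRegression(C=1e6, tol=1e-10, max_iter=1000).fit(X, y)
        theirs = np.array([ref.intercept_[0], ref.coef_[0][0], ref.coef_[0][1]])
        assert np.allclose(ours, theirs, atol=1e-3)

    def test_null_data_slopes_near_zero(self):
        rng = np.random.default_rng(8)
        data = [
            LabeledCandidate(float(rng.uniform()), float(rng.uniform()), int(rng.integers(2)))
            for _ in range(4000)
        ]
        params = fit_logistic(data)
        assert abs(params.beta1) < 0.3 and abs(params.beta2) < 0.3

    def test_complete_separation_raises_without_ridge(self):
        data = [LabeledCandidate(0.9, 0.9, 1)] * 20 + [LabeledCandidate(0.1, 0.1, 0)] * 20
        with pytest.raises(SeparationError, match="ridge"):
            fit_logistic(data, ridge=0.0)
        # a positive ridge makes the same data fittable
        params = fit_logistic(data, ridge=1e-2)
        assert np.all(np.isfinite(params.as_array()))

    def test_single_class_with_ridge_fits_intercept(self):
        data = [LabeledCandidate(0.5, 0.5, 1)] * 30
        params = fit_logistic(data, ridge=1e-3)
        assert np.all(np.isfinite(params.as_array()))
        assert params.beta0 > 0  # all-positive data pulls the intercept up


class TestMetrics:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [1, 1, 0, 0]
        assert auroc(scores, labels) == 1.0
        assert aupr(scores, labels) == 1.0

    def test_all_tied_scores_give_half_auroc(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.random(200), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=200)
        labels[0], labels[1] = 1, 0
        assert auroc(scores, labels) == pytest.approx(
            auroc_brute_force(scores, labels), abs=1e-12
        )

    def test_aupr_matches_step_integral_oracle(self):
        rng = np.random.default_rng(10)
        scores = np.round(rng.random(150), 2)
        labels = rng.integers(0, 2, size=150)
        labels[0], labels[1] = 1, 0
        order = np.argsort(-scores, kind="stable")
        area, tp, fp, prev_recall = 0.0, 0, 0, 0.0
        n_pos = int(labels.sum())
        distinct = np.unique(scores)[::-1]
        for t in distinct:
            tp = int(((scores >= t) & (labels == 1)).sum())
            fp = int(((scores >= t) & (labels == 0)).sum())
            recall = tp / n_pos
            precision = tp / (tp + fp)
            area += (recall - prev_recall) * precision
            prev_recall = recall
        assert aupr(scores, labels) == pytest.approx(area, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(11)
        scores = rng.random(80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        assert auroc(scores, labels) == pytest.approx(
            auroc(np.exp(3 * scores), labels), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])
        with pytest.raises(ValueError):
            aupr([0.1, 0.2], [0, 0])


class TestWindowGrid:
    def test_default_grid_is_thirteen_windows(self):
        assert DEFAULT_WINDOW_GRID == tuple(range(0, 4801, 400))
        assert len(DEFAULT_WINDOW_GRID) == 13

    def test_flush_endpoint_variant(self):
        assert window_grid(5000, 400, flush=True)[-1] == 5000
        assert len(window_grid(5000, 400, flush=True)) == 14

    def test_single_window_grid_selects_it(self, small_bundle):
        from orthomap.chain import build_index
        from orthomap.features import MatchedFeatureConfig

        b = small_bundle
        cfg = MatchedFeatureConfig(pairs=b.feature_pairs, motifs=b.motifs)
        report = window_grid_search(
            b.queries, build_index(b.chains), cfg, b.gold,
            b.query_genome, b.target_genome, grid=[2000],
        )
        assert report.selected_window == 2000
        assert report.params is not None
        assert len(report.table) == 1

    def test_zero_candidate_windows_recorded_not_fatal(self):
        from orthomap.chain import build_index
        from orthomap.features import MatchedFeatureConfig

        cfg = MatchedFeatureConfig(pairs=[], motifs=[])
        report = window_grid_search(
            [GenomicInterval("nowhere", 0, 100)],
            build_index([]), cfg, PeakSet([]), {}, {}, grid=[0, 400],
        )
        assert report.selected_window is None
        assert report.table["auroc"].isna().all()


class TestCrossValidation:
    def build_datasets(self, bundle, tissues):
        datasets = []
        for i, pair in enumerate(bundle.feature_pairs):
            datasets.append(
                TrainingDataset(
                    name=f"ds{i}",
                    tissue=tissues[i % len(tissues)],
                    query_peaks=pair.query_peaks,
                    target_peaks=pair.target_peaks,
                )
            )
        return datasets

    def test_fold_bookkeeping_excludes_held_out_tissue(self, small_bundle):
        from orthomap.chain import build_index

        b = small_bundle
        datasets = self.build_datasets(b, ["heart", "liver", "lung"])
        report = cross_validate(
            datasets, build_index(b.chains), b.motifs,
            b.query_genome, b.target_genome, grid=[2000], resolution=100,
        )
        assert len(report.fold_params) == 6
        mean = np.mean([p.as_array() for p in report.fold_params], axis=0)
        assert np.allclose(report.params.as_array(), mean)
        # each fold trains features on 4 datasets (6 minus the 2 sharing tissue)
        assert set(report.table["fold"]) == {f"ds{i}" for i in range(6)}

    def test_single_tissue_rejected(self, small_bundle):
        from orthomap.chain import build_index

        b = small_bundle
        datasets = self.build_datasets(b, ["heart"])
        with pytest.raises(ValueError, match="tissues"):
            cross_validate(
                datasets, build_index(b.chains), b.motifs,
                b.query_genome, b.target_genome, grid=[2000],
            )
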