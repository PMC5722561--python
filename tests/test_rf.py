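"""Random-forest layer: OOB votes, importance null, selection, 0.632+,
vote-fraction differences."""

import numpy as np
import pandas as pd
import pytest

from biomepair import (
    RFConfig,
    RFFit,
    ValidationError,
    backward_variable_selection,
    bootstrap_632plus,
    drop_schedule,
    estimate_632plus,
    field_effect_test,
    fit_rf,
    importance_null,
    merge_genus_tables,
    no_information_rate,
    vote_fraction_differences,
)


def _separable(n=40, p=10, gap=3.0, seed=42):
    rng = np.random.default_rng(seed)
    x = np.vstack([rng.normal(0, 1, (n // 2, p)), rng.normal(gap, 1, (n // 2, p))])
    y = np.array([False] * (n // 2) + [True] * (n // 2))
    return x, y


class TestRFConfig:
    def test_even_ntree_rejected(self):
        with pytest.raises(ValidationError, match="odd"):
            RFConfig(ntree=100).validate()

    def test_mtry_exceeding_features_rejected(self):
        with pytest.raises(ValidationError, match="mtry"):
            RFConfig(ntree=11, mtry=20).validate(n_features=5)


class TestFitRF:
    def test_separable_clusters_low_oob(self):
        x, y = _separable()
        fit = fit_rf(x, y, RFConfig(ntree=501, mtry=3, seed=7))
        assert fit.oob_error <= 0.1

    def test_vote_fractions_consistent_with_oob_error(self):
        x, y = _separable(gap=1.0)
        fit = fit_rf(x, y, RFConfig(ntree=301, mtry=3, seed=1))
        assert np.all((fit.vote_fraction >= 0) & (fit.vote_fraction <= 1))
        recomputed = float(np.mean((fit.vote_fraction > 0.5) != fit.y))
        assert fit.oob_error == recomputed

    def test_single_tree_leaves_samples_uncovered(self):
        x, y = _separable()
        with pytest.raises(ValidationError, match="increase ntree"):
            fit_rf(x, y, RFConfig(ntree=1, mtry=3, seed=0))

    def test_single_class_rejected(self):
        x, _ = _separable()
        with pytest.raises(ValidationError, match="per class"):
            fit_rf(x, np.ones(len(x), dtype=bool), RFConfig(ntree=11, mtry=3))

    def test_deterministic_under_seed(self):
        x, y = _separable(gap=1.0)
        a = fit_rf(x, y, RFConfig(ntree=101, mtry=3, seed=5))
        b = fit_rf(x, y, RFConfig(ntree=101, mtry=3, seed=5))
        assert np.array_equal(a.vote_fraction, b.vote_fraction)

    def test_importance_highlights_informative_feature(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(40, 8))
        y = np.array([False] * 20 + [True] * 20)
        x[:, 2] += np.where(y, 2.5, 0.0)
        fit = fit_rf(x, y, RFConfig(ntree=301, mtry=3, seed=9), compute_importance=True)
        assert fit.importance.idxmax() == "f2"


class TestImportanceNull:
    def test_informative_rank_one_beats_null(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 20))
        y = np.array([False] * 20 + [True] * 20)
        x[:, 0] += np.where(y, 2.0, 0.0)
        res = importance_null(x, y, RFConfig(ntree=301, mtry=4, seed=11, n_random_models=5))
        assert res.observed_curve[0] > res.null_mean[0]

    def test_pure_noise_within_null_band(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(40, 20))
        y = np.array([False] * 20 + [True] * 20)
        res = importance_null(x, y, RFConfig(ntree=301, mtry=4, seed=11, n_random_models=10))
        assert not np.any(res.observed_curve > res.null_mean + 3 * res.null_sd)

    def test_curves_non_increasing(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(30, 10))
        y = np.array([False] * 15 + [True] * 15)
        res = importance_null(x, y, RFConfig(ntree=101, mtry=3, seed=2, n_random_models=3))
        assert np.all(np.diff(res.observed_curve) <= 1e-12)
        assert np.all(np.diff(res.null_curves, axis=1) <= 1e-12)

    def test_too_few_models_rejected(self):
        x, y = _separable()
        with pytest.raises(ValidationError, match="random models"):
            importance_null(x, y, RFConfig(ntree=11, mtry=3, n_random_models=1))


class TestBackwardSelection:
    def test_drop_schedule_half_of_eight(self):
        assert drop_schedule(8, 0.5) == [8, 4, 2]

    def test_drop_schedule_fifth_of_112(self):
        sizes = drop_schedule(112, 0.2)
        assert sizes[0] == 112 and sizes[-1] == 2
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_full_point_matches_full_model_oob(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(40, 20))
        y = np.array([False] * 20 + [True] * 20)
        x[:, :3] += np.where(y[:, None], 1.5, 0.0)
        cfg = RFConfig(ntree=301, mtry=4, seed=3)
        sel = backward_variable_selection(x, y, cfg)
        assert sel.oob_errors[0] == sel.full_fit.oob_error

    def test_all_noise_selects_smallest_minimum(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(30, 16))
        y = np.array([False] * 15 + [True] * 15)
        sel = backward_variable_selection(x, y, RFConfig(ntree=101, mtry=4, seed=4))
        err = np.asarray(sel.oob_errors)
        assert np.all(np.abs(err - 0.5) < 0.35)  # hovers around chance
        last_min = max(i for i, e in enumerate(err) if e == err.min())
        assert len(sel.selected_features) == sel.subset_sizes[last_min]

    def test_informative_features_recovered(self):
        rng = np.random.default_rng(9000)
        x = rng.normal(size=(60, 40))
        y = np.array([False] * 30 + [True] * 30)
        x[:, :5] += np.where(y[:, None], 1.5, 0.0)
        sel = backward_variable_selection(x, y, RFConfig(ntree=301, mtry=6, seed=0))
        planted = {f"f{i}" for i in range(5)}
        # the importance ranking puts the informative features on top ...
        assert len(planted & set(sel.ranking[:5])) >= 4
        # ... and the selected subset is drawn from them
        assert set(sel.selected_features) <= planted
        assert min(sel.oob_errors) <= 0.15


class TestNoInformationRate:
    def test_balanced_all_one_class(self):
        y = [True] * 5 + [False] * 5
        assert no_information_rate(y, [True] * 10) == pytest.approx(0.5)

    def test_depends_only_on_marginals(self):
        y = [True] * 5 + [False] * 5
        assert no_information_rate(y, y) == pytest.approx(0.5)

    def test_single_class_matching(self):
        assert no_information_rate([True] * 4, [True] * 4) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            no_information_rate([], [])


class TestEstimate632Plus:
    def test_maximal_overfitting(self):
        err1c, r, w, e = estimate_632plus(0.0, 0.5, 0.5)
        assert (r, w, e) == (1.0, pytest.approx(1.0), pytest.approx(0.5))

    def test_no_overfitting_limit(self):
        err1c, r, w, e = estimate_632plus(0.2, 0.2, 0.5)
        assert r == 0.0 and w == pytest.approx(0.632)
        assert e == pytest.approx(0.2)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            eb, e1, g = rng.uniform(0, 1, 3)
            e1c, r, w, e = estimate_632plus(eb, e1, g)
            assert 0.632 <= w <= 1.0
            assert min(eb, e1c) - 1e-12 <= e <= max(eb, e1c) + 1e-12


class TestBootstrap632Plus:
    def test_matches_straight_line_oracle(self):
        """Exact agreement with a plain-loop re-implementation of the
        estimator bookkeeping on a fixed 12-sample, 3-feature dataset."""
        rng = np.random.default_rng(99)
        x = rng.normal(size=(12, 3))
        y = np.array([False] * 6 + [True] * 6)
        x[:, 0] += np.where(y, 1.0, 0.0)
        cfg = RFConfig(ntree=101, mtry=2, seed=17, n_bootstrap=50)
        ev = bootstrap_632plus(x, y, cfg)

        # oracle: replicate the resampling stream, recompute everything
        full = fit_rf(x, y, cfg)
        app_pred = full.model.predict(x).astype(bool)
        err_bar = np.mean(app_pred != y)
        p1, q1 = np.mean(y), np.mean(app_pred)
        gamma = p1 * (1 - q1) + (1 - p1) * q1
        r2 = np.random.default_rng((cfg.seed * 15485863 + 7) % (2**31 - 1))
        n = 12
        losses = [[] for _ in range(n)]
        for b in range(50):
            while True:
                idx = r2.integers(0, n, size=n)
                held = np.setdiff1d(np.arange(n), idx)
                if held.size and len(np.unique(y[idx])) == 2:
                    break
            bs = int(r2.integers(0, 2**31 - 1))
            fit = fit_rf(x[idx], y[idx], cfg, seed=bs)
            pred = fit.model.predict(x[held]).astype(bool)
            for i, h in enumerate(held):
                losses[h].append(pred[i] != y[h])
        err1 = np.mean([np.mean(l) for l in losses])
        err1c = min(err1, gamma)
        r_hat = (err1c - err_bar) / (gamma - err_bar) if err1c > err_bar and gamma > err_bar else 0.0
        r_hat = min(max(r_hat, 0.0), 1.0)
        w = 0.632 / (1 - 0.368 * r_hat)
        expected = (1 - w) * err_bar + w * err1c

        assert ev.err_apparent == pytest.approx(err_bar, abs=1e-12)
        assert ev.gamma == pytest.approx(gamma, abs=1e-12)
        assert ev.err_loo_bootstrap == pytest.approx(err1, abs=1e-12)
        assert ev.err_632plus == pytest.approx(expected, abs=1e-12)

    def test_quantities_within_unit_interval(self):
        x, y = _separable(n=20, gap=1.5)
        ev = bootstrap_632plus(x, y, RFConfig(ntree=101, mtry=3, seed=2, n_bootstrap=30))
        for v in (ev.err_apparent, ev.err_loo_bootstrap, ev.gamma, ev.err_632plus):
            assert 0.0 <= v <= 1.0
        assert 0.632 <= ev.weight <= 1.0

    def test_selection_inside_bootstrap_reports_frequencies(self):
        rng = np.random.default_rng(31)
        x = pd.DataFrame(rng.normal(size=(20, 6)), columns=[f"g{i}" for i in range(6)])
        y = np.array([False] * 10 + [True] * 10)
        x.iloc[:, 0] += np.where(y, 2.0, 0.0)
        ev = bootstrap_632plus(
            x, y, RFConfig(ntree=101, mtry=2, seed=3, n_bootstrap=10), with_selection=True
        )
        assert ev.selection_frequency is not None
        assert len(ev.selected_sets) == 10
        assert ev.selection_frequency.between(0, 1).all()
        # the informative variable should feature in most selected sets
        assert ev.selection_frequency["g0"] >= 0.5


def _fake_fit(sample_ids, votes, y):
    return RFFit(
        sample_ids=sample_ids,
        feature_names=["f0"],
        y=np.asarray(y),
        vote_fraction=np.asarray(votes, dtype=float),
        oob_error=0.0,
        importance=None,
        model=None,
    )


class TestVoteDifferences:
    def test_perfect_separation_gives_d_one(self, small_cohort):
        cohort, _ = small_cohort
        ids, votes, y = [], [], []
        for t, n in cohort.pairs.values():
            ids += [t, n]
            votes += [1.0, 0.0]
            y += [True, False]
        vd = vote_fraction_differences(_fake_fit(ids, votes, y), cohort)
        assert np.all(vd.d == 1.0)
        assert vd.correct_tumor.all() and vd.correct_nontumor.all()

    def test_swapped_votes_negate_d(self, small_cohort):
        cohort, _ = small_cohort
        rng = np.random.default_rng(0)
        ids, votes, y = [], [], []
        for t, n in cohort.pairs.values():
            vt, vn = rng.uniform(size=2)
            ids += [t, n]
            votes += [vt, vn]
            y += [True, False]
        vd = vote_fraction_differences(_fake_fit(ids, votes, y), cohort)
        swapped = [votes[i + 1 - 2 * (i % 2)] for i in range(len(votes))]
        vd2 = vote_fraction_differences(_fake_fit(ids, swapped, y), cohort)
        assert np.allclose(vd2.d, -vd.d)

    def test_missing_vote_excludes_pair(self, small_cohort):
        cohort, _ = small_cohort
        pairs = list(cohort.pairs.values())
        ids, votes, y = [], [], []
        for t, n in pairs[1:]:
            ids += [t, n]
            votes += [0.8, 0.2]
            y += [True, False]
        vd = vote_fraction_differences(_fake_fit(ids, votes, y), cohort)
        assert len(vd.excluded_patients) == 1
        assert len(vd.patients) == cohort.n_pairs - 1

    def test_mean_d_positive_on_default_signal(self, default_cohort):
        cohort, _ = default_cohort
        feats, _ = merge_genus_tables(cohort)
        labels = cohort.metadata_frame().loc[feats.index, "tissue"].to_numpy()
        fit = fit_rf(feats, labels, RFConfig(ntree=301, seed=13))
        vd = vote_fraction_differences(fit, cohort)
        from scipy import stats as sps

        t, p = sps.ttest_1samp(vd.d, 0.0)
        assert vd.d.mean() > 0 and p < 0.05


class TestFieldEffect:
    def test_identical_d_vectors_give_p_one(self, small_cohort):
        cohort, _ = small_cohort
        # assign d so that both t-stage groups see the same values
        meta = cohort.metadata_frame().drop_duplicates("patient_id").set_index("patient_id")
        by_group = {"low": [], "high": []}
        for pid in cohort.pairs:
            by_group[meta.loc[pid, "t_stage"]].append(pid)
        ids, votes, y = [], [], []
        for group, pids in by_group.items():
            for k, pid in enumerate(pids):
                t, n = cohort.pairs[pid]
                d = 0.1 + 0.05 * k
                ids += [t, n]
                votes += [0.5 + d / 2, 0.5 - d / 2]
                y += [True, False]
        k = min(len(by_group["low"]), len(by_group["high"]))
        keep_pids = by_group["low"][:k] + by_group["high"][:k]
        import dataclasses

        trimmed = dataclasses.replace(
            cohort, pairs={p: cohort.pairs[p] for p in keep_pids}
        )
        vd = vote_fraction_differences(_fake_fit(ids, votes, y), trimmed)
        fe = field_effect_test(vd, trimmed)
        assert fe.p_value == pytest.approx(1.0)

    def test_group_size_one_rejected(self, small_cohort):
        import dataclasses

        cohort, _ = small_cohort
        meta = cohort.metadata_frame().drop_duplicates("patient_id").set_index("patient_id")
        low = [p for p in cohort.pairs if meta.loc[p, "t_stage"] == "low"]
        high = [p for p in cohort.pairs if meta.loc[p, "t_stage"] == "high"]
        keep = low[:1] + high
        trimmed = dataclasses.replace(cohort, pairs={p: cohort.pairs[p] for p in keep})
        ids, votes, y = [], [], []
        for t, n in trimmed.pairs.values():
            ids += [t, n]
            votes += [0.9, 0.1]
            y += [True, False]
        vd = vote_fraction_differences(_fake_fit(ids, votes, y), trimmed)
        with pytest.raises(ValidationError, match="at least 2"):
            field_effect_test(vd, trimmed)

    def test_ranksum_variant_runs(self, default_cohort):
        cohort, _ = default_cohort
        feats, _ = merge_genus_tables(cohort)
        labels = cohort.metadata_frame().loc[feats.index, "tissue"].to_numpy()
        fit = fit_rf(feats, labels, RFConfig(ntree=151, seed=2))
        vd = vote_fraction_differences(fit, cohort)
        fe = field_effect_test(vd, cohort, method="ranksum")
        assert 0 <= fe.p_value <= 1
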