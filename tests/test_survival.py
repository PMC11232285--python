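import numpy as np
import pytest
from scipy import stats

import ctgansurv as cs
from ctgansurv.survival import (concordance_index, fit_superpc, km_curve,
                                logrank_test, predict_partial_hazard,
                                run_cv_benchmark, stratify_and_test)


def brute_force_concordance(times, events, risks):
    """Pair enumeration from the definition: comparable iff the earlier time
    is an event and the times differ; risk ties count 1/2."""
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    return num / den if den else 0.5


def brute_force_logrank(t1, e1, t2, e2):
    """Per-event-time 2x2 hypergeometric summation."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group = np.concatenate([np.zeros(len(t1)), np.ones(len(t2))])
    o_minus_e = var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var if var > 0 else 0.0
    return chi2, stats.chi2.sf(chi2, 1) if var > 0 else 1.0


class TestConcordance:
    def test_perfect_ranking(self):
        assert concordance_index([3, 5, 10], [1, 1, 1], [1.2, 0.9, 0.1]) == 1.0

    def test_anti_ranking(self):
        assert concordance_index([3, 5, 10], [1, 1, 1], [0.1, 0.9, 1.2]) == 0.0

    def test_censored_first_subject_leaves_one_pair(self):
        # only the 5-vs-10 pair is comparable; risk ordering decides alone
        assert concordance_index([3, 5, 10], [0, 1, 1], [9.0, 0.2, 0.1]) == 1.0
        assert concordance_index([3, 5, 10], [0, 1, 1], [9.0, 0.1, 0.2]) == 0.0
        assert concordance_index([3, 5, 10], [0, 1, 1], [9.0, 0.5, 0.5]) == 0.5

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(2, 31)
            times = rng.integers(1, 10, n).astype(float)  # heavy ties
            events = rng.integers(0, 2, n)
            risks = np.round(rng.normal(size=n), 1)  # risk ties too
            if not ((times[:, None] < times) & (events[:, None] == 1)).any():
                continue
            assert concordance_index(times, events, risks) == pytest.approx(
                brute_force_concordance(times, events, risks), abs=0)

    def test_no_comparable_pairs_returns_half_with_warning(self):
        with pytest.warns(UserWarning):
            assert concordance_index([5, 5], [1, 1], [1.0, 2.0]) == 0.5

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            concordance_index([1, 2], [1], [0.1, 0.2])


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        t, s = km_curve([1, 2, 3], [1, 1, 1])
        steps = dict(zip(t, s))
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[2.0] == pytest.approx(1 / 3)
        assert steps[3.0] == pytest.approx(0.0)

    def test_all_censored_flat_at_one(self):
        _, s = km_curve([1, 2, 3], [0, 0, 0])
        assert (s == 1.0).all()

    def test_censoring_shrinks_risk_set_without_drop(self):
        # (1, 2+, 3): S(1) = 2/3, no drop at 2, S(3) = 0
        t, s = km_curve([1, 2, 3], [1, 0, 1])
        steps = dict(zip(t, s))
        assert steps[1.0] == pytest.approx(2 / 3)
        assert steps[2.0] == pytest.approx(2 / 3)
        assert steps[3.0] == pytest.approx(0.0)

    def test_random_no_censoring_equals_ecdf_complement(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 20, 30).astype(float)
        t, s = km_curve(times, np.ones(30, int))
        for ti, si in zip(t, s):
            assert si == pytest.approx((times > ti).mean())


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 0, 1, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        t1, t2 = rng.exponential(1, 20), rng.exponential(2, 25)
        e1, e2 = rng.integers(0, 2, 20), rng.integers(0, 2, 25)
        a = logrank_test(t1, e1, t2, e2)
        b = logrank_test(t2, e2, t1, e1)
        assert a[0] == pytest.approx(b[0], abs=1e-10)

    def test_single_event_single_table(self):
        # one event at t=1 in group 1; group 2 censored later:
        # O - E = 1 - 1/2, V = 1/4 -> chi2 = 1
        chi2, p = logrank_test([1.0], [1], [5.0], [0])
        exp_chi2, exp_p = brute_force_logrank(
            np.array([1.0]), np.array([1]), np.array([5.0]), np.array([0]))
        assert chi2 == pytest.approx(exp_chi2, abs=1e-10)
        assert p == pytest.approx(exp_p, abs=1e-10)

    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n1, n2 = rng.integers(3, 25, 2)
            t1 = rng.integers(1, 15, n1).astype(float)
            t2 = rng.integers(1, 15, n2).astype(float)
            e1, e2 = rng.integers(0, 2, n1), rng.integers(0, 2, n2)
            if e1.sum() + e2.sum() == 0:
                continue
            chi2, _ = logrank_test(t1, e1, t2, e2)
            exp, _ = brute_force_logrank(t1, e1, t2, e2)
            assert chi2 == pytest.approx(exp, abs=1e-10)

    def test_no_events_warns(self):
        with pytest.warns(UserWarning):
            chi2, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert (chi2, p) == (0.0, 1.0)


def _signal_dataset(n=150, n_genes=20, seed=0, effect=1.5):
    cfg = cs.SyntheticConfig(n_a=n, n_b=50, n_genes=n_genes, n_informative=5,
                             effect_size=effect, seed=seed)
    dom_a, _, _ = cs.simulate_pair(cfg)
    return dom_a


class TestSuperPC:
    def test_single_retained_gene_reduces_to_that_gene(self):
        ds = _signal_dataset()
        model = fit_superpc(ds, seed=0)
        if len(model.retained_genes) == 1:
            assert abs(model.pc_loadings[0]) == pytest.approx(1.0)
        # loadings always unit norm
        assert np.linalg.norm(model.pc_loadings) == pytest.approx(1.0)

    def test_signal_recovered_in_train_concordance(self):
        ds = _signal_dataset(n=300, seed=1)
        model = fit_superpc(ds, seed=1)
        risks = predict_partial_hazard(model, ds.expression)
        assert concordance_index(ds.times, ds.events, risks) > 0.65

    def test_zero_coefficient_gives_unit_hazards(self):
        ds = _signal_dataset()
        model = fit_superpc(ds, seed=0)
        model.cox_coefficient = 0.0
        np.testing.assert_allclose(predict_partial_hazard(model, ds.expression), 1.0)

    def test_hazard_monotone_in_pc_score(self):
        ds = _signal_dataset()
        model = fit_superpc(ds, seed=0)
        hz = predict_partial_hazard(model, ds.expression)
        keep = np.isin(model.gene_ids, model.retained_genes)
        score = ((ds.expression.values - model.gene_means)
                 / np.where(model.gene_sds > 1e-12, model.gene_sds, 1.0))[:, keep] @ model.pc_loadings
        order = np.argsort(score)
        hz_sorted = hz[order]
        if model.cox_coefficient > 0:
            assert (np.diff(hz_sorted) >= 0).all()
        else:
            assert (np.diff(hz_sorted) <= 0).all()

    def test_missing_gene_rejected_at_prediction(self):
        ds = _signal_dataset()
        model = fit_superpc(ds, seed=0)
        with pytest.raises(Exception, match="genes"):
            predict_partial_hazard(model, ds.expression.subset_genes(
                ds.expression.gene_ids[:2]))


class TestStratify:
    def test_equal_hazards_put_everyone_low_risk(self):
        ds = _signal_dataset(n=60)
        model = fit_superpc(ds, seed=0)
        model.cox_coefficient = 0.0  # all partial hazards = 1
        with pytest.warns(UserWarning):
            _, p = stratify_and_test(model, ds, ds)
        assert p == 1.0

    def test_separating_hazards_give_small_p(self):
        ps = []
        for seed in range(5):
            cfg = cs.SyntheticConfig(n_a=400, n_b=50, n_genes=20, n_informative=5,
                                     effect_size=2.0, seed=seed)
            ds, _, _ = cs.simulate_pair(cfg)
            n_train = int(0.7 * ds.n_samples)
            train = ds.subset(np.arange(n_train))
            test = ds.subset(np.arange(n_train, ds.n_samples))
            model = fit_superpc(train, seed=seed)
            _, p = stratify_and_test(model, train, test)
            ps.append(p)
        assert np.median(ps) < 0.05

    def test_threshold_from_train_only(self):
        ds = _signal_dataset(n=120, seed=3)
        model = fit_superpc(ds, seed=3)
        test = ds.subset(np.arange(40))
        _, p1 = stratify_and_test(model, ds, test)
        shuffled = test.subset(np.random.default_rng(0).permutation(40))
        _, p2 = stratify_and_test(model, ds, shuffled)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestBenchmark:
    def test_identical_conditions_tie(self, small_pair, tiny_model):
        dom_a, dom_b, _ = small_pair
        model, _ = tiny_model
        tr = cs.generate(model, dom_a, "AB")
        res = run_cv_benchmark(dom_b, {"x": tr, "y": tr}, n_rounds=3, seed=0)
        assert res.medians["x"] == res.medians["y"]
        np.testing.assert_array_equal(res.c_index["x"], res.c_index["y"])

    def test_round_counts_and_conditions(self, small_pair, tiny_model):
        dom_a, dom_b, _ = small_pair
        model, _ = tiny_model
        tr = cs.generate(model, dom_a, "AB")
        res = run_cv_benchmark(dom_b, {"ctgan": tr}, n_rounds=4, seed=1)
        assert res.conditions == ["real", "ctgan"]
        assert all(len(res.c_index[c]) == 4 for c in res.conditions)

    def test_generated_samples_never_in_test_fold(self, small_pair, tiny_model, monkeypatch):
        dom_a, dom_b, _ = small_pair
        model, _ = tiny_model
        tr = cs.generate(model, dom_a, "AB")
        seen_tests = []
        import ctgansurv.survival as sv
        orig = sv.fit_superpc

        def spy(train, **kw):
            seen_tests.append(list(train.sample_ids))
            return orig(train, **kw)
        monkeypatch.setattr(sv, "fit_superpc", spy)
        res = run_cv_benchmark(dom_b, {"ctgan": tr}, n_rounds=2, seed=0)
        # augmented fits contain gen: IDs; real test C-index count intact
        assert any(any(s.startswith("gen:") for s in ids) for ids in seen_tests)
        assert len(res.c_index["real"]) == 2
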