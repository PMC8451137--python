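"""Evaluation harness: parent-coverage splits, sampling scenarios,
precision metrics, marker panels, association scan, augmentation."""

import numpy as np
import pytest

from cropboost import geno, harness, pheno, simpop
from cropboost.metrics import binary_auc
from cropboost.pedigree import Pedigree


class TestParentCoverageSplits:
    @pytest.mark.parametrize("scheme", ["MP", "M", "P", "neither"])
    def test_scheme_predicate_holds(self, scheme):
        ped = simpop.make_crosses([f"m{i}" for i in range(12)],
                                  [f"t{j}" for j in range(6)])
        for seed in range(5):
            plan = harness.split_by_parent_coverage(ped, scheme, 1 / 6, seed)
            assert harness.check_split(plan, ped)
            assert not set(plan.train_ids) & set(plan.test_ids)
            assert plan.test_ids and plan.train_ids

    def test_small_factorial_held_out_father(self, factorial_pedigree):
        """Hold out one of 3 fathers: 8 train / 4 test, every test mother
        covered by training, no test father parents a training F1."""
        ped = factorial_pedigree
        plan = harness.split_by_parent_coverage(ped, "M", 1 / 3, seed=0)
        assert len(plan.train_ids) == 8 and len(plan.test_ids) == 4
        par = dict(zip(ped.f1_ids, zip(ped.mother, ped.father)))
        train_f = {par[s][1] for s in plan.train_ids}
        test_f = {par[s][1] for s in plan.test_ids}
        assert len(train_f) == 2 and len(test_f) == 1
        assert not train_f & test_f
        assert {par[s][0] for s in plan.test_ids} <= \
               {par[s][0] for s in plan.train_ids}

    def test_neither_shares_no_parent(self):
        ped = simpop.make_crosses([f"m{i}" for i in range(20)],
                                  [f"t{j}" for j in range(10)])
        plan = harness.split_by_parent_coverage(ped, "neither", 1 / 6, 3)
        par = dict(zip(ped.f1_ids, zip(ped.mother, ped.father)))
        for s in plan.test_ids:
            for t in plan.train_ids:
                assert par[s][0] != par[t][0] and par[s][1] != par[t][1]

    def test_default_ratio_five_to_one(self):
        ped = simpop.make_crosses([f"m{i}" for i in range(30)],
                                  [f"t{j}" for j in range(6)])
        plan = harness.split_by_parent_coverage(ped, "random", seed=1)
        assert len(plan.test_ids) == 30  # floor(180/6)
        assert len(plan.train_ids) == 150

    def test_unsatisfiable_scheme_errors(self):
        ped = simpop.make_crosses(["m0", "m1"], ["t0"])
        with pytest.raises(ValueError):
            harness.split_by_parent_coverage(ped, "M", 0.5, 0)


class TestSamplingScenarios:
    def test_scenario1_train_size_grid(self):
        ids = [f"s{i}" for i in range(6210)]
        plans = harness.sampling_scenarios(ids, 1, seed=0, repeats=1,
                                           fixed_size=621)
        sizes = [len(p.train_ids) for p in plans]
        assert sizes == [5589, 4347, 3105, 1863, 621, 207, 124, 88, 69]
        assert all(len(p.test_ids) == 621 for p in plans)

    def test_scenario2_test_size_grid(self):
        ids = [f"s{i}" for i in range(6210)]
        plans = harness.sampling_scenarios(ids, 2, seed=0, repeats=1,
                                           fixed_size=621)
        assert [len(p.test_ids) for p in plans] == \
            [69, 88, 124, 207, 621, 1863, 3105, 4347, 5589]

    def test_scenario3_ninety_percent_train(self):
        ids = [f"s{i}" for i in range(6210)]
        plans = harness.sampling_scenarios(ids, 3, seed=0, repeats=2)
        sizes = sorted({len(p.train_ids) + len(p.test_ids) for p in plans},
                       reverse=True)
        assert sizes[0] == 6210 and sizes[-1] == 690
        for p in plans:
            total = len(p.train_ids) + len(p.test_ids)
            assert len(p.train_ids) == int(np.floor(total * 0.9))

    def test_plans_disjoint_and_repeated(self):
        ids = [f"s{i}" for i in range(300)]
        plans = harness.sampling_scenarios(ids, 4, seed=5, repeats=3)
        for p in plans:
            assert not set(p.train_ids) & set(p.test_ids)
        # repeats produce different draws
        assert plans[0].train_ids != plans[1].train_ids


class TestEvaluate:
    def test_perfect_and_negated_predictions(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 3, (60, 5)).astype(float)
        y = rng.normal(size=60)
        ids = [f"s{i}" for i in range(60)]
        plan = harness.SplitPlan(ids[:40], ids[40:], "random", 0, 1 / 3)
        passthrough = lambda Xtr, ytr, Xte: y[40:]
        rep = harness.evaluate_regression(passthrough, (ids, X), y, [plan])
        assert rep.per_repeat[0] == pytest.approx(1.0)
        negate = lambda Xtr, ytr, Xte: -y[40:]
        rep = harness.evaluate_regression(negate, (ids, X), y, [plan])
        assert rep.per_repeat[0] == pytest.approx(-1.0)

    def test_bit_reproducible_with_same_seeds(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, (90, 12)).astype(float)
        y = X[:, 0] + rng.normal(0, 1, 90)
        ids = [f"s{i}" for i in range(90)]
        plans = harness.sampling_scenarios(ids, 1, seed=3, repeats=2,
                                           fixed_size=15)
        spec = ("gbdt", {"n_iterations": 5, "min_samples_leaf": 2})
        a = harness.evaluate_regression(spec, (ids, X), y, plans)
        b = harness.evaluate_regression(spec, (ids, X), y, plans)
        assert a.per_repeat == b.per_repeat

    def test_auc_concordant_pair_arithmetic(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        assert binary_auc(np.array([1, 1, 0, 0]), scores) == 1.0
        assert binary_auc(np.array([1, 0, 1, 0]), scores) == 0.75

    def test_label_permutation_null_auc(self):
        rng = np.random.default_rng(2)
        aucs = []
        for _ in range(200):
            labels = rng.permutation([0] * 10 + [1] * 10)
            aucs.append(binary_auc(labels, rng.normal(size=20)))
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_classification_separable_labels(self):
        rng = np.random.default_rng(3)
        x = np.repeat([0.0, 1.0, 2.0], 40)
        X = np.column_stack([x, rng.integers(0, 3, 120).astype(float)])
        y = x * 2.0 + rng.normal(0, 0.2, 120)
        labels = pheno.label_quantiles(y)
        ids = [f"s{i}" for i in range(120)]
        perm = rng.permutation(120)
        plan = harness.SplitPlan([ids[i] for i in perm[:90]],
                                 [ids[i] for i in perm[90:]],
                                 "random", 0, 0.25)
        rep = harness.evaluate_classification(
            ("gbdt", {"n_iterations": 20, "min_samples_leaf": 2}),
            (ids, X), labels, [plan], n_classes=3)
        assert rep.metric == "multiclass_auc"
        assert rep.per_repeat[0] > 0.8

    def test_missing_class_fold_skipped(self):
        ids = [f"s{i}" for i in range(20)]
        X = np.random.default_rng(4).integers(0, 3, (20, 3)).astype(float)
        labels = np.array([0] * 10 + [1] * 10)
        plan = harness.SplitPlan(ids[5:], ids[:5], "random", 0, 0.25)
        with pytest.warns(UserWarning, match="class absent"):
            rep = harness.evaluate_classification(
                ("gbdt", {"n_iterations": 2}), (ids, X), labels, [plan], 2)
        assert rep.per_repeat == []


class TestMarkerPanel:
    def test_full_panel_equals_plain_evaluation(self):
        rng = np.random.default_rng(5)
        X = rng.integers(0, 3, (80, 10)).astype(float)
        y = X[:, 2] + rng.normal(0, 0.5, 80)
        params = {"n_iterations": 10, "min_samples_leaf": 2}
        res = harness.select_marker_panel(
            ([f"s{i}" for i in range(80)], X), y, [10], repeats=3,
            seed=0, params=params)
        np.testing.assert_allclose(res.ig_r[10], res.full_r, atol=1e-12)

    def test_single_qtl_recovered_in_top_panel(self):
        cfg = simpop.SimConfig(n_maternal=80, n_testers=5, n_markers=150,
                               n_qtl=1, h2=0.7, dominance_frac=0.0,
                               n_epistatic_pairs=0, seed=13)
        pop = simpop.simulate_population(cfg)
        enc = geno.encode_additive(pop.f1)
        y = pop.phenotypes.values[:, 0]
        params = {"n_iterations": 30, "min_samples_leaf": 10}
        res = harness.select_marker_panel(enc, y, [12], repeats=5, seed=1,
                                          params=params)
        causal = pop.truth["qtl_markers"][0]
        causal_col = enc.to_array()[:, pop.truth["qtl_idx"][0]]
        # causal marker or a perfect-LD proxy must rank in the top 12
        proxies = {
            enc.marker_ids[j]
            for j in range(enc.n_markers)
            if abs(np.corrcoef(enc.to_array()[:, j], causal_col)[0, 1]) > 0.999}
        assert causal in proxies
        assert set(res.ranked_markers[:12]) & proxies

    def test_oversized_panel_skipped(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, (40, 8)).astype(float)
        y = rng.normal(size=40)
        with pytest.warns(UserWarning, match="exceed marker count"):
            res = harness.select_marker_panel(
                ([f"s{i}" for i in range(40)], X), y, [4, 100], repeats=2,
                seed=0, params={"n_iterations": 2})
        assert res.panel_sizes == [4]


class TestAssociationScan:
    def test_planted_signal_is_top_hit(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, (200, 50)).astype(float)
        y = 2.0 * X[:, 17] + rng.normal(0, 0.5, 200)
        res = harness.association_scan(X, y)
        assert int(np.argmin(res.p_value)) == 17
        assert res.beta[17] == pytest.approx(2.0, abs=0.2)

    def test_monomorphic_marker_p_one(self):
        rng = np.random.default_rng(8)
        X = rng.integers(0, 3, (50, 3)).astype(float)
        X[:, 1] = 1.0
        res = harness.association_scan(X, rng.normal(size=50))
        assert res.p_value[1] == 1.0 and res.beta[1] == 0.0

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(9)
        X = rng.integers(0, 3, (300, 1000)).astype(float)
        y = rng.normal(size=300)
        res = harness.association_scan(X, y)
        frac = float((res.p_value < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_matches_scipy_linregress(self):
        from scipy import stats
        rng = np.random.default_rng(10)
        X = rng.integers(0, 3, (40, 5)).astype(float)
        y = rng.normal(size=40)
        res = harness.association_scan(X, y)
        for j in range(5):
            lr = stats.linregress(X[:, j], y)
            assert res.beta[j] == pytest.approx(lr.slope, abs=1e-10)
            assert res.p_value[j] == pytest.approx(lr.pvalue, abs=1e-10)


class TestAugment:
    def _setup(self, seed=0):
        from cropboost import gbdt
        cfg = simpop.SimConfig(n_maternal=60, n_testers=6, n_markers=80,
                               n_qtl=5, h2=0.7, seed=seed)
        pop = simpop.simulate_population(cfg)
        enc = geno.encode_additive(pop.f1)
        y = pop.phenotypes.values[:, 0]
        obs_ids = pop.f1.sample_ids[:300]
        new_ids = pop.f1.sample_ids[300:]
        model = gbdt.fit(enc.subset_samples(obs_ids), y[:300],
                         n_iterations=20, min_samples_leaf=10)
        P_obs = pheno.PhenotypeTable(obs_ids, ["trait"], y[:300, None])
        return pop, enc, model, P_obs, new_ids

    def test_rows_flagged_and_counted(self):
        pop, enc, model, P_obs, new_ids = self._setup()
        aug = harness.augment_with_predictions(
            model, enc.subset_samples(new_ids), P_obs)
        assert aug.n_samples == 300 + len(new_ids)
        assert aug.observed[:300].all()
        assert not aug.observed[300:].any()

    def test_zero_unphenotyped_identity(self):
        pop, enc, model, P_obs, _ = self._setup()
        out = harness.augment_with_predictions(
            model, enc.subset_samples([]), P_obs)
        assert out is P_obs

    def test_overlap_rejected(self):
        pop, enc, model, P_obs, new_ids = self._setup()
        with pytest.raises(ValueError, match="both"):
            harness.augment_with_predictions(
                model, enc.subset_samples(P_obs.sample_ids[:5]), P_obs)


class TestParentalFeatures:
    def test_parent_traits_appended(self, small_pop):
        pop = small_pop
        enc = geno.encode_additive(pop.f1)
        parents = pheno.PhenotypeTable(
            pop.maternal.sample_ids + pop.testers.sample_ids, ["tr"],
            np.arange(len(pop.maternal.sample_ids)
                      + len(pop.testers.sample_ids), dtype=float)[:, None])
        ids, X, names = harness.append_parental_features(
            enc, pop.pedigree, parents)
        assert X.shape == (enc.n_samples, enc.n_markers + 2)
        assert names[-2:] == ["mother_tr", "father_tr"]
        pidx = {s: i for i, s in enumerate(parents.sample_ids)}
        for row, sid in zip(X, ids):
            mo, fa = dict(zip(pop.pedigree.f1_ids,
                              zip(pop.pedigree.mother,
                                  pop.pedigree.father)))[sid]
            assert row[-2] == parents.values[pidx[mo], 0]
            assert row[-1] == parents.values[pidx[fa], 0]
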