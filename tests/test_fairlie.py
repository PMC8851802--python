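import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from u5dgap import fairlie
from u5dgap.synthetic_data import SimConfig, generate


def frame_from(Xcols: dict, y, sex, weight=None) -> pd.DataFrame:
    frame = pd.DataFrame(Xcols)
    frame["died_u5"] = y
    frame["sex"] = sex
    frame["weight"] = 1.0 if weight is None else weight
    return frame


@pytest.fixture(scope="module")
def desk_split(desk_dataset):
    records, truth = desk_dataset
    names = [c.name for c in SimConfig().covariates]
    info = fairlie.DesignInfo.from_frame(records, names)
    A = records[records.sex == "male"].reset_index(drop=True)
    B = records[records.sex == "female"].reset_index(drop=True)
    return records, A, B, info, names


class TestFitLogit:
    def test_intercept_only_closed_forms(self):
        X = np.ones((1000, 1))
        coeffs = fairlie.fit_logit(X, np.repeat([0, 1], 500))
        assert coeffs.params[0] == pytest.approx(0.0, abs=1e-8)
        y = np.zeros(1000)
        y[:51] = 1
        coeffs = fairlie.fit_logit(X, y)
        assert coeffs.params[0] == pytest.approx(math.log(51 / 949), abs=1e-8)

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fairlie.fit_logit(np.ones((10, 1)), np.ones(10))

    def test_separation_detected_and_named(self):
        rng = np.random.default_rng(0)
        x = np.repeat([0.0, 1.0], 50)
        X = np.column_stack([np.ones(100), x, rng.normal(size=100)])
        y = x.copy()  # x separates y perfectly
        with pytest.raises(ValueError, match="separation"):
            fairlie.fit_logit(X, y, columns=["const", "sep", "noise"])

    def test_recovers_generator_coefficients(self):
        # single country, no cluster noise: the logit model is exactly specified
        cfg = SimConfig(n_countries=1, clusters_per_country=100,
                        children_per_cluster=400, cluster_sd=0.0, seed=21)
        records, _ = generate(cfg)
        names = [c.name for c in cfg.covariates]
        info = fairlie.DesignInfo.from_frame(records, names)
        X = np.column_stack([info.matrix(records),
                             (records.sex == "male").to_numpy(float)])
        y = records.died_u5.to_numpy(float)
        import statsmodels.api as sm
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        fitted = fairlie.fit_logit(X, y, columns=info.columns + ["sex"])
        true_by_col = {"birth_weight[small]": 0.8, "birth_weight[very small]": 1.8,
                       "twin[multiple]": 1.5, "residence[rural]": 0.15}
        for col, true_val in true_by_col.items():
            j = info.columns.index(col)
            assert abs(fitted.params[j] - true_val) < 3 * ref.bse[j]


class TestDecomposeTotal:
    def test_identical_groups_zero_everywhere(self, desk_split):
        _, A, _, info, _ = desk_split
        X = info.matrix(A)
        beta = fairlie.fit_logit(X, A.died_u5.to_numpy(float), columns=info.columns)
        total, explained, unexplained = fairlie.decompose_total(X, X, beta, beta)
        assert total == explained == unexplained == 0.0

    def test_group_mle_total_matches_observed_gap(self, desk_split):
        # mean-matching property of the weighted logit MLE
        _, A, B, info, _ = desk_split
        XA, XB = info.matrix(A), info.matrix(B)
        wA, wB = A.weight.to_numpy(), B.weight.to_numpy()
        betaA = fairlie.fit_logit(XA, A.died_u5.to_numpy(float), wA)
        betaB = fairlie.fit_logit(XB, B.died_u5.to_numpy(float), wB)
        total, _, _ = fairlie.decompose_total(XA, XB, betaA, betaB, wA, wB)
        observed = (A.died_u5 @ wA / wA.sum()) - (B.died_u5 @ wB / wB.sum())
        assert total == pytest.approx(observed, abs=1e-8)

    def test_label_swap_negates_all_terms(self, desk_split):
        _, A, B, info, _ = desk_split
        XA, XB = info.matrix(A), info.matrix(B)
        betaA = fairlie.fit_logit(XA, A.died_u5.to_numpy(float), columns=info.columns)
        betaB = fairlie.fit_logit(XB, B.died_u5.to_numpy(float), columns=info.columns)
        t1 = fairlie.decompose_total(XA, XB, betaA, betaB)
        t2 = fairlie.decompose_total(XB, XA, betaB, betaA)
        # label swap exchanges both the data and the reference coefficients,
        # so total flips sign while the two components swap and flip
        assert t2[0] == pytest.approx(-t1[0], abs=1e-12)

    def test_identity_link_is_blinder_oaxaca(self, rng):
        n = 250
        x1 = rng.normal(size=2 * n)
        x2 = rng.binomial(1, 0.4, size=2 * n).astype(float)
        beta = np.array([0.1, 0.05, 0.08])
        X = np.column_stack([np.ones(2 * n), x1, x2])
        XA, XB = X[:n], X[n:]
        common = fairlie.LogitCoefficients(beta, ["const", "x1", "x2"],
                                           "pooled", "identity")
        total, explained, unexplained = fairlie.decompose_total(XA, XB, common, common)
        oaxaca = beta @ (XA.mean(0) - XB.mean(0))
        assert explained == pytest.approx(oaxaca, abs=1e-12)
        assert unexplained == pytest.approx(0.0, abs=1e-12)


class TestMatching:
    def test_equal_sizes_sort_then_zip(self, rng):
        pa, pb = rng.random(50), rng.random(50)
        pairs = fairlie.match_samples(pa, pb, rng)
        assert (pa[pairs.a_index] == np.sort(pa)).all()
        assert (pb[pairs.b_index] == np.sort(pb)).all()

    def test_subsample_size_and_uniqueness(self, rng):
        pairs = fairlie.match_samples(rng.random(200), rng.random(100), rng)
        assert len(pairs) == 100
        assert len(set(pairs.a_index)) == 100

    def test_fixed_seed_reproducible(self):
        pa = np.random.default_rng(1).random(80)
        pb = np.random.default_rng(2).random(30)
        p1 = fairlie.match_samples(pa, pb, np.random.default_rng(9))
        p2 = fairlie.match_samples(pa, pb, np.random.default_rng(9))
        assert (p1.a_index == p2.a_index).all() and (p1.b_index == p2.b_index).all()


def brute_force_two_var(XA, XB, alpha, b1, b2):
    """Direct evaluation of the two bracketed means of the sequential rule.

    First bracket: switch X1 from B to A while X2 holds A's values;
    second: switch X2 from A... i.e. contribution of X2 from the all-B side.
    """
    n = len(XA)
    c1 = np.mean(expit(alpha + XA[:, 0] * b1 + XA[:, 1] * b2)
                 - expit(alpha + XB[:, 0] * b1 + XA[:, 1] * b2))
    c2 = np.mean(expit(alpha + XB[:, 0] * b1 + XA[:, 1] * b2)
                 - expit(alpha + XB[:, 0] * b1 + XB[:, 1] * b2))
    return c1, c2


class TestSequential:
    def make_pairs(self):
        XA = np.array([[1, 0], [1, 1], [0, 1], [1, 0], [0, 0], [1, 1]], float)
        XB = np.array([[0, 0], [0, 1], [0, 0], [1, 1], [0, 1], [0, 0]], float)
        alpha, b1, b2 = -2.0, 0.7, -0.4
        beta = np.array([alpha, b1, b2])
        blocks = {"x1": [1], "x2": [2]}
        DA = np.column_stack([np.ones(6), XA])
        DB = np.column_stack([np.ones(6), XB])
        pooled = fairlie.LogitCoefficients(beta, ["const", "x1", "x2"], "pooled")
        return XA, XB, DA, DB, pooled, blocks, (alpha, b1, b2)

    def test_six_pair_toy_matches_brute_force(self):
        XA, XB, DA, DB, pooled, blocks, (alpha, b1, b2) = self.make_pairs()
        contribs, explained = fairlie.sequential_contributions(
            DA, DB, pooled, blocks, ordering=["x2", "x1"])
        c1, c2 = brute_force_two_var(XA, XB, alpha, b1, b2)
        assert contribs["x1"] == pytest.approx(c1, abs=1e-12)
        assert contribs["x2"] == pytest.approx(c2, abs=1e-12)
        assert explained == pytest.approx(c1 + c2, abs=1e-12)

    def test_single_covariate_is_whole_explained_term(self):
        _, _, DA, DB, pooled, _, _ = self.make_pairs()
        contribs, explained = fairlie.sequential_contributions(
            DA, DB, pooled, {"x1": [1, 2]}, ordering=["x1"])
        assert contribs["x1"] == pytest.approx(explained, abs=1e-14)

    def test_identical_paired_values_contribute_zero(self):
        XA, XB, DA, DB, pooled, blocks, _ = self.make_pairs()
        DB2 = DB.copy()
        DB2[:, 1] = DA[:, 1]  # x1 identical within every pair
        contribs, _ = fairlie.sequential_contributions(
            DA, DB2, pooled, blocks, ordering=["x1", "x2"])
        assert contribs["x1"] == 0.0

    def test_telescoping_for_every_ordering(self, rng):
        k, n = 4, 60
        DA = np.column_stack([np.ones(n), rng.binomial(1, 0.5, (n, k))])
        DB = np.column_stack([np.ones(n), rng.binomial(1, 0.4, (n, k))])
        beta = np.concatenate([[-1.5], rng.normal(0, 0.6, k)])
        pooled = fairlie.LogitCoefficients(beta, [], "pooled")
        blocks = {f"v{j}": [j + 1] for j in range(k)}
        for ordering in itertools.permutations(blocks):
            contribs, explained = fairlie.sequential_contributions(
                DA, DB, pooled, blocks, list(ordering))
            assert sum(contribs.values()) == pytest.approx(explained, abs=1e-10)

    def test_bad_ordering_rejected(self):
        _, _, DA, DB, pooled, blocks, _ = self.make_pairs()
        with pytest.raises(ValueError, match="permutation"):
            fairlie.sequential_contributions(DA, DB, pooled, blocks, ["x1"])


class TestReplication:
    def test_d1_equal_sizes_fixed_ordering_equals_single_call(self, rng):
        n = 40
        frameA = frame_from({"x": rng.binomial(1, 0.6, n).astype(str)},
                            rng.binomial(1, 0.3, n), "male")
        frameB = frame_from({"x": rng.binomial(1, 0.4, n).astype(str)},
                            rng.binomial(1, 0.2, n), "female")
        both = pd.concat([frameA, frameB], ignore_index=True)
        info = fairlie.DesignInfo.from_frame(both, ["x"])
        X = info.matrix(both)
        pooled = fairlie.fit_logit(X, both.died_u5.to_numpy(float),
                                   columns=info.columns)
        res = fairlie.replicate_decomposition(frameA, frameB, info, pooled,
                                              D=1, randomize_ordering=False,
                                              seed=4, weight_col=None)
        pred_a = expit(info.matrix(frameA) @ pooled.params)
        pred_b = expit(info.matrix(frameB) @ pooled.params)
        pairs = fairlie.match_samples(pred_a, pred_b, np.random.default_rng(4))
        contribs, explained = fairlie.sequential_contributions(
            info.matrix(frameA)[pairs.a_index], info.matrix(frameB)[pairs.b_index],
            pooled, info.blocks, ["x"])
        assert res.explained == pytest.approx(explained, abs=1e-14)
        assert res.table.contribution.iloc[0] == pytest.approx(contribs["x"], abs=1e-14)

    def test_same_seed_identical_results(self, desk_split):
        records, _, _, _, names = desk_split
        r1 = fairlie.fairlie_decompose(records, names, D=5, seed=31)
        r2 = fairlie.fairlie_decompose(records, names, D=5, seed=31)
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.explained == r2.explained

    def test_identity_link_reproduces_oaxaca_any_d_any_ordering(self, rng):
        # equal group sizes so the subsample draw is degenerate
        n = 250
        x1 = rng.binomial(1, 0.6, 2 * n).astype(str)
        x2 = rng.choice(["a", "b", "c"], 2 * n)
        y = rng.binomial(1, 0.3 + 0.1 * (x1 == "1"), 2 * n)
        sex = np.array(["male"] * n + ["female"] * n)
        records = frame_from({"x1": x1, "x2": x2}, y, sex)
        res_fixed = fairlie.fairlie_decompose(records, ["x1", "x2"], D=3,
                                              randomize_ordering=False, seed=1,
                                              link="identity", weight_col=None)
        res_rand = fairlie.fairlie_decompose(records, ["x1", "x2"], D=7,
                                             randomize_ordering=True, seed=5,
                                             link="identity", weight_col=None)
        info = fairlie.DesignInfo.from_frame(records, ["x1", "x2"])
        X = np.column_stack([info.matrix(records),
                             (records.sex == "male").to_numpy(float)])
        beta = fairlie.fit_logit(X, y.astype(float), link="identity").params[:-1]
        XA = info.matrix(records[records.sex == "male"])
        XB = info.matrix(records[records.sex == "female"])
        for res in (res_fixed, res_rand):
            for var in ("x1", "x2"):
                cols = info.blocks[var]
                oaxaca = beta[cols] @ (XA[:, cols].mean(0) - XB[:, cols].mean(0))
                got = res.table.set_index("variable").loc[var, "contribution"]
                assert got == pytest.approx(oaxaca, abs=1e-12)

    def test_randomized_ordering_se_at_least_subsampling_se(self, desk_split):
        # equal-size groups make the subsample draw degenerate, so any spread
        # must come from ordering randomization
        records, A, B, info, names = desk_split
        m = min(len(A), len(B))
        trimmed = pd.concat([A.iloc[:m], B.iloc[:m]], ignore_index=True)
        sub_only = fairlie.fairlie_decompose(trimmed, names, D=6, seed=2,
                                             randomize_ordering=False)
        rand = fairlie.fairlie_decompose(trimmed, names, D=6, seed=2,
                                         randomize_ordering=True)
        assert sub_only.table.se.max() == pytest.approx(0.0, abs=1e-15)
        assert (rand.table.se >= sub_only.table.se - 1e-15).all()
        assert rand.table.se.max() > 0

    def test_percent_of_gap_sums_to_explained_share(self, desk_split):
        records, _, _, _, names = desk_split
        res = fairlie.fairlie_decompose(records, names, D=4, seed=17,
                                        randomize_ordering=False)
        pct = fairlie.percent_of_gap(res)
        assert pct.sum() == pytest.approx(100 * res.explained / res.total_gap,
                                          abs=1e-8)

    def test_invalid_replication_count(self, desk_split):
        records, A, B, info, _ = desk_split
        pooled = fairlie.LogitCoefficients(np.zeros(len(info.columns)),
                                           info.columns, "pooled")
        with pytest.raises(ValueError, match="at least 1"):
            fairlie.replicate_decomposition(A, B, info, pooled, D=0)
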