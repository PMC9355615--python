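import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from guildassembly.errors import DegenerateStatisticError, ValidationError
from guildassembly.matrix_stats import (category_contrast, forward_select_mrm,
                                        mantel, mrm, nmds, partial_mantel,
                                        permanova, variation_partitioning)
from guildassembly.tabular_io import DistanceMatrix

from conftest import random_distance_matrix, signed_matrix_from_condensed


def _labels(n):
    return tuple(f"s{i}" for i in range(n))


def _condensed(dm):
    iu = np.triu_indices(dm.n, k=1)
    return dm.values[iu]


def brute_mantel(dx, dy, alternative):
    """Independent exhaustive-permutation Mantel oracle (np.corrcoef based)."""
    n = dx.n
    iu = np.triu_indices(n, k=1)
    y = dy.values[iu]
    r_obs = np.corrcoef(dx.values[iu], y)[0, 1]
    count = 0
    for perm in itertools.permutations(range(n)):
        xp = dx.values[np.ix_(perm, perm)][iu]
        r_p = np.corrcoef(xp, y)[0, 1]
        count += (abs(r_p) >= abs(r_obs) if alternative == "two-sided"
                  else r_p >= r_obs)
    return r_obs, count / math.factorial(n)


class TestMantel:
    def test_self_correlation(self):
        d = random_distance_matrix(np.random.default_rng(0), 8)
        res = mantel(d, d, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p >= 1 / 100

    def test_label_mismatch_errors(self):
        d1 = random_distance_matrix(np.random.default_rng(1), 5)
        d2 = random_distance_matrix(np.random.default_rng(2), 5,
                                    labels=_labels(5)[::-1])
        with pytest.raises(ValidationError, match="labels"):
            mantel(d1, d2)

    def test_zero_variance_errors(self):
        flat = DistanceMatrix(_labels(4), np.ones((4, 4)) - np.eye(4))
        d = random_distance_matrix(np.random.default_rng(3), 4)
        with pytest.raises(DegenerateStatisticError):
            mantel(flat, d, n_perm=99, seed=0)

    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_exact_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(4)
        dx = random_distance_matrix(rng, 5)
        dy = random_distance_matrix(rng, 5)
        res = mantel(dx, dy, method="exact", alternative=alternative)
        r_oracle, p_oracle = brute_mantel(dx, dy, alternative)
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p == p_oracle

    def test_monte_carlo_close_to_exact(self):
        rng = np.random.default_rng(5)
        dx = random_distance_matrix(rng, 6)
        dy = random_distance_matrix(rng, 6)
        exact = mantel(dx, dy, method="exact").p
        mc = mantel(dx, dy, n_perm=4999, seed=6).p
        se = np.sqrt(exact * (1 - exact) / 4999)
        assert abs(mc - exact) < 4 * se + 1e-3

    def test_reorder_invariance(self):
        rng = np.random.default_rng(7)
        dx = random_distance_matrix(rng, 6)
        dy = random_distance_matrix(rng, 6)
        order = list(_labels(6))
        rng.shuffle(order)
        r1 = mantel(dx, dy, method="exact")
        r2 = mantel(dx.reorder(order), dy.reorder(order), method="exact")
        assert r1.r == pytest.approx(r2.r, abs=1e-12)
        assert r1.p == r2.p

    def test_null_calibration(self):
        # dy independent of dx: permutation p should be ~uniform
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            dx = random_distance_matrix(rng, 8)
            dy = random_distance_matrix(rng, 8)
            pvals.append(mantel(dx, dy, n_perm=999,
                                seed=int(rng.integers(2 ** 31))).p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_p_floor(self):
        pts = np.arange(6.0)
        d = DistanceMatrix(_labels(6), np.abs(pts[:, None] - pts[None, :]))
        res = mantel(d, d, n_perm=999, seed=9, alternative="greater")
        assert res.p >= 1 / 1000


class TestPartialMantel:
    def test_uncorrelated_control(self):
        rng = np.random.default_rng(10)
        dx = random_distance_matrix(rng, 10)
        dy = DistanceMatrix(dx.labels,
                            dx.values + random_distance_matrix(rng, 10).values)
        dz = random_distance_matrix(rng, 10, labels=dx.labels)
        plain = mantel(dx, dy, n_perm=99, seed=0).r
        partial = partial_mantel(dx, dy, dz, n_perm=99, seed=0).r
        assert abs(partial - plain) < 0.25

    def test_identical_control_errors(self):
        rng = np.random.default_rng(11)
        dx = random_distance_matrix(rng, 6)
        dy = random_distance_matrix(rng, 6)
        with pytest.raises(DegenerateStatisticError):
            partial_mantel(dx, dy, dy, n_perm=99, seed=0)

    def test_residual_regression_oracle(self):
        # [DERIVED] partial r == correlation of OLS residuals of x|z and y|z
        rng = np.random.default_rng(12)
        dx = random_distance_matrix(rng, 6)
        dy = random_distance_matrix(rng, 6)
        dz = random_distance_matrix(rng, 6)
        res = partial_mantel(dx, dy, dz, n_perm=99, seed=0)
        x, y, z = (_condensed(m) for m in (dx, dy, dz))
        Z = np.column_stack([np.ones_like(z), z])
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.r == pytest.approx(oracle, abs=1e-12)

    def test_exact_enumeration(self):
        rng = np.random.default_rng(13)
        dx = random_distance_matrix(rng, 5)
        dy = random_distance_matrix(rng, 5)
        dz = random_distance_matrix(rng, 5)
        res = partial_mantel(dx, dy, dz, method="exact")
        # independent enumeration of the same statistic
        iu = np.triu_indices(5, k=1)
        y, z = dy.values[iu], dz.values[iu]
        r_yz = np.corrcoef(y, z)[0, 1]

        def pr(xv):
            r_xy = np.corrcoef(xv, y)[0, 1]
            r_xz = np.corrcoef(xv, z)[0, 1]
            return (r_xy - r_xz * r_yz) / np.sqrt(
                (1 - r_xz ** 2) * (1 - r_yz ** 2))

        obs = pr(dx.values[iu])
        count = sum(
            abs(pr(dx.values[np.ix_(p, p)][iu])) >= abs(obs)
            for p in itertools.permutations(range(5)))
        assert res.r == pytest.approx(obs, abs=1e-12)
        assert res.p == count / 120


class TestMrm:
    def test_perfect_predictor(self):
        d = random_distance_matrix(np.random.default_rng(14), 8)
        res = mrm(d, {"self": d}, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert res.coefficients["self"] == pytest.approx(1.0, abs=1e-9)

    def test_single_predictor_matches_mantel_r2(self):
        rng = np.random.default_rng(15)
        dy = random_distance_matrix(rng, 8)
        dx = random_distance_matrix(rng, 8)
        r = mantel(dx, dy, n_perm=99, seed=0).r
        res = mrm(dy, {"x": dx}, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(r ** 2, abs=1e-12)

    def test_exact_matches_enumeration_oracle(self):
        # [DERIVED] all 120 permutations of a 5-sample response; per-predictor
        # t statistics recomputed independently with lstsq
        rng = np.random.default_rng(16)
        dy = random_distance_matrix(rng, 5)
        preds = {"a": random_distance_matrix(rng, 5),
                 "b": random_distance_matrix(rng, 5)}
        res = mrm(dy, preds, method="exact")
        iu = np.triu_indices(5, k=1)

        def zsc(v):
            return (v - v.mean()) / v.std(ddof=1)

        X = np.column_stack([np.ones(10), zsc(preds["a"].values[iu]),
                             zsc(preds["b"].values[iu])])

        def tvals(yv):
            yv = zsc(yv)
            beta, rss_arr, *_ = np.linalg.lstsq(X, yv, rcond=None)
            resid = yv - X @ beta
            rss = float(resid @ resid)
            sigma2 = rss / (10 - 3)
            cov = np.linalg.inv(X.T @ X) * sigma2
            return beta[1:] / np.sqrt(np.diagonal(cov)[1:])

        t_obs = tvals(dy.values[iu])
        counts = np.zeros(2)
        for p in itertools.permutations(range(5)):
            t_p = tvals(dy.values[np.ix_(p, p)][iu])
            counts += np.abs(t_p) >= np.abs(t_obs) - 1e-12
        assert res.p_per_predictor["a"] == counts[0] / 120
        assert res.p_per_predictor["b"] == counts[1] / 120

    def test_collinear_predictors_error(self):
        d = random_distance_matrix(np.random.default_rng(17), 6)
        with pytest.raises(ValidationError, match="collinear"):
            mrm(d, {"a": d, "b": d}, n_perm=99, seed=0)

    def test_signal_vs_noise_calibration(self):
        # dy = 0.8*D1 + noise; D1 significant, pure-noise D2 not, most runs
        rng = np.random.default_rng(18)
        labels = _labels(10)
        m = 45
        sig_d1, nonsig_d2 = 0, 0
        runs = 20
        for _ in range(runs):
            z1 = rng.normal(size=m)
            z2 = rng.normal(size=m)
            noise = rng.normal(size=m)
            y = 0.8 * z1 + 0.6 * noise
            dy = signed_matrix_from_condensed(labels, y)
            d1 = signed_matrix_from_condensed(labels, z1)
            d2 = signed_matrix_from_condensed(labels, z2)
            res = mrm(dy, {"D1": d1, "D2": d2}, n_perm=199,
                      seed=int(rng.integers(2 ** 31)))
            sig_d1 += res.p_per_predictor["D1"] < 0.05
            nonsig_d2 += res.p_per_predictor["D2"] >= 0.05
        assert sig_d1 >= int(0.85 * runs)
        assert nonsig_d2 >= int(0.7 * runs)


class TestForwardSelection:
    def test_no_candidate_significant(self):
        rng = np.random.default_rng(19)
        dy = random_distance_matrix(rng, 8)
        cands = {f"n{i}": random_distance_matrix(rng, 8) for i in range(3)}
        res = forward_select_mrm(dy, cands, alpha=0.001, n_perm=199, seed=0)
        assert res.selected == ()
        assert res.r_squared == 0.0

    def test_alpha_one_enters_all_by_gain(self):
        rng = np.random.default_rng(20)
        labels = _labels(9)
        m = 36
        z1, z2, z3 = (rng.normal(size=m) for _ in range(3))
        y = 1.0 * z1 + 0.5 * z2 + 0.1 * z3
        dy = signed_matrix_from_condensed(labels, y)
        cands = {"big": signed_matrix_from_condensed(labels, z1),
                 "mid": signed_matrix_from_condensed(labels, z2),
                 "tiny": signed_matrix_from_condensed(labels, z3)}
        res = forward_select_mrm(dy, cands, alpha=1.0, n_perm=99, seed=1)
        assert set(res.selected) == {"big", "mid", "tiny"}
        assert res.selection_path[0]["added"] == "big"
        gains = [step["r_squared"] for step in res.selection_path]
        assert gains == sorted(gains)

    def test_true_drivers_selected_first(self):
        rng = np.random.default_rng(21)
        labels = _labels(10)
        m = 45
        hits = 0
        runs = 10
        for _ in range(runs):
            zs = [rng.normal(size=m) for _ in range(5)]
            y = 0.9 * zs[0] + 0.8 * zs[1] + 0.3 * rng.normal(size=m)
            dy = signed_matrix_from_condensed(labels, y)
            cands = {f"c{i}": signed_matrix_from_condensed(labels, z)
                     for i, z in enumerate(zs)}
            res = forward_select_mrm(dy, cands, alpha=0.05, n_perm=199,
                                     seed=int(rng.integers(2 ** 31)))
            hits += set(res.selected[:2]) == {"c0", "c1"}
        assert hits >= 8


class TestVpa:
    def test_orthogonal_space_pure_zero(self):
        rng = np.random.default_rng(22)
        labels = _labels(12)
        m = 66
        zenv = rng.normal(size=m)
        zsp = rng.normal(size=m)
        y = zenv + 0.1 * rng.normal(size=m)
        res = variation_partitioning(
            signed_matrix_from_condensed(labels, y),
            env={"e": signed_matrix_from_condensed(labels, zenv)},
            space={"s": signed_matrix_from_condensed(labels, zsp)})
        assert abs(res.pure_space) < 0.08
        assert res.pure_env > 0.8

    def test_identical_groups_all_shared(self):
        rng = np.random.default_rng(23)
        d = random_distance_matrix(rng, 8)
        dy = random_distance_matrix(rng, 8)
        res = variation_partitioning(dy, env={"e": d}, space={"s": d})
        assert res.pure_env == pytest.approx(0.0, abs=1e-9)
        assert res.pure_space == pytest.approx(0.0, abs=1e-9)
        assert res.shared == pytest.approx(res.r2_full, abs=1e-9)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(24)
        dy = random_distance_matrix(rng, 7)
        res = variation_partitioning(
            dy, env={"e": random_distance_matrix(rng, 7)},
            space={"s": random_distance_matrix(rng, 7)})
        total = (res.pure_env + res.pure_space + res.shared
                 + res.unexplained)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_recovers_constructed_shares(self):
        # [DERIVED] y = a*z1 + b*z2 with orthonormalized components:
        # pure fractions approach a^2, b^2 variance shares
        rng = np.random.default_rng(25)
        labels = _labels(14)
        m = 91
        a2, b2 = 0.5, 0.3
        errs_env, errs_sp = [], []
        for _ in range(10):
            q, _ = np.linalg.qr(rng.normal(size=(m, 3)))
            z1, z2, eps = q[:, 0], q[:, 1], q[:, 2]
            y = (np.sqrt(a2) * z1 + np.sqrt(b2) * z2
                 + np.sqrt(1 - a2 - b2) * eps)
            res = variation_partitioning(
                signed_matrix_from_condensed(labels, y),
                env={"e": signed_matrix_from_condensed(labels, z1)},
                space={"s": signed_matrix_from_condensed(labels, z2)})
            errs_env.append(res.pure_env - a2)
            errs_sp.append(res.pure_space - b2)
        assert abs(np.mean(errs_env)) < 0.05
        assert abs(np.mean(errs_sp)) < 0.05


class TestPermanova:
    def test_separated_blocks_minimal_p(self):
        # groups big enough that re-drawing the same partition is unlikely,
        # so maximal separation attains the smoothed floor 1/(n_perm+1)
        n = 16
        vals = np.full((n, n), 10.0)
        vals[:8, :8] = 1.0
        vals[8:, 8:] = 1.0
        np.fill_diagonal(vals, 0.0)
        d = DistanceMatrix(_labels(n), vals)
        res = permanova(d, ["g1"] * 8 + ["g2"] * 8, n_perm=999, seed=0)
        assert res.p == 1 / 1000

    def test_singleton_group_errors(self):
        d = random_distance_matrix(np.random.default_rng(26), 5)
        with pytest.raises(ValidationError, match="fewer than 2"):
            permanova(d, ["a", "a", "a", "a", "b"])

    def test_exact_matches_skbio_enumeration(self):
        # independent oracle: skbio's statistic + exhaustive label perms
        import skbio

        rng = np.random.default_rng(27)
        d = random_distance_matrix(rng, 6)
        groups = ["a", "a", "a", "b", "b", "b"]
        res = permanova(d, groups, method="exact")
        sk = skbio.DistanceMatrix(d.values.copy(), ids=list(d.labels))

        def sk_f(g):
            out = skbio.stats.distance.permanova(sk, grouping=list(g),
                                                 permutations=0)
            return out["test statistic"]

        f_obs = sk_f(groups)
        assert res.pseudo_f == pytest.approx(f_obs, abs=1e-9)
        garr = np.array(groups)
        count = sum(
            sk_f(garr[list(p)]) >= f_obs - 1e-12
            for p in itertools.permutations(range(6)))
        assert res.p == count / 720


class TestNmds:
    def test_equilateral_low_stress(self):
        d = DistanceMatrix(_labels(3), np.ones((3, 3)) - np.eye(3))
        res = nmds(d, k=2, n_starts=8, seed=0)
        assert res.stress < 0.01

    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(28)
        pts = rng.uniform(size=(8, 2))
        diff = pts[:, None, :] - pts[None, :, :]
        d = DistanceMatrix(_labels(8), np.sqrt((diff ** 2).sum(axis=2)))
        res = nmds(d, k=2, n_starts=20, seed=1)
        assert res.stress < 0.01

    def test_deterministic(self):
        d = random_distance_matrix(np.random.default_rng(29), 7)
        r1 = nmds(d, k=2, n_starts=5, seed=3)
        r2 = nmds(d, k=2, n_starts=5, seed=3)
        np.testing.assert_array_equal(r1.coords.values, r2.coords.values)

    def test_k_too_large_errors(self):
        d = random_distance_matrix(np.random.default_rng(30), 4)
        with pytest.raises(ValidationError, match="k="):
            nmds(d, k=4)


class TestCategoryContrast:
    def _attribute(self, labels, values):
        return pd.Series(values, index=list(labels))

    def test_all_equal_shares_letter(self):
        labels = _labels(9)
        dev = signed_matrix_from_condensed(labels, np.zeros(36))
        attr = self._attribute(labels, np.arange(9.0))
        res = category_contrast(dev, attr, n_bins=3)
        assert len(set(res.letters.values())) == 1

    def test_shifted_bins_minimal_p(self):
        rng = np.random.default_rng(31)
        labels = _labels(12)
        attr = self._attribute(labels, np.arange(12.0))
        vals = np.zeros((12, 12))
        low = np.arange(12) < 6
        # large constant offset for pairs within the low half
        for i in range(12):
            for j in range(12):
                if i != j:
                    vals[i, j] = 100.0 if (low[i] and low[j]) else rng.uniform()
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 0)
        dev = DistanceMatrix(labels, vals, signed=True)
        res = category_contrast(dev, attr, n_bins=2)
        p = res.pairwise_p[("low", "high")]
        assert p == min(res.pairwise_p.values())
        assert p < 0.001
        assert res.letters["low"] != res.letters["high"]

    def test_small_bin_excluded(self):
        labels = _labels(5)
        dev = signed_matrix_from_condensed(
            labels, np.random.default_rng(32).normal(size=10))
        # 2 low, 2 medium, 1 high sample -> high bin has no within-bin pair
        attr = self._attribute(labels, [0.0, 0.1, 1.0, 1.1, 5.0])
        res = category_contrast(dev, attr, n_bins=3)
        assert "high" in res.excluded

    def test_null_calibration(self):
        rng = np.random.default_rng(33)
        labels = _labels(12)
        false_pos = 0
        runs = 40
        for _ in range(runs):
            dev = signed_matrix_from_condensed(labels,
                                               rng.normal(size=66))
            attr = self._attribute(labels, rng.normal(size=12))
            res = category_contrast(dev, attr, n_bins=2)
            false_pos += res.pairwise_p[("low", "high")] < 0.05
        assert false_pos <= int(0.25 * runs)
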