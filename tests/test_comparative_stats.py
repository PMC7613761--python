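"""Spearman, OLS intervals, PGLS under Brownian motion, RBH and operon stats."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from napscan import comparative_stats as cs
from napscan.io_formats import OperonMap, QuantTable, ValidationError
from napscan.quantification import fractional_abundances


def tree_from(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestSpearman:
    def test_monotone_limits(self):
        x = [1, 2, 3, 4, 5]
        rho, _ = cs.spearman(x, [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = cs.spearman(x, [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_average_ranks_for_ties(self):
        rho, _ = cs.spearman([1, 2, 3, 4], [1, 2, 2, 4])
        # brute-force rank formula with midranks
        rx = np.array([1, 2, 3, 4.0])
        ry = np.array([1, 2.5, 2.5, 4.0])
        expected = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(expected)

    def test_exact_p_small_n(self):
        # perfectly concordant n=4: only 2 of 24 permutations reach |rho|=1
        _, p = cs.spearman([1, 2, 3, 4], [1, 2, 3, 4])
        assert p == pytest.approx(2 / 24)

    def test_exact_matches_scipy_moderate_n(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        rho, _ = cs.spearman(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, p1 = cs.spearman(x, y)
        rho2, p2 = cs.spearman(np.exp(x), y)
        rho3, p3 = cs.spearman(x, y**3)
        assert rho1 == pytest.approx(rho2) == pytest.approx(rho3)
        assert p1 == pytest.approx(p2) == pytest.approx(p3)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValidationError):
            cs.spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestDomainOgtScreen:
    def _screen_input(self, rng, n_species=19, n_features=40, linked=True):
        species = [f"sp{i}" for i in range(n_species)]
        ogt = pd.Series(rng.uniform(24, 98, n_species), index=species)
        rows = {}
        for f in range(n_features):
            rows[f"feat{f}"] = rng.uniform(0.01, 1.0, n_species)
        nap = 0.075 * ogt.to_numpy() - 2.0 + rng.normal(0, 0.6, n_species)
        rows["NAP"] = np.clip(nap, 0.01, None)
        return pd.DataFrame(rows, index=species).T, ogt

    def test_nap_ranks_first_when_only_nap_is_linked(self, rng):
        abund, ogt = self._screen_input(rng)
        res = cs.domain_ogt_screen(abund, ogt)
        assert res.nap_rank == 1

    def test_shuffled_ogt_centres_rho_at_zero(self, rng):
        abund, ogt = self._screen_input(rng)
        shuffled = pd.Series(rng.permutation(ogt.to_numpy()), index=ogt.index)
        res = cs.domain_ogt_screen(abund.drop(index="NAP"), shuffled)
        assert abs(res.table["rho"].mean()) < 0.15

    def test_sparse_feature_dropped(self, rng):
        abund, ogt = self._screen_input(rng)
        abund.loc["feat0", abund.columns[5:]] = 0.0
        res = cs.domain_ogt_screen(abund, ogt, min_species=10)
        assert "feat0" not in res.table.index


class TestOlsPredict:
    def test_perfect_collinearity_zero_width(self):
        fit = cs.ols_predict([0, 10, 20], [0, 10, 20])
        point, mean_ci, pred_int = fit.predict(5.0)
        assert point == pytest.approx(5.0)
        assert mean_ci[0] == pytest.approx(mean_ci[1]) == pytest.approx(5.0)
        assert pred_int[0] == pytest.approx(5.0)

    def test_intervals_match_statsmodels(self, rng):
        x = rng.uniform(0, 100, 19)
        y = 0.07 * x - 1 + rng.normal(0, 0.5, 19)
        fit = cs.ols_predict(x, y)
        point, mean_ci, pred_int = fit.predict(37.0)
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        frame = res.get_prediction([1.0, 37.0]).summary_frame(alpha=0.05)
        assert point == pytest.approx(frame["mean"].iloc[0])
        assert mean_ci[0] == pytest.approx(frame["mean_ci_lower"].iloc[0])
        assert mean_ci[1] == pytest.approx(frame["mean_ci_upper"].iloc[0])
        assert pred_int[0] == pytest.approx(frame["obs_ci_lower"].iloc[0])
        assert pred_int[1] == pytest.approx(frame["obs_ci_upper"].iloc[0])

    def test_closed_form_mean_halfwidth(self, rng):
        x = rng.uniform(0, 50, 12)
        y = rng.normal(size=12)
        fit = cs.ols_predict(x, y)
        x0 = 20.0
        point, mean_ci, _ = fit.predict(x0)
        sxx = float(((x - x.mean()) ** 2).sum())
        half = (
            stats.t.ppf(0.975, 10)
            * fit.residual_se
            * math.sqrt(1 / 12 + (x0 - x.mean()) ** 2 / sxx)
        )
        assert mean_ci[1] - point == pytest.approx(half)

    def test_two_points_interval_undefined(self):
        fit = cs.ols_predict([0, 1], [0, 1])
        assert fit.slope == pytest.approx(1.0)
        with pytest.raises(ValidationError):
            fit.predict(0.5)


class TestPglsBm:
    def test_bm_covariance_of_three_taxon_tree(self):
        tree = tree_from("((A:1,B:1):1,C:2);")
        C = cs.bm_covariance(tree, ["A", "B", "C"])
        assert np.allclose(C, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_three_taxon_gls_matches_hand_inverted_oracle(self):
        tree = tree_from("((A:1,B:1):1,C:2);")
        x = {"A": 1.0, "B": 2.0, "C": 4.0}
        y = {"A": 1.5, "B": 2.6, "C": 4.1}
        fit = cs.pgls_bm(tree, x, y)
        # hand-inverted C: block [[2,1],[1,2]]^-1 = 1/3 [[2,-1],[-1,2]]
        Cinv = np.array([[2 / 3, -1 / 3, 0], [-1 / 3, 2 / 3, 0], [0, 0, 1 / 2]])
        X = np.array([[1, 1.0], [1, 2.0], [1, 4.0]])
        yv = np.array([1.5, 2.6, 4.1])
        A = X.T @ Cinv @ X
        b = X.T @ Cinv @ yv
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        Ainv = np.array([[A[1, 1], -A[0, 1]], [-A[1, 0], A[0, 0]]]) / det
        beta = Ainv @ b
        assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
        assert fit.slope == pytest.approx(beta[1], abs=1e-10)

    def test_star_tree_equals_ols(self, rng):
        tips = [f"A{i}" for i in range(12)]
        tree = tree_from("(" + ",".join(f"{t}:1.0" for t in tips) + ");")
        x = {t: float(rng.normal()) for t in tips}
        y = {t: 2 * x[t] + 1 + float(rng.normal(0, 0.2)) for t in tips}
        fit = cs.pgls_bm(tree, x, y)
        ols = cs.ols_predict([x[t] for t in tips], [y[t] for t in tips])
        assert abs(fit.slope - ols.slope) < 1e-8
        assert abs(fit.intercept - ols.intercept) < 1e-8

    def test_branch_length_scale_invariance(self, rng):
        tree = tree_from("((A:1,B:1):1,(C:0.5,D:0.5):1.5);")
        x = {t: float(rng.normal()) for t in "ABCD"}
        y = {t: float(rng.normal()) for t in "ABCD"}
        fit1 = cs.pgls_bm(tree, x, y)
        tree2 = tree_from("((A:3,B:3):3,(C:1.5,D:1.5):4.5);")
        fit2 = cs.pgls_bm(tree2, x, y)
        assert fit1.slope == pytest.approx(fit2.slope, abs=1e-10)
        assert fit1.intercept == pytest.approx(fit2.intercept, abs=1e-10)

    def test_identity_relationship_recovered(self):
        tree = tree_from("((A:1,B:1):1,C:2);")
        vals = {"A": 3.0, "B": 5.0, "C": 9.0}
        fit = cs.pgls_bm(tree, vals, dict(vals))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_tip_mismatch_reported(self):
        tree = tree_from("((A:1,B:1):1,C:2);")
        with pytest.raises(ValidationError, match="D"):
            cs.pgls_bm(tree, {"A": 1, "B": 2, "D": 3}, {"A": 1, "B": 2, "D": 3})

    def test_bootstrap_ci_contains_slope_and_is_seeded(self, rng):
        tips = [f"A{i}" for i in range(10)]
        tree = tree_from("(" + ",".join(f"{t}:1.0" for t in tips) + ");")
        x = {t: float(rng.normal()) for t in tips}
        y = {t: 2 * x[t] + float(rng.normal(0, 0.3)) for t in tips}
        fit1 = cs.pgls_bm(tree, x, y, bootstrap=True, n_boot=200, seed=4)
        fit2 = cs.pgls_bm(tree, x, y, bootstrap=True, n_boot=200, seed=4)
        assert fit1.bootstrap_ci == fit2.bootstrap_ci
        lo, hi = fit1.bootstrap_ci
        assert lo < 2.0 < hi


def _fp(raw):
    data = pd.DataFrame(
        {
            "protein_id": list(raw),
            "raw_intensity": list(raw.values()),
            "lfq_intensity": float("nan"),
            "aliases": "",
        }
    )
    return fractional_abundances(QuantTable("sp", "c", "r", data), prefer_lfq=False)


class TestRbhCorrelation:
    def test_identity_pairs_rho_one(self):
        raw = {f"p{i}": float(i + 1) for i in range(10)}
        fp = _fp(raw)
        rho, n = cs.rbh_abundance_correlation(fp, fp, [(k, k) for k in raw])
        assert rho == pytest.approx(1.0)
        assert n == 10

    def test_independent_abundances_near_zero(self, rng):
        rhos = []
        for _ in range(20):
            a = {f"p{i}": float(10 ** rng.normal(0, 1)) for i in range(30)}
            b = {f"p{i}": float(10 ** rng.normal(0, 1)) for i in range(30)}
            rho, _ = cs.rbh_abundance_correlation(
                _fp(a), _fp(b), [(k, k) for k in a]
            )
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.15

    def test_undetected_pairs_dropped(self):
        a = {"p1": 1.0, "p2": 2.0, "p3": 3.0, "p4": 4.0}
        b = {"p1": 1.0, "p2": 2.0, "p3": 3.0, "p4": 0.0}
        rho, n = cs.rbh_abundance_correlation(
            _fp(a), _fp(b), [(k, k) for k in a] + [("ghost", "p1")]
        )
        assert n == 3

    def test_too_few_pairs_rejected(self):
        a = {"p1": 1.0, "p2": 2.0, "p3": 3.0}
        with pytest.raises(ValidationError):
            cs.rbh_abundance_correlation(_fp(a), _fp(a), [("p1", "p1"), ("p2", "p2")])


class TestGenesPerTu:
    @pytest.mark.parametrize(
        "operons,expected",
        [
            ({"a": ["g1"], "b": ["g2", "g3"], "c": ["g4", "g5", "g6"]}, 2.0),
            ({"a": ["g1"], "b": ["g2"]}, 1.0),
            ({"a": ["g1", "g2", "g3", "g4", "g5"]}, 5.0),
        ],
    )
    def test_mean_sizes(self, operons, expected):
        assert cs.genes_per_tu(OperonMap(operons)) == expected

    def test_empty_map_rejected(self):
        om = OperonMap({"a": ["g1"]})
        om.operons = {}
        with pytest.raises(ValidationError):
            cs.genes_per_tu(om)
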