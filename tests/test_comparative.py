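import math

import numpy as np
import pandas as pd
import pytest

from mitosel import (
    DistanceMatrix,
    Tree,
    env_distance_matrix,
    glm_env,
    mantel_test,
    pic_contrasts,
    pic_regression,
    trait_distance_matrix,
)

from oracles import tree_covariance


def random_env(seed: int, n: int, index=None) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    index = index or [f"s{i}" for i in range(n)]
    return pd.DataFrame(
        rng.normal(size=(n, 19)),
        columns=[f"BIO{i}" for i in range(1, 20)],
        index=index,
    )


class TestPicContrasts:
    def test_cherry_closed_form(self):
        tree = Tree.from_newick("(A:1,B:1);")
        cs = pic_contrasts(tree, {"A": 3.0, "B": 1.0})
        assert cs.values == pytest.approx([math.sqrt(2)])

    def test_constant_trait_gives_zero_contrasts(self, quartet_tree):
        cs = pic_contrasts(quartet_tree, {t: 2.5 for t in "ABCD"})
        assert np.allclose(cs.values, 0.0)

    def test_count_equals_tips_minus_one(self):
        tree = Tree.from_newick("(((A:1,B:2):1,(C:1,D:1):2):1,(E:3,F:1):2);")
        cs = pic_contrasts(tree, dict(zip("ABCDEF", range(6))))
        assert len(cs.contrasts) == 5

    @pytest.mark.parametrize("newick", [
        "(((A:1,B:2):1,(C:1,D:1):2):1,(E:3,F:1):2);",
        "((A:0.5,(B:1,C:0.4):0.6):1.2,(D:2,(E:0.3,F:0.9):1.1):0.2);",
    ])
    def test_contrasts_are_unit_variance_uncorrelated_gls(self, newick):
        """The contrast coefficient vectors C must satisfy C V C' = I for the
        Brownian-motion covariance V implied by the tree."""
        tree = Tree.from_newick(newick)
        labels, V = tree_covariance(tree)
        C = []
        for k in range(len(labels)):
            unit = {name: float(i == k) for i, name in enumerate(labels)}
            C.append(pic_contrasts(tree, unit).values)
        C = np.array(C).T  # contrasts x tips
        assert np.allclose(C @ V @ C.T, np.eye(len(labels) - 1), atol=1e-10)

    def test_missing_trait_rejected(self, quartet_tree):
        with pytest.raises(ValueError, match="missing trait"):
            pic_contrasts(quartet_tree, {"A": 1.0, "B": 2.0})

    def test_sign_invariance_under_cherry_swap(self):
        t1 = Tree.from_newick("((A:1,B:2):1,C:3);")
        t2 = Tree.from_newick("((B:2,A:1):1,C:3);")
        trait = {"A": 1.0, "B": 4.0, "C": 2.0}
        v1 = pic_contrasts(t1, trait).values
        v2 = pic_contrasts(t2, trait).values
        assert np.allclose(np.abs(v1), np.abs(v2))


class TestPicRegression:
    def test_exact_doubling(self, quartet_tree):
        x = pic_contrasts(quartet_tree, {"A": 1, "B": 2, "C": 5, "D": 7})
        y = pic_contrasts(quartet_tree, {"A": 2, "B": 4, "C": 10, "D": 14})
        fit = pic_regression(x, y)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.intercept == 0.0

    def test_slope_recovery_with_noise(self):
        rng = np.random.default_rng(8)
        newick = "((((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):2):1,(G:2,H:2):1);"
        tree = Tree.from_newick(newick)
        slopes = []
        for _ in range(100):
            x = {t.name: rng.normal() for t in tree.tips}
            y = {k: 1.5 * v + 0.1 * rng.normal() for k, v in x.items()}
            fit = pic_regression(pic_contrasts(tree, x), pic_contrasts(tree, y))
            slopes.append(fit.slope)
        assert np.median(slopes) == pytest.approx(1.5, abs=0.1)


class TestEnvDistance:
    def test_identical_rows_have_zero_distance(self):
        env = random_env(0, 5)
        env.iloc[1] = env.iloc[0]
        d = env_distance_matrix(env)
        assert d.matrix[0, 1] == pytest.approx(0.0)

    def test_three_four_five_unstandardized(self):
        df = pd.DataFrame({"BIO1": [0.0, 3.0], "BIO2": [0.0, 4.0]},
                          index=["a", "b"])
        d = env_distance_matrix(df, columns=["BIO1", "BIO2"], standardize=False)
        assert d.matrix[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop_brute_force(self):
        env = random_env(1, 6)
        d = env_distance_matrix(env, standardize=False)
        for i in range(6):
            for j in range(6):
                want = math.sqrt(((env.iloc[i] - env.iloc[j]) ** 2).sum())
                assert d.matrix[i, j] == pytest.approx(want, abs=1e-12)

    def test_standardization_is_affine_invariant(self):
        env = random_env(2, 6)
        scaled = env.copy()
        scaled["BIO3"] = scaled["BIO3"] * 40.0 - 7.0
        d1 = env_distance_matrix(env)
        d2 = env_distance_matrix(scaled)
        assert np.allclose(d1.matrix, d2.matrix, atol=1e-10)

    def test_zero_variance_variable_dropped(self):
        env = random_env(3, 5)
        env["BIO7"] = 4.2
        d = env_distance_matrix(env)  # should not raise
        assert d.matrix.shape == (5, 5)


class TestMantel:
    def test_self_correlation_is_one_with_minimal_p(self):
        d = env_distance_matrix(random_env(4, 8))
        res = mantel_test(d, d, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_reproducible_for_fixed_seed(self):
        d1 = env_distance_matrix(random_env(5, 8))
        d2 = env_distance_matrix(random_env(6, 8))
        a = mantel_test(d1, d2, n_perm=199, seed=42)
        b = mantel_test(d1, d2, n_perm=199, seed=42)
        assert a.p == b.p and a.r == b.r

    def test_constant_matrix_rejected(self):
        labels = ["a", "b", "c", "d"]
        m = DistanceMatrix(labels, 1 - np.eye(4))
        d = env_distance_matrix(random_env(7, 4, index=labels))
        with pytest.raises(ValueError, match="constant"):
            mantel_test(d, m, n_perm=99, seed=0)

    def test_label_mismatch_rejected(self):
        d1 = env_distance_matrix(random_env(8, 5))
        env = random_env(9, 5)
        env.index = [f"t{i}" for i in range(5)]
        d2 = env_distance_matrix(env)
        with pytest.raises(ValueError, match="labels"):
            mantel_test(d1, d2, n_perm=99, seed=0)


class TestGlmEnv:
    def test_recovers_single_associated_variable(self):
        rng = np.random.default_rng(10)
        env = random_env(11, 30)
        omega = {
            "ATP6": {
                s: 0.1 + 0.02 * env.loc[s, "BIO6"] + rng.normal(0, 0.005)
                for s in env.index
            }
        }
        (res,) = glm_env(omega, env)
        assert "BIO6" in res.retained
        assert res.p_values["BIO6"] < 0.05

    def test_duplicate_predictor_dropped_by_vif(self):
        rng = np.random.default_rng(12)
        env = random_env(13, 25)
        env["BIO2"] = env["BIO1"]  # perfect collinearity
        omega = {
            "ND2": {
                s: 0.2 + 0.05 * env.loc[s, "BIO1"] + rng.normal(0, 0.01)
                for s in env.index
            }
        }
        (res,) = glm_env(omega, env)
        assert not {"BIO1", "BIO2"} <= set(res.retained)
        assert set(res.retained) & {"BIO1", "BIO2"}

    def test_too_few_species_rejected(self):
        env = random_env(14, 5)
        omega = {"ND1": {s: 0.2 for s in env.index}}
        with pytest.raises(ValueError, match="fewer than 6"):
            glm_env(omega, env)


class TestTraitDistance:
    def test_symmetric_zero_diagonal(self):
        df = pd.DataFrame(np.random.default_rng(15).normal(size=(6, 13)),
                          index=[f"s{i}" for i in range(6)])
        d = trait_distance_matrix(df)
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.allclose(np.diag(d.matrix), 0.0)
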