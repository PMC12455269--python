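import itertools
import math

import numpy as np
import pandas as pd
import pytest

from amyspace.association import ClinicalAssociationMatrix
from amyspace.inference import (group_difference, permutation_corr_test,
                                signflip_effect_size_test,
                                similarity_of_profiles, storey_fdr)


# ---------------------------------------------------------------------------
# independent oracles

def t_oracle(d: np.ndarray) -> float:
    sd = d.std(ddof=1)
    if sd == 0:
        return math.inf * np.sign(d.mean()) if d.mean() != 0 else 0.0
    return d.mean() / (sd / math.sqrt(len(d)))


def signflip_p_oracle(d: np.ndarray) -> float:
    """Exhaustive enumeration of all 2^n sign patterns."""
    t_obs = t_oracle(d)
    count = total = 0
    for signs in itertools.product([1.0, -1.0], repeat=len(d)):
        total += 1
        if t_oracle(d * np.array(signs)) >= t_obs:
            count += 1
    return count / total


def stepup_q_oracle(p: np.ndarray) -> np.ndarray:
    """Brute-force step-up adjusted values: q_i = min over p_(j) >= p_i of
    m * p_(j) / rank(j)."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        best = min(best, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(best, 1.0)
    return q


# ---------------------------------------------------------------------------
# sign-flip effect-size test

class TestSignFlip:
    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 8), (2, 10), (3, 5)])
    def test_matches_exhaustive_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        z = rng.normal(0.35, 0.15, n)
        res = signflip_effect_size_test(z)
        d = np.abs(z) - math.atanh(0.3)
        assert res.p == pytest.approx(signflip_p_oracle(d), abs=1e-14)
        assert res.n_perm == 2**n

    def test_all_boundary_z_is_degenerate(self):
        z = np.full(8, math.atanh(0.3))
        res = signflip_effect_size_test(z)
        assert res.p == 1.0 and res.t_stat == 0.0

    def test_uniform_positive_d_hits_single_pattern(self):
        z = np.full(10, math.atanh(0.3) + 0.2)
        res = signflip_effect_size_test(z)
        assert res.p == pytest.approx(1.0 / 1024)

    def test_symmetric_d_gives_half_p(self):
        # exactly mirrored d with distinct magnitudes: T = 0 and the null is
        # symmetric with negligible mass at T* = 0, so p ~ 0.5
        mags = np.linspace(0.05, 0.2, 16)
        d = np.concatenate([mags, -mags])
        z = math.atanh(0.3) + d  # all positive, so |z| - atanh(0.3) = d
        res = signflip_effect_size_test(z, n_perm=10000, seed=4)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(0.5, abs=0.02)

    def test_reproducible_and_validated(self):
        z = np.random.default_rng(5).normal(0.4, 0.1, 35)
        a = signflip_effect_size_test(z, n_perm=500, seed=7)
        b = signflip_effect_size_test(z, n_perm=500, seed=7)
        assert a.p == b.p
        with pytest.raises(ValueError, match="at least 3"):
            signflip_effect_size_test(np.array([0.1, 0.2]))


# ---------------------------------------------------------------------------
# permutation correlation

class TestPermutationCorr:
    def test_exhaustive_identity_n5(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        r, p = permutation_corr_test(x, x)
        assert r == pytest.approx(1.0)
        # only the identity and the full reversal achieve |r| = 1
        count = sum(
            1 for perm in itertools.permutations(range(5))
            if abs(np.corrcoef(x, x[list(perm)])[0, 1]) >= 1.0 - 1e-12)
        assert p == pytest.approx(count / 120)

    def test_random_exhaustive_matches_enumeration(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        r_obs, p = permutation_corr_test(x, y)
        count = sum(
            1 for perm in itertools.permutations(range(6))
            if abs(np.corrcoef(x, y[list(perm)])[0, 1]) >= abs(r_obs) - 1e-12)
        assert p == pytest.approx(count / 720)

    def test_pairwise_complete_and_errors(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0, 6.0, 7.0, 8.0])
        y = np.arange(8.0)
        r, _ = permutation_corr_test(x, y)
        assert r == pytest.approx(1.0)
        with pytest.raises(ValueError, match="constant"):
            permutation_corr_test(np.arange(5.0), np.ones(5))

    def test_null_calibration_at_n35(self):
        rng = np.random.default_rng(2)
        rejections = 0
        reps = 400
        for i in range(reps):
            x = rng.normal(size=35)
            y = rng.normal(size=35)
            _, p = permutation_corr_test(x, y, n_perm=1000, seed=i)
            rejections += p <= 0.05
        assert abs(rejections / reps - 0.05) < 0.03


# ---------------------------------------------------------------------------
# Storey FDR

class TestStoreyFdr:
    def test_all_ones(self):
        np.testing.assert_allclose(storey_fdr(np.ones(10)), 1.0)

    def test_pi0_one_equals_stepup_oracle(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(storey_fdr(p, pi0=1.0),
                                   [0.04, 0.04, 0.04, 0.04], atol=1e-14)
        rng = np.random.default_rng(3)
        for _ in range(20):
            batch = rng.uniform(1e-6, 1.0, rng.integers(2, 60))
            np.testing.assert_allclose(storey_fdr(batch, pi0=1.0),
                                       stepup_q_oracle(batch), atol=1e-12)

    def test_single_p(self):
        assert storey_fdr([0.37], pi0=1.0)[0] == pytest.approx(0.37)

    def test_estimated_pi0_shrinks_q_under_signal(self):
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 1e-4, 50), rng.uniform(0, 1, 50)])
        q_est = storey_fdr(p)
        q_bh = storey_fdr(p, pi0=1.0)
        assert np.all(q_est <= q_bh + 1e-12)

    def test_monotone_in_sorted_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(1e-4, 1, 40)
        q = storey_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            storey_fdr([0.0, 0.5])
        with pytest.raises(ValueError, match=r"\(0, 1\]"):
            storey_fdr([0.5, 1.2])


# ---------------------------------------------------------------------------
# group differences

class TestGroupDifference:
    def _table(self):
        rng = np.random.default_rng(6)
        n = 20
        return pd.DataFrame({
            "group": np.repeat([0, 1], n // 2),
            "cont": rng.normal(size=n),
            "cat": rng.integers(0, 2, n),
        })

    def test_identical_groups_null(self):
        vals = np.arange(10.0)
        table = pd.DataFrame({"group": [0] * 10 + [1] * 10,
                              "cont": np.concatenate([vals, vals])})
        out = group_difference(table, "group")
        assert out.loc["cont", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["cont", "p"] == pytest.approx(1.0)

    def test_balanced_contingency_is_null(self):
        table = pd.DataFrame({"group": [0] * 20 + [1] * 20,
                              "cat": ([0] * 10 + [1] * 10) * 2})
        out = group_difference(table, "group")
        assert out.loc["cat", "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc["cat", "p"] == pytest.approx(1.0)

    def test_chi2_matches_hand_formula(self):
        # contingency {{20, 5}, {5, 20}}
        group = [0] * 25 + [1] * 25
        cat = [0] * 20 + [1] * 5 + [0] * 5 + [1] * 20
        table = pd.DataFrame({"group": group, "cat": cat})
        out = group_difference(table, "group")
        observed = np.array([[20, 5], [5, 20]])
        expected = np.outer(observed.sum(1), observed.sum(0)) / observed.sum()
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert out.loc["cat", "statistic"] == pytest.approx(chi2, abs=1e-12)

    def test_q_column_and_validation(self):
        out = group_difference(self._table(), "group")
        assert {"statistic", "p", "q", "test"} <= set(out.columns)
        with pytest.raises(ValueError, match="binary"):
            group_difference(pd.DataFrame({"group": [0, 1, 2], "v": [1, 2, 3.0]}),
                             "group")


# ---------------------------------------------------------------------------
# similarity

def _cam(r: pd.DataFrame, modality="m"):
    return ClinicalAssociationMatrix(modality_id=modality, r=r,
                                     n=r.notna().astype(int))


class TestSimilarity:
    def _matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.uniform(-0.8, 0.8, (4, 3)),
                            index=list("abcd"), columns=["v1", "v2", "v3"])

    def test_identical_and_negated(self):
        m = self._matrix()
        assert similarity_of_profiles(_cam(m), _cam(m)).r_sim == pytest.approx(1.0)
        assert similarity_of_profiles(_cam(-m), _cam(m)).r_sim == pytest.approx(-1.0)

    def test_missing_cells_excluded(self):
        m = self._matrix()
        holed = m.copy()
        holed.iloc[0, 0] = np.nan
        res = similarity_of_profiles(_cam(holed), _cam(m))
        assert res.n_cells == 11

    def test_label_mismatch_rejected(self):
        m = self._matrix()
        other = m.rename(index={"a": "zz"})
        with pytest.raises(ValueError, match="labels"):
            similarity_of_profiles(_cam(m), _cam(other))

    def test_permutation_p_null_calibration(self):
        # independent metric and amyloid structure -> p roughly uniform
        rng = np.random.default_rng(7)
        n_sub, rois, vars_ = 20, list("abcd"), ["v1", "v2", "v3"]
        rejections = 0
        reps = 200
        for i in range(reps):
            means = pd.DataFrame(rng.normal(size=(n_sub, 4)), columns=rois)
            clin = pd.DataFrame(rng.normal(size=(n_sub, 3)), columns=vars_)
            amy = pd.DataFrame(
                np.corrcoef(means.T @ clin.to_numpy())[:4, :4][:, :3],
                index=rois, columns=vars_)
            met = self._matrix(seed=100 + i)
            res = similarity_of_profiles(_cam(met), _cam(amy), n_perm=200,
                                         seed=i, amyloid_roi_means=means,
                                         clinical=clin)
            rejections += res.p <= 0.05
        assert rejections / reps < 0.12
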