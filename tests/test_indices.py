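"""Shannon diversity, the four distance schemes and nearest-neighbour
uniqueness, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kendalltau, spearmanr

from microaging.indices import (
    DistanceMatrix,
    diversity_adjusted_uniqueness,
    kendall_tau_b_matrix,
    pairwise_distances,
    shannon_diversity,
    uniqueness,
)
from microaging.profiles import AbundanceTable, ValidationError, clr_transform


def _table(arr, scale="counts"):
    arr = np.asarray(arr, dtype=float)
    return AbundanceTable(
        pd.DataFrame(
            arr,
            index=[f"t{i}" for i in range(arr.shape[0])],
            columns=[f"s{j}" for j in range(arr.shape[1])],
        ),
        scale=scale,
    )


def random_table(rng, n_taxa=30, n_samples=20, zero_frac=0.35):
    arr = rng.gamma(0.6, 2.0, size=(n_taxa, n_samples))
    arr[rng.random(arr.shape) < zero_frac] = 0.0
    arr[0, :] += 0.5  # no all-zero samples, no constant-rank samples
    return _table(arr)


def brute_force_distance(X, metric, clr_vals=None):
    """Double-loop reference for all four metrics."""
    n = X.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = X[:, i], X[:, j]
            if metric == "bray_curtis":
                val = np.abs(x - y).sum() / (x + y).sum()
            elif metric == "jaccard":
                px, py = x > 0, y > 0
                val = 1 - (px & py).sum() / (px | py).sum()
            elif metric == "aitchison":
                val = np.linalg.norm(clr_vals[:, i] - clr_vals[:, j])
            else:  # kendall on the union of detected taxa
                mask = (x > 0) | (y > 0)
                tau = kendalltau(x[mask], y[mask]).statistic
                val = (1 - tau) / 2
            d[i, j] = d[j, i] = val
    return d


class TestShannon:
    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0.5, 0.5], np.log(2)),
            ([1.0, 0.0], 0.0),
            ([0.5, 0.25, 0.25], 1.0397),  # -(0.5 ln 0.5 + 2 * 0.25 ln 0.25)
        ],
    )
    def test_hand_values(self, column, expected):
        t = _table(np.asarray(column)[:, None], scale="relative" if sum(column) == 1 else "counts")
        assert shannon_diversity(t).iloc[0] == pytest.approx(expected, abs=1e-4)

    def test_bounded_by_log_richness(self, rng):
        t = random_table(rng)
        h = shannon_diversity(t)
        assert (h >= 0).all()
        assert (h <= np.log(t.shape[0]) + 1e-12).all()

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValidationError):
            shannon_diversity(_table([[0.0], [0.0]]))


class TestDistances:
    @pytest.mark.parametrize("metric", ["bray_curtis", "jaccard", "aitchison", "kendall"])
    def test_matches_bruteforce(self, metric, rng):
        t = random_table(rng)
        pc = 1e-6
        dm = pairwise_distances(t, metric, pseudocount=pc)
        clr_vals = (
            clr_transform(t, pc).values.to_numpy() if metric == "aitchison" else None
        )
        ref = brute_force_distance(t.values.to_numpy(), metric, clr_vals)
        np.testing.assert_allclose(dm.values, ref, atol=1e-10)

    @pytest.mark.parametrize("metric", ["bray_curtis", "jaccard", "aitchison", "kendall"])
    def test_identical_samples_distance_zero(self, metric, rng):
        col = rng.gamma(1, 1, size=8)
        t = _table(np.column_stack([col, col, rng.gamma(1, 1, size=8) + 0.1]))
        dm = pairwise_distances(t, metric, pseudocount=1e-6)
        assert dm.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranks_kendall_is_one(self):
        x = np.arange(1, 7, dtype=float)
        t = _table(np.column_stack([x, x[::-1]]))
        dm = pairwise_distances(t, "kendall")
        assert dm.values[0, 1] == pytest.approx(1.0)

    def test_bray_curtis_hand_example(self):
        t = _table(np.array([[0.7, 0.3], [0.3, 0.7]]), scale="relative")
        dm = pairwise_distances(t, "bray_curtis")
        assert dm.values[0, 1] == pytest.approx(0.4)

    def test_aitchison_perturbation_invariance(self, rng):
        x = rng.gamma(2, 1, size=10)
        y = rng.gamma(2, 1, size=10)
        p = rng.gamma(2, 1, size=10)
        base = pairwise_distances(_table(np.column_stack([x, y])), "aitchison", pseudocount=0)
        pert = pairwise_distances(
            _table(np.column_stack([x * p, y * p])), "aitchison", pseudocount=0
        )
        assert pert.values[0, 1] == pytest.approx(base.values[0, 1], abs=1e-10)

    def test_kendall_constant_rank_sample_rejected(self):
        arr = np.ones((5, 3))
        arr[:, 1] = np.arange(1, 6)
        with pytest.raises(ValidationError, match="constant-rank"):
            kendall_tau_b_matrix(arr)

    def test_single_taxon_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_distances(_table([[1.0, 2.0]]), "bray_curtis")


class TestUniqueness:
    def test_row_minimum_hand_example(self):
        d = np.array([[0.0, 0.2, 0.5], [0.2, 0.0, 0.4], [0.5, 0.4, 0.0]])
        dm = DistanceMatrix(d, ["a", "b", "c"], "bray_curtis")
        u = uniqueness(dm, pd.Series("st", index=["a", "b", "c"]))
        np.testing.assert_allclose(u.to_numpy(), [0.2, 0.2, 0.4])

    def test_matches_bruteforce_rowmin_per_study(self, rng):
        n = 16
        d = rng.random(size=(n, n))
        d = np.triu(d, 1)
        d = d + d.T
        ids = [f"s{i}" for i in range(n)]
        groups = pd.Series(["A"] * 8 + ["B"] * 8, index=ids)
        dm = DistanceMatrix(d, ids, "jaccard" if d.max() <= 1 else "aitchison")
        u = uniqueness(dm, groups)
        for i, sid in enumerate(ids):
            same = [j for j in range(n) if groups.iloc[j] == groups.iloc[i] and j != i]
            assert u[sid] == min(d[i, j] for j in same)

    def test_duplicate_sample_gets_zero_and_no_one_increases(self, rng):
        col = rng.gamma(1, 1, size=6) + 0.1
        others = rng.gamma(1, 1, size=(6, 3)) + 0.1
        base_t = _table(np.column_stack([col, others]))
        ids = base_t.sample_ids
        g = pd.Series("st", index=ids)
        before = uniqueness(pairwise_distances(base_t, "bray_curtis"), g)
        dup_arr = np.column_stack([col, others, col])
        dup_t = _table(dup_arr)
        g2 = pd.Series("st", index=dup_t.sample_ids)
        after = uniqueness(pairwise_distances(dup_t, "bray_curtis"), g2)
        assert after.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert after.iloc[-1] == pytest.approx(0.0, abs=1e-12)
        assert (after.iloc[:4].to_numpy() <= before.to_numpy() + 1e-12).all()

    def test_singleton_study_rejected(self):
        d = np.array([[0.0, 0.1], [0.1, 0.0]])
        dm = DistanceMatrix(d, ["a", "b"], "bray_curtis")
        with pytest.raises(ValidationError, match="lonely"):
            uniqueness(dm, pd.Series({"a": "st1", "b": "lonely"}))


class TestAdjustedUniqueness:
    def test_exactly_linear_gives_zero_residuals(self, rng):
        sh = pd.Series(rng.uniform(1, 3, size=30), index=[f"s{i}" for i in range(30)])
        u = 0.3 * sh + 0.1
        g = pd.Series("st", index=sh.index)
        resid = diversity_adjusted_uniqueness(sh, u, g)
        assert np.abs(resid.to_numpy()).max() < 1e-8

    def test_slope_zero_gives_centered_uniqueness(self, rng):
        sh = pd.Series(rng.uniform(1, 3, size=200), index=[f"s{i}" for i in range(200)])
        u = pd.Series(0.5 + rng.normal(0, 1e-12, size=200), index=sh.index)
        resid = diversity_adjusted_uniqueness(sh, u, pd.Series("st", index=sh.index))
        np.testing.assert_allclose(resid.to_numpy(), (u - 0.5).to_numpy(), atol=1e-6)

    def test_planted_slope_removed(self, rng):
        n = 2000
        sh = pd.Series(rng.uniform(1, 4, size=n), index=[f"s{i}" for i in range(n)])
        u = 0.3 * sh + rng.normal(0, 0.1, size=n)
        resid = diversity_adjusted_uniqueness(sh, u, pd.Series("st", index=sh.index))
        rho = spearmanr(sh, resid).statistic
        assert abs(rho) < 0.05

    def test_constant_shannon_warns_and_centers(self):
        sh = pd.Series([2.0, 2.0, 2.0], index=list("abc"))
        u = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        with pytest.warns(RuntimeWarning, match="constant Shannon"):
            resid = diversity_adjusted_uniqueness(sh, u, pd.Series("st", index=sh.index))
        np.testing.assert_allclose(resid.to_numpy(), [-0.1, 0.0, 0.1], atol=1e-12)
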