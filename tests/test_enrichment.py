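"""Drawing-lots permutation test, hypergeometric oracle, Bonferroni, ORA."""

import math
from itertools import combinations

import numpy as np
import pytest

from mirconverge.enrichment import (
    bonferroni_adjust,
    hypergeom_tail,
    pathway_ora,
    permutation_enrichment_test,
)


def _exact_tail(M, b, n, k):
    """Independent oracle: direct binomial-coefficient arithmetic."""
    total = math.comb(M, n)
    return sum(
        math.comb(b, i) * math.comb(M - b, n - i)
        for i in range(k, min(b, n) + 1)
    ) / total


class TestHypergeomTail:
    def test_worked_example(self):
        # 1 - [C(15,4) + C(5,1)C(15,3)] / C(20,4)
        expected = 1 - (math.comb(15, 4) + math.comb(5, 1) * math.comb(15, 3)) / math.comb(20, 4)
        assert hypergeom_tail(20, 5, 4, 2) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2487, abs=5e-5)

    def test_edges(self):
        assert hypergeom_tail(20, 5, 4, 0) == 1.0
        assert hypergeom_tail(20, 0, 4, 1) == 0.0
        assert hypergeom_tail(20, 5, 4, 5) == 0.0  # k > min(b, n)

    @pytest.mark.parametrize("M,b,n", [(10, 3, 4), (25, 10, 7), (40, 20, 15)])
    def test_matches_binomial_coefficient_oracle(self, M, b, n):
        for k in range(0, min(b, n) + 1):
            assert hypergeom_tail(M, b, n, k) == pytest.approx(
                _exact_tail(M, b, n, k), rel=1e-10
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hypergeom_tail(10, 11, 4, 1)
        with pytest.raises(ValueError):
            hypergeom_tail(10, 3, 4, -1)


class TestPermutationTest:
    UNIVERSE = [f"m{i:03d}" for i in range(20)]

    def test_empirical_p_near_exact_tail(self):
        # M=20, b=5, n=4, k_obs=2
        binders = {"g": set(self.UNIVERSE[:3]) | set(self.UNIVERSE[10:12])}
        candidates = set(self.UNIVERSE[:2]) | set(self.UNIVERSE[15:17])
        n_draws = 100_000
        (rec,) = permutation_enrichment_test(
            binders, self.UNIVERSE, candidates, n_draws=n_draws, rng_seed=5
        )
        assert (rec.M, rec.b, rec.n, rec.k_obs) == (20, 5, 4, 2)
        p = rec.p_exact
        assert p == pytest.approx(_exact_tail(20, 5, 4, 2), rel=1e-10)
        assert abs(rec.p_emp - p) <= 3 * math.sqrt(p * (1 - p) / n_draws) + 1 / n_draws

    def test_saturated_binder_set_gives_p_one(self):
        binders = {"g": set(self.UNIVERSE)}  # b = M: every draw overlaps fully
        (rec,) = permutation_enrichment_test(
            binders, self.UNIVERSE, self.UNIVERSE[:4], n_draws=500, rng_seed=0
        )
        assert rec.p_emp == 1.0

    def test_zero_overlap_gives_p_one(self):
        binders = {"g": set(self.UNIVERSE[10:15])}
        candidates = set(self.UNIVERSE[:4])  # disjoint from binders
        (rec,) = permutation_enrichment_test(
            binders, self.UNIVERSE, candidates, n_draws=500, rng_seed=0
        )
        assert rec.k_obs == 0
        assert rec.p_emp == 1.0

    def test_empty_binder_set_gives_p_one(self):
        (rec,) = permutation_enrichment_test(
            {"g": set()}, self.UNIVERSE, self.UNIVERSE[:4], n_draws=200, rng_seed=0
        )
        assert rec.b == 0 and rec.p_emp == 1.0

    def test_add_one_estimator_floor(self):
        """p_emp is never 0 and never below 1/(n_draws + 1)."""
        binders = {"g": set(self.UNIVERSE[:4])}
        (rec,) = permutation_enrichment_test(
            binders, self.UNIVERSE, self.UNIVERSE[:4], n_draws=2000, rng_seed=1
        )
        assert rec.k_obs == 4
        assert rec.p_emp >= 1 / 2001

    def test_p_emp_nonincreasing_in_k_obs(self):
        """Genes with larger observed overlap never get larger p (shared draws)."""
        universe = [f"m{i:03d}" for i in range(50)]
        candidates = universe[:10]
        b = 20
        binders = {
            f"g{k}": set(candidates[:k]) | set(universe[10:10 + b - k])
            for k in range(0, 11)
        }
        recs = permutation_enrichment_test(
            binders, universe, candidates, n_draws=20_000, rng_seed=9
        )
        by_k = {r.k_obs: r.p_emp for r in recs}
        assert sorted(by_k) == list(range(11))
        ps = [by_k[k] for k in range(11)]
        assert all(a >= b_ for a, b_ in zip(ps, ps[1:]))

    def test_candidates_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            permutation_enrichment_test(
                {"g": set()}, self.UNIVERSE, {"not-there"}, n_draws=10
            )

    def test_binders_outside_universe_are_ignored(self):
        binders = {"g": {"m000", "m001", "alien"}}
        (rec,) = permutation_enrichment_test(
            binders, self.UNIVERSE, self.UNIVERSE[:4], n_draws=100, rng_seed=2
        )
        assert rec.b == 2

    def test_deterministic_under_fixed_seed(self):
        binders = {"g": set(self.UNIVERSE[:5])}
        args = (binders, self.UNIVERSE, set(self.UNIVERSE[:4]))
        r1 = permutation_enrichment_test(*args, n_draws=5000, rng_seed=3)
        r2 = permutation_enrichment_test(*args, n_draws=5000, rng_seed=3)
        assert r1 == r2


class TestBonferroni:
    def test_threshold_matches_alpha_over_g(self):
        p_adj, thr = bonferroni_adjust([0.001] * 180, alpha=0.05)
        assert thr == pytest.approx(0.05 / 180, rel=1e-12)
        # the conventional printed truncation of 0.05/180
        assert 2.77e-4 < thr < 2.78e-4
        assert np.allclose(p_adj, 0.18)

    def test_single_test_is_identity(self):
        p_adj, thr = bonferroni_adjust([0.03], alpha=0.05)
        assert thr == 0.05
        assert p_adj[0] == pytest.approx(0.03)

    def test_adjusted_p_capped_at_one(self):
        p_adj, _ = bonferroni_adjust([0.9, 0.5, 0.5, 0.5, 0.5], alpha=0.05)
        assert p_adj[0] == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([])
        with pytest.raises(ValueError):
            bonferroni_adjust([0.0, 0.5])
        with pytest.raises(ValueError):
            bonferroni_adjust([0.5], alpha=1.5)


class TestPathwayORA:
    def test_perfect_overlap_reduces_to_hypergeometric_minimum(self):
        background = [f"x{i}" for i in range(100)]
        query = set(background[:10])
        df = pathway_ora(query, {"S": query}, background)
        assert df.loc[0, "overlap"] == 10
        assert df.loc[0, "p"] == pytest.approx(hypergeom_tail(100, 10, 10, 10), rel=1e-12)
        assert df.loc[0, "p"] == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_disjoint_sets_give_p_one(self):
        background = [f"x{i}" for i in range(30)]
        df = pathway_ora(set(background[:5]), {"S": set(background[20:25])}, background)
        assert df.loc[0, "overlap"] == 0
        assert df.loc[0, "p"] == 1.0

    def test_matches_exhaustive_enumeration_oracle(self):
        """On universes small enough to enumerate every possible query draw,
        the ORA p equals the exact fraction of draws with >= k overlap."""
        rng = np.random.default_rng(23)
        for _ in range(25):
            M = int(rng.integers(6, 13))
            background = [f"x{i}" for i in range(M)]
            n = int(rng.integers(1, M))
            set_size = int(rng.integers(1, M))
            query = set(rng.choice(background, size=n, replace=False))
            ann = set(rng.choice(background, size=set_size, replace=False))
            k = len(query & ann)
            if k == 0:
                continue
            count = sum(
                1
                for draw in combinations(background, n)
                if len(set(draw) & ann) >= k
            )
            expected = count / math.comb(M, n)
            df = pathway_ora(query, {"S": ann}, background)
            assert df.loc[0, "p"] == pytest.approx(expected, rel=1e-9)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            pathway_ora(set(), {"S": {"a"}}, [])
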