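"""Spearman correlation, cluster formation, and the permutation test,
each checked against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betacoh.permutation import (
    correlation_map,
    form_clusters,
    permutation_test,
    spearman_rho,
)

# ---------------------------------------------------------------- oracles


def _avg_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) computed from first principles."""
    x = np.asarray(x, dtype=float)
    out = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        out[i] = less + (equal + 1) / 2.0
    return out


def _spearman_oracle(x, y) -> float:
    """Pearson correlation of average ranks, written out longhand."""
    rx, ry = _avg_ranks(x), _avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def _flood_fill_clusters(mask: np.ndarray) -> list[set]:
    """Orthogonal connected components by explicit flood fill."""
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                comp, stack = set(), [(i, j)]
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    comp.add((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = a + da, b + db
                        if (0 <= na < mask.shape[0] and 0 <= nb < mask.shape[1]
                                and mask[na, nb] and not seen[na, nb]):
                            seen[na, nb] = True
                            stack.append((na, nb))
                comps.append(comp)
    return comps


# ---------------------------------------------------------------- spearman


class TestSpearman:
    def test_perfect_monotone(self):
        rho, p = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-6

    def test_perfect_inverse(self):
        x = np.arange(6.0)
        rho, _ = spearman_rho(x, -x)
        assert rho == -1.0

    def test_textbook_example(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([3, 1, 4, 2, 5.0])
        d = _avg_ranks(x) - _avg_ranks(y)
        expect = 1 - 6 * (d**2).sum() / (5 * (25 - 1))
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(expect)

    @given(
        data=st.lists(
            st.tuples(st.integers(-5, 5), st.integers(-5, 5)),
            min_size=4, max_size=12,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_rank_formula_oracle(self, data):
        x = np.array([a for a, _ in data], dtype=float)
        y = np.array([b for _, b in data], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            with pytest.raises(ValueError):
                spearman_rho(x, y)
            return
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(_spearman_oracle(x, y), abs=1e-12)

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2, 3])


class TestCorrelationMap:
    def test_linear_maps_give_rho_one(self, rng):
        diffs = rng.standard_normal(8)
        maps = 2.0 * diffs[:, None, None] + np.zeros((8, 3, 4))
        rho, p = correlation_map(diffs, maps)
        assert np.allclose(rho, 1.0)
        assert np.all(p < 1e-6)

    def test_constant_maps_all_flagged(self, rng):
        diffs = rng.standard_normal(6)
        maps = np.ones((6, 2, 3))
        rho, p = correlation_map(diffs, maps)
        assert np.isnan(rho).all() and np.isnan(p).all()

    def test_misaligned_subject_ids_rejected(self, rng):
        diffs = rng.standard_normal(5)
        maps = rng.standard_normal((5, 2, 2))
        with pytest.raises(ValueError):
            correlation_map(diffs, maps, subject_ids=list("abcde"),
                            map_ids=list("abced"))

    def test_incomplete_subjects_dropped_pairwise(self, rng):
        diffs = rng.standard_normal(7)
        maps = rng.standard_normal((7, 2, 2))
        maps[3, 0, 0] = np.nan
        rho_full, _ = correlation_map(diffs, maps)
        keep = np.arange(7) != 3
        rho_drop, _ = correlation_map(diffs[keep], maps[keep])
        assert np.allclose(rho_full, rho_drop)

    def test_too_few_complete_subjects(self, rng):
        diffs = rng.standard_normal(4)
        maps = rng.standard_normal((4, 2, 2))
        maps[0] = np.nan
        with pytest.raises(ValueError):
            correlation_map(diffs, maps)


# ---------------------------------------------------------------- clusters


class TestFormClusters:
    def test_l_shaped_region_one_cluster(self):
        p = np.ones((3, 3))
        rho = np.zeros((3, 3))
        for (i, j) in [(0, 0), (1, 0), (1, 1)]:
            p[i, j] = 0.01
            rho[i, j] = 0.5
        cl = form_clusters(p, rho)
        assert len(cl) == 1
        assert sorted(cl[0].cells) == [(0, 0), (1, 0), (1, 1)]
        assert cl[0].mass == pytest.approx(1.5)

    def test_diagonal_cells_separate(self):
        p = np.ones((2, 2))
        rho = np.zeros((2, 2))
        p[0, 0] = p[1, 1] = 0.01
        rho[0, 0] = rho[1, 1] = 0.4
        assert len(form_clusters(p, rho)) == 2

    def test_sign_separation(self):
        p = np.full((1, 2), 0.01)
        rho = np.array([[0.5, -0.5]])
        cl = form_clusters(p, rho)
        assert len(cl) == 2
        assert {c.sign for c in cl} == {"positive", "negative"}

    def test_no_supra_threshold_cells(self):
        assert form_clusters(np.ones((3, 3)), np.zeros((3, 3))) == []

    @given(seed=st.integers(0, 100_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_flood_fill_oracle(self, seed):
        r = np.random.default_rng(seed)
        p = r.random((6, 6))
        rho = r.standard_normal((6, 6))
        cl = form_clusters(p, rho, alpha=0.3)
        got = sorted(frozenset(c.cells) for c in cl)
        expect = []
        for sign in (1, -1):
            mask = (p < 0.3) & (np.sign(rho) == sign)
            expect.extend(frozenset(c) for c in _flood_fill_clusters(mask))
        assert got == sorted(expect)
        for c in cl:
            assert c.mass == pytest.approx(
                sum(abs(rho[i, j]) for (i, j) in c.cells)
            )
            assert c.mass > 0


# ---------------------------------------------------------------- permutation


class TestPermutationTest:
    def test_deterministic_from_seed(self, rng):
        diffs = rng.standard_normal(10)
        maps = rng.standard_normal((10, 4, 5))
        a = permutation_test(diffs, maps, n_perm=150, seed=5)
        b = permutation_test(diffs, maps, n_perm=150, seed=5)
        assert np.array_equal(a.null_max_mass, b.null_max_mass)
        assert [c.significant for c in a.clusters] == [
            c.significant for c in b.clusters
        ]

    def test_exhaustive_permutations_for_small_n(self, rng):
        diffs = rng.standard_normal(5)
        maps = rng.standard_normal((5, 3, 3))
        res = permutation_test(diffs, maps, n_perm=1000, seed=1)
        assert res.n_perm == 120  # 5! distinct permutations, each used once

    def test_null_invariant_to_subject_relabeling(self, rng):
        """Exchangeability: relabeling subjects consistently in both inputs
        leaves the (exhaustive) null distribution unchanged."""
        diffs = rng.standard_normal(5)
        maps = rng.standard_normal((5, 3, 3))
        perm = rng.permutation(5)
        a = permutation_test(diffs, maps, n_perm=1000, seed=2)
        b = permutation_test(diffs[perm], maps[perm], n_perm=1000, seed=7)
        assert np.allclose(np.sort(a.null_max_mass), np.sort(b.null_max_mass))

    def test_permutation_p_formula(self, rng):
        diffs = rng.standard_normal(9)
        maps = rng.standard_normal((9, 4, 4))
        res = permutation_test(diffs, maps, n_perm=200, seed=3)
        for c in res.clusters:
            expect = (1 + int((res.null_max_mass >= c.mass).sum())) / (1 + res.n_perm)
            assert c.p_perm == pytest.approx(expect)
            assert c.significant == (c.mass > res.null_quantile)

    def test_planted_effect_detected(self):
        from betacoh.validation import planted_dataset

        rng = np.random.default_rng(11)
        diffs, maps, mask = planted_dataset(rng, n_subjects=20, rho=0.8)
        res = permutation_test(diffs, maps, n_perm=300, seed=4)
        sig = [c for c in res.clusters if c.significant]
        assert any(mask[i, j] for c in sig for (i, j) in c.cells)

    def test_n_perm_floor(self, rng):
        with pytest.raises(ValueError):
            permutation_test(rng.standard_normal(6),
                             rng.standard_normal((6, 2, 2)), n_perm=50)
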