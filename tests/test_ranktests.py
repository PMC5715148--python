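"""Friedman, Conover post hoc, BH adjustment, compact letter display.

Oracles: an independently coded ranks-and-formula evaluation (loops,
no shared code), scipy's Friedman implementation, and exhaustive
within-block permutation enumeration on tiny tables.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from isoforage import conover_pairwise, friedman, letter_display
from isoforage.errors import ValidationError

TOY_4x3 = np.array(
    [
        [7.1, 4.9, 1.2],
        [8.3, 6.6, 2.4],
        [4.4, 6.1, 1.9],
        [9.0, 4.2, 3.3],
    ]
)


def oracle_friedman_statistic(x):
    """Tie-corrected Friedman statistic via explicit loops (independent
    of the package's vectorized rank machinery)."""
    b, k = x.shape
    ranks = []
    for row in x:
        order = sorted(range(k), key=lambda j: row[j])
        r = [0.0] * k
        j = 0
        while j < k:
            tied = [order[j]]
            while j + len(tied) < k and row[order[j + len(tied)]] == row[order[j]]:
                tied.append(order[j + len(tied)])
            avg = sum(range(j + 1, j + len(tied) + 1)) / len(tied)
            for t in tied:
                r[t] = avg
            j += len(tied)
        ranks.append(r)
    rj = [sum(ranks[i][j] for i in range(b)) for j in range(k)]
    a = sum(ranks[i][j] ** 2 for i in range(b) for j in range(k))
    c = b * k * (k + 1) ** 2 / 4.0
    if a == c:
        return 0.0
    return (k - 1) * sum((r - b * (k + 1) / 2.0) ** 2 for r in rj) / (a - c)


def oracle_conover_p(x):
    """Textbook Conover Friedman post hoc, coded independently."""
    b, k = x.shape
    ranks = np.array([stats.rankdata(row) for row in x])
    rj = ranks.sum(axis=0)
    a = (ranks**2).sum()
    bb = (rj**2).sum() / b
    dof = (b - 1) * (k - 1)
    out = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            se = np.sqrt(2 * b * (a - bb) / dof)
            if se == 0.0:
                out[i, j] = 1.0 if rj[i] == rj[j] else 0.0
            else:
                t = abs(rj[i] - rj[j]) / se
                out[i, j] = min(1.0, 2 * stats.t.sf(t, dof))
    return out


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        table = np.tile([[3.0, 3.0, 3.0]], (5, 1))
        res = friedman(table)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_toy_table_matches_loop_oracle_and_no_tie_closed_form(self):
        res = friedman(TOY_4x3)
        assert res.statistic == pytest.approx(oracle_friedman_statistic(TOY_4x3), abs=1e-12)
        # no ties here, so the classic closed form applies
        b, k = TOY_4x3.shape
        rj = np.array([stats.rankdata(row) for row in TOY_4x3]).sum(axis=0)
        closed = 12.0 / (b * k * (k + 1)) * (rj**2).sum() - 3 * b * (k + 1)
        assert res.statistic == pytest.approx(closed, abs=1e-12)
        assert res.df == 2

    def test_agrees_with_scipy_with_and_without_ties(self, rng):
        for trial in range(20):
            x = rng.integers(0, 5, size=(6, 4)).astype(float)  # many ties
            ours = friedman(x)
            if np.all(x == x[:, [0]]):
                continue
            try:
                ref = stats.friedmanchisquare(*x.T)
            except ValueError:
                continue
            assert ours.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-10)

    def test_k2_reduces_to_sign_test_statistic(self, rng):
        for _ in range(10):
            x = rng.normal(size=(8, 2))
            wins2 = int((x[:, 1] > x[:, 0]).sum())
            wins1 = 8 - wins2
            assert friedman(x).statistic == pytest.approx((wins2 - wins1) ** 2 / 8.0)

    def test_missing_cell_rejected(self):
        x = TOY_4x3.copy()
        x[0, 0] = np.nan
        with pytest.raises(ValidationError):
            friedman(x)

    @given(
        table=st.lists(
            st.lists(st.integers(-3, 3), min_size=3, max_size=3),
            min_size=3, max_size=5,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_invariant_under_blockwise_monotone_transform(self, table):
        x = np.array(table, dtype=float)
        transformed = np.exp(0.7 * x) + 2.0  # strictly increasing map
        assert friedman(x).statistic == pytest.approx(
            friedman(transformed).statistic, abs=1e-9
        )


class TestExhaustivePermutationOracle:
    """On every table with b <= 4, k <= 3, the implementation must agree
    with brute-force evaluation over all within-block orderings."""

    @pytest.mark.parametrize("b,k", [(3, 3), (4, 3), (4, 2)])
    def test_statistic_matches_oracle_for_all_permutations(self, b, k, rng):
        base = rng.normal(size=(b, k))
        perms = list(itertools.permutations(range(k)))
        for combo in itertools.islice(itertools.product(perms, repeat=b), 0, None, 7):
            x = np.array([base[i, list(combo[i])] for i in range(b)])
            assert friedman(x).statistic == pytest.approx(
                oracle_friedman_statistic(x), abs=1e-10
            )

    def test_chi2_p_consistent_with_exact_permutation_p(self, rng):
        x = TOY_4x3
        obs = friedman(x).statistic
        perms = list(itertools.permutations(range(3)))
        all_stats = [
            oracle_friedman_statistic(np.array([x[i, list(c[i])] for i in range(4)]))
            for c in itertools.product(perms, repeat=4)
        ]
        p_exact = np.mean([s >= obs - 1e-12 for s in all_stats])
        assert friedman(x).pvalue == pytest.approx(p_exact, abs=0.1)

    def test_conover_matches_textbook_oracle_on_permuted_tables(self, rng):
        base = rng.normal(size=(3, 3))
        perms = list(itertools.permutations(range(3)))
        for combo in itertools.islice(itertools.product(perms, repeat=3), 0, None, 5):
            x = np.array([base[i, list(combo[i])] for i in range(3)])
            res = conover_pairwise(x)
            np.testing.assert_allclose(res.raw_p, oracle_conover_p(x), atol=1e-12)


class TestConover:
    def test_identical_columns_all_p_one(self):
        table = np.tile([[2.0, 2.0, 2.0]], (4, 1))
        res = conover_pairwise(table)
        assert np.all(res.raw_p == 1.0)
        assert np.all(res.adjusted_p == 1.0)
        assert res.letters == ["a", "a", "a"]

    def test_toy_matches_hand_evaluation(self):
        res = conover_pairwise(TOY_4x3)
        np.testing.assert_allclose(res.raw_p, oracle_conover_p(TOY_4x3), atol=1e-12)

    def test_bh_step_up_arithmetic(self):
        # p*(m/i) = (.04, .04, .04, .5); the step-up minimum keeps them
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_adjusted_dominate_raw_and_preserve_order(self, rng):
        x = rng.normal(size=(6, 5))
        res = conover_pairwise(x)
        iu = np.triu_indices(5, 1)
        raw, adj = res.raw_p[iu], res.adjusted_p[iu]
        assert np.all(adj >= raw - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        p = np.ones((4, 4))
        assert letter_display(p) == ["a", "a", "a", "a"]

    def test_all_pairs_significant_distinct_letters(self):
        p = np.full((4, 4), 0.001)
        np.fill_diagonal(p, 1.0)
        letters = letter_display(p)
        assert len(set(letters)) == 4

    def test_chain_structure_a_ab_b(self):
        p = np.ones((3, 3))
        p[0, 2] = p[2, 0] = 0.01  # only the outer pair differs
        assert letter_display(p) == ["a", "ab", "b"]

    def test_sharing_iff_not_significant(self, rng):
        for _ in range(20):
            p = np.ones((5, 5))
            iu = np.triu_indices(5, 1)
            vals = rng.uniform(0, 0.2, len(iu[0]))
            p[iu] = vals
            p.T[iu] = vals
            letters = letter_display(p, alpha=0.05)
            for i in range(5):
                for j in range(i + 1, 5):
                    share = bool(set(letters[i]) & set(letters[j]))
                    assert share == (p[i, j] >= 0.05), (p, letters)
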