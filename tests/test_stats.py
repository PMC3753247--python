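"""Exact binomial tests, Bonferroni, significance boundaries, t-tests."""

import math
from fractions import Fraction

import numpy as np
import pytest

from pupilrps.game import SessionResult, Strategy, play_choices
from pupilrps.stats import (
    binomial_tail,
    bonferroni,
    learning_curve,
    significance_boundary,
    t_tests,
)


def exact_tail(n: int, k: int, p=Fraction(1, 3)) -> Fraction:
    """Independent oracle: exact rational term-by-term summation of
    sum_{k<=i<=n} C(n,i) p^i (1-p)^(n-i)."""
    return sum(
        Fraction(math.comb(n, i)) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


def test_binomial_tail_matches_rational_oracle_exhaustively():
    for n in range(1, 31):
        for k in range(0, n + 1):
            expected = float(exact_tail(n, k))
            got = binomial_tail(n, k).p_value
            assert got == pytest.approx(expected, rel=1e-12)


def test_binomial_tail_reference_value():
    """37 wins in 75 games at chance 1/3 has tail probability 0.003."""
    r = binomial_tail(75, 37)
    assert r.p_rounded == 0.003
    assert r.p_value == pytest.approx(float(exact_tail(75, 37)), rel=1e-12)


@pytest.mark.parametrize("n", [1, 7, 50, 100])
def test_binomial_tail_normalizes_at_k_zero(n):
    assert binomial_tail(n, 0).p_value == pytest.approx(1.0, rel=1e-14)


def test_binomial_tail_single_game():
    assert binomial_tail(1, 1).p_value == pytest.approx(1 / 3)


def test_binomial_tail_monotone_in_k():
    for n in (10, 75):
        tails = [binomial_tail(n, k).p_value for k in range(n + 1)]
        assert all(a > b for a, b in zip(tails, tails[1:]))


def test_binomial_tail_input_validation():
    with pytest.raises(ValueError):
        binomial_tail(10, 11)
    with pytest.raises(ValueError):
        binomial_tail(10, -1)
    with pytest.raises(ValueError):
        binomial_tail(10, 5, p_chance=1.0)


def test_significance_flag_uses_corrected_level():
    r = binomial_tail(75, 37, alpha=0.05, n_comparisons=10)
    assert r.alpha_corrected == 0.005
    assert r.significant  # 0.003 < 0.005
    assert not binomial_tail(75, 36, alpha=0.05, n_comparisons=10).significant


@pytest.mark.parametrize("alpha, m, expected", [(0.05, 10, 0.005), (0.05, 1, 0.05),
                                                (0.05, 5, 0.01)])
def test_bonferroni(alpha, m, expected):
    assert bonferroni(alpha, m) == pytest.approx(expected)


def test_bonferroni_rejects_zero_comparisons():
    with pytest.raises(ValueError):
        bonferroni(0.05, 0)


def test_significance_boundary_small_n_impossible():
    # even all wins cannot reach 0.05 for n <= 2 (tails 1/3 and 1/9);
    # n = 3 is the first where 3/3 wins qualifies ((1/3)^3 < 0.05)
    b = significance_boundary(3, alpha=0.05)
    assert b.k_min.tolist() == [-1, -1, 3]


def test_significance_boundary_brute_force_agreement():
    """Boundary equals the least k whose oracle tail is below alpha."""
    b = significance_boundary(60, alpha=0.05)
    for n in (5, 10, 20, 40, 60):
        brute = next(
            (k for k in range(n + 1) if exact_tail(n, k) < Fraction(1, 20)), -1
        )
        assert b.k_min[n - 1] == brute


def test_significance_boundary_at_75():
    b = significance_boundary(75, alpha=0.05)
    k75 = b.k_min[74]
    assert binomial_tail(75, int(k75)).p_value < 0.05
    assert binomial_tail(75, int(k75) - 1).p_value >= 0.05
    assert k75 <= 37  # 37/75 (tail 0.003) is comfortably significant


def test_boundary_properties_monotone_and_decreasing_fraction():
    b = significance_boundary(200, alpha=0.05)
    k = b.k_min
    defined = k >= 0
    assert (np.diff(k[defined]) >= 0).all()  # k_min nondecreasing in n
    frac = b.boundary_fraction()
    # the boundary fraction approaches chance from above
    assert np.nanmin(frac) > 1 / 3
    assert frac[199] < frac[np.argmax(defined)]


def _session_from_outcomes(outcomes):
    n = len(outcomes)
    return SessionResult(
        [f"g{i}" for i in range(n)],
        np.zeros(n, dtype=int),
        np.zeros(n, dtype=int),
        np.asarray(outcomes, dtype=int),
    )


def test_learning_curve_all_wins_reaches_significance_early():
    lc = learning_curve(_session_from_outcomes([1] * 75), alpha=0.05, m_comparisons=10)
    assert lc.first_significant_game is not None
    assert lc.first_significant_game < 20
    # the first flagged game really is the first below the corrected level
    first = lc.first_significant_game
    assert lc.p_values[first - 1] < 0.005
    assert (lc.p_values[: first - 1] >= 0.005).all()


def test_learning_curve_all_losses_never_significant():
    lc = learning_curve(_session_from_outcomes([-1] * 75))
    assert lc.first_significant_game is None


def test_learning_curve_endpoint_depends_only_on_totals():
    """37 wins by game 75 is significant at 0.005 regardless of order."""
    rng = np.random.default_rng(5)
    outcomes = np.array([1] * 37 + [-1] * 38)
    for _ in range(3):
        rng.shuffle(outcomes)
        lc = learning_curve(_session_from_outcomes(outcomes), m_comparisons=10)
        assert lc.p_values[-1] == pytest.approx(binomial_tail(75, 37).p_value)
        assert lc.p_values[-1] < 0.005


def test_t_test_against_constant_chance():
    g = [0.6, 0.55, 0.62, 0.58, 0.61]
    r = t_tests(g, kind="one_sample", popmean=1 / 3)
    assert r.df == 4
    assert r.t > 0
    assert r.p_value < 0.01


def test_t_test_group_equal_to_chance_gives_p_one():
    r = t_tests([1 / 3] * 5, kind="one_sample", popmean=1 / 3)
    assert r.t == 0.0
    assert r.p_value == 1.0


def test_t_test_zero_variance_unequal_means_warns():
    with pytest.warns(RuntimeWarning):
        r = t_tests([0.6] * 5, kind="one_sample", popmean=1 / 3)
    assert r.p_value == 0.0
    assert math.isinf(r.t)


def test_paired_t_test_identical_groups():
    g = [0.4, 0.5, 0.6]
    r = t_tests(g, g, kind="paired")
    assert r.t == 0.0 and r.p_value == 1.0


def test_unpaired_t_test_pooled_df():
    a = [0.5, 0.6, 0.55, 0.65]
    b = [0.3, 0.35, 0.32]
    r = t_tests(a, b, kind="unpaired")
    assert r.df == 5
    assert r.p_value < 0.05


def test_t_test_input_validation():
    with pytest.raises(ValueError):
        t_tests([0.5], kind="one_sample")
    with pytest.raises(ValueError):
        t_tests([0.5, 0.6], [0.1, 0.2, 0.3], kind="paired")
    with pytest.raises(ValueError):
        t_tests([0.5, 0.6], kind="sign_test")


def test_type_one_error_rate_under_null_strategy():
    """Fraction of uniform-random 75-game sessions declared significant at
    the corrected 0.005 level stays at or below nominal (+3 SE)."""
    rng = np.random.default_rng(17)
    n_sessions, n_games = 1000, 75
    hits = 0
    for _ in range(n_sessions):
        opp = rng.integers(0, 3, size=n_games)
        s = play_choices(opp, Strategy.uniform_random(), rng=rng)
        hits += binomial_tail(n_games, s.n_wins, alpha=0.05, n_comparisons=10).significant
    rate = hits / n_sessions
    se = np.sqrt(0.005 * 0.995 / n_sessions)
    assert rate <= 0.005 + 3 * se
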