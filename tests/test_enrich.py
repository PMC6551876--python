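"""Fisher 2x2 machinery, transition grid, and the signed-rank test."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from monometh.enrich import (
    P_CAP, expression_shift, feature_enrichment, fisher_2x2, fisher_margin_p,
    results_to_frame, tf_binding_gain, transition_matrix,
)


def fisher_oracle(a, b, c, d):
    """Exact-integer two-sided probability-mass p (independent route).

    Uses math.comb and Fraction throughout; the 1e-7 relative tie slack is
    applied in integer arithmetic.
    """
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n - (N - K)), min(n, K)
    num = {k: comb(K, k) * comb(N - K, n - k) for k in range(lo, hi + 1)}
    scale = 10**7
    total = sum(m for m in num.values() if m * scale <= num[a] * (scale + 1))
    return float(min(Fraction(total, comb(N, n)), 1))


def test_fisher_worked_example():
    odds, p, pc = fisher_2x2(12, 5, 3, 9)
    assert np.isclose(odds, (12 * 9) / (5 * 3))
    assert np.isclose(p, fisher_oracle(12, 5, 3, 9), rtol=1e-12)
    assert pc == p


def test_fisher_degenerate_tables():
    odds, p, _ = fisher_2x2(0, 10, 0, 10)
    assert np.isnan(odds) and p == 1.0
    odds, _, _ = fisher_2x2(5, 0, 3, 2)
    assert odds == np.inf
    odds, _, _ = fisher_2x2(0, 5, 3, 2)
    assert odds == 0.0
    with pytest.raises(ValueError):
        fisher_2x2(-1, 2, 3, 4)
    with pytest.raises(ValueError):
        fisher_2x2(0, 0, 0, 0)


def test_fisher_matches_scipy_reference():
    """Dual-route check against an established implementation."""
    rng = np.random.default_rng(8)
    for _ in range(300):
        a, b, c, d = (int(x) for x in rng.integers(0, 60, 4))
        if a + b + c + d == 0:
            continue
        p = fisher_2x2(a, b, c, d)[1]
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert np.isclose(p, ref, rtol=1e-9), (a, b, c, d)


def test_fisher_margin_class_consistency():
    """fisher_margin_p rows equal fisher_2x2 called table by table."""
    for N, K, n in [(20, 7, 9), (30, 15, 15), (12, 0, 5), (9, 9, 4)]:
        lo, hi = max(0, n - (N - K)), min(n, K)
        ps = fisher_margin_p(N, K, n)
        for i, a in enumerate(range(lo, hi + 1)):
            b, c, d = n - a, K - a, (N - K) - (n - a)
            assert np.isclose(ps[i], fisher_2x2(a, b, c, d)[1], rtol=1e-14)


def test_p_cap_floor():
    _, p, pc = fisher_2x2(500, 10, 10, 500)
    assert p < P_CAP and pc == P_CAP


def test_results_frame_and_log2():
    res = feature_enrichment(
        pd.Index(["a", "b"]),
        pd.Series({"a": True, "b": False, "c": True, "d": False, "e": False}),
        pd.Index(["c", "d", "e"]))
    tab = results_to_frame(res)
    assert tab.loc[0, ["a", "b", "c", "d"]].tolist() == [1, 1, 1, 2]
    assert np.isclose(tab.loc[0, "log2_or"],
                      np.log2(tab.loc[0, "odds_ratio"]))


def test_feature_enrichment_strata_counts():
    feature = pd.Series(True, index=[f"p{i}" for i in range(10)])
    strata = pd.Series(
        ["E"] * 4 + ["Q"] * 6, index=feature.index)
    targets = pd.Index(["p0", "p1", "p4"])
    background = feature.index.difference(targets)
    res = feature_enrichment(targets, feature, background, strata=strata)
    by = {r.stratum: r for r in res}
    assert (by["E"].a, by["E"].b, by["E"].c, by["E"].d) == (2, 1, 2, 5)
    assert (by["Q"].a, by["Q"].b, by["Q"].c, by["Q"].d) == (1, 2, 5, 2)
    for r in res:
        assert r.a + r.b == len(targets)
        assert r.c + r.d == len(background)


def test_transition_matrix_counts_and_flags():
    gain = pd.Index(["g1", "g2", "g3"])
    loss = pd.Index(["l1", "l2"])
    s_mono = pd.Series({"g1": "Q", "g2": "Q", "g3": "E", "l1": "Q", "l2": "E",
                        "x": "Q"})
    s_mac = pd.Series({"g1": "Q", "g2": "Q", "g3": "E", "l1": "E", "l2": "E",
                       "x": None})
    out = transition_matrix(gain, loss, s_mono, s_mac)
    qq = out[(out.state_mono == "Q") & (out.state_mac == "Q")].iloc[0]
    assert (qq.a, qq.b, qq.c, qq.d) == (2, 1, 0, 2)
    qe = out[(out.state_mono == "Q") & (out.state_mac == "E")].iloc[0]
    assert (qe.a, qe.c) == (0, 1)
    assert qe.odds_ratio == 0.0 and qe.flagged
    empty = out[(out.state_mono == "E") & (out.state_mac == "Q")].iloc[0]
    assert np.isnan(empty.odds_ratio) and empty.flagged
    assert out.attrs["n_excluded"] == 0


def test_transition_matrix_excludes_no_call():
    gain = pd.Index(["g1", "x"])
    loss = pd.Index(["l1"])
    s_mono = pd.Series({"g1": "Q", "x": "Q", "l1": "Q"})
    s_mac = pd.Series({"g1": "Q", "x": None, "l1": "E"})
    out = transition_matrix(gain, loss, s_mono, s_mac)
    assert out.attrs["n_excluded"] == 1
    assert out["a"].sum() == 1 and out["c"].sum() == 1


def test_tf_binding_gain():
    gain = pd.Index(["g1", "g2"])
    bg = pd.Index(["b1", "b2", "b3"])
    binding = pd.Series({"g1": True, "g2": True, "b1": False, "b2": True,
                         "b3": False})
    delta = pd.Series({"g1": 0.2, "g2": -0.1, "b1": 0.0, "b2": 0.0, "b3": 0.0})
    res, mean_pct = tf_binding_gain(gain, bg, binding, delta, "CEBP_like")
    assert (res.a, res.b, res.c, res.d) == (2, 0, 1, 2)
    assert np.isclose(mean_pct, 15.0)
    with pytest.raises(ValueError, match="no motif-overlapping"):
        tf_binding_gain(pd.Index([]), bg, binding, delta, "CEBP_like")


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _expr(diffs, base=1.0):
    genes = [f"g{i}" for i in range(len(diffs))]
    return genes, pd.DataFrame(
        {"monocyte": base, "macrophage": base + np.asarray(diffs)}, index=genes)


def signed_rank_oracle(diffs):
    """Two-sided exact p by full sign-assignment enumeration."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=n)]
    ws = np.asarray(ws)
    lo = (ws <= w_obs + 1e-9).mean()
    hi = (ws >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(lo, hi))


def test_expression_shift_all_positive_six_genes():
    genes, expr = _expr([0.5, 0.8, 1.1, 0.3, 0.9, 0.7])
    w, p, med = expression_shift(genes, expr)
    assert np.isclose(p, 2 / 64)
    assert np.isclose(med, 0.75)


def test_expression_shift_zero_differences():
    genes, expr = _expr([0.0] * 6)
    w, p, med = expression_shift(genes, expr)
    assert p == 1.0 and med == 0.0


def test_expression_shift_matches_enumeration():
    rng = np.random.default_rng(9)
    for n in (5, 6, 8, 10):
        for _ in range(5):
            diffs = rng.normal(0, 1, n)
            genes, expr = _expr(diffs)
            _, p, _ = expression_shift(genes, expr)
            assert np.isclose(p, signed_rank_oracle(diffs), atol=1e-12)


def test_expression_shift_requires_five_genes():
    genes, expr = _expr([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match=">=5"):
        expression_shift(genes, expr)


def test_expression_shift_deduplicates_and_filters():
    genes, expr = _expr([0.5, 0.8, 1.1, 0.3, 0.9])
    got = expression_shift(genes + genes + ["absent"], expr)
    assert np.isclose(got[1], signed_rank_oracle([0.5, 0.8, 1.1, 0.3, 0.9]),
                      atol=1e-12)
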