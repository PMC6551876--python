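"""Paired within-donor ANOVA, FDR, and DMC classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from monometh.ewas import (
    DEFAULT_STATES, bh_fdr, call_dmcs, effect_concordance, ewas_scan,
    fit_paired_anova,
)


def anova_oracle(y):
    """Definitional two-way ANOVA via explicit residuals (independent route)."""
    n, k = y.shape
    grand = y.mean()
    state_means = np.array([y[:, c].mean() for c in range(k)])
    donor_means = np.array([y[d, :].mean() for d in range(n)])
    ss_state = n * sum((m - grand) ** 2 for m in state_means)
    ss_res = sum(
        (y[d, c] - state_means[c] - donor_means[d] + grand) ** 2
        for d in range(n) for c in range(k)
    )
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms, ms_res = ss_state / df1, ss_res / df2
    F = ms / ms_res
    p = stats.f.sf(F, df1, df2)
    se = np.sqrt(ms_res * df1 / (n * k))
    t = (state_means - grand) / se
    return ms, F, p, t, state_means


def test_anova_matches_definitional_oracle():
    rng = np.random.default_rng(11)
    for _ in range(50):
        y = rng.random((4, 6))
        res = fit_paired_anova(y)
        ms, F, p, t, means = anova_oracle(y)
        assert np.isclose(res.ms, ms, rtol=1e-10)
        assert np.isclose(res.F, F, rtol=1e-10)
        assert np.isclose(res.p, p, rtol=1e-10)
        np.testing.assert_allclose(res.partial_t, t, rtol=1e-9)
        np.testing.assert_allclose(res.state_means, means, rtol=1e-12)


def test_anova_zero_residual_is_degenerate():
    y = np.tile([0.1, 0.2, 0.3, 0.4, 0.5, 0.6], (4, 1))
    res = fit_paired_anova(y)
    assert res.F == np.inf and res.p == 0.0 and res.degenerate


def test_anova_all_equal_convention():
    res = fit_paired_anova(np.full((4, 6), 0.3))
    assert res.F == 0.0 and res.p == 1.0 and not res.degenerate
    assert np.all(res.partial_t == 0)


def test_anova_requires_three_complete_donors():
    rng = np.random.default_rng(0)
    y = rng.random((4, 6))
    y[0, 0] = np.nan
    y[1, 3] = np.nan
    with pytest.raises(ValueError, match=">=3"):
        fit_paired_anova(y)


def test_anova_drops_incomplete_donors():
    rng = np.random.default_rng(1)
    y = rng.random((5, 6))
    y[2, 4] = np.nan
    res = fit_paired_anova(y)
    ref = fit_paired_anova(np.delete(y, 2, axis=0))
    assert res.n_donors == 4
    assert np.isclose(res.F, ref.F, rtol=1e-12)


def test_anova_invariances():
    rng = np.random.default_rng(2)
    y = rng.random((4, 6)) * 0.5
    base = fit_paired_anova(y)
    shifted = fit_paired_anova(y + 0.2)
    assert np.isclose(base.F, shifted.F, rtol=1e-8)
    assert np.isclose(base.ms, shifted.ms, rtol=1e-8)
    permuted = fit_paired_anova(y[[3, 1, 0, 2]])
    assert np.isclose(base.F, permuted.F, rtol=1e-12)


def test_partial_t_sums_to_zero():
    rng = np.random.default_rng(3)
    for _ in range(20):
        res = fit_paired_anova(rng.random((4, 6)))
        assert abs(res.partial_t.sum()) < 1e-8 * np.abs(res.partial_t).max()


def test_growing_effect_never_decreases_f():
    rng = np.random.default_rng(4)
    noise = rng.normal(0, 0.03, (4, 6))
    effect = np.array([0, 0.1, 0.1, 0.1, 0.1, 0.1])
    fs = []
    for scale in [0.5, 1.0, 1.5, 2.0]:
        y = np.clip(0.3 + scale * effect + noise, 0, 1)
        fs.append(fit_paired_anova(y).F)
    assert all(a <= b for a, b in zip(fs, fs[1:]))


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_oracle(p):
    """Step-up formula applied directly, written independently."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        q[i] = running
    return q


def test_bh_worked_example():
    np.testing.assert_allclose(
        bh_fdr([0.005, 0.1, 0.9]), [0.015, 0.15, 0.9], rtol=1e-12)


def test_bh_matches_stepup_oracle_small():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)


def test_bh_handles_ties_and_extremes():
    p = np.array([0.0, 0.0, 1.0, 0.5, 0.5])
    np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)


def test_bh_rejects_invalid():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    assert bh_fdr(np.array([])).size == 0


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_monotone_in_rank(p):
    q = bh_fdr(np.array(p))
    order = np.argsort(p, kind="mergesort")
    assert all(q[order[i]] <= q[order[i + 1]] + 1e-15 for i in range(len(p) - 1))
    assert np.all((q >= 0) & (q <= 1))
    assert np.all(q >= np.array(p) - 1e-15)


# ---------------------------------------------------------------------------
# scan + classification
# ---------------------------------------------------------------------------

def _scan_small(n_cpgs=40, seed=6, missing=()):
    rng = np.random.default_rng(seed)
    donors = [f"D{i}" for i in range(1, 5)]
    cols, samples = [], []
    vals = rng.random((n_cpgs, 4, 6))
    for d_i, d in enumerate(donors):
        for c_i, c in enumerate(DEFAULT_STATES):
            samples.append({"sample_id": f"{d}_{c}", "donor": d,
                            "cell_type": c, "sex": "F"})
            cols.append(vals[:, d_i, c_i])
    beta = pd.DataFrame(np.column_stack(cols),
                        index=[f"cg{i}" for i in range(n_cpgs)],
                        columns=[s["sample_id"] for s in samples])
    for probe, sample in missing:
        beta.loc[probe, sample] = np.nan
    sheet = pd.DataFrame(samples).set_index("sample_id")
    return beta, sheet


def test_scan_agrees_with_single_cpg_fit():
    beta, sheet = _scan_small()
    out = ewas_scan(beta, sheet)
    for probe in ["cg0", "cg17", "cg39"]:
        y = beta.loc[probe].to_numpy().reshape(4, 6)
        ref = fit_paired_anova(y)
        assert np.isclose(out.loc[probe, "ms"], ref.ms, rtol=1e-12)
        assert np.isclose(out.loc[probe, "F"], ref.F, rtol=1e-12)
        assert np.isclose(out.loc[probe, "p"], ref.p, rtol=1e-12)


def test_scan_complete_case_per_donor():
    beta, sheet = _scan_small(missing=[("cg3", "D2_monocyte")])
    out = ewas_scan(beta, sheet)
    assert out.loc["cg3", "n_donors"] == 3
    y = beta.loc["cg3"].to_numpy().reshape(4, 6)
    ref = fit_paired_anova(y)  # drops donor 2 internally
    assert np.isclose(out.loc["cg3", "F"], ref.F, rtol=1e-12)


def test_scan_skips_underpowered_cpgs():
    missing = [("cg5", f"D{d}_monocyte") for d in (1, 2)]
    beta, sheet = _scan_small(missing=missing)
    out = ewas_scan(beta, sheet)
    assert out.loc["cg5", "skipped_reason"] != ""
    assert np.isnan(out.loc["cg5", "p"]) and np.isnan(out.loc["cg5", "q"])
    tested = out["p"].notna()
    np.testing.assert_allclose(
        out.loc[tested, "q"], bh_oracle(out.loc[tested, "p"].to_numpy()),
        rtol=1e-12)


def _record(t, means, q=0.001, ms=0.01):
    row = {"ms": ms, "F": 10.0, "p": q / 10, "q": q}
    for c, v in zip(DEFAULT_STATES, t):
        row[f"t_{c}"] = v
    for c, v in zip(DEFAULT_STATES, means):
        row[f"mean_{c}"] = v
    return row


def test_phase_attribution_and_contrasts():
    rows = {
        # monocyte dominates -> differentiation; gain since derived > mono
        "diff": _record([-5, 1, 1, 1, 1, 1], [0.2, 0.5, 0.5, 0.5, 0.5, 0.5]),
        # macrophage dominates -> macrophage-specific
        "mac": _record([1, -5, 1, 1, 1, 1], [0.5, 0.2, 0.5, 0.5, 0.5, 0.5]),
        # one activated state dominates -> activation:<state>
        "act": _record([1, 1, 1, -5, 1, 1], [0.5, 0.5, 0.5, 0.2, 0.5, 0.5]),
        # two states within 0.9 of the max -> multi
        "multi": _record([-5, 4.6, 0, 0, 0, 0], [0.2, 0.6, 0.5, 0.5, 0.5, 0.5]),
    }
    out = call_dmcs(pd.DataFrame(rows).T)
    assert out.loc["diff", "phase"] == "differentiation"
    assert out.loc["mac", "phase"] == "macrophage-specific"
    assert out.loc["act", "phase"] == "activation:M_IL4"
    assert out.loc["multi", "phase"] == "multi"

    # differentiation delta: mean(five derived) - monocyte
    assert np.isclose(out.loc["diff", "delta_beta"], 0.5 - 0.2)
    assert out.loc["diff", "direction"] == "gain"
    # macrophage-specific delta: macrophage - mean(other five)
    assert np.isclose(out.loc["mac", "delta_beta"], 0.2 - 0.5)
    assert out.loc["mac", "direction"] == "loss"
    # activation delta: activated state - naive macrophage
    assert np.isclose(out.loc["act", "delta_beta"], 0.2 - 0.5)
    # the monocyte->macrophage contrast is always reported
    assert np.isclose(out.loc["diff", "delta_mono_mac"], 0.3)


def test_dmc_thresholds_are_strict():
    rows = {
        "ok": _record([-5, 1, 1, 1, 1, 1], [0.2] + [0.5] * 5, q=0.049, ms=0.003),
        "q_at_bound": _record([-5, 1, 1, 1, 1, 1], [0.2] + [0.5] * 5, q=0.05, ms=0.003),
        "ms_at_bound": _record([-5, 1, 1, 1, 1, 1], [0.2] + [0.5] * 5, q=0.01, ms=0.0025),
    }
    out = call_dmcs(pd.DataFrame(rows).T)
    assert bool(out.loc["ok", "is_dmc"])
    assert not bool(out.loc["q_at_bound", "is_dmc"])
    assert not bool(out.loc["ms_at_bound", "is_dmc"])


def test_switch_flag_crosses_half():
    rec = _record([-5, 1, 1, 1, 1, 1], [0.3, 0.7, 0.7, 0.7, 0.7, 0.7])
    out = call_dmcs(pd.DataFrame({"x": rec}).T)
    assert bool(out.loc["x", "switch_flag"])
    rec2 = _record([-5, 1, 1, 1, 1, 1], [0.1, 0.3, 0.3, 0.3, 0.3, 0.3])
    out2 = call_dmcs(pd.DataFrame({"x": rec2}).T)
    assert not bool(out2.loc["x", "switch_flag"])


def test_effect_concordance():
    a = np.array([0.1, -0.2, 0.3, 0.15])
    r, n = effect_concordance(a, 2 * a)
    assert np.isclose(r, 1.0) and n == 4
    r2, _ = effect_concordance(a, -a)
    assert np.isclose(r2, -1.0)
    r3, n3 = effect_concordance(np.r_[a, np.nan], np.r_[2 * a, 1.0])
    assert np.isclose(r3, 1.0) and n3 == 4
    with pytest.raises(ValueError, match="finite pairs"):
        effect_concordance([1.0, 2.0], [1.0, 2.0])
    r4, _ = effect_concordance(np.zeros(5), a[[0, 1, 2, 3, 0]])
    assert np.isnan(r4)
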