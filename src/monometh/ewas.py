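"""Per-CpG paired differential-methylation testing.

The design is balanced: every donor contributes one sample per cell state.
For such data the random-donor-intercept mixed model reduces exactly to a
two-way within-donor ANOVA, which is what is implemented here — it is
deterministic, closed-form, and (for complete data) identical to the REML
route with Satterthwaite denominator degrees of freedom (k-1)(n-1).

Per CpG we report the between-state mean squares (the effect-size criterion),
the F statistic and p-value, per-state "partial t" statistics (state-mean
deviation from the grand mean over its standard error) used to attribute a
DMC to differentiation versus activation, and the signed methylation
difference defining gain versus loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: fixed state order used for tie-breaking in the attribution argmax
DEFAULT_STATES = (
    "monocyte",
    "macrophage",
    "M_LPS_IFNg",
    "M_IL4",
    "M_oxLDL",
    "M_acLDL",
)

#: the five macrophage-derived states (everything but the monocyte)
MACROPHAGE_DERIVED = DEFAULT_STATES[1:]


class DegenerateFit(Warning):
    pass


@dataclass
class AnovaResult:
    ms: float
    F: float
    p: float
    partial_t: np.ndarray
    state_means: np.ndarray
    ms_residual: float
    n_donors: int
    degenerate: bool = False


def fit_paired_anova(y: np.ndarray) -> AnovaResult:
    """Balanced two-way within-donor ANOVA for one CpG.

    Parameters
    ----------
    y : array, shape (n_donors, k_states)
        Beta values for one CpG, rows = donors, columns = cell states.
        Rows containing NaN are dropped (complete-case per donor); at least
        3 complete donors are required.

    Notes
    -----
    ms       = SS_state / (k-1)                        (effect size)
    F        = ms / MS_residual, df (k-1, (k-1)(n-1))
    t_c      = (mean_c - grand) / SE,  SE^2 = MS_residual * (k-1) / (n*k)

    Degenerate cases: MS_residual == 0 with ms > 0 -> F = inf, p = 0,
    flagged; all values identical -> F = 0, p = 1 by convention.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("expected a donors x states table")
    complete = ~np.isnan(y).any(axis=1)
    y = y[complete]
    n, k = y.shape
    if n < 3:
        raise ValueError(f"need >=3 complete donors, got {n}")
    res = _anova_batch(y[None, :, :])
    return AnovaResult(
        ms=float(res["ms"][0]),
        F=float(res["F"][0]),
        p=float(res["p"][0]),
        partial_t=res["partial_t"][0],
        state_means=res["state_means"][0],
        ms_residual=float(res["ms_res"][0]),
        n_donors=n,
        degenerate=bool(res["degenerate"][0]),
    )


def _anova_batch(y: np.ndarray) -> dict[str, np.ndarray]:
    """Vectorized balanced two-way ANOVA over a (m, n_donors, k_states) stack."""
    m, n, k = y.shape
    grand = y.mean(axis=(1, 2))
    state_means = y.mean(axis=1)                        # (m, k)
    donor_means = y.mean(axis=2)                        # (m, n)
    dev_state = state_means - grand[:, None]
    ss_state = n * (dev_state**2).sum(axis=1)
    ss_donor = k * ((donor_means - grand[:, None]) ** 2).sum(axis=1)
    ss_total = ((y - grand[:, None, None]) ** 2).sum(axis=(1, 2))
    ss_res = np.clip(ss_total - ss_state - ss_donor, 0.0, None)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms = ss_state / df1
    ms_res = ss_res / df2

    with np.errstate(divide="ignore", invalid="ignore"):
        F = ms / ms_res
        se = np.sqrt(ms_res * df1 / (n * k))
        partial_t = dev_state / se[:, None]

    degenerate = ms_res <= 0
    null_flat = degenerate & (ms <= 0)
    F = np.where(degenerate & (ms > 0), np.inf, F)
    F = np.where(null_flat, 0.0, F)
    with np.errstate(invalid="ignore"):
        partial_t = np.where(degenerate[:, None], np.where(
            np.abs(dev_state) > 0, np.sign(dev_state) * np.inf, 0.0), partial_t)
    p = stats.f.sf(F, df1, df2)
    p = np.where(null_flat, 1.0, p)
    return {
        "ms": ms,
        "F": F,
        "p": p,
        "partial_t": partial_t,
        "state_means": state_means,
        "ms_res": ms_res,
        "degenerate": degenerate & (ms > 0),
    }


def bh_fdr(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0,1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def ewas_scan(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    states: tuple[str, ...] = DEFAULT_STATES,
    min_donors: int = 3,
) -> pd.DataFrame:
    """Run the paired ANOVA over every CpG of a beta matrix.

    A CpG is tested on the donors with complete data across all states;
    CpGs with fewer than ``min_donors`` complete donors are skipped and
    reported with ``skipped_reason`` set.  Returns one row per CpG with
    columns ms, F, p, q, t_<state>..., plus bookkeeping columns.
    """
    donors = sorted(sheet["donor"].unique())
    k, nd = len(states), len(donors)
    sample_of = {
        (r["donor"], r["cell_type"]): s for s, r in sheet.iterrows()
    }
    cols = []
    for d in donors:
        for c in states:
            s = sample_of.get((d, c))
            cols.append(beta[s].to_numpy() if s is not None else np.full(len(beta), np.nan))
    cube = np.stack(cols, axis=1).reshape(len(beta), nd, k)

    complete = ~np.isnan(cube).any(axis=2)              # (m, nd)
    n_complete = complete.sum(axis=1)
    testable = n_complete >= min_donors

    out = pd.DataFrame(index=beta.index.copy())
    out.index.name = "probe_id"
    for col in ["ms", "F", "p", "q"]:
        out[col] = np.nan
    for c in states:
        out[f"t_{c}"] = np.nan
    for c in states:
        out[f"mean_{c}"] = np.nan
    out["n_donors"] = n_complete
    out["degenerate"] = False
    out["skipped_reason"] = ""
    out.loc[~testable, "skipped_reason"] = "fewer than %d complete donors" % min_donors

    # group testable CpGs by their complete-donor pattern so each group is a
    # balanced stack and can be handled in one vectorized call
    patterns = {}
    idx_testable = np.flatnonzero(testable)
    for i in idx_testable:
        patterns.setdefault(complete[i].tobytes(), []).append(i)
    for key, idxs in patterns.items():
        mask = np.frombuffer(key, dtype=bool)
        sub = cube[np.ix_(idxs, np.flatnonzero(mask))]
        res = _anova_batch(sub)
        rows = out.index[idxs]
        out.loc[rows, "ms"] = res["ms"]
        out.loc[rows, "F"] = res["F"]
        out.loc[rows, "p"] = res["p"]
        out.loc[rows, [f"t_{c}" for c in states]] = res["partial_t"]
        out.loc[rows, [f"mean_{c}" for c in states]] = res["state_means"]
        out.loc[rows, "degenerate"] = res["degenerate"]

    tested = out["p"].notna()
    out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    return out


def call_dmcs(
    records: pd.DataFrame,
    q_max: float = 0.05,
    ms_min: float = 0.0025,
    states: tuple[str, ...] = DEFAULT_STATES,
    multi_frac: float = 0.9,
) -> pd.DataFrame:
    """Classify tested CpGs into DMCs with phase and direction.

    A CpG is a DMC iff q < q_max and ms > ms_min.  The contributing cell
    state is the argmax of |partial t| (ties broken by the fixed state
    order): the monocyte maps to the differentiation phase, the unstimulated
    macrophage to "macrophage-specific", an activated state to
    "activation:<state>".  When a second state reaches ``multi_frac`` of the
    max |t| the phase is "multi".  delta_beta is the contrast that defines
    gain (positive) versus loss (negative):

    - differentiation: mean(five macrophage-derived states) - mean(monocyte)
    - activation:      mean(activated state) - mean(macrophage)
    - macrophage-specific: mean(macrophage) - mean(other five states)
    """
    out = records.copy()
    t_cols = [f"t_{c}" for c in states]
    m_cols = [f"mean_{c}" for c in states]
    tmat = out[t_cols].to_numpy(dtype=float)
    means = out[m_cols].to_numpy(dtype=float)
    absT = np.abs(tmat)
    # argmax with fixed-order tie-break = plain argmax over the ordered axis
    top = np.argmax(absT, axis=1)
    maxT = absT[np.arange(len(out)), top]
    with np.errstate(invalid="ignore"):
        n_near = (absT >= multi_frac * maxT[:, None]).sum(axis=1)

    mono_i = states.index("monocyte")
    mac_i = states.index("macrophage")
    other_than_mac = [i for i in range(len(states)) if i != mac_i]
    derived = [i for i in range(len(states)) if i != mono_i]

    phase = np.empty(len(out), dtype=object)
    delta = np.full(len(out), np.nan)
    for i in range(len(out)):
        if not np.isfinite(maxT[i]) and np.isnan(maxT[i]):
            phase[i] = ""
            continue
        s = top[i]
        if n_near[i] >= 2:
            phase[i] = "multi"
        elif s == mono_i:
            phase[i] = "differentiation"
        elif s == mac_i:
            phase[i] = "macrophage-specific"
        else:
            phase[i] = f"activation:{states[s]}"
        if s == mono_i or phase[i] == "multi":
            delta[i] = means[i, derived].mean() - means[i, mono_i]
        elif s == mac_i:
            delta[i] = means[i, mac_i] - means[i, other_than_mac].mean()
        else:
            delta[i] = means[i, s] - means[i, mac_i]

    out["phase"] = phase
    out["top_state"] = [states[s] for s in top]
    out["delta_beta"] = delta
    out["direction"] = np.where(delta > 0, "gain", "loss")
    # differentiation contrast also reported for every CpG (used by the WGBS
    # integration, which compares monocyte vs macrophage regardless of phase)
    out["delta_mono_mac"] = means[:, mac_i] - means[:, mono_i]
    out["switch_flag"] = (means[:, mono_i] - 0.5) * (means[:, mac_i] - 0.5) < 0
    with np.errstate(invalid="ignore"):
        out["is_dmc"] = (out["q"] < q_max) & (out["ms"] > ms_min)
    out["is_dmc"] = out["is_dmc"].fillna(False)
    return out


def effect_concordance(delta_a: np.ndarray, delta_b: np.ndarray) -> tuple[float, int]:
    """Pearson correlation of two effect-size vectors over complete pairs."""
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must be paired")
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(f"need >=3 finite pairs, got {n}")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        return float("nan"), n
    return float(np.corrcoef(a, b)[0, 1]), n
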