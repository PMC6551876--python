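"""Fisher-exact enrichment analyses.

One uniform 2x2 machinery serves every annotation class: chromatin states
per cell type, the gain-over-loss state-transition grid, promoter-capture
Hi-C enhancers, DNaseI hypersensitive-site changes and TF binding gain at
motifs.  Odds ratios are the plain cross-product ad/bc (infinite / zero
ratios are reported as-is with a flag); two-sided p-values use the
probability-mass convention (sum of tables at most as probable as the one
observed) and are floored at 2.2e-16 in the ``p_capped`` column.  The
expression-shift test is a Wilcoxon signed-rank on paired per-gene log
expression differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_fdr

P_CAP = 2.2e-16

#: relative slack when comparing table probabilities for the two-sided
#: probability-mass rule (same convention as R's fisher.test)
TIE_REL = 1 + 1e-7


def fisher_margin_p(total: int, k_feature: int, n_target: int) -> np.ndarray:
    """Two-sided Fisher p for every feasible table with the given margins.

    For fixed margins (grand total, feature-column total, target-row total)
    the table is determined by the count ``a``; its null distribution is
    hypergeometric.  Returns the two-sided probability-mass p-value (sum of
    outcomes at most as probable as the observed one, with a 1e-7 relative
    tie slack) for every ``a`` in the support, in increasing order of ``a``.
    """
    lo = max(0, n_target - (total - k_feature))
    hi = min(n_target, k_feature)
    ks = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(ks, total, k_feature, n_target)
    order = np.sort(pmf)
    csum = np.cumsum(order)
    pos = np.searchsorted(order, pmf * TIE_REL, side="right")
    return np.minimum(csum[pos - 1], 1.0)


@dataclass
class EnrichmentResult:
    stratum: str
    a: int  # target & feature
    b: int  # target & not feature
    c: int  # background & feature
    d: int  # background & not feature
    odds_ratio: float
    p: float
    p_capped: float
    direction_set: str = "all"
    flagged: bool = False

    @property
    def log2_or(self) -> float:
        with np.errstate(divide="ignore"):
            return float(np.log2(self.odds_ratio))


def fisher_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, float]:
    """Two-sided Fisher exact test for [[a, b], [c, d]].

    Returns (odds_ratio, p, p_capped) with OR = ad/bc; OR is inf when
    b*c == 0 with a*d > 0, and nan for the all-degenerate 0/0 case.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty table")
    if b * c == 0:
        odds = np.nan if a * d == 0 else np.inf
    else:
        odds = (a * d) / (b * c)
    total, k_feature, n_target = a + b + c + d, a + c, a + b
    lo = max(0, n_target - (total - k_feature))
    p = float(fisher_margin_p(total, k_feature, n_target)[a - lo])
    return float(odds), p, max(p, P_CAP)


def _result(stratum, a, b, c, d, direction_set="all") -> EnrichmentResult:
    odds, p, pc = fisher_2x2(a, b, c, d)
    flagged = not np.isfinite(odds) or odds == 0
    return EnrichmentResult(stratum, a, b, c, d, odds, p, pc, direction_set, flagged)


def results_to_frame(results: list[EnrichmentResult], fdr: bool = True) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "stratum": [r.stratum for r in results],
            "direction_set": [r.direction_set for r in results],
            "a": [r.a for r in results],
            "b": [r.b for r in results],
            "c": [r.c for r in results],
            "d": [r.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "log2_or": [r.log2_or for r in results],
            "p": [r.p for r in results],
            "p_capped": [r.p_capped for r in results],
            "flagged": [r.flagged for r in results],
        }
    )
    if fdr and len(df):
        df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def feature_enrichment(
    targets: pd.Index | np.ndarray,
    feature: pd.Series,
    background: pd.Index | np.ndarray,
    strata: pd.Series | None = None,
    direction_set: str = "all",
) -> list[EnrichmentResult]:
    """Per-stratum 2x2 enrichment of a boolean per-CpG feature.

    ``feature`` (and optional ``strata``) are indexed by probe id.  With
    ``strata`` given, the feature tested in stratum s is "CpG carries label
    s"; otherwise ``feature`` itself is the single tested feature.
    Background defaults (at the caller) to all measured non-target CpGs.
    """
    targets = pd.Index(targets)
    background = pd.Index(background)
    if strata is None:
        ft, fb = feature.loc[targets], feature.loc[background]
        a, b = int(ft.sum()), int((~ft).sum())
        c, d = int(fb.sum()), int((~fb).sum())
        return [_result("feature", a, b, c, d, direction_set)]
    out = []
    st, sb = strata.loc[targets], strata.loc[background]
    for s in sorted(strata.dropna().unique()):
        a = int((st == s).sum())
        b = len(st) - a
        c = int((sb == s).sum())
        d = len(sb) - c
        out.append(_result(str(s), a, b, c, d, direction_set))
    return out


def transition_matrix(
    gain: pd.Index,
    loss: pd.Index,
    state_mono: pd.Series,
    state_mac: pd.Series,
    states: list[str] | None = None,
) -> pd.DataFrame:
    """Gain-over-loss enrichment per (monocyte state -> macrophage state).

    For each transition (s, t): a 2x2 of {gain, loss} x {in transition,
    not}; OR > 1 means the transition is gain-enriched.  CpGs with a
    no-call state in either cell type are excluded (count reported in the
    ``n_excluded`` frame attribute).
    """
    pairs_g = pd.DataFrame({"s": state_mono.loc[gain], "t": state_mac.loc[gain]})
    pairs_l = pd.DataFrame({"s": state_mono.loc[loss], "t": state_mac.loc[loss]})
    ok_g, ok_l = pairs_g.notna().all(axis=1), pairs_l.notna().all(axis=1)
    n_excluded = int((~ok_g).sum() + (~ok_l).sum())
    pairs_g, pairs_l = pairs_g[ok_g], pairs_l[ok_l]
    if states is None:
        states = sorted(set(pairs_g["s"]) | set(pairs_l["s"]) | set(pairs_g["t"]) | set(pairs_l["t"]))
    rows = []
    ng, nl = len(pairs_g), len(pairs_l)
    for s in states:
        for t in states:
            a = int(((pairs_g["s"] == s) & (pairs_g["t"] == t)).sum())
            c = int(((pairs_l["s"] == s) & (pairs_l["t"] == t)).sum())
            if a == 0 and c == 0:
                rows.append({"state_mono": s, "state_mac": t, "a": 0, "b": ng,
                             "c": 0, "d": nl, "odds_ratio": np.nan,
                             "log2_or": np.nan, "p": np.nan, "p_capped": np.nan,
                             "flagged": True})
                continue
            odds, p, pc = fisher_2x2(a, ng - a, c, nl - c)
            with np.errstate(divide="ignore"):
                l2 = np.log2(odds) if not np.isnan(odds) else np.nan
            rows.append({"state_mono": s, "state_mac": t, "a": a, "b": ng - a,
                         "c": c, "d": nl - c, "odds_ratio": odds, "log2_or": l2,
                         "p": p, "p_capped": pc,
                         "flagged": not np.isfinite(odds) or odds == 0})
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


def tf_binding_gain(
    gain_dmcs: pd.Index,
    background: pd.Index,
    binding_gain: pd.Series,
    delta_beta: pd.Series,
    motif: str,
) -> tuple[EnrichmentResult, float]:
    """Enrichment of TF binding gain at motif-overlapping gain-DMCs.

    ``gain_dmcs`` / ``background`` are the motif-overlapping CpG sets;
    ``binding_gain`` is the per-CpG "peak in macrophage, none in monocyte"
    flag.  Also returns the mean methylation difference (in percent) of the
    tested gain-DMCs.
    """
    if len(gain_dmcs) == 0 or len(background) == 0:
        raise ValueError(f"no motif-overlapping CpGs for motif {motif!r}")
    ft = binding_gain.loc[gain_dmcs]
    fb = binding_gain.loc[background]
    res = _result(motif, int(ft.sum()), int((~ft).sum()), int(fb.sum()),
                  int((~fb).sum()), direction_set="gain")
    mean_delta_pct = float(np.abs(delta_beta.loc[gain_dmcs]).mean() * 100)
    return res, mean_delta_pct


def expression_shift(
    genes: list[str], expression: pd.DataFrame,
    col_a: str = "monocyte", col_b: str = "macrophage",
) -> tuple[float, float, float]:
    """Wilcoxon signed-rank test on paired per-gene expression differences.

    Differences are ``col_b - col_a`` (macrophage minus monocyte logTPM) for
    the unique genes present in the expression table.  Exact p for n <= 25
    (no ties), normal approximation with continuity correction otherwise.
    Returns (W statistic, two-sided p, median difference).
    """
    genes = [g for g in dict.fromkeys(genes) if g in expression.index]
    if len(genes) < 5:
        raise ValueError(f"need >=5 genes with expression, got {len(genes)}")
    d = (expression.loc[genes, col_b] - expression.loc[genes, col_a]).to_numpy()
    if np.all(d == 0):
        return 0.0, 1.0, 0.0
    nz = d[d != 0]
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), float(np.median(d))
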