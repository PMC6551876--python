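"""Effect-size and DMR-size threshold sensitivity.

Quantifies how stringent analysis choices (a minimum methylation difference
of 30% instead of 5%; restricting to regions of at least 4 CpGs instead of
individual CpGs) shrink the DMC set, separately for gain and loss, and
whether the regulatory enrichments computed on the retained subsets agree
with the full-set results.

The input set for every cutoff is the WGBS-covered, direction-consistent
DMCs (each carries the WGBS difference at its seed CpG and its DMR member
count).  The "5-30%" bin is closed (0.05 <= |d| <= 0.30) and ">30%" strict;
DMR bins are {<=4, >4} CpGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EFFECT_BINS = {
    "gt5": lambda d: d >= 0.05,
    "5to30": lambda d: (d >= 0.05) & (d <= 0.30),
    "gt30": lambda d: d > 0.30,
}
DMR_BINS = {
    "le4": lambda n: n <= 4,
    "gt4": lambda n: n > 4,
}


def apply_cutoffs(dmc_wgbs: pd.DataFrame) -> pd.DataFrame:
    """Retention report over every effect-bin x DMR-bin combination.

    ``dmc_wgbs`` is the per-DMC WGBS integration table (columns direction,
    covered, concordant, wgbs_delta, dmr_n_cpg); only covered, concordant
    rows enter the base set.  Returns one row per (effect_bin, dmr_bin)
    including the marginal "any" bins, with retained counts and lost
    fractions split by gain/loss.
    """
    base = dmc_wgbs[dmc_wgbs["covered"] & dmc_wgbs["concordant"]].copy()
    absd = base["wgbs_delta"].abs()
    ncpg = base["dmr_n_cpg"]
    gain = base["direction"] == "gain"
    n_gain, n_loss = int(gain.sum()), int((~gain).sum())
    rows = []
    effect_items = [("any", None)] + list(EFFECT_BINS.items())
    dmr_items = [("any", None)] + list(DMR_BINS.items())
    for ename, efn in effect_items:
        for dname, dfn in dmr_items:
            keep = pd.Series(True, index=base.index)
            if efn is not None:
                keep &= efn(absd)
            if dfn is not None:
                keep &= dfn(ncpg)
            rg = int((keep & gain).sum())
            rl = int((keep & ~gain).sum())
            rows.append({
                "effect_bin": ename,
                "dmr_bin": dname,
                "n_input_gain": n_gain,
                "n_input_loss": n_loss,
                "n_retained_gain": rg,
                "n_retained_loss": rl,
                "frac_lost_gain": 1 - rg / n_gain if n_gain else np.nan,
                "frac_lost_loss": 1 - rl / n_loss if n_loss else np.nan,
                "frac_lost_total": (1 - (rg + rl) / (n_gain + n_loss)
                                    if n_gain + n_loss else np.nan),
            })
    report = pd.DataFrame(rows)
    report.attrs["n_not_covered"] = int((~dmc_wgbs["covered"]).sum())
    report.attrs["n_not_concordant"] = int(
        (dmc_wgbs["covered"] & ~dmc_wgbs["concordant"]).sum())
    return report


def retained_sets(dmc_wgbs: pd.DataFrame) -> dict[tuple[str, str], pd.Index]:
    """Probe-id sets retained in each cutoff cell (same bins as apply_cutoffs)."""
    base = dmc_wgbs[dmc_wgbs["covered"] & dmc_wgbs["concordant"]]
    absd = base["wgbs_delta"].abs()
    ncpg = base["dmr_n_cpg"]
    out = {}
    for ename, efn in [("any", None)] + list(EFFECT_BINS.items()):
        for dname, dfn in [("any", None)] + list(DMR_BINS.items()):
            keep = pd.Series(True, index=base.index)
            if efn is not None:
                keep &= efn(absd)
            if dfn is not None:
                keep &= dfn(ncpg)
            out[(ename, dname)] = base.index[keep]
    return out


def rerun_enrichments(
    subsets: dict[tuple[str, str], pd.Index],
    directions: pd.Series,
    enrich_fn,
    min_size: int = 20,
) -> pd.DataFrame:
    """Re-run an enrichment callable on every retained subset.

    ``enrich_fn(targets: pd.Index, direction: str) -> DataFrame`` must
    return a stratum/log2_or table (the chromatin-state or DHS or motif
    family).  Subsets with fewer than ``min_size`` members in a direction
    are marked insufficient and skipped.  Results are concatenated with
    effect_bin / dmr_bin / direction keys for side-by-side comparison.
    """
    pieces = []
    for (ename, dname), idx in subsets.items():
        for direction in ("gain", "loss"):
            sub = idx[directions.loc[idx] == direction]
            base = {"effect_bin": ename, "dmr_bin": dname,
                    "direction": direction, "n_retained": len(sub)}
            if len(sub) < min_size:
                pieces.append(pd.DataFrame([{**base, "stratum": None,
                                             "insufficient": True}]))
                continue
            tab = enrich_fn(sub, direction).copy()
            for k, v in base.items():
                tab[k] = v
            tab["insufficient"] = False
            pieces.append(tab)
    return pd.concat(pieces, ignore_index=True)
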