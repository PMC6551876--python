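"""WGBS integration: concordance filtering and seed-and-extend DMRs.

Array DMCs are mapped onto whole-genome bisulfite CpG tracks (monocyte and
macrophage per-cell-type means).  A mapped DMC is concordant when the WGBS
difference (macrophage - monocyte) has the array direction and magnitude of
at least ``min_diff`` (default 5%).  A DMR is demarcated around a concordant
seed by greedy extension over consecutive WGBS CpGs that keep a
same-direction difference of at least ``min_diff`` and lie within
``max_gap`` bp of the previous member; extension stops at the first failure
in each direction.  A single-CpG DMR has length 1 bp by convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrich import fisher_2x2


@dataclass
class WgbsPair:
    """Joined monocyte/macrophage WGBS tracks, position-sorted per chromosome.

    ``delta`` is macrophage - monocyte, matching the gain/loss orientation of
    the array analysis.
    """

    by_chrom: dict[str, pd.DataFrame]  # columns: pos0, beta_mono, beta_mac, delta, n_mono, n_mac

    @classmethod
    def from_tracks(
        cls,
        mono: pd.DataFrame,
        mac: pd.DataFrame,
        n_donors_mono: pd.Series | int = 4,
        n_donors_mac: pd.Series | int = 4,
    ) -> "WgbsPair":
        """Inner-join two chrom/pos0/beta tracks on position."""
        m = mono.rename(columns={"beta": "beta_mono"})
        a = mac.rename(columns={"beta": "beta_mac"})
        if isinstance(n_donors_mono, int):
            m["n_mono"] = n_donors_mono
        else:
            m = m.merge(n_donors_mono.rename("n_mono"), left_on=["chrom", "pos0"], right_index=True)
        if isinstance(n_donors_mac, int):
            a["n_mac"] = n_donors_mac
        else:
            a = a.merge(n_donors_mac.rename("n_mac"), left_on=["chrom", "pos0"], right_index=True)
        j = m.merge(a, on=["chrom", "pos0"], how="inner")
        j["delta"] = j["beta_mac"] - j["beta_mono"]
        by = {
            c: g.sort_values("pos0").reset_index(drop=True)
            for c, g in j.groupby("chrom")
        }
        return cls(by)


@dataclass
class DmrRecord:
    seed_probe_id: str
    chrom: str
    start: int          # 1-based position of first member CpG
    end: int            # 1-based position of last member CpG
    n_cpg: int
    mean_delta: float   # mean of member deltas (macrophage - monocyte)
    member_pos: list[int] = field(default_factory=list)

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def map_dmc_to_wgbs(
    chrom: str,
    pos0: int,
    pair: WgbsPair,
    min_donors: int = 3,
) -> int | None:
    """Locate the WGBS CpG at the array CpG's exact position.

    Returns the row index into the chromosome's joined track, or None if the
    position is absent from either track or covered by fewer than
    ``min_donors`` donors in either cell type ("insufficiently covered").
    """
    track = pair.by_chrom.get(chrom)
    if track is None:
        return None
    pos = track["pos0"].to_numpy()
    i = int(np.searchsorted(pos, pos0))
    if i >= len(pos) or pos[i] != pos0:
        return None
    if track["n_mono"].iat[i] < min_donors or track["n_mac"].iat[i] < min_donors:
        return None
    return i


def extend_dmr(
    probe_id: str,
    chrom: str,
    seed_idx: int,
    pair: WgbsPair,
    array_direction: int,
    min_diff: float = 0.05,
    max_gap: int = 1000,
) -> DmrRecord | None:
    """Seed-and-extend DMR demarcation around a mapped DMC.

    ``array_direction`` is +1 (gain) or -1 (loss) from the array analysis.
    Returns None when the seed itself is not concordant (WGBS difference
    below ``min_diff`` or of the wrong sign).
    """
    track = pair.by_chrom[chrom]
    pos = track["pos0"].to_numpy()
    delta = track["delta"].to_numpy()

    def qualifies(i: int) -> bool:
        return array_direction * delta[i] >= min_diff

    if not qualifies(seed_idx):
        return None
    lo = hi = seed_idx
    while lo - 1 >= 0 and qualifies(lo - 1) and pos[lo] - pos[lo - 1] <= max_gap:
        lo -= 1
    while hi + 1 < len(pos) and qualifies(hi + 1) and pos[hi + 1] - pos[hi] <= max_gap:
        hi += 1
    members = list(range(lo, hi + 1))
    return DmrRecord(
        seed_probe_id=probe_id,
        chrom=chrom,
        start=int(pos[lo]) + 1,
        end=int(pos[hi]) + 1,
        n_cpg=len(members),
        mean_delta=float(delta[lo : hi + 1].mean()),
        member_pos=[int(p) + 1 for p in pos[lo : hi + 1]],
    )


def demarcate_dmrs(
    dmcs: pd.DataFrame,
    cpg_map: pd.DataFrame,
    pair: WgbsPair,
    min_diff: float = 0.05,
    max_gap: int = 1000,
    min_donors: int = 3,
) -> pd.DataFrame:
    """Map every DMC to WGBS and demarcate DMRs around concordant seeds.

    ``dmcs`` must carry a ``direction`` column (gain/loss on the
    monocyte-to-macrophage axis).  Returns a per-DMC frame with coverage
    status, WGBS delta at the seed, concordance flag and DMR geometry.
    """
    rows = []
    for pid, rec in dmcs.iterrows():
        chrom = cpg_map.loc[pid, "chrom"]
        pos0 = int(cpg_map.loc[pid, "pos0"])
        sgn = 1 if rec["direction"] == "gain" else -1
        i = map_dmc_to_wgbs(chrom, pos0, pair, min_donors=min_donors)
        row = {
            "probe_id": pid,
            "chrom": chrom,
            "pos": pos0 + 1,
            "direction": rec["direction"],
            "covered": i is not None,
            "wgbs_delta": np.nan,
            "concordant": False,
            "dmr_n_cpg": np.nan,
            "dmr_length_bp": np.nan,
            "dmr_mean_delta_pct": np.nan,
        }
        if i is not None:
            track = pair.by_chrom[chrom]
            row["wgbs_delta"] = float(track["delta"].iat[i])
            dmr = extend_dmr(pid, chrom, i, pair, sgn, min_diff=min_diff, max_gap=max_gap)
            if dmr is not None:
                row["concordant"] = True
                row["dmr_n_cpg"] = dmr.n_cpg
                row["dmr_length_bp"] = dmr.length_bp
                row["dmr_mean_delta_pct"] = dmr.mean_delta * 100
        rows.append(row)
    return pd.DataFrame(rows).set_index("probe_id")


def concordance_enrichment(
    dmc_table: pd.DataFrame,
    non_dmc_table: pd.DataFrame,
) -> dict:
    """Fold enrichment of WGBS concordance in DMCs over non-DMCs.

    Both inputs are outputs of :func:`demarcate_dmrs`-style mapping with
    ``covered`` and ``concordant`` columns; rates are computed among covered
    CpGs.  Fold = concordant rate in DMCs / rate in non-DMCs; p from the
    Fisher exact test on the 2x2 of concordance status.
    """
    d = dmc_table[dmc_table["covered"]]
    n = non_dmc_table[non_dmc_table["covered"]]
    if len(d) == 0 or len(n) == 0:
        raise ValueError("both groups must contain covered CpGs")
    a, b = int(d["concordant"].sum()), int((~d["concordant"]).sum())
    c, dd = int(n["concordant"].sum()), int((~n["concordant"]).sum())
    rate_d = a / len(d)
    rate_n = c / len(n)
    fold = np.inf if rate_n == 0 else rate_d / rate_n
    odds, p, pc = fisher_2x2(a, b, c, dd)
    return {
        "n_dmc_covered": len(d),
        "n_dmc_concordant": a,
        "n_non_dmc_covered": len(n),
        "n_non_dmc_concordant": c,
        "rate_dmc": rate_d,
        "rate_non_dmc": rate_n,
        "fold": float(fold),
        "odds_ratio": odds,
        "p": p,
        "p_capped": pc,
    }
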