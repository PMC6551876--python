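"""Synthetic study generator.

Emulates the statistical structure of a paired monocyte/macrophage
methylation study: four donors by six cell states (monocyte, naive
macrophage and four activated subsets), donor random effects on a bimodal
baseline methylation level, planted gain/loss effects for differentiation
and (rare, loss-dominated) activation, per-cell-type WGBS tracks in which
planted effects span short regions or single CpGs, per-donor chromatin-state
and DNaseI tracks with configurable inter-donor concordance, motif and
ChIP-seq placements co-located with planted DMCs, Hi-C enhancer intervals
and a nearest-gene expression table.  Every generated object can be written
to the plain-text formats the readers in :mod:`monometh.io` consume, plus a
ground-truth table for acceptance testing.

The generator is deterministic per seed; independent substreams are spawned
per component so adding one component never shifts another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .annotate import nearest_genes_bulk
from .ewas import DEFAULT_STATES
from .motif import Pwm, consensus_pwm, reverse_complement, write_pwms

CHROM_STATES = (
    "TSS", "active_TSS", "flanking_active_TSS", "enhancer", "active_enhancer",
    "transcription", "quiescent", "polycomb", "bivalent",
)

#: default background distribution over (state_mono == state_mac) pairs
_BG_STATE_P = {
    "quiescent": 0.55, "transcription": 0.12, "enhancer": 0.08, "TSS": 0.06,
    "active_TSS": 0.05, "flanking_active_TSS": 0.04, "active_enhancer": 0.04,
    "polycomb": 0.04, "bivalent": 0.02,
}

#: transitions that preferentially receive planted gain-DMCs (repressed or
#: becoming repressed) and loss-DMCs (losing repression / gaining activity)
GAIN_TRANSITIONS = (
    ("quiescent", "quiescent"), ("polycomb", "polycomb"),
    ("enhancer", "quiescent"), ("flanking_active_TSS", "quiescent"),
)
LOSS_TRANSITIONS = (
    ("quiescent", "enhancer"), ("enhancer", "active_enhancer"),
    ("polycomb", "enhancer"), ("quiescent", "active_enhancer"),
)

MOTIF_CONSENSUS = {
    "CEBP_like": "TTGCGCAA",
    "ETS_like": "AGAGGAAGTG",
    "AP1_like": "TGACTCAT",
}
MOTIF_CHIP = {"CEBP_like": "CEBP", "ETS_like": "PU1"}  # which TF binds which motif


@dataclass
class SimConfig:
    """Study-level parameters of the synthetic data generator."""

    n_cpgs: int = 6000
    n_donors: int = 4
    cell_states: tuple[str, ...] = DEFAULT_STATES
    donor_sd: float = 0.05
    noise_sd: float = 0.03
    # planted differentiation effects (gain dominates, as observed)
    n_gain_diff: int = 400
    n_loss_diff: int = 140
    gain_effect_range: tuple[float, float] = (0.06, 0.28)
    loss_effect_range: tuple[float, float] = (0.10, 0.50)
    # activation effects: rare and loss-dominated; (n_gain, n_loss) per subtype
    activation_counts: dict = field(default_factory=lambda: {
        "M_LPS_IFNg": (1, 8), "M_IL4": (0, 1), "M_oxLDL": (0, 1), "M_acLDL": (0, 1),
    })
    n_mac_specific_gain: int = 1
    n_mac_specific_loss: int = 1
    clamp_margin: float = 0.02
    # WGBS regional structure
    frac_single_cpg: float = 0.26
    gain_region_extra_mean: float = 1.5   # multi-CpG size = 2 + Poisson(mean)
    loss_region_extra_mean: float = 3.0
    concordant_frac: float = 0.5
    bg_spurious_wgbs: float = 0.10        # random-sign spurious >=5% differences
    wgbs_noise_sd: float = 0.012
    wgbs_coverage: float = 0.78
    wgbs_n_donors: int = 4
    neighbors_per_side: int = 8
    # annotation tracks
    state_concordance: float = 0.9
    n_state_donors: int = 5
    n_dnase_mono: int = 26
    n_dnase_mac: int = 4
    segment_bp: int = 800
    gain_transition_frac: float = 0.5
    loss_transition_frac: float = 0.6
    enhancer_stable_frac_gain: float = 0.3
    enhancer_stable_frac_loss: float = 0.3
    dhs_change_gain: float = 0.30
    dhs_change_loss: float = 0.60
    dhs_bg: dict = field(default_factory=lambda: {
        "both": 0.05, "mono_only": 0.025, "mac_only": 0.025,
    })
    hic_prob_dmc: float = 0.25
    hic_prob_bg: float = 0.18
    # motifs / ChIP
    motif_window: int = 25
    gain_motif_probs: dict = field(default_factory=lambda: {
        "CEBP_like": 0.5, "ETS_like": 0.35,
    })
    loss_motif_probs: dict = field(default_factory=lambda: {"AP1_like": 0.6})
    bg_motif_rate: float = 0.06           # total, split over the three motifs
    chip_gain_at_motif: float = 0.6
    chip_gain_bg: float = 0.05
    chip_stable_bg: float = 0.15
    # genes / expression
    expr_shift_gain: float = -0.8
    expr_shift_loss: float = 1.0
    expr_noise: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_cpgs <= 0 or self.n_donors < 3:
            raise ValueError("need n_cpgs > 0 and n_donors >= 3")
        if self.donor_sd <= 0 or self.noise_sd <= 0:
            raise ValueError("SDs must be positive")
        n_planted = (self.n_gain_diff + self.n_loss_diff
                     + self.n_mac_specific_gain + self.n_mac_specific_loss
                     + sum(g + l for g, l in self.activation_counts.values()))
        if n_planted > self.n_cpgs // 2:
            raise ValueError("too many planted CpGs for the map size")
        for lo, hi in (self.gain_effect_range, self.loss_effect_range):
            if not 0 < lo < hi < 1:
                raise ValueError("effect ranges must satisfy 0 < lo < hi < 1")
        if not 0 <= self.frac_single_cpg <= 1:
            raise ValueError("frac_single_cpg must be a probability")


@dataclass
class SimStudy:
    """All generated inputs plus ground truth, in memory."""

    config: SimConfig
    beta: pd.DataFrame
    sheet: pd.DataFrame
    cpg_map: pd.DataFrame
    truth: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    wgbs_mono: pd.DataFrame | None = None
    wgbs_mac: pd.DataFrame | None = None
    wgbs_ndonors: pd.DataFrame | None = None
    genome: dict[str, str] = field(default_factory=dict)
    motif_sites: list = field(default_factory=list)
    state_tracks: dict = field(default_factory=dict)   # cell_type -> donor -> [GenomicInterval]
    dnase_tracks: dict = field(default_factory=dict)
    chip_tracks: dict = field(default_factory=dict)    # tf -> cell_type -> [GenomicInterval]
    hic: dict = field(default_factory=dict)            # cell_type -> [GenomicInterval]
    genes: pd.DataFrame | None = None
    expression: pd.DataFrame | None = None
    pwms: list = field(default_factory=list)
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# Stage 1: beta matrix
# ---------------------------------------------------------------------------

def _bimodal_baseline(rng: np.random.Generator, n: int) -> np.ndarray:
    """Baseline methylation spanning ~0..1 with mass near both extremes."""
    return rng.beta(0.4, 0.4, size=n)


def simulate_study(cfg: SimConfig) -> SimStudy:
    """Generate the beta matrix, sample sheet, CpG map and truth table."""
    cfg.validate()
    root = np.random.default_rng(cfg.seed)
    rngs = {k: np.random.default_rng(s) for k, s in zip(
        ["map", "plant", "beta", "wgbs", "tracks", "genome", "genes"],
        root.integers(0, 2**31 - 1, size=7),
    )}
    rng = rngs["map"]

    # positions on two synthetic chromosomes
    chroms = ["chr1", "chr2"]
    per = [cfg.n_cpgs - cfg.n_cpgs // 2, cfg.n_cpgs // 2]
    recs = []
    chrom_lengths = {}
    pid = 0
    for chrom, n in zip(chroms, per):
        gaps = rng.integers(600, 2000, size=n)
        pos0 = 10_000 + np.cumsum(gaps)
        chrom_lengths[chrom] = int(pos0[-1] + 10_000)
        for p in pos0:
            recs.append((f"cg{pid:07d}", chrom, int(p) + 1))
            pid += 1
    cpg_map = pd.DataFrame(recs, columns=["probe_id", "chrom", "pos"])
    cpg_map["strand"] = "*"
    cpg_map = cpg_map.set_index("probe_id")
    cpg_map["pos0"] = cpg_map["pos"] - 1

    # plant effects
    prng = rngs["plant"]
    states = list(cfg.cell_states)
    mono_i, mac_i = states.index("monocyte"), states.index("macrophage")
    n_total_planted = (cfg.n_gain_diff + cfg.n_loss_diff
                       + cfg.n_mac_specific_gain + cfg.n_mac_specific_loss
                       + sum(g + l for g, l in cfg.activation_counts.values()))
    chosen = prng.choice(cfg.n_cpgs, size=n_total_planted, replace=False)
    cursor = 0

    def take(n):
        nonlocal cursor
        out = chosen[cursor:cursor + n]
        cursor += n
        return out

    truth_rows = []
    effects = np.zeros((cfg.n_cpgs, len(states)))

    def plant(idx, phase, direction, rng_):
        lo, hi = cfg.gain_effect_range if direction == "gain" else cfg.loss_effect_range
        for i in idx:
            e = rng_.uniform(lo, hi) * (1 if direction == "gain" else -1)
            if phase == "differentiation":
                cols = [j for j in range(len(states)) if j != mono_i]
            elif phase == "macrophage-specific":
                cols = [mac_i]
            else:  # activation:<subtype>
                cols = [states.index(phase.split(":", 1)[1])]
            effects[i, cols] = e
            truth_rows.append({
                "probe_id": cpg_map.index[i], "phase": phase,
                "direction": direction, "true_delta": e,
            })

    plant(take(cfg.n_gain_diff), "differentiation", "gain", prng)
    plant(take(cfg.n_loss_diff), "differentiation", "loss", prng)
    for subtype, (ng, nl) in cfg.activation_counts.items():
        plant(take(ng), f"activation:{subtype}", "gain", prng)
        plant(take(nl), f"activation:{subtype}", "loss", prng)
    plant(take(cfg.n_mac_specific_gain), "macrophage-specific", "gain", prng)
    plant(take(cfg.n_mac_specific_loss), "macrophage-specific", "loss", prng)

    truth = pd.DataFrame(truth_rows).set_index("probe_id")

    # baselines, redrawn where the planted effect would leave [margin, 1-margin]
    brng = rngs["beta"]
    mu = _bimodal_baseline(brng, cfg.n_cpgs)
    lo_m, hi_m = cfg.clamp_margin, 1 - cfg.clamp_margin
    emin, emax = effects.min(axis=1), effects.max(axis=1)
    n_redrawn = 0
    for _ in range(200):
        bad = (mu + emin < lo_m) | (mu + emax > hi_m) | (mu < lo_m) | (mu > hi_m)
        bad &= (emin != 0) | (emax != 0)
        if not bad.any():
            break
        n_redrawn += int(bad.sum())
        mu[bad] = _bimodal_baseline(brng, int(bad.sum()))

    donors = [f"D{i+1}" for i in range(cfg.n_donors)]
    donor_eff = brng.normal(0, cfg.donor_sd, size=(cfg.n_cpgs, cfg.n_donors))
    noise = brng.normal(0, cfg.noise_sd, size=(cfg.n_cpgs, cfg.n_donors, len(states)))
    cube = (mu[:, None, None] + donor_eff[:, :, None]
            + effects[:, None, :] + noise)
    cube = np.clip(cube, 0.0, 1.0)

    samples, cols = [], []
    for d_i, d in enumerate(donors):
        for c_i, c in enumerate(states):
            samples.append({"sample_id": f"{d}_{c}", "donor": d, "cell_type": c,
                            "sex": "M" if d_i % 2 == 0 else "F"})
            cols.append(cube[:, d_i, c_i])
    beta = pd.DataFrame(
        np.column_stack(cols), index=cpg_map.index,
        columns=[s["sample_id"] for s in samples],
    )
    sheet = pd.DataFrame(samples).set_index("sample_id")

    truth["mu"] = mu[[cpg_map.index.get_loc(p) for p in truth.index]]
    study = SimStudy(
        config=cfg, beta=beta, sheet=sheet, cpg_map=cpg_map, truth=truth,
        chrom_lengths=chrom_lengths, n_redrawn=n_redrawn,
    )
    study._rngs = rngs  # substreams for the later stages
    return study


# ---------------------------------------------------------------------------
# Stage 2: WGBS tracks
# ---------------------------------------------------------------------------

def simulate_wgbs(cfg: SimConfig, study: SimStudy) -> SimStudy:
    """Per-cell-type WGBS tracks with regional planted effects.

    Planted differentiation effects marked concordant span a short run of
    consecutive WGBS CpGs (size 1 with probability ``frac_single_cpg``, else
    2 + Poisson); all member CpGs carry the seed's signed difference.  The
    realized member count is written back into the truth table
    (``region_n_cpg``), since neighbours are truncated at the midpoint to
    the adjacent array CpG.
    """
    rng = study._rngs["wgbs"]
    truth = study.truth
    diff = truth[truth["phase"] == "differentiation"]
    concordant = pd.Series(rng.random(len(diff)) < cfg.concordant_frac, index=diff.index)
    sizes = {}
    for pid, rec in diff.iterrows():
        if rng.random() < cfg.frac_single_cpg:
            sizes[pid] = 1
        else:
            mean_extra = (cfg.gain_region_extra_mean if rec["direction"] == "gain"
                          else cfg.loss_region_extra_mean)
            sizes[pid] = 2 + int(rng.poisson(mean_extra))

    mu_all = pd.Series(
        {pid: m for pid, m in zip(study.truth.index, study.truth["mu"])}
    )
    rows = []  # chrom, pos0, base, delta, n_mono, n_mac, member_of
    region_realized = {}
    region_id = {}
    next_region = 0
    for chrom, cmap in study.cpg_map.groupby("chrom", sort=False):
        pos0 = cmap["pos0"].to_numpy()
        for j, (pid, rec) in enumerate(cmap.iterrows()):
            p = int(rec["pos0"])
            left_lim = (pos0[j - 1] + p) // 2 if j > 0 else 0
            right_lim = (p + pos0[j + 1]) // 2 if j + 1 < len(pos0) else p + 5000
            lefts, cur = [], p
            for _ in range(cfg.neighbors_per_side):
                cur = cur - (15 + int(rng.geometric(1 / 45)))
                if cur <= left_lim:
                    break
                lefts.append(cur)
            rights, cur = [], p
            for _ in range(cfg.neighbors_per_side):
                cur = cur + (15 + int(rng.geometric(1 / 45)))
                if cur >= right_lim:
                    break
                rights.append(cur)

            is_diff = pid in diff.index
            base_seed = float(mu_all[pid]) if pid in mu_all.index else float(rng.beta(0.4, 0.4))
            delta_seed = 0.0
            members: set[int] = set()
            if is_diff and bool(concordant[pid]):
                delta_seed = float(truth.loc[pid, "true_delta"])
                want = sizes[pid]
                members = {p}
                li, ri = 0, 0
                while len(members) < want and (li < len(lefts) or ri < len(rights)):
                    if ri < len(rights) and (ri <= li or li >= len(lefts)):
                        members.add(rights[ri]); ri += 1
                    elif li < len(lefts):
                        members.add(lefts[li]); li += 1
                region_realized[pid] = len(members)
                region_id[pid] = next_region
                next_region += 1

            covered = rng.random() < cfg.wgbs_coverage
            n_don = cfg.wgbs_n_donors if covered else 2
            if delta_seed == 0.0 and rng.random() < cfg.bg_spurious_wgbs:
                # spurious >=5% differences at seed positions without a
                # planted region; random sign, so half match the array
                # direction of a background CpG; sign points inward when the
                # baseline leaves no room, so clipping cannot erase the
                # configured background rate
                delta_seed = float(rng.uniform(0.05, 0.18)) * (1 if rng.random() < 0.5 else -1)
                if not 0.0 <= base_seed + delta_seed <= 1.0:
                    delta_seed = -delta_seed
            rows.append((chrom, p, base_seed, delta_seed, n_don, cfg.wgbs_n_donors))
            for q in lefts + rights:
                if q in members:
                    base, delta = base_seed, delta_seed
                else:
                    # non-region CpGs differ only by measurement noise
                    base, delta = float(rng.beta(0.4, 0.4)), 0.0
                rows.append((chrom, q, base, delta, cfg.wgbs_n_donors, cfg.wgbs_n_donors))

    df = pd.DataFrame(rows, columns=["chrom", "pos0", "base", "delta", "n_mono", "n_mac"])
    df = df.drop_duplicates(["chrom", "pos0"]).sort_values(["chrom", "pos0"]).reset_index(drop=True)
    noise_m = rng.normal(0, cfg.wgbs_noise_sd, size=len(df))
    noise_a = rng.normal(0, cfg.wgbs_noise_sd, size=len(df))
    mono = np.clip(df["base"] + noise_m, 0, 1)
    mac = np.clip(df["base"] + df["delta"] + noise_a, 0, 1)
    study.wgbs_mono = pd.DataFrame({"chrom": df["chrom"], "pos0": df["pos0"], "beta": mono})
    study.wgbs_mac = pd.DataFrame({"chrom": df["chrom"], "pos0": df["pos0"], "beta": mac})
    study.wgbs_ndonors = df[["chrom", "pos0", "n_mono", "n_mac"]].copy()

    truth["wgbs_concordant"] = False
    truth.loc[diff.index, "wgbs_concordant"] = concordant
    truth["region_id"] = pd.Series(region_id, dtype="Int64")
    truth["region_n_cpg"] = pd.Series(region_realized, dtype="Int64")
    return study


# ---------------------------------------------------------------------------
# Stage 3: annotation tracks, genome, motifs, ChIP, Hi-C, genes, expression
# ---------------------------------------------------------------------------

def _draw_state_pair(rng, direction: str | None, cfg: SimConfig) -> tuple[str, str]:
    bg_states = list(_BG_STATE_P)
    bg_p = np.array(list(_BG_STATE_P.values()))
    def background_pair():
        s = bg_states[rng.choice(len(bg_states), p=bg_p)]
        if rng.random() < 0.92:
            return s, s
        return s, bg_states[rng.choice(len(bg_states), p=bg_p)]
    if direction == "gain":
        u = rng.random()
        if u < cfg.gain_transition_frac:
            return GAIN_TRANSITIONS[rng.integers(len(GAIN_TRANSITIONS))]
        if u < cfg.gain_transition_frac + cfg.enhancer_stable_frac_gain:
            return ("enhancer", "enhancer") if rng.random() < 0.5 else ("active_enhancer", "active_enhancer")
        return background_pair()
    if direction == "loss":
        u = rng.random()
        if u < cfg.loss_transition_frac:
            return LOSS_TRANSITIONS[rng.integers(len(LOSS_TRANSITIONS))]
        if u < cfg.loss_transition_frac + cfg.enhancer_stable_frac_loss:
            return ("enhancer", "enhancer") if rng.random() < 0.5 else ("active_enhancer", "active_enhancer")
        return background_pair()
    return background_pair()


def simulate_annotation_tracks(cfg: SimConfig, study: SimStudy) -> SimStudy:
    """Generate all interval tracks, the genome, motifs, ChIP, genes, expression."""
    rng = study._rngs["tracks"]
    grng = study._rngs["genome"]
    truth, cmap = study.truth, study.cpg_map
    diff = truth[truth["phase"] == "differentiation"]
    direction_of = diff["direction"].to_dict()

    # --- chromatin-state consensus on a segment grid -----------------------
    seg_pairs: dict[str, np.ndarray] = {}
    for chrom, L in study.chrom_lengths.items():
        n_seg = L // cfg.segment_bp + 1
        pairs = np.empty((n_seg, 2), dtype=object)
        for i in range(n_seg):
            pairs[i] = _draw_state_pair(rng, None, cfg)
        seg_pairs[chrom] = pairs
    for pid in diff.index:
        chrom, p = cmap.loc[pid, "chrom"], int(cmap.loc[pid, "pos0"])
        seg_pairs[chrom][p // cfg.segment_bp] = _draw_state_pair(
            rng, direction_of[pid], cfg)

    truth["state_mono"] = [
        seg_pairs[cmap.loc[pid, "chrom"]][int(cmap.loc[pid, "pos0"]) // cfg.segment_bp][0]
        for pid in truth.index]
    truth["state_mac"] = [
        seg_pairs[cmap.loc[pid, "chrom"]][int(cmap.loc[pid, "pos0"]) // cfg.segment_bp][1]
        for pid in truth.index]

    donors5 = [f"SD{i+1}" for i in range(cfg.n_state_donors)]
    study.state_tracks = {"monocyte": {}, "macrophage": {}}
    for ct_i, ct in enumerate(["monocyte", "macrophage"]):
        for d in donors5:
            ivs = []
            for chrom, pairs in seg_pairs.items():
                labels = pairs[:, ct_i].copy()
                flip = rng.random(len(labels)) >= cfg.state_concordance
                for i in np.flatnonzero(flip):
                    others = [s for s in CHROM_STATES if s != labels[i]]
                    labels[i] = others[rng.integers(len(others))]
                for i, lab in enumerate(labels):
                    ivs.append(mio.GenomicInterval(
                        chrom, i * cfg.segment_bp, (i + 1) * cfg.segment_bp, str(lab),
                        donor=d, cell_type=ct))
            study.state_tracks[ct][d] = ivs

    # --- DNaseI consensus + per-donor peaks --------------------------------
    dhs_pair = {}
    bg = cfg.dhs_bg
    for pid in cmap.index:
        d = direction_of.get(pid)
        u = rng.random()
        if d == "gain" and u < cfg.dhs_change_gain:
            dhs_pair[pid] = (False, True)
        elif d == "loss" and u < cfg.dhs_change_loss:
            dhs_pair[pid] = (False, True)
        else:
            v = rng.random()
            if v < bg["both"]:
                dhs_pair[pid] = (True, True)
            elif v < bg["both"] + bg["mono_only"]:
                dhs_pair[pid] = (True, False)
            elif v < bg["both"] + bg["mono_only"] + bg["mac_only"]:
                dhs_pair[pid] = (False, True)
            else:
                dhs_pair[pid] = (False, False)
    truth["dhs_mono"] = [dhs_pair[p][0] for p in truth.index]
    truth["dhs_mac"] = [dhs_pair[p][1] for p in truth.index]

    study.dnase_tracks = {"monocyte": {}, "macrophage": {}}
    n_dnase = {"monocyte": cfg.n_dnase_mono, "macrophage": cfg.n_dnase_mac}
    for ct_i, ct in enumerate(["monocyte", "macrophage"]):
        donor_ivs = {f"DN{ct[:2]}{i+1}": [] for i in range(n_dnase[ct])}
        donor_names = list(donor_ivs)
        for pid in cmap.index:
            has = dhs_pair[pid][ct_i]
            p_yes = 0.85 if has else 0.03
            votes = rng.random(n_dnase[ct]) < p_yes
            chrom, p = cmap.loc[pid, "chrom"], int(cmap.loc[pid, "pos0"])
            for d_i in np.flatnonzero(votes):
                donor_ivs[donor_names[d_i]].append(
                    mio.GenomicInterval(chrom, max(0, p - 75), p + 75, "1",
                                        donor=donor_names[d_i], cell_type=ct))
        study.dnase_tracks[ct] = donor_ivs

    # --- Hi-C enhancer intervals ------------------------------------------
    study.hic = {"monocyte": [], "macrophage": []}
    is_diff_dmc = cmap.index.isin(diff.index)
    for ct in ["monocyte", "macrophage"]:
        p_cover = np.where(is_diff_dmc, cfg.hic_prob_dmc, cfg.hic_prob_bg)
        covered = rng.random(len(cmap)) < p_cover
        for pid in cmap.index[covered]:
            chrom, p = cmap.loc[pid, "chrom"], int(cmap.loc[pid, "pos0"])
            study.hic[ct].append(
                mio.GenomicInterval(chrom, max(0, p - 400), p + 400, "enh", cell_type=ct))

    # --- genome + motif placements ----------------------------------------
    genome_arr = {
        chrom: grng.integers(0, 4, size=L).astype(np.uint8)
        for chrom, L in study.chrom_lengths.items()
    }
    motif_names = list(MOTIF_CONSENSUS)
    site_list = []
    motif_of: dict[str, str | None] = {}
    for pid in cmap.index:
        d = direction_of.get(pid)
        probs = (cfg.gain_motif_probs if d == "gain"
                 else cfg.loss_motif_probs if d == "loss" else None)
        motif = None
        if probs is not None:
            u, acc = rng.random(), 0.0
            for m, pm in probs.items():
                acc += pm
                if u < acc:
                    motif = m
                    break
        else:
            if rng.random() < cfg.bg_motif_rate:
                motif = motif_names[rng.integers(len(motif_names))]
        motif_of[pid] = motif
        if motif is None:
            continue
        cons = MOTIF_CONSENSUS[motif]
        if rng.random() < 0.5:
            cons = reverse_complement(cons)
        chrom, p = cmap.loc[pid, "chrom"], int(cmap.loc[pid, "pos0"])
        start = p + int(rng.integers(-cfg.motif_window + 5, cfg.motif_window - len(cons) - 4))
        start = max(0, min(start, study.chrom_lengths[chrom] - len(cons)))
        codes = np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in cons], dtype=np.uint8)
        genome_arr[chrom][start:start + len(cons)] = codes
        site_list.append(mio.GenomicInterval(chrom, start, start + len(cons), motif))
    study.motif_sites = site_list
    truth["motif"] = [motif_of.get(p) for p in truth.index]
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    study.genome = {c: lut[a].tobytes().decode() for c, a in genome_arr.items()}
    study.pwms = [consensus_pwm(m, cons) for m, cons in MOTIF_CONSENSUS.items()]

    # --- ChIP peaks (CEBP, PU1) -------------------------------------------
    study.chip_tracks = {tf: {"monocyte": [], "macrophage": []} for tf in MOTIF_CHIP.values()}
    chip_gain_flag = {}
    for pid, motif in motif_of.items():
        if motif is None or motif not in MOTIF_CHIP:
            continue
        tf = MOTIF_CHIP[motif]
        chrom, p = cmap.loc[pid, "chrom"], int(cmap.loc[pid, "pos0"])
        iv = lambda: mio.GenomicInterval(chrom, max(0, p - 100), p + 100, tf)
        is_gain_dmc = direction_of.get(pid) == "gain"
        u = rng.random()
        if is_gain_dmc and u < cfg.chip_gain_at_motif:
            study.chip_tracks[tf]["macrophage"].append(iv())
            chip_gain_flag[pid] = True
        elif u < cfg.chip_gain_bg:
            study.chip_tracks[tf]["macrophage"].append(iv())
            chip_gain_flag[pid] = True
        elif u < cfg.chip_gain_bg + cfg.chip_stable_bg:
            study.chip_tracks[tf]["monocyte"].append(iv())
            study.chip_tracks[tf]["macrophage"].append(iv())
    truth["chip_binding_gain"] = [bool(chip_gain_flag.get(p, False)) for p in truth.index]

    # --- genes + expression ------------------------------------------------
    genes_rng = study._rngs["genes"]
    gene_rows = []
    gid = 0
    for chrom, L in study.chrom_lengths.items():
        pos = 2000
        while pos < L - 8000:
            span = int(genes_rng.integers(2000, 6000))
            strand = "+" if genes_rng.random() < 0.5 else "-"
            tss, tes = (pos, pos + span) if strand == "+" else (pos + span, pos)
            gene_rows.append({"gene": f"GENE{gid:05d}", "chrom": chrom,
                              "tss": tss, "tes": tes, "strand": strand})
            gid += 1
            pos += span + int(genes_rng.integers(4000, 9000))
    genes = pd.DataFrame(gene_rows)
    study.genes = genes

    ng = nearest_genes_bulk(cmap.loc[diff.index], genes)
    shift = pd.Series(0.0, index=genes["gene"])
    noise = genes_rng.normal(0, cfg.expr_noise, size=len(shift))
    shift[:] = noise
    for pid, gene in ng["nearest_gene"].items():
        if gene is None:
            continue
        shift[gene] = (cfg.expr_shift_gain if direction_of[pid] == "gain"
                       else cfg.expr_shift_loss) + genes_rng.normal(0, 0.1)
    mono_expr = genes_rng.uniform(1, 8, size=len(genes))
    study.expression = pd.DataFrame({
        "gene": genes["gene"],
        "monocyte": mono_expr,
        "macrophage": mono_expr + shift.to_numpy(),
    }).set_index("gene")
    return study


def simulate_all(cfg: SimConfig) -> SimStudy:
    """Run all three generator stages."""
    study = simulate_study(cfg)
    simulate_wgbs(cfg, study)
    simulate_annotation_tracks(cfg, study)
    return study


# ---------------------------------------------------------------------------
# Writers: materialise a study as the plain-text inputs the pipeline reads
# ---------------------------------------------------------------------------

def write_study(study: SimStudy, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_beta_matrix(study.beta, study.sheet, out / "beta.tsv", out / "samples.tsv")
    mio.write_cpg_map(study.cpg_map, out / "cpg_map.tsv")
    study.truth.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)
    if study.wgbs_mono is not None:
        mio.write_bedgraph(study.wgbs_mono, out / "wgbs_monocyte.bedGraph")
        mio.write_bedgraph(study.wgbs_mac, out / "wgbs_macrophage.bedGraph")
        study.wgbs_ndonors.to_csv(out / "wgbs_donor_counts.tsv", sep="\t", index=False)
    if study.genome:
        mio.write_fasta(study.genome, out / "genome.fa")
        mio.write_bed(study.motif_sites, out / "motif_sites.bed")
        write_pwms(study.pwms, out / "motifs.jaspar.txt")
    for ct, donors in study.state_tracks.items():
        for d, ivs in donors.items():
            mio.write_bed(ivs, out / f"states_{ct}_{d}.bed")
    for ct, donors in study.dnase_tracks.items():
        for d, ivs in donors.items():
            mio.write_bed(ivs, out / f"dnase_{ct}_{d}.bed")
    for tf, cts in study.chip_tracks.items():
        for ct, ivs in cts.items():
            mio.write_bed(ivs, out / f"chip_{tf}_{ct}.bed")
    for ct, ivs in study.hic.items():
        mio.write_bed(ivs, out / f"hic_{ct}.bed")
    if study.genes is not None:
        study.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        study.expression.reset_index().to_csv(out / "expression.tsv", sep="\t", index=False)
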