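"""Mapping CpGs to nearest genes and consensus regulatory annotations.

Chromatin states and DNaseI peaks come as per-donor interval tracks; the
consensus label at a position is a majority call (e.g. the same chromatin
state in at least 3 of 5 donors, a DNaseI peak in at least 13 of 26
monocyte donors / 2 of 4 macrophage donors).  Consensus is evaluated at the
cytosine position of each CpG, not per segment, so segment boundaries never
need reconciling.  Nearest genes are found by distance to the closest
transcription start or end site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GenomicInterval

NO_CALL = None


def majority_call(labels: list[str | None], min_votes: int) -> str | None:
    """The unique label reaching ``min_votes`` among donors, else no-call.

    ``None`` entries (no annotation for that donor at this position) carry
    no vote.  If two labels both reach the threshold (possible when
    min_votes <= donors/2) the call is ambiguous -> no-call.
    """
    if not labels:
        raise ValueError("need at least one donor label")
    counts = Counter(l for l in labels if l is not None)
    winners = [l for l, c in counts.items() if c >= min_votes]
    if len(winners) == 1:
        return winners[0]
    return NO_CALL


class DonorTrackSet:
    """Per-donor interval tracks supporting point-label queries and voting."""

    def __init__(self, per_donor: dict[str, list[GenomicInterval]]):
        self.donors = sorted(per_donor)
        self._trees: dict[str, dict[str, IntervalTree]] = {}
        for donor, ivs in per_donor.items():
            trees: dict[str, IntervalTree] = {}
            for iv in ivs:
                trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.label)
            self._trees[donor] = trees

    def labels_at(self, chrom: str, pos0: int) -> list[str | None]:
        out = []
        for donor in self.donors:
            tree = self._trees[donor].get(chrom)
            hits = tree[pos0] if tree is not None else set()
            out.append(next(iter(hits)).data if hits else None)
        return out

    def consensus_at(self, chrom: str, pos0: int, min_votes: int) -> str | None:
        return majority_call(self.labels_at(chrom, pos0), min_votes)

    def consensus_segments(self, min_votes: int) -> tuple[list[GenomicInterval], pd.DataFrame]:
        """Consensus as merged BED4 segments plus a per-segment vote table.

        Votes are constant between adjacent interval breakpoints, so the
        consensus is evaluated once per elementary segment and adjacent
        equal-label segments are merged.
        """
        chroms = sorted({c for t in self._trees.values() for c in t})
        segments: list[GenomicInterval] = []
        votes = []
        for chrom in chroms:
            bps = sorted({
                p for donor in self.donors
                for iv in self._trees[donor].get(chrom, IntervalTree())
                for p in (iv.begin, iv.end)
            })
            run_label, run_start = None, None
            for lo, hi in zip(bps[:-1], bps[1:]):
                label = self.consensus_at(chrom, lo, min_votes)
                if label != run_label:
                    if run_label is not None:
                        segments.append(GenomicInterval(chrom, run_start, lo, run_label))
                    run_label, run_start = label, lo
                if label is not None:
                    counts = Counter(l for l in self.labels_at(chrom, lo) if l is not None)
                    votes.append({"chrom": chrom, "start": lo, "end": hi,
                                  "label": label, "votes": counts[label]})
            if run_label is not None:
                segments.append(GenomicInterval(chrom, run_start, bps[-1], run_label))
        return segments, pd.DataFrame(votes)


class IntervalSet:
    """A plain (consensus-free) interval set with point membership queries."""

    def __init__(self, intervals: list[GenomicInterval]):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.label)

    def contains(self, chrom: str, pos0: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree[pos0])

    def labels_overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return set()
        return {h.data for h in tree.overlap(start, end)}


def nearest_gene(
    chrom: str, pos: int, genes: pd.DataFrame
) -> tuple[str | None, float]:
    """Nearest gene by distance to the closest TSS or TES (1-based points).

    Ties are broken by smaller distance to the TSS, then by lexicographic
    gene name.  Returns (None, nan) when the chromosome carries no gene.
    """
    sub = genes[genes["chrom"] == chrom]
    if len(sub) == 0:
        return None, float("nan")
    d_tss = (sub["tss"] - pos).abs()
    d_tes = (sub["tes"] - pos).abs()
    d = np.minimum(d_tss, d_tes)
    best = d.min()
    cand = sub.loc[d == best].copy()
    cand["d_tss"] = d_tss.loc[cand.index]
    cand = cand.sort_values(["d_tss", "gene"])
    return str(cand["gene"].iloc[0]), float(best)


def nearest_genes_bulk(cpg_map: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Vectorized nearest-gene lookup for a whole CpG map.

    Same contract and tie-breaking as :func:`nearest_gene`; returns a
    probe-indexed frame with nearest_gene and gene_distance columns.  Exact
    distance ties fall back to the scalar routine (rare).
    """
    out_gene = np.full(len(cpg_map), None, dtype=object)
    out_dist = np.full(len(cpg_map), np.nan)
    pid_pos = {pid: i for i, pid in enumerate(cpg_map.index)}
    for chrom, sub in genes.groupby("chrom"):
        cpgs = cpg_map[cpg_map["chrom"] == chrom]
        if len(cpgs) == 0:
            continue
        sites = np.concatenate([sub["tss"].to_numpy(), sub["tes"].to_numpy()])
        site_gene = np.concatenate([sub["gene"].to_numpy()] * 2)
        order = np.argsort(sites, kind="stable")
        sp, sg = sites[order], site_gene[order]
        pos = cpgs["pos"].to_numpy()
        r = np.searchsorted(sp, pos)
        d_right = np.where(r < len(sp), np.abs(sp[np.clip(r, 0, len(sp) - 1)] - pos), np.inf)
        d_left = np.where(r > 0, np.abs(sp[np.clip(r - 1, 0, len(sp) - 1)] - pos), np.inf)
        d = np.minimum(d_left, d_right)
        # a tie needs the scalar tie-break rule; detect any second site at distance d
        n_at_d = (
            np.searchsorted(sp, pos + d, side="right")
            - np.searchsorted(sp, pos - d, side="left")
        )
        pick = np.where(d_right < d_left, np.clip(r, 0, len(sp) - 1),
                        np.clip(r - 1, 0, len(sp) - 1))
        rows = [pid_pos[p] for p in cpgs.index]
        out_dist[rows] = d
        out_gene[rows] = sg[pick]
        for j, (pid, tie) in enumerate(zip(cpgs.index, n_at_d > 1)):
            if tie:
                g, dd = nearest_gene(chrom, int(cpgs["pos"].iloc[j]), genes)
                out_gene[pid_pos[pid]] = g
                out_dist[pid_pos[pid]] = dd
    return pd.DataFrame(
        {"nearest_gene": out_gene, "gene_distance": out_dist}, index=cpg_map.index
    )


def annotate_cpgs(
    cpg_map: pd.DataFrame,
    state_tracks: dict[str, DonorTrackSet],
    dnase_tracks: dict[str, DonorTrackSet],
    hic: dict[str, IntervalSet],
    genes: pd.DataFrame,
    motif_sites: IntervalSet | None = None,
    state_min_votes: int = 3,
    dnase_min_votes: dict[str, int] | None = None,
    window_halfwidth: int = 25,
) -> pd.DataFrame:
    """One annotation row per CpG.

    State / DHS / Hi-C-enhancer membership is a point overlap at the
    cytosine position; motif hits are sites overlapping the +-window around
    it.  Uncovered positions are annotated no-call (states) or False
    (peaks).  Cell-type keys: "monocyte" and "macrophage".
    """
    dnase_min_votes = dnase_min_votes or {"monocyte": 13, "macrophage": 2}
    rows = []
    for pid, rec in cpg_map.iterrows():
        chrom, pos0 = rec["chrom"], int(rec["pos0"])
        row: dict = {"probe_id": pid}
        for ct, tracks in state_tracks.items():
            row[f"state_{_short(ct)}"] = tracks.consensus_at(chrom, pos0, state_min_votes)
        for ct, tracks in dnase_tracks.items():
            call = tracks.consensus_at(chrom, pos0, dnase_min_votes[ct])
            row[f"dhs_{_short(ct)}"] = call is not None
        for ct, ivset in hic.items():
            row[f"hic_{_short(ct)}"] = ivset.contains(chrom, pos0)
        if motif_sites is not None:
            hits = motif_sites.labels_overlapping(
                chrom, pos0 - window_halfwidth, pos0 + window_halfwidth + 1
            )
            row["motif_hits"] = ",".join(sorted(hits))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("probe_id")
    return out.join(nearest_genes_bulk(cpg_map, genes))


def _short(cell_type: str) -> str:
    return {"monocyte": "mono", "macrophage": "mac"}.get(cell_type, cell_type)
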