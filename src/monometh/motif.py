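"""Known-motif PWM enrichment around DMCs.

A simplified known-motif scan: position weight matrices are scored by
log2-odds against a background base composition, a window is called a hit
when some offset (either strand) reaches a configurable fraction of the
motif's maximum attainable score, and per-motif enrichment of DMC windows
versus a seeded random sample of non-DMC windows is assessed with the
Fisher exact test.  De novo motif discovery and GC-matched backgrounds are
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import EnrichmentResult, _result, results_to_frame

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class Pwm:
    """A position weight matrix over ACGT with log2-odds scoring."""

    name: str
    probs: np.ndarray                  # (L, 4), rows sum to 1
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("probs must be (L, 4)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("each PWM position must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def log_odds(self) -> np.ndarray:
        """(L, 4) log2-odds matrix with pseudocount smoothing."""
        p = (self.probs + self.pseudocount) / (1 + 4 * self.pseudocount)
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        # summed left-to-right like the scanner accumulates window scores,
        # so an exact consensus match reaches the maximum bit-for-bit and
        # threshold_frac = 1.0 behaves as advertised
        return float(sum(self.log_odds.max(axis=1).tolist()))

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.name, self.probs[::-1, ::-1], self.pseudocount,
                   self.background[::-1])


@dataclass(frozen=True)
class MotifHit:
    motif: str
    chrom: str
    start: int   # 0-based offset of the match
    strand: str
    score: float


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN to 0..3 (N -> -1)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    bad = (out == -1) & (arr != ord("N"))
    if bad.any():
        raise ValueError(f"invalid character {chr(arr[np.argmax(bad)])!r} in sequence")
    return out


def _scan_codes(codes: np.ndarray, lom: np.ndarray) -> np.ndarray:
    """Scores of every window of length L along an encoded sequence.

    N positions (code -1) contribute 0 (the background expectation).
    """
    L = lom.shape[0]
    n = len(codes) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for i in range(L):
        col = codes[i : i + n]
        contrib = np.where(col >= 0, lom[i, np.clip(col, 0, 3)], 0.0)
        scores += contrib
    return scores


def scan_pwm(
    seq: str, pwm: Pwm, threshold_frac: float = 0.8, chrom: str = "seq"
) -> list[MotifHit]:
    """Scan both strands of a sequence for PWM matches.

    A hit is any offset whose log2-odds score reaches ``threshold_frac`` of
    the motif's maximum attainable score.  Minus-strand hits are reported at
    their forward-strand start coordinate.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    if not seq:
        return []
    codes = encode(seq)
    thr = threshold_frac * pwm.max_score
    hits = []
    fwd = _scan_codes(codes, pwm.log_odds)
    rev = _scan_codes(codes, pwm.reverse_complement().log_odds)
    for i in np.flatnonzero(fwd >= thr):
        hits.append(MotifHit(pwm.name, chrom, int(i), "+", float(fwd[i])))
    for i in np.flatnonzero(rev >= thr):
        hits.append(MotifHit(pwm.name, chrom, int(i), "-", float(rev[i])))
    return sorted(hits, key=lambda h: (h.start, h.strand))


def window_has_hit(
    seqs: dict[str, str],
    chrom: str,
    pos0: int,
    pwm: Pwm,
    window_halfwidth: int = 25,
    threshold_frac: float = 0.8,
) -> bool:
    """Does the +-window around a CpG contain at least one PWM hit?

    Windows reaching past chromosome bounds are truncated.
    """
    seq = seqs[chrom]
    lo = max(0, pos0 - window_halfwidth)
    hi = min(len(seq), pos0 + window_halfwidth + 1)
    return bool(scan_pwm(seq[lo:hi], pwm, threshold_frac, chrom))


def motif_enrichment(
    target_cpgs: pd.DataFrame,
    background_pool: pd.DataFrame,
    seqs: dict[str, str],
    pwms: list[Pwm],
    window_halfwidth: int = 25,
    threshold_frac: float = 0.8,
    background_n: int = 50000,
    rng: np.random.Generator | None = None,
    direction_set: str = "all",
) -> pd.DataFrame:
    """Per-motif enrichment of targets over a sampled CpG background.

    ``target_cpgs`` / ``background_pool`` are frames with chrom and pos0
    columns (probe-indexed).  ``background_n`` CpGs are sampled without
    replacement from the pool (all of it when smaller).  Motifs are ranked
    by p; a motif with zero hits anywhere is flagged uninformative.
    """
    rng = rng or np.random.default_rng()
    n_bg = min(background_n, len(background_pool))
    bg = background_pool.iloc[
        rng.choice(len(background_pool), size=n_bg, replace=False)
    ]
    results = []
    for pwm in pwms:
        t_hits = np.array([
            window_has_hit(seqs, r.chrom, int(r.pos0), pwm, window_halfwidth, threshold_frac)
            for r in target_cpgs.itertuples()
        ])
        b_hits = np.array([
            window_has_hit(seqs, r.chrom, int(r.pos0), pwm, window_halfwidth, threshold_frac)
            for r in bg.itertuples()
        ])
        a, b = int(t_hits.sum()), int((~t_hits).sum())
        c, d = int(b_hits.sum()), int((~b_hits).sum())
        res = _result(pwm.name, a, b, c, d, direction_set)
        if a + c == 0:
            res.flagged = True
        results.append(res)
    df = results_to_frame(results)
    df["uninformative"] = (df["a"] + df["c"]) == 0
    return df.sort_values(["p", "stratum"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# JASPAR-style plain-text PWM IO
# ---------------------------------------------------------------------------

def read_pwms(path: str | Path, pseudocount: float = 0.01) -> list[Pwm]:
    """Read JASPAR-style matrices: '>name' then four 'A [ 1 2 ... ]' rows.

    Counts (or probabilities) are normalised column-wise to probabilities.
    """
    pwms = []
    name, rows = None, {}
    def flush():
        if name is None:
            return
        mat = np.array([rows[b] for b in BASES], dtype=float).T  # (L, 4)
        mat = mat / mat.sum(axis=1, keepdims=True)
        pwms.append(Pwm(name, mat, pseudocount))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name, rows = line[1:].split()[0], {}
            else:
                base, rest = line.split(None, 1)
                vals = rest.replace("[", " ").replace("]", " ").split()
                rows[base.upper()] = [float(v) for v in vals]
    flush()
    return pwms


def write_pwms(pwms: list[Pwm], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.name}\n")
            for j, base in enumerate(BASES):
                vals = " ".join(f"{v:.4f}" for v in pwm.probs[:, j])
                fh.write(f"{base} [ {vals} ]\n")


def consensus_pwm(name: str, consensus: str, match_prob: float = 0.85,
                  pseudocount: float = 0.01) -> Pwm:
    """Build a PWM concentrated on a consensus sequence."""
    off = (1 - match_prob) / 3
    mat = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus.upper()):
        mat[i, _CODE[b]] = match_prob
    return Pwm(name, mat, pseudocount)
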