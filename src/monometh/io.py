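"""File formats and coordinate conventions.

Everything genomic is held internally in 0-based half-open coordinates.
CpG maps are read with 1-based cytosine positions (the methylation-array
manifest convention) and converted exactly once, on read, to a ``pos0``
column; all overlap arithmetic downstream uses ``pos0``.

Formats handled here: BED3/BED4 interval tracks, bedGraph WGBS tracks with a
donor-count sidecar, TSV beta matrix + sample sheet, CpG position maps, gene
models, expression tables and FASTA genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class BedParseError(ValueError):
    """Raised for malformed interval lines; carries the offending line number."""


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """A labelled genomic interval, 0-based half-open.

    ``label`` carries whatever the track encodes: a chromatin-state name, a
    binary peak flag ("1"), a motif name or an enhancer id.  ``donor`` and
    ``cell_type`` are optional provenance for per-donor tracks.
    """

    chrom: str
    start: int
    end: int
    label: str = "1"
    donor: str | None = None
    cell_type: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if not self.label:
            raise ValueError("label must be non-empty")

    def contains(self, pos0: int) -> bool:
        """Point overlap at a 0-based position (half-open arithmetic)."""
        return self.start <= pos0 < self.end


@dataclass(frozen=True)
class CpGSite:
    """A measured cytosine; ``pos`` is the 1-based manifest coordinate."""

    probe_id: str
    chrom: str
    pos: int
    strand: str = "*"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos is 1-based and must be >= 1, got {self.pos}")

    @property
    def pos0(self) -> int:
        return self.pos - 1


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED3/BED4 file into intervals, order preserved.

    Column 4 supplies the label when present, else "1" (binary-peak
    convention).  Malformed coordinates raise :class:`BedParseError` naming
    the 1-based line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            label = fields[3] if len(fields) > 3 and fields[3] else "1"
            try:
                out.append(GenomicInterval(fields[0], start, end, label))
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a single-CpG bedGraph (chrom, start, end, value in [0,1]).

    Returns a frame with columns chrom, pos0 (=start), beta.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "beta"],
        comment="#",
    )
    bad = df[(df["beta"] < 0) | (df["beta"] > 1)]
    if len(bad):
        raise ValidationError(f"{path}: bedGraph values outside [0,1] at rows {bad.index[:5].tolist()}")
    out = df.rename(columns={"start": "pos0"})[["chrom", "pos0", "beta"]]
    return out


def write_bedgraph(df: pd.DataFrame, path: str | Path) -> None:
    """Write chrom/pos0/beta rows as single-base bedGraph records."""
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": df["pos0"].astype(int),
            "end": df["pos0"].astype(int) + 1,
            "beta": df["beta"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Beta matrix + sample sheet
# ---------------------------------------------------------------------------

def read_beta_matrix(
    path: str | Path, samplesheet: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a CpG x sample beta matrix and its sample sheet.

    The matrix is TSV with probe ids in the first column; the sheet is TSV
    with columns sample_id, donor, cell_type, sex.  Matrix columns must match
    the sheet's sample ids exactly (as sets); values must lie in [0,1] or be
    missing (empty/NaN).
    """
    beta = pd.read_csv(path, sep="\t", index_col=0)
    sheet = pd.read_csv(samplesheet, sep="\t", dtype=str).set_index("sample_id")
    missing_cols = set(sheet.index) - set(beta.columns)
    extra_cols = set(beta.columns) - set(sheet.index)
    if missing_cols or extra_cols:
        raise ValidationError(
            "beta matrix / sample sheet mismatch: "
            f"missing from matrix {sorted(missing_cols)}, "
            f"absent from sheet {sorted(extra_cols)}"
        )
    if beta.index.duplicated().any():
        dupes = beta.index[beta.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate probe ids: {dupes[:5]}")
    vals = beta.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (vals < 0) | (vals > 1)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"beta value outside [0,1]: {vals[r, c]} at probe "
            f"{beta.index[r]}, sample {beta.columns[c]}"
        )
    return beta[list(sheet.index)], sheet


def write_beta_matrix(
    beta: pd.DataFrame, sheet: pd.DataFrame, path: str | Path, sheet_path: str | Path
) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")
    sheet.reset_index().to_csv(sheet_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CpG map, gene models, expression
# ---------------------------------------------------------------------------

def read_cpg_map(path: str | Path) -> pd.DataFrame:
    """Read probe_id/chrom/pos(/strand) TSV; adds the 0-based ``pos0`` column."""
    df = pd.read_csv(path, sep="\t")
    if df["probe_id"].duplicated().any():
        raise ValidationError("duplicate probe ids in CpG map")
    if (df["pos"] < 1).any():
        raise ValidationError("CpG map positions are 1-based and must be >= 1")
    if "strand" not in df.columns:
        df["strand"] = "*"
    df = df.set_index("probe_id")
    df["pos0"] = df["pos"] - 1
    return df


def write_cpg_map(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "pos", "strand") if c in df.columns]
    df[cols].reset_index().to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Gene models TSV: gene, chrom, tss, tes (1-based points), strand."""
    df = pd.read_csv(path, sep="\t")
    if (df["tss"] == df["tes"]).any():
        raise ValidationError("gene with tss == tes")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValidationError(f"invalid strand for genes {df.loc[bad, 'gene'].tolist()[:5]}")
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression TSV: gene + one logTPM column per cell type; gene-indexed."""
    return pd.read_csv(path, sep="\t").set_index("gene")


# ---------------------------------------------------------------------------
# FASTA (synthetic genomes)
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            else:
                if name is None:
                    raise ValidationError(f"{path}: sequence before header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": [iv.start for iv in intervals],
            "end": [iv.end for iv in intervals],
            "label": [iv.label for iv in intervals],
        }
    )
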