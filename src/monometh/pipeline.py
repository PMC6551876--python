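"""End-to-end pipeline driver.

Stages: (simulate) -> ewas -> annotate -> enrich -> dmr -> motif ->
thresholds.  Each stage consumes in-memory objects and writes a TSV; a JSON
manifest records versions, seed, thresholds and per-stage record counts.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .annotate import DonorTrackSet, IntervalSet, annotate_cpgs
from .config import PipelineConfig
from .dmr import WgbsPair, concordance_enrichment, demarcate_dmrs
from .enrich import (
    expression_shift,
    feature_enrichment,
    results_to_frame,
    tf_binding_gain,
    transition_matrix,
)
from .ewas import call_dmcs, ewas_scan
from .motif import motif_enrichment, read_pwms
from .simulate import MOTIF_CHIP, SimStudy, simulate_all, write_study
from .thresholds import apply_cutoffs, rerun_enrichments, retained_sets


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineResult:
    config: PipelineConfig
    dmc_table: pd.DataFrame | None = None
    annotation: pd.DataFrame | None = None
    enrichment: dict = field(default_factory=dict)
    dmr_table: pd.DataFrame | None = None
    nondmc_wgbs: pd.DataFrame | None = None
    concordance: dict = field(default_factory=dict)
    motif_tables: dict = field(default_factory=dict)
    retention: pd.DataFrame | None = None
    rerun: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def load_study_from_dir(cfg: PipelineConfig, indir: str | Path) -> SimStudy:
    """Read pipeline inputs from a directory in the generator's layout."""
    d = Path(indir)
    beta, sheet = mio.read_beta_matrix(d / "beta.tsv", d / "samples.tsv")
    cpg_map = mio.read_cpg_map(d / "cpg_map.tsv")
    study = SimStudy(config=cfg.sim, beta=beta, sheet=sheet, cpg_map=cpg_map,
                     truth=pd.DataFrame())
    tp = d / "truth.tsv"
    if tp.exists():
        study.truth = pd.read_csv(tp, sep="\t").set_index("probe_id")
    if (d / "wgbs_monocyte.bedGraph").exists():
        study.wgbs_mono = mio.read_bedgraph(d / "wgbs_monocyte.bedGraph")
        study.wgbs_mac = mio.read_bedgraph(d / "wgbs_macrophage.bedGraph")
        study.wgbs_ndonors = pd.read_csv(d / "wgbs_donor_counts.tsv", sep="\t")
    if (d / "genome.fa").exists():
        study.genome = mio.read_fasta(d / "genome.fa")
        study.motif_sites = mio.read_bed(d / "motif_sites.bed")
        study.pwms = read_pwms(d / "motifs.jaspar.txt")
    for ct in ("monocyte", "macrophage"):
        study.state_tracks[ct] = {
            p.stem.split("_")[-1]: mio.read_bed(p)
            for p in sorted(d.glob(f"states_{ct}_*.bed"))
        }
        study.dnase_tracks[ct] = {
            p.stem.split("_")[-1]: mio.read_bed(p)
            for p in sorted(d.glob(f"dnase_{ct}_*.bed"))
        }
        hp = d / f"hic_{ct}.bed"
        if hp.exists():
            study.hic[ct] = mio.read_bed(hp)
    for p in sorted(d.glob("chip_*_*.bed")):
        _, tf, ct = p.stem.split("_", 2)
        study.chip_tracks.setdefault(tf, {})[ct] = mio.read_bed(p)
    if (d / "genes.tsv").exists():
        study.genes = mio.read_gene_models(d / "genes.tsv")
        study.expression = mio.read_expression(d / "expression.tsv")
    return study


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(cfg: PipelineConfig, write: bool = True) -> PipelineResult:
    cfg.validate()
    out = Path(cfg.outdir)
    if write:
        out.mkdir(parents=True, exist_ok=True)

    if cfg.simulate:
        cfg.sim.seed = cfg.seed
        study = simulate_all(cfg.sim)
        if write:
            write_study(study, out / "inputs")
    else:
        study = load_study_from_dir(cfg, cfg.inputs["dir"])

    result = PipelineResult(config=cfg, truth=study.truth if len(study.truth) else None)
    counts: dict[str, int] = {}

    dmc = _run_ewas(study, cfg)
    result.dmc_table = dmc
    counts["cpgs_tested"] = int(dmc["p"].notna().sum())
    counts["dmcs"] = int(dmc["is_dmc"].sum())

    annotation = None
    if "annotate" in cfg.stages:
        annotation = _run_annotate(study, cfg)
        result.annotation = annotation
        counts["cpgs_annotated"] = len(annotation)

    if "enrich" in cfg.stages and annotation is not None:
        result.enrichment = _run_enrich(study, cfg, dmc, annotation)

    if "dmr" in cfg.stages and study.wgbs_mono is not None:
        dmr_table, nondmc, conc = _run_dmr(study, cfg, dmc)
        result.dmr_table = dmr_table
        result.nondmc_wgbs = nondmc
        result.concordance = conc
        counts["dmcs_wgbs_covered"] = int(dmr_table["covered"].sum())
        counts["dmcs_wgbs_concordant"] = int(dmr_table["concordant"].sum())

    if "motif" in cfg.stages and study.genome:
        result.motif_tables = _run_motif(study, cfg, dmc)

    if ("thresholds" in cfg.stages and result.dmr_table is not None
            and annotation is not None):
        result.retention, result.rerun = _run_thresholds(
            study, cfg, dmc, result.dmr_table, annotation)

    result.manifest = {
        "package": "monometh",
        "version": __version__,
        "seed": cfg.seed,
        "thresholds": {
            "fdr_q": cfg.fdr_q, "ms_cutoff": cfg.ms_cutoff,
            "wgbs_min_diff": cfg.wgbs_min_diff, "dmr_max_gap": cfg.dmr_max_gap,
            "motif_window": cfg.motif_window, "background_n": cfg.background_n,
        },
        "counts": counts,
    }
    if write:
        _write_outputs(result, out)
    return result


@_stage("ewas")
def _run_ewas(study: SimStudy, cfg: PipelineConfig) -> pd.DataFrame:
    scan = ewas_scan(study.beta, study.sheet, states=cfg.sim.cell_states,
                     min_donors=cfg.min_donors)
    return call_dmcs(scan, q_max=cfg.fdr_q, ms_min=cfg.ms_cutoff,
                     states=cfg.sim.cell_states, multi_frac=cfg.multi_frac)


@_stage("annotate")
def _run_annotate(study: SimStudy, cfg: PipelineConfig) -> pd.DataFrame:
    state_tracks = {ct: DonorTrackSet(d) for ct, d in study.state_tracks.items()}
    dnase_tracks = {ct: DonorTrackSet(d) for ct, d in study.dnase_tracks.items()}
    hic = {ct: IntervalSet(ivs) for ct, ivs in study.hic.items()}
    motif_sites = IntervalSet(study.motif_sites) if study.motif_sites else None
    return annotate_cpgs(
        study.cpg_map, state_tracks, dnase_tracks, hic, study.genes,
        motif_sites=motif_sites, state_min_votes=cfg.state_min_votes,
        dnase_min_votes={"monocyte": cfg.dnase_min_votes_mono,
                         "macrophage": cfg.dnase_min_votes_mac},
        window_halfwidth=cfg.motif_window,
    )


def _dmc_sets(dmc: pd.DataFrame):
    """Differentiation gain/loss DMC ids and the measured non-DMC background."""
    is_diff = dmc["is_dmc"] & (dmc["phase"] == "differentiation")
    gain = dmc.index[is_diff & (dmc["direction"] == "gain")]
    loss = dmc.index[is_diff & (dmc["direction"] == "loss")]
    background = dmc.index[~dmc["is_dmc"] & dmc["p"].notna()]
    return gain, loss, background


@_stage("enrich")
def _run_enrich(study: SimStudy, cfg: PipelineConfig, dmc: pd.DataFrame,
                ann: pd.DataFrame) -> dict:
    gain, loss, bg = _dmc_sets(dmc)
    out: dict = {}

    state_results = []
    for ct in ("mono", "mac"):
        for name, targets in (("gain", gain), ("loss", loss)):
            res = feature_enrichment(
                targets, ann[f"state_{ct}"].notna(), bg,
                strata=ann[f"state_{ct}"], direction_set=name)
            tab = results_to_frame(res)
            tab["cell_type"] = ct
            state_results.append(tab)
    out["states"] = pd.concat(state_results, ignore_index=True)

    out["transitions"] = transition_matrix(
        gain, loss, ann["state_mono"], ann["state_mac"])

    hic_results = []
    for ct in ("mono", "mac"):
        res = feature_enrichment(gain.union(loss), ann[f"hic_{ct}"], bg)
        tab = results_to_frame(res, fdr=False)
        tab["cell_type"] = ct
        hic_results.append(tab)
    out["hic"] = pd.concat(hic_results, ignore_index=True)

    dhs_change = ann["dhs_mono"] != ann["dhs_mac"]
    dhs_results = []
    for name, targets in (("gain", gain), ("loss", loss)):
        tab = results_to_frame(
            feature_enrichment(targets, dhs_change, bg, direction_set=name),
            fdr=False)
        dhs_results.append(tab)
    out["dhs_change"] = pd.concat(dhs_results, ignore_index=True)

    # TF binding gain at motif-overlapping CpGs
    if study.chip_tracks and "motif_hits" in ann.columns:
        chip_sets = {tf: {ct: IntervalSet(ivs) for ct, ivs in cts.items()}
                     for tf, cts in study.chip_tracks.items()}
        rows = []
        for motif, tf in MOTIF_CHIP.items():
            has_motif = ann["motif_hits"].fillna("").str.split(",").apply(
                lambda hits: motif in hits)
            t_idx = gain[has_motif.loc[gain]]
            b_idx = bg[has_motif.loc[bg]]
            if len(t_idx) == 0 or len(b_idx) == 0:
                continue
            binding_gain = pd.Series({
                pid: (chip_sets[tf]["macrophage"].contains(
                        study.cpg_map.loc[pid, "chrom"], int(study.cpg_map.loc[pid, "pos0"]))
                      and not chip_sets[tf]["monocyte"].contains(
                        study.cpg_map.loc[pid, "chrom"], int(study.cpg_map.loc[pid, "pos0"])))
                for pid in t_idx.union(b_idx)})
            res, mean_d = tf_binding_gain(t_idx, b_idx, binding_gain,
                                          dmc["delta_beta"], motif)
            rows.append({"motif": motif, "tf": tf, "a": res.a, "b": res.b,
                         "c": res.c, "d": res.d, "odds_ratio": res.odds_ratio,
                         "log2_or": res.log2_or, "p": res.p,
                         "p_capped": res.p_capped,
                         "mean_delta_pct": mean_d, "flagged": res.flagged})
        out["tf_binding_gain"] = pd.DataFrame(rows)

    if study.expression is not None and "nearest_gene" in ann.columns:
        rows = []
        for name, targets in (("gain", gain), ("loss", loss)):
            genes = [g for g in ann.loc[targets, "nearest_gene"] if g is not None]
            try:
                w, p, med = expression_shift(genes, study.expression)
                rows.append({"direction_set": name, "n_genes": len(set(genes)),
                             "W": w, "p": p, "median_shift": med})
            except ValueError:
                rows.append({"direction_set": name, "n_genes": len(set(genes)),
                             "W": np.nan, "p": np.nan, "median_shift": np.nan})
        out["expression_shift"] = pd.DataFrame(rows)
    return out


@_stage("dmr")
def _run_dmr(study: SimStudy, cfg: PipelineConfig, dmc: pd.DataFrame):
    nd = study.wgbs_ndonors.set_index(["chrom", "pos0"])
    pair = WgbsPair.from_tracks(
        study.wgbs_mono, study.wgbs_mac,
        n_donors_mono=nd["n_mono"], n_donors_mac=nd["n_mac"])
    gain, loss, bg = _dmc_sets(dmc)
    diff_dmcs = dmc.loc[gain.union(loss)]
    dmr_table = demarcate_dmrs(
        diff_dmcs, study.cpg_map, pair, min_diff=cfg.wgbs_min_diff,
        max_gap=cfg.dmr_max_gap, min_donors=cfg.wgbs_min_donors)
    # non-DMCs: direction from the sign of the monocyte->macrophage contrast
    nond = dmc.loc[bg].copy()
    nond["direction"] = np.where(nond["delta_mono_mac"] > 0, "gain", "loss")
    nondmc_table = demarcate_dmrs(
        nond, study.cpg_map, pair, min_diff=cfg.wgbs_min_diff,
        max_gap=cfg.dmr_max_gap, min_donors=cfg.wgbs_min_donors)
    conc = concordance_enrichment(dmr_table, nondmc_table)
    concordant = dmr_table[dmr_table["concordant"]]
    conc["median_dmr_n_cpg"] = float(concordant["dmr_n_cpg"].median())
    conc["median_dmr_length_bp"] = float(concordant["dmr_length_bp"].median())
    conc["single_cpg_fraction"] = (
        float((concordant["dmr_n_cpg"] == 1).mean()) if len(concordant) else np.nan)
    return dmr_table, nondmc_table, conc


@_stage("motif")
def _run_motif(study: SimStudy, cfg: PipelineConfig, dmc: pd.DataFrame) -> dict:
    gain, loss, bg = _dmc_sets(dmc)
    rng = np.random.default_rng(cfg.seed + 101)
    tables = {}
    for name, targets in (("gain", gain), ("loss", loss)):
        tables[name] = motif_enrichment(
            study.cpg_map.loc[targets], study.cpg_map.loc[bg], study.genome,
            study.pwms, window_halfwidth=cfg.motif_window,
            threshold_frac=cfg.motif_threshold_frac,
            background_n=cfg.background_n, rng=rng, direction_set=name)
    return tables


def make_enrichment_fn(ann: pd.DataFrame, background: pd.Index):
    """Enrichment callable used for the threshold-sensitivity re-runs.

    Computes the chromatin-state (macrophage consensus) and DHS-change
    enrichments of a target CpG set against a fixed background, as a single
    stratum/log2_or table keyed by ``family``.
    """
    def enrich_states(targets: pd.Index, direction: str) -> pd.DataFrame:
        res = feature_enrichment(targets, ann["state_mac"].notna(), background,
                                 strata=ann["state_mac"], direction_set=direction)
        tab = results_to_frame(res, fdr=False)
        tab["family"] = "state_mac"
        dhs_change = ann["dhs_mono"] != ann["dhs_mac"]
        tab2 = results_to_frame(
            feature_enrichment(targets, dhs_change, background,
                               direction_set=direction),
            fdr=False)
        tab2["family"] = "dhs_change"
        return pd.concat([tab, tab2], ignore_index=True)

    return enrich_states


@_stage("thresholds")
def _run_thresholds(study: SimStudy, cfg: PipelineConfig, dmc: pd.DataFrame,
                    dmr_table: pd.DataFrame, ann: pd.DataFrame):
    retention = apply_cutoffs(dmr_table)
    subsets = retained_sets(dmr_table)
    _, _, bg = _dmc_sets(dmc)
    rerun = rerun_enrichments(subsets, dmr_table["direction"],
                              make_enrichment_fn(ann, bg),
                              min_size=cfg.rerun_min_size)
    return retention, rerun


def _write_outputs(result: PipelineResult, out: Path) -> None:
    dmc = result.dmc_table
    if result.annotation is not None:
        dmc = dmc.join(result.annotation)
    if result.dmr_table is not None:
        dmc = dmc.join(result.dmr_table[
            ["covered", "wgbs_delta", "concordant", "dmr_n_cpg",
             "dmr_length_bp", "dmr_mean_delta_pct"]])
    dmc.reset_index().to_csv(out / "dmc_table.tsv", sep="\t", index=False)
    for name, tab in result.enrichment.items():
        tab.to_csv(out / f"enrichment_{name}.tsv", sep="\t", index=False)
    if result.dmr_table is not None:
        result.dmr_table.reset_index().to_csv(out / "dmr_table.tsv", sep="\t", index=False)
        with open(out / "wgbs_concordance.json", "w") as fh:
            json.dump(result.concordance, fh, indent=2)
    for name, tab in result.motif_tables.items():
        tab.to_csv(out / f"motif_enrichment_{name}.tsv", sep="\t", index=False)
    if result.retention is not None:
        result.retention.to_csv(out / "retention.tsv", sep="\t", index=False)
        result.rerun.to_csv(out / "rerun_enrichments.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
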