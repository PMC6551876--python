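# Methods

This document describes the statistical model, the defaults and their
rationale, what the synthetic generator does and does not emulate, the
numerical conventions, and known limitations. Every empirical number
quoted in the README is produced by `scripts/acceptance.py` or the test
suite; this document makes no empirical claims beyond those.

## 1. Per-CpG model (ewas)

Each CpG is measured as a beta value (methylation fraction in [0, 1]) for
every donor × cell state, with the six states monocyte, naive macrophage
and four activated subsets (`M_LPS_IFNg`, `M_IL4`, `M_oxLDL`, `M_acLDL`).
The design is paired and balanced: the model is the two-way within-donor
ANOVA

y_{dc} = mu + donor_d + state_c + e_{dc}

fitted per CpG by closed-form sums of squares. For complete balanced data
this is *exactly* the random donor-intercept mixed model fitted by REML
with Satterthwaite denominator degrees of freedom (k−1)(n−1); the
acceptance suite verifies the equivalence against `lmerTest` to 1e-6
relative on F and p. Donors with any missing state at a CpG are dropped
(complete-case per CpG); at least `min_donors = 3` complete donors are
required, otherwise the CpG is reported as skipped.

Reported per CpG:

- `ms` — between-state mean squares, SS_state/(k−1): the effect-size
  criterion.
- `F`, `p` — F = ms / MS_residual on (k−1, (k−1)(n−1)) df.
- `q` — Benjamini–Hochberg adjusted p over the tested CpGs.
- `t_<state>` — partial t: (state mean − grand mean)/SE with
  SE² = MS_residual·(k−1)/(nk).

Degenerate conventions: zero residual variance with a non-zero state
effect gives F = ∞, p = 0, flagged; an entirely constant CpG gives F = 0,
p = 1.

**DMC calling.** A CpG is a DMC iff `q < 0.05` (strict) and `ms > 0.0025`
(strict). The contributing state is the argmax of |partial t| (ties broken
by the fixed state order): monocyte ⇒ differentiation phase, naive
macrophage ⇒ macrophage-specific, activated state ⇒ `activation:<state>`;
if a second state reaches `multi_frac = 0.9` of the maximum |t| the phase
is `multi`. The direction-defining contrast (`delta_beta`) is
phase-matched: differentiation uses mean(five macrophage-derived states) −
monocyte; activation uses activated − naive macrophage; macrophage-specific
uses macrophage − mean(others). Gain means positive contrast. The
monocyte→macrophage contrast (`delta_mono_mac`) is additionally reported
for every CpG, and `switch_flag` marks CpGs crossing beta = 0.5 between
the two.

Rationale for defaults: `fdr_q = 0.05` and `ms_cutoff = 0.0025` are the
conventional significance level plus a minimum-effect filter that excludes
statistically significant but tiny effects (for a pure differentiation
effect of size e, ms = (2/3)e², so the cutoff corresponds to |e| ≳ 0.061).

## 2. Annotation (annotate)

Per-CpG annotations are consensus calls over per-donor interval tracks,
all in half-open 0-based coordinates internally (BED convention; 1-based
positions at IO boundaries where the format requires it):

- **Chromatin state**: the label assigned by at least `state_min_votes = 3`
  of 5 donor segmentations at the CpG position, else no call.
- **DHS**: present iff called in ≥13 of 26 monocyte donors, ≥2 of 4
  macrophage donors (per-cell-type vote thresholds `dnase_min_votes_*`,
  half of the donor panel each).
- **Enhancer (Hi-C)**: overlap with promoter-capture interaction regions,
  per cell type.
- **Nearest gene**: minimum distance to a gene body, ties broken by TSS
  distance then lexicographic gene id.
- **Motif window**: motif instances overlapping ±`motif_window = 25` bp
  around the CpG.

## 3. Enrichment (enrich)

All enrichments are 2×2 Fisher exact tests of a target CpG set against the
measured non-DMC background. The odds ratio is the plain cross-product
ad/bc (∞ or 0 reported as-is and flagged); the two-sided p-value uses the
probability-mass convention — the sum of hypergeometric outcomes at most
as probable as the observed one, with a 1e-7 relative tie slack (the same
convention as R's `fisher.test`). p-values are computed in-house from the
hypergeometric pmf over the margin support (vectorized sort + cumulative
sum), which the acceptance suite verifies against exact integer
enumeration of *every* table with N ≤ 60 and against
`scipy.stats.fisher_exact` on random tables. Reported p-values are floored
at 2.2e-16 in a separate `p_capped` column.

Families computed by the pipeline: chromatin-state strata per cell type,
the gain-versus-loss state-transition grid (monocyte state → macrophage
state), Hi-C enhancer overlap, DHS change, and TF-binding gain (peak in
macrophage, none in monocyte) at motif-overlapping gain-DMCs.

**Expression shift.** For genes nearest to gain- (resp. loss-) DMCs, a
Wilcoxon signed-rank test on paired log-expression differences
(macrophage − monocyte), exact for n ≤ 25 without ties, normal
approximation with continuity correction otherwise; at least 5 genes
required.

## 4. WGBS integration and DMRs (dmr)

Array DMCs are mapped to WGBS positions covered in ≥`wgbs_min_donors = 3`
donors in both cell types. A DMC is *concordant* if the WGBS
macrophage−monocyte difference at its position has the DMC's direction and
magnitude ≥`wgbs_min_diff = 0.05` (inclusive). DMRs are demarcated by
seed-and-extend: starting from the concordant seed CpG, consecutive WGBS
CpGs are added while each qualifies (same direction, ≥5% difference) and
the gap to the previous member is ≤`dmr_max_gap = 1000` bp (inclusive);
extension stops at the first non-qualifying CpG on each side. The result
equals the unique maximal contiguous qualifying run containing the seed
(verified against brute-force enumeration). A single-CpG DMR has length
1 bp; otherwise length is last−first+1 in 1-based inclusive coordinates.
Concordance enrichment compares the concordant fraction of DMCs against
measured non-DMCs (fold and Fisher p).

## 5. Motifs (motif)

PWMs are scored as log2-odds against a uniform base background with
pseudocount 0.01. Both strands of the ±25 bp window around each CpG are
scanned; a window is a hit when any offset reaches
`motif_threshold_frac = 0.8` of the motif's maximum attainable score
(maximum computed with the same summation order as the scanner, so a
consensus match at threshold 1.0 is found exactly). Enrichment compares
DMC windows against `background_n = 50,000` CpGs sampled without
replacement from the measured non-DMC pool with a seeded generator.
N bases contribute the background expectation (score 0). De novo motif
discovery and GC-matched backgrounds are out of scope.

## 6. Threshold sensitivity (thresholds)

The base set is the WGBS-covered, direction-concordant DMCs. Effect bins
on |WGBS Δβ|: >5% (≥0.05), 5–30% (closed interval), >30% (strict); DMR
bins: ≤4 and >4 CpGs; plus marginal "any" bins. For every bin combination
the retained counts and lost fractions are reported separately for gain
and loss, and the chromatin-state and DHS-change enrichments are re-run on
each retained subset (subsets with <`rerun_min_size = 20` members in a
direction are marked insufficient). Retention is monotone in cutoff
stringency, and the full-set re-run reproduces the primary enrichments
identically (both are tested).

## 7. Synthetic study generator

The generator emulates, per seed and with independent substreams per
component (adding a component never shifts another's draws):

- **Array**: 6,000 CpGs × 4 donors × 6 states; bimodal baseline betas;
  donor random effects (SD 0.05) and measurement noise (SD 0.03);
  truncation of baselines so planted effects stay inside [0.02, 0.98].
- **Planted effects**: 400 differentiation gain (Δβ uniform 0.06–0.28) and
  140 loss (0.10–0.50) — gain more numerous but weaker, loss stronger, as
  in the motivating biology; rare, loss-dominated activation effects
  (8 loss + 1 gain for LPS+IFNγ, 1 loss each for the other subsets) and
  one macrophage-specific CpG per direction.
- **WGBS**: per-cell-type tracks covering 78% of array CpGs plus flanking
  neighbours; half of the planted differentiation effects are marked
  WGBS-concordant; of those, 26% are single-CpG and the rest span regions
  of 2+Poisson CpGs (mean extra 1.5 for gain, 3.0 for loss — gain regions
  shorter); 10% of background CpGs carry spurious random-sign ≥5%
  differences; WGBS noise SD 0.012.
- **Annotation tracks**: per-donor chromatin-state segmentations (5
  donors, 90% concordance, 800 bp segments) with planted gain-DMCs
  preferentially at repressed/repressing transitions (quiescent→quiescent,
  polycomb→polycomb, enhancer→quiescent, flanking-active-TSS→quiescent)
  and loss-DMCs at activating ones (quiescent→enhancer,
  enhancer→active-enhancer, polycomb→enhancer, quiescent→active-enhancer);
  DNase tracks for 26 monocyte / 4 macrophage donors with DHS-change rates
  0.30 (gain) / 0.60 (loss) versus 5%/2.5%/2.5% background; Hi-C enhancer
  intervals more frequent at DMCs (0.25 vs 0.18).
- **Sequence**: a small genome with CEBP-like, ETS-like (gain-associated)
  and AP1-like (loss-associated) consensus motifs planted in DMC windows
  at rates 0.5/0.35 (gain) and 0.6 (loss) versus a 6% background rate;
  ChIP peaks for the corresponding TFs gained in macrophage at 60% of
  motif-bearing gain-DMCs versus 5% background.
- **Expression**: nearest-gene logTPM table with −0.8 mean shift for
  gain-DMC genes and +1.0 for loss-DMC genes, noise SD 0.3.

Not emulated: genome-scale CpG counts and LD-like correlation between
array probes, read-level WGBS sampling noise, realistic chromatin-state
transition grammar beyond the planted transitions, probe-level array
artifacts, cell-composition effects, and sex chromosomes.

All inputs can be written to plain-text formats (TSV beta matrix and
sample sheet, BED/bedGraph tracks, FASTA genome, JASPAR-style PWMs) and
read back; a written-then-reread study reproduces the in-memory DMC calls
exactly.

## 8. Numerical choices

- Balanced ANOVA by direct sums of squares with a clip of SS_residual at
  zero against cancellation; vectorized over CpGs grouped by their
  complete-donor pattern.
- BH via `statsmodels.stats.multitest.multipletests`, verified against the
  definitional step-up formula.
- Fisher p from `scipy.stats.hypergeom.pmf` over the margin support with a
  1e-7 relative tie slack; this in-house route makes exhaustive
  verification of all N ≤ 60 tables fast.
- Signed-rank via `scipy.stats.wilcoxon` (exact when n ≤ 25 and tie-free).
- Coordinates are 0-based half-open internally; conversions happen only at
  IO boundaries. DMR lengths are 1-based inclusive (single CpG = 1 bp).
- Determinism: every stochastic step draws from `numpy.random.default_rng`
  seeded from the single pipeline seed (fixed offsets per component);
  identical config + seed gives byte-identical output files.

## 9. Limitations

- The ANOVA route requires complete balanced data per CpG; donors with a
  missing state are dropped rather than modelled (no partial pooling).
- The mean-squares effect criterion is scale-dependent on beta values and
  inherits their heteroscedasticity; no M-value transform is offered.
- Attribution by argmax |partial t| is a heuristic; correlated activation
  and differentiation effects can be labelled `multi`.
- Enrichment backgrounds are measured non-DMC CpGs, not GC- or
  coverage-matched sets.
- The motif stage scans a fixed small PWM set; it does not discover
  motifs, and hit calling uses a single score threshold.
- The generator's ground truth makes qualitative claims testable but is
  not a calibrated model of any real cohort; absolute counts and odds
  ratios depend on its parameter defaults.
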