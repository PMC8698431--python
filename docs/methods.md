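# Methods

This note documents the models, defaults and numerical choices behind
`gtdmeth`, in the package's own words. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scales and summaries

Methylation is carried as β ∈ [0,1] (methylated signal fraction) and
transformed to M = log₂(β/(1−β)) for testing, since M-values are close to
homoscedastic across the β range. β is clipped into [ε, 1−ε] with
ε = 10⁻⁶ before the logit so M stays finite at the support boundary; the
round trip M→β is exact inside the clip band.

The global per-tissue methylation level is defined as the **median across
probes of the per-probe median across the group's samples**. Pooling all
(probe, sample) entries into one median is an alternative reading; the
median-of-medians form is robust to unbalanced group sizes and the two
differ negligibly for near-symmetric designs, so the package uses the
former throughout.

## Differential methylation

Two routes are implemented because they serve different questions:

* **Pairwise route** (`dm_ttest_contrast`). Per probe, a two-sided F-test
  on the variance ratio at level α_F = 0.05 (a conventional level; no
  other value is singled out by the analysis design) routes to the
  pooled-variance Student t (equality not rejected) or Welch's t with
  Satterthwaite degrees of freedom. Significance: Benjamini–Hochberg
  q < 0.1, applied per contrast over all tested probes. Degenerate probes
  (zero variance in both groups) return t = 0, p = 1 when means agree and
  a flagged p = 0 otherwise.
* **Moderated route** (`dm_moderated`). A one-way group-means fit per
  probe over all four groups; residual variances are shrunk towards an
  inverse-chi-square prior whose hyperparameters (d₀, s₀²) are estimated
  by method of moments on log residual variances (the excess of
  var(log s²) over trigamma(d/2) is inverted through the trigamma
  function; non-positive excess collapses to d₀ = ∞, i.e. every probe
  gets s₀²). The moderated t uses d + d₀ degrees of freedom and q < 0.05.
  Setting d₀ = 0 reproduces the ordinary t exactly, which the tests use as
  the no-shrinkage anchor.

Δβ is always the difference of per-probe group median β (target −
reference). Categories: mild 0.125 < |Δβ| ≤ 0.25, moderate ≤ 0.5, strong
> 0.5, with the lower boundary **strict** (|Δβ| = 0.125 is "none"); the
analysis conventions this follows state the threshold both as "> 0.125"
and "≥ 0.125" in different places, and the package adopts the strict
form everywhere, so boundary probes never qualify.

Gene calls require a probe to pass **both** the q threshold and the |Δβ|
threshold (the conjunctive reading; both thresholds are arguments).
Multi-gene probes ("GENE1;GENE2") contribute to every listed gene after
within-probe de-duplication. TSS profiles use 100 bp bins over the first
1 kbp by default, with 200 bp available via a parameter; frequencies are
counts of direction-matching DM probes divided by all probes in the
window, and an empty window yields an explicit null rather than zeros.

## Clustering

Samples are clustered on Euclidean distances between β columns with the
Ward.D2 criterion (the Murtagh–Legendre squared-distance update, which is
what scipy's `ward` on raw observations computes); ties break to the
lowest merge index. Clade purity — the fraction of a group's samples
inside its largest all-same-group subtree — is this package's metric for
"each tissue forms its own clade" (purity 1 for every group). Bootstrap
clade support is deliberately out of scope.

## Integration

DE selection per contrast: q < 0.05 (mole vs placenta, RNA-Seq-style) or
q < 0.1 (CC vs VT, microarray-style), both with |FC| ≥ 2 **inclusive**.
The 12-subset partition crosses {both contrasts, mole only, CC only} with
the four (methylation, expression) direction pairs; UM/DR and DM/UR are
flagged "regulation-likely". A gene qualifying in both contrasts with
*different* direction pairs is placed in both single-contrast subsets and
never in M&C — the only documented exception to pairwise disjointness,
tracked in the partition's `conflicting` set. Enrichment odds ratios use
(a·d)/(b·c) with Haldane's 0.5 correction only when a cell is zero
(flagged); the Fisher p always comes from the uncorrected table, and the
universe is an explicit argument reported alongside results.

## Over-representation

The pathway step is a generic hypergeometric upper-tail test against a
GMT collection over an explicit universe, with BH correction across the
tested sets, fold enrichment (overlap/|query|)/(|set|/|universe|), and a
`min_overlap` filter defaulting to 2 (singleton overlaps carry no
evidence). An EASE mode subtracts one from the overlap for the
conservative modified-Fisher behaviour some annotation tools default to.

## Immunoscores

Composite donor scores: mean of annotations per core, then unweighted
mean of core means per donor — equal to the grand annotation mean only in
balanced designs (tested both ways). Group comparison defaults to
Mann–Whitney, exact when the combined n ≤ 20 without ties, otherwise the
tie-corrected normal approximation; an unpaired t-test is available since
both appear in common practice for this design. Degenerate all-identical
inputs return p = 1.

## Synthetic-data generator

The generator's defaults are the study conditions, not tuning knobs:

* **Groups and sizes.** VT 19, PLA 12, MOLE 4 samples; CC is simulated
  with 4 samples (cell-line data in this field can have as few as 2, but
  4 keeps within-group variance estimable for the routed t-test while
  staying in the study's 4–19 range).
* **β noise.** Per probe and sample, β ~ Beta(cκ, (1−c)κ) around a probe
  center c with concentration κ = 150, giving a within-group SD of
  ≈ 0.04 at mid-range — a realistic 450K replicate spread. No
  within-group dispersion is published for these tissues, so κ is this
  package's calibration (stated here once; the null-calibration and
  recovery tests characterise its consequences).
* **Centers.** Baseline logits come from a two-component normal mixture
  (modes near β = 0.12 and 0.80, 55%/45%) reproducing 450K bimodality.
  Each group shifts the baseline in logit space; the shift is solved by
  bisection so the median of the final probe centers (including planted
  and imprinted probes) equals the configured group median exactly —
  defaults 0.25 / 0.37 / 0.45 / 0.59 for VT / PLA / MOLE / CC.
* **Planted DM.** 8% of probes per pathological group, disjoint across
  groups and excluding imprinted probes, with Δβ offsets 0.18/0.35/0.55
  (mild/moderate/strong) applied to the baseline of the contrast analysed
  downstream: PLA and CC against VT, MOLE against PLA (the mole analysis
  contrast is mole vs placenta, so planting against the placenta baseline
  makes the planted Δβ equal the configured magnitude in the contrast
  that is actually tested). Direction mixes (hyper fractions 0.60 / 0.67
  / 0.96) and category weights tilt strong effects towards
  choriocarcinoma, mirroring the disease pattern; the exact mixes are
  calibration choices. Placement is restricted to probes where the offset
  center stays inside (0,1); an infeasible configuration raises.
* **Imprints.** Maternal (0.7%) and paternal (3.2%) probe classes are
  disjoint Bernoulli draws (≈ 139 and 633 probes at the 20,000-probe
  default). Class centers per group: maternal 0.45/0.50/0.80/0.65 and
  paternal 0.45/0.50/0.25/0.75 (VT/PLA/MOLE/CC) — values chosen to
  reproduce the qualitative pattern (maternal marks highest in moles;
  paternal marks erased in moles, gained in choriocarcinoma); only the
  orderings, not the levels, are externally constrained.
* **TSS distances.** 55% uniform within 200 bp of the TSS plus an
  exponential tail (scale 1.2 kbp) truncated at 5 kbp, concentrating mass
  in the promoter-proximal zone as on the real array.
* **Expression.** DE fractions 27% (mole) and 14% (CC) of genes;
  direction biases 72% / 31% upregulated; planted DE genes get
  |log₂FC| = 1 + Exp(0.8) and q ~ U(0, 0.8·q_max) while background genes
  get |log₂FC| < 1, so the stated thresholds select exactly the planted
  set. Methylation–expression coupling: a planted-DE gene with a planted
  methylation direction is regulated oppositely (hyper→down) with
  probability `coupling_strength` (defaults 0.32 mole, 0.71 CC); the
  direction bias applies to the rest, so the realised overall bias drifts
  from the nominal one as coupling strengthens.
* **Immunoscores.** 2–3 cores per donor, 2–6 annotations per core;
  score = group mean + donor effect + noise, with donor SD 1.3 and
  annotation SD 0.6 calibrated to the reported group SEM scale, and a
  configurable case shift (1.19 recovers composite means near 5.14 vs
  6.33 at the study's 24/17 donor counts).
* **Seeds.** One master seed; each table draws from its own derived
  substream, so regenerating one artifact never disturbs the others.

What the generator does **not** emulate: raw IDAT intensities, type-I/II
probe chemistry bias, batch effects (and hence functional normalization),
cell-composition mixtures, spatial correlation of probes along the
genome, and realistic gene-length/probe-density correlation. Passing
recovery tests therefore demonstrates the correctness of the analysis
machinery under the planted statistical structure, not robustness to
those real-data artifacts.

## Problem sizes

Default simulations use 20,000 probes × 2,000 genes (the analysis-ready
slice of an array after filtering), which the recovery analyses complete
in seconds; unit tests run reduced sizes (2,000–8,000 probes) chosen so
planted effects remain comfortably detectable at the configured noise.

## Known limitations

* The moderated route tests a single pairwise contrast from the one-way
  fit; arbitrary design matrices are out of scope.
* The partition treats a conflicting-direction gene by double listing
  (see above) rather than inventing a 13th category.
* Odds-ratio universes must be supplied by the caller; there is no
  hidden default background.
* The exact Mann–Whitney switch (combined n ≤ 20, no ties) is a
  convention; near the switch the exact and approximate p differ
  slightly.
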