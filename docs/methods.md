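# Methods

## Problem

HER2 amplification status drives trastuzumab eligibility in advanced
gastric cancer, but biopsy DNA is a bulk extract: cancer cells are mixed
with diploid stromal and inflammatory cells, which dilutes any
copy-number signal measured by PCR. `tcchart` implements a closed-form
deconvolution of that dilution — the tumor-content (TC) chart — so that a
chamber-count digital PCR ratio plus an estimate of tumor cellularity
yields a three-way amplified / equivocal / non-amplified call without in
situ hybridization.

## Digital PCR quantification

A 48.770 digital array splits each 4 µl reaction into 770 chambers at
limiting dilution. With molecules per chamber Poisson(λ) and chambers
independent, a chamber is positive iff it received ≥ 1 molecule, so the
maximum-likelihood occupancy correction from k positives out of N is

    λ̂ = −ln(1 − k/N).

The HER2/CEP17 ratio is r = λ̂_HER2 / λ̂_CEP17. Confidence intervals are
delta-method: Var(λ̂) ≈ p/(N(1−p)) with p = k/N, and the ratio interval
is formed on the log scale (squared CVs add). This is cheap and accurate
at N = 770; exact (Clopper–Pearson-style) intervals are out of scope.
Multi-panel runs are pooled by summing k and N before correcting once;
chambers at equal loading are exchangeable, and pooling m identical
panels provably leaves r unchanged. Saturation (k = N) is an error, not
a cap: capping would bias r downward silently.

Worked cell-line controls: LCL (diploid) 383/398 positives → r = 0.95;
SK-BR-3 639/206 → r = 5.69; H522 513/310 → r = 2.130, which we report as
2.13 while the source table prints 2.14 — a one-digit discrepancy that
cannot be resolved from the printed counts (panel pooling or rounding
conventions at the instrument are unknowable) and is deliberately not
chased.

## The TC chart

Let x be the tumor content ratio (fraction of nucleated cells that are
cancer), A and B the per-cancer-cell CEP17 and HER2 copy numbers, and
assume (i) cancer cells are homogeneous in copy number and (ii)
non-cancerous cells are diploid at both loci. The bulk ratio is

    r = (Bx + 2(1−x)) / (Ax + 2(1−x)).

Amplification is defined per-cell as B/A ≥ 2. Substituting B = 2A gives
the iso-curve family

    r(x; A) = 2 − 2(1−x) / ((A−2)x + 2),

monotone increasing in A, equal to x + 1 at A = 2 and (7x+1)/(3x+1) at
A = 8. Clinically A stays within [2, 8] (observed 2.0–6.0, 8 is a safety
margin; both bounds are configurable). Hence:

- r < x + 1 ⇒ B/A < 2 for every admissible A: **negative**;
- r ≥ (7x+1)/(3x+1) ⇒ B/A ≥ 2 for every admissible A: **positive**;
- in between the call depends on the unknown A: **equivocal**.

The band is half-open (x + 1 ≤ r < upper is equivocal; ties go to the
less-negative category). All curves pass exactly through (0, 1) (pure
stroma) and (1, 2) (pure tumor at B/A = 2). One derivation subtlety: the
positive-boundary formula is the same minus form as the negative one
(2 − 2(1−x)/((A−2)x+2)); writing it with a plus sign does not reduce to
(7x+1)/(3x+1), which is the normative rational function.

At x = 0 both boundaries collapse to r = 1 and any r ≥ 1 would be
"positive", which is biologically meaningless — the framework presumes
tumor cells are present. Samples with x below a floor (default 0.05)
therefore return UNDETERMINED with a warning instead of a call.

When A is measured (DISH CEP17 signals over 20 nuclei, A = count/20),
the model inverts exactly:

    B/A = r + 2(r−1)(1−x) / (Ax),

and under the pure-tumor convention (x = 1) the per-cell HER2 copy
number is B′ = r·A. The round-trip identity (invert ∘ forward = B/A) is
algebraically exact and tested to 1e−9 over a 10⁴-point grid.

## DISH and IHC

DISH metrics over n scored nuclei (default 20): ratio = HER2/CEP17
signal totals, per-cell averages; the CEP17 average is the measured A.
Classification follows the ASCO/CAP dual-probe rules, with "and/or" in
the positive rule read as inclusive-or (positive iff ratio ≥ 2.0 or
average HER2 ≥ 6.0 signals/cell; equivocal iff average in [4.0, 6.0);
else negative). Uncountable HER2 clusters are capped at 7/14/21 signals
by size class via an optional per-nucleus helper; the main API accepts
pre-tallied totals. Rounding happens only at presentation, never before
a threshold comparison. IHC is carried as the four-level Dako score and
cross-tabulated against chart areas in `concordance_table`.

## Tumor content estimation

x = n_cancer / n_total over the nuclei of the H&E section adjacent to
the DNA-extracted sections. The commercial image pipelines used in
practice reduce, per their own description, to separating enlarged
cancer nuclei from stromal nuclei by size; the package's stand-in is a
size-threshold classifier on a tabulated nucleus-size feature, with the
AUTO threshold chosen by Otsu's two-class variance criterion
(`skimage.filters.threshold_otsu`). A manual threshold is always
accepted. This is deliberately minimal: it does no segmentation, no
stain handling, and no multi-feature classification, so passing tests
show the counting arithmetic and threshold logic are right, not that
real whole-slide images would be classified correctly.

## Simulator

The generator fixes a truth (A, B, x, mean cell-genome equivalents per
chamber m) and samples positive-chamber counts as
Binomial(N·n_panels, 1 − exp(−λ)) with

    λ_ref = m(Ax + 2(1−x)),   λ_tar = m(Bx + 2(1−x)),

whose ratio equals the forward model exactly. Defaults: m = 0.25
(reference occupancy λ ≈ 0.5–1, matching the 0–1 molecule/chamber
operating range and the magnitudes of the cell-line counts), N = 770 per
panel. A single integer seed drives the whole stream; identical configs
are bit-reproducible. The stepwise DNA-mixing design (eight tumor:diploid
volume steps 8:2 … 1:9) is modelled by reading DNA mass fraction as x —
a known approximation, since aneuploid genomes do not weigh the same per
cell, but it is the convention the mixing experiment itself plots.
`fit_b_prime_series` recovers B from such a series by the exact
linearization r(Ax + 2(1−x)) − 2(1−x) = Bx (1-D least squares, closed
form).

Not modelled: pipetting error, chamber-volume variability, amplification
efficiency, probe dropout. Simulation-based tests therefore validate the
estimators under the occupancy model, not instrument physics.

## Problem sizes and numerical choices

- Property grids: boundary theorem over A ∈ {2, 2.5, …, 8},
  B/A ∈ {0.10, …, 1.99} (step 0.01) and {2.0, …, 10.0} (step 0.1),
  x ∈ {0.05, …, 1.00} (step 0.01). At B/A exactly 2 the float forward
  ratio can land one ulp below the boundary; the tests accept that tie
  at 1e−12 relative, since exact arithmetic ties upward.
- Monte-Carlo sizes: 10,000 replicates for interval coverage, 100–400
  seeded replicates at 77,000 pooled chambers for ratio recovery and
  end-to-end label accuracy, 1,000 replicates for noisy mixture-series
  recovery. These sizes keep the whole suite under a few seconds while
  leaving comfortable statistical margin.
- B′ for a cell line is computed from the measured ratio reported at
  2 d.p. (the convention of the worked examples), so B′ = 5.69 × 4.15 =
  23.61 for SK-BR-3.
- The diploid stromal copy number is fixed at 2 and not configurable:
  every boundary derivation hard-codes it.

## Known limitations

- Homogeneous-tumor assumption: subclonal amplification mixes into r and
  is not identifiable from a single (r, x) point.
- The classifier refuses no call other than UNDETERMINED at low x; it
  does not propagate the ratio CI into the label (a point estimate
  crossing a boundary flips the call).
- The TCR stand-in ignores everything about images except a size column.
- The chart's hybrid linear/log vertical axis is rendered with a symlog
  break at r = 2.5; the exact break placement is cosmetic.
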