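# Methods

## Two-state fast-exchange model

The analysis assumes that, in a saturated complex, each reporting residue
exchanges between two local conformers — free-like `f` and engaged `a` —
faster than their chemical-shift difference, so its cross-peak is the
population-weighted average of the two endpoint positions.  The endpoints
are operationally defined: `f` is the peak in the peptide-free spectrum and
`a` is the peak in a chosen reference complex (the most stable, most fully
engaged complex available; which complex plays this role is a configuration
choice).  Complexes whose bound fraction is below 0.99 are flagged and
excluded unless overridden, because free/bound exchange would otherwise
masquerade as partial engagement.

All distances are computed in the scaled coordinate plane (δ_H, 0.1·δ_N),
which makes the conventional combined shift δΔ = sqrt((0.1ΔN)² + ΔH²)
Euclidean.  The same 0.1 factor is applied to ¹³C dimensions for CH series;
there is no community consensus for a carbon weight, so the factor is a
single configurable parameter (`x_scale`) used consistently for distances,
projections and noise.

The scalar projection is computed two independent ways — the law-of-cosines
form s = (z²+x²−y²)/(2z) on the three pairwise distances, and the coordinate
dot product — and the test suite requires agreement to 1e-9 ppm.  x²−s² is
clamped to zero before the square root when it is negative by ≤1e-12 ppm²
(pure rounding); larger violations raise.  CCSP values are *not* clipped to
[0, 100]%: observations beyond an endpoint are legitimate (noise at high or
low engagement) and are reported as computed.

## Positional uncertainty

The default per-peak uncertainty is 0.0051 ppm combined (2.5 Hz at 500 MHz),
the empirical reproducibility of resonances that do not move across
complexes.  `reference_resonance_sigma` re-estimates it from any set of
immobile series as the pooled per-coordinate standard deviation about each
series' mean position, which is the maximum-likelihood estimate under the
isotropic noise model used throughout.

CCSP errors are propagated by Monte Carlo: all three peaks are perturbed by
isotropic Gaussian noise of σ per scaled coordinate and the half-width of
the central 95% interval of the resulting CCSP distribution is reported
(10⁴ draws, seeded).  Monte Carlo was chosen over analytic partials because
the projection is strongly nonlinear when the observation sits near an
endpoint or the line is short.  The reported "±" is therefore a 95%
interval, not a standard deviation — a deliberate interpretation, since the
convention behind published ± values of this kind is usually unstated.
Draws whose perturbed line is shorter than σ itself carry no direction
information and are discarded; if more than 10% of draws are discarded the
error is reported as undefined (raised), and the orchestrating model simply
skips error propagation for series with z < 4σ, which the screen rejects
anyway.

## Contamination screen

Two rules, both with inclusive thresholds at the stated values: z ≥ 0.03 ppm
(shorter lines cannot be read accurately), and at least 60% of complexes
with p/z strictly below 0.10.  Complexes lacking a peak for a series count
in neither numerator nor denominator — a missing peak (overlap, broadening)
is not evidence of contamination.  The screen is monotone in both thresholds
(property-tested).  Purely *parallel* contamination is undetectable by
construction — an offset along the line is indistinguishable from a
population shift.  The synthetic generator therefore plants perpendicular
offsets (worst case for the screen) and the package inherits this blind spot
from the method itself.

## Clustering and group averages

Row similarity is uncentered correlation (Σuv/√(Σu²Σv²)) with pairwise
deletion of missing cells, computed on raw (un-normalised) CCSP values; the
dendrogram uses average linkage on 1 − similarity via
`scipy.cluster.hierarchy`.  scipy's deterministic merge order serves as the
tie-break rule; exact distance ties have measure zero for continuous data.
Rows sharing fewer than two complexes with every other row are excluded with
a warning.  Uncentered (rather than Pearson) correlation is the convention
of the clustering tools used for this kind of profile data; note it is
generous to profiles with similar positive means, which is acceptable here
because grouping is ultimately confirmed by cutting the tree, not by the
absolute similarity values.

Group averages are arithmetic means over member residues with Student-t 95%
intervals, t(0.975, n−1)·sd/√n; a single-member group yields a mean with an
undefined (NaN) interval, zero members yield a missing value.  Default
groups: SI = backbone 9, 11, 25; SII = backbone 30–32, 34, 37–39, 49, 57
plus the *side-chain* NH of 36 (the backbone amide of 36 is deliberately not
a member); SII_RT = backbone 13, 15, 16.  All groups are configurable.

## Binding thermodynamics

`fraction_bound` solves the exact single-site mass balance (quadratic); the
weak-binding hyperbola is never used because protein (70–100 µM) and K_d
(µM-range) are comparable in the motivating experiments.  Titration fits run
nonlinear least squares of shift_free + shift_max·fraction_bound(K_d, P₀, L)
with shift_free fixed at the zero-ligand point when present; 95% CIs come
from the fit covariance with a t critical value at n−p degrees of freedom.
Simulation shows these intervals cover the truth ≈92% of the time at the
default noise — slightly below nominal, the usual behaviour of Wald
intervals for a nonlinear scale parameter.  ΔG_B = RT ln(K_d [M]) with
R = 0.0019872 kcal/(mol·K) and T defaulting to 303.15 K (the calorimetry
temperature); ΔC_p is the OLS slope of ΔH vs T with its standard error.
Note that with the typical four temperatures the slope estimate has two
degrees of freedom, so ±2·SE covers only ~81% — calibration statements use
t(0.975, 2) ≈ 4.30.

Growth codes (0/3/6/8) are ordinal labels only.  The threshold analysis
reports the maximum engagement among non-growers (code 0), the minimum among
growers (code ≥ 6, codes of 3 being the transition zone), their midpoint as
the threshold estimate, and any complexes violating monotone separation as
named exceptions; no regression is performed on the codes.

## Hydrogen exchange

Intensities are fitted to A·e^(−kt), optionally with a plateau term for
incomplete deuteration (selected per series by AIC under `model="auto"`).
Rates outside the observable window are flagged rather than reported: less
than a 2-fold drop (or fitted half-life beyond the experiment) flags a slow
exchanger, decay completed before the first sampling interval flags a fast
exchanger.  Protection is log₁₀(k_intrinsic/k_exchange) against a
user-supplied intrinsic-rate table (standard external calculators produce
these; no intrinsic-rate model is implemented).  Σ log P defaults to summing
residues 17, 32, 33, 36 — the canonical specificity-surface probe set — with
a wider loop-residue set also provided; neither is asserted as canonical.
No conversion of Σ log P differences to ΔΔG is implemented: the published
shorthand relating the two is not reproducible by 2.303·RT arithmetic at the
experiment temperature, so the package declines to encode it.

## Synthetic data

The generator emulates the study conditions: a 59-residue domain, 24
saturated complexes, three responding groups (SI, SII, SII_RT) and an inert
remainder (z = 0).  Per residue, a free endpoint is drawn in the amide
window and the engaged endpoint placed at a seeded random angle at distance
z — U(0.03, 0.12) ppm for SI (several-fold smaller shifts than the
specificity surface) and U(0.1, 0.5) ppm for SII and the RT tip.  Engaged
populations are drawn per complex per group from U(0.2, 1.0), matching the
observed ~20–100% range; groups are drawn independently, the cleanest
condition for testing that clustering separates them (real surfaces are
partially coupled, so real trees are harder than synthetic ones).
Contamination is a perpendicular offset on chosen (residue, complex) cells.
Every emitted peak — free and reference included — gets isotropic Gaussian
noise of 0.0051 ppm per scaled coordinate.  One global seed governs all
draws, with per-residue/per-complex substreams so partial config changes do
not reshuffle everything.

What the generator does *not* emulate: exchange-regime lineshape effects
(broadening, slow-exchange doubling), peak overlap and missing assignments,
correlated engagement between surfaces, parallel contamination, and
temperature/referencing drifts.  Passing recovery tests therefore
demonstrates correctness of the computation under the stated model, not
robustness to every pathology of real spectra.

A multi-macro-state variant assigns each residue a membership set over
macro-states (e.g. W, X, Y, Z) with per-complex weights; a residue's CCSP is
the summed weight of states in which it is engaged.  This generates data in
which residues in one group legitimately hold different CCSP values — the
signature distinguishing >2 macro-states from the simple two-state picture.

## Problem sizes and numerical choices

Default analyses and the acceptance script use 59 residues × 24 complexes,
10⁴ Monte-Carlo draws per propagated error, 100 titration replicates for
coverage calibration, and 20 exchange series over the observable rate
window — sizes chosen to match the motivating study's scale while keeping a
full run in seconds.  Degenerate inputs fail loudly: a zero-length CCSP line
raises, an empty screen input raises, all-zero vectors are rejected by the
similarity, and flat titrations/decays are flagged rather than fitted
silently.

## Known limitations

* Only one reference bound state per dataset; residues needing more than two
  endpoint states are not deconvolved (the multi-state generator exists to
  *produce* such data, not to fit it).
* The NMR-STAR reader covers BMRB chemical-shift loops (v2 and v3) with
  whitespace-delimited values; it is not a general STAR parser.
* Peptide-side resonances are not modelled; the analysis is domain-centric.
* No spectral processing, peak picking or assignment — inputs are assigned
  peak positions.
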