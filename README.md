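# colinshift

Co-linear chemical shift perturbation (CCSP) analysis of protein–peptide
complexes from 2D NMR peak lists.

## The problem

When a peptide-binding domain (the motivating system is the 59-residue yeast
Abp1p SH3 domain bound by 24 related proline-rich peptides) is fully
saturated (>99% bound) with each of many related peptides, the cross-peak of
a given residue often does not sit at one of two positions but somewhere *on
the straight line* connecting its peptide-free position and its position in
a reference fully-engaged complex.  This co-linearity means the residue
exchanges rapidly between just two local conformers — a free-like `f` state
and an engaged `a` state — and its fractional position along the line is the
population of the engaged conformer inside the bound-state ensemble.
Measuring that population per residue, per complex, turns routine HSQC peak
lists into a map of *how much* of the binding surface each peptide actually
engages, something occupancy and affinity alone cannot reveal.

`colinshift` implements the complete analysis for spectroscopists with
assigned peak lists in hand: projection geometry, uncertainty propagation,
screening against sequence "contamination", clustering of coupled residues,
group averaging, and the downstream fits that relate engagement to binding
thermodynamics (K_d, ΔG_B, ΔC_p), hydrogen-exchange protection (Σ log P) and
coded phenotypes.

## The model

All geometry lives in the scaled plane (δ_H, 0.1·δ_N), where the combined
shift difference between two peaks is Euclidean:

    δΔ = sqrt((0.1·Δδ_N)² + Δδ_H²)

For each residue the CCSP line runs from the free peak to the reference
fully-bound peak (length *z*).  With *x* = |free→obs| and *y* = |obs→ref|,
the observed peak decomposes into a scalar projection and a perpendicular
residual:

    s = (z² + x² − y²) / (2z)          p = sqrt(x² − s²)
    CCSP% = 100 · s / z

Under two-state fast exchange, CCSP% estimates the engaged-conformer
population; *p/z* measures departure from two-state behaviour.  A series is
kept for analysis only if *z* ≥ 0.03 ppm and at least 60% of complexes have
*p/z* < 0.10 (direct peptide-sequence effects on surface residues scatter
peaks off the line).  Selected residues are clustered by uncentered
correlation of their CCSP profiles with average linkage; group averages
carry Student-t 95% confidence intervals.  Per-peak positional uncertainty
defaults to 0.0051 ppm (combined, 2.5 Hz at 500 MHz) and is propagated to
each CCSP value by Monte Carlo.

Binding isotherms use the exact single-site quadratic (protein and peptide
concentrations are comparable), ΔG_B = RT ln K_d, ΔC_p is the OLS slope of
ΔH vs T, and hydrogen-exchange rates come from exponential intensity decays,
converted to log₁₀ protection factors against user-supplied intrinsic rates.

## Worked example

```python
from colinshift import Peak2D, project_onto_line, propagate_ccsp_error

free = Peak2D(8.0, 120.0)   # peptide-free position (1H, 15N ppm)
ref  = Peak2D(8.5, 120.0)   # reference fully-bound position
obs  = Peak2D(8.2, 121.0)   # this complex

r = project_onto_line(free, ref, obs)
print(f"line length z    = {r.z:.3f} ppm")
print(f"projection s     = {r.s:.3f} ppm")
print(f"perpendicular p  = {r.p:.3f} ppm")
print(f"CCSP             = {r.ccsp_percent:.1f} %")
print(f"error (95%)      = {propagate_ccsp_error(free, ref, obs, seed=0):.1f} %")
```

prints

```
line length z    = 0.500 ppm
projection s     = 0.200 ppm
perpendicular p  = 0.100 ppm
CCSP             = 40.0 %
error (95%)      = 2.5 %
```

i.e. in this complex the residue populates the engaged conformer 40% of the
time, and sits 0.1 ppm off the line (p/z = 0.2 — this cell would count
against the residue in the contamination screen).

A full dataset run (here on the package's own synthetic generator, which
plants known engaged populations for the three canonical surface groups SI,
SII and the RT-loop tip):

```python
from colinshift import CCSPAnalysis, SyntheticConfig, generate_peaklists

config = SyntheticConfig(seed=11)       # 59 residues, 24 complexes
free, ref, complexes, truth = generate_peaklists(config)
results = CCSPAnalysis.from_peak_sets(free, ref, complexes).fit(errors="none")
print(results.summary())
print(results.correlate_groups("SII", "SII_RT").summary())
```

```
Co-linear chemical shift perturbation analysis
==============================================
resonance series            : 60
complexes                   : 24
degenerate lines (z = 0)    : 0
screen thresholds           : z >= 0.03 ppm, >= 60% of complexes with p/z < 0.1

Screen outcome by resonance class:
        class  n_series  selected  small_shift  off_line
  backbone NH        59        15           44         0
side-chain NH         1         1            0         0

selected series             : 16 (9, 11, 13, 15, 16, 25, 30, 31, 32, 34, 36s, 37, 38, 39, 49, 57)

Group-average CCSP (%) by complex:
                SI           SII        SII_RT
C01  60.2 +/- 14.9  55.2 +/- 2.6  45.7 +/- 5.3
C02  27.5 +/- 28.9  59.9 +/- 2.3  68.1 +/- 6.2
...
CCSP[SII_RT] ~ CCSP[SII]: slope=0.1882, intercept=46.15, R^2=0.0382 (rounded 0.04), n=24
```

The 44 small-shift rejections are the inert bulk of the domain; the 16
selected series are exactly the planted responders, and the SI confidence
intervals are visibly wider than SII's because SI lines are several-fold
shorter at the same noise.

## Command line

`colinshift` exposes each stage as a subcommand over plain-text files:

```sh
colinshift simulate --outdir demo --seed 3        # synthetic peak lists
colinshift ccsp   --free demo/free.csv --ref demo/reference.csv \
                  --complex C01=demo/C01.csv --complex C02=demo/C02.csv
colinshift screen --free ... --ref ... --complex ...
colinshift cluster --matrix ccsp.csv --cut 3
colinshift titrate --data titration.csv --protein-total 100
colinshift hdx    --data hdx.csv --intrinsic intrinsic.csv
colinshift run    run.yaml                        # full pipeline + manifest
```

Accepted inputs: CSV peak tables (`residue,atom,h_ppm,x_ppm`), Sparky
whitespace lists, and NMR-STAR v2/v3 chemical-shift depositions (BMRB
dialect).  Side-chain NH series use the `36s` label convention and are kept
distinct from backbone amides.

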