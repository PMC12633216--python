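# Methods

## The statistic: high-coverage locus counts

For each barcode, fragments (insert size < 900 bp, autosomes only) are
scanned by a sweep line; every maximal interval with coverage depth ≥ 3 is
a candidate high-coverage locus.  Intervals are half-open (`[start, end)`),
so two loci that merely touch at a coordinate remain distinct.  Per
chromosome, loci from all cells are unioned into one reference set, and a
binary loci × cells matrix records which cells overlap which merged locus.
The high-coverage locus count (HCLC) of a cell is its column sum.

Two nuclei under one barcode roughly double the chance of any locus
reaching depth 3 from independent copies, so multiplets populate the right
tail of the HCLC distribution.

## The model

Let `x` be HCLC.  Cells with `x <= x_min` are set aside (posterior 0); the
remaining `N_T` of `N` cells are transformed by a Box–Cox map
`z = (x^lambda - 1) / lambda`, with `lambda` chosen by profile maximum
likelihood over `[-2, 2]` so the bulk of `z` is close to normal.

On the `z` scale the library is a two-group mixture
`f = pi0 f0 + (1 - pi0) f1` with `f0` normal and `f1` unspecified.

**Mixture density.**  `z` is binned into 120 equal-width bins and the bin
counts are fit by a Poisson regression (log link) on a natural cubic spline
basis with 7 degrees of freedom; interior knots sit at equally spaced
quantiles of the bin centers and the basis is linear beyond the boundary
knots, so log-density tails are extrapolated linearly.  The fitted curve,
normalized by `N_T` times the bin width, is the density estimate
`f_hat`; its cumulative sum gives `F_hat`.

Knot placement note: placing knots at *count-weighted* quantiles of the
data (rather than unweighted quantiles of the bin centers) concentrates all
flexibility in the singlet bulk and leaves the multiplet shoulder fit by
one near-linear segment, which inflates the tail and biases `pi0` down.
Unweighted center quantiles spread the knots across the observed range and
recover the two-normal oracle (below) substantially better, so that is
what the package uses.

**Central matching.**  Around the mode `c_max` of `f_hat`, over the bins
whose centers fall in the 20th–60th percentile interval of `z` (where
essentially every cell is a singlet — the "zero assumption"), a quadratic
`beta0 + beta1 d + beta2 d^2` with `d = center - c_max` is fit to
`log f_hat` by least squares.  Concavity (`beta2 < 0`) is required.  Then

```
delta0 = c_max - beta1 / (2 beta2)        # singlet mean
sigma0 = (-2 beta2)^(-1/2)                # singlet sd
```

and the truncated singlet proportion `pi0_T` is the ratio of the
quadratic's implied bin counts to the spline's fitted counts, capped at 1.
The library-wide singlet proportion folds the excluded cells back in as
singlets: `pi0 = 1 - (N_T / N)(1 - pi0_T)`.  Estimated multiplet
prevalence is `1 - pi0`.

**Posterior and calls.**  Each retained cell gets
`p_j = clip(1 - pi0_T f0(z_j) / f_hat(z_j), 0, 1)`; excluded cells get 0.
Two decision rules are provided:

- *local FDR*: call multiplet when `p_j > 0.8` (20% local FDR among
  calls);
- *Bayesian FDR*: for a right-sided cutoff `t`, the estimated tail FDR is
  `pi0_T (1 - F0(t)) / (1 - F_hat(t))`; the rule uses the smallest `t`
  on a grid (bin centers plus observed `z` values) whose estimate is at or
  below the nominal level, and calls all cells with `z >= t`.  Grid points
  at or beyond the last bin center are dropped — there `F_hat = 1` and no
  tail mass remains to define a rule.  If no cutoff achieves the level, no
  cell is called.

**Integration.**  With `p_j` and the library prior `pi0`, the per-cell
Bayes factor is `BF_j = [p_j / (1 - p_j)] / [(1 - pi0) / pi0]`.  Treating
an external caller's multiplet probability `q_j` as the prior and assuming
conditional independence of the two evidence sources given the cell's
class, the combined posterior is `q_j BF_j / (q_j BF_j + 1 - q_j)`.  The
update is exactly invertible: feeding back `1 - pi0` as the prior recovers
`p_j` to machine precision.

## Choosing the truncation threshold

`x_min` exists to remove a zero-inflated pile of low-quality barcodes
(debris, ambient-dominated droplets) that survives permissive cell calling
and would otherwise distort the Box–Cox exponent and the central window.
For each candidate threshold in `0..Q1` (the HCLC first quartile), the
model is refit and scored by the cross-entropy of the fitted singlet normal
over the central band `|z - delta0| <= sigma0`.  The trace falls steeply
while candidates cut into the junk pile and flattens once the pile is gone;
the chosen threshold is the elbow — the point of maximum perpendicular
distance to the chord between the first and last trace points, after
min–max normalization of both axes.  Candidates whose refit fails are
recorded and skipped.

## The simulator

`SimulationConfig` defaults define the study conditions used throughout the
tests and acceptance targets.

- **Singlets**: site `i` of cell `j` is hit with probability
  `min(1, d_j q_i)` over 2,500 sites, with per-site rates `q_i` lognormal
  (median 0.013, log-sd 0.6) and per-cell depth multipliers `d_j`
  lognormal (log-sd 0.25, about a 25% coefficient of variation).  The
  resulting HCLC is right-skewed with mean ≈ 50 and a variance/mean ratio
  ≈ 8, matching the Poisson-overdispersed counts seen in real droplet
  snATAC libraries after multi-read-locus counting.
- **Doublets**: as in hashing-based benchmarks, pairs of simulated cells
  are drawn without replacement and replaced by one barcode carrying the
  elementwise union of the two binary profiles.  `doublet_proportion` is
  the doublet fraction of the final library, exact up to rounding.
- **Low-quality barcodes** (`low_quality_fraction`, default 0): junk
  droplets with depth multipliers around `2e-4`.  Because one HCLC unit
  needs three fragments overlapping a locus, the rate of nonzero HCLC
  falls roughly as the cube of relative depth, so these barcodes sit almost
  entirely at HCLC 0 — the pile that `x_min` truncation removes.  They are
  never doublet constituents: doublet benchmarks pair real cells.

The default excludes junk because the standard artificial-doublet benchmark
pairs QC-passing cells from an already-called library.  What the generator
does *not* emulate: chromatin-state heterogeneity across cell types, copy
number variation, locus-length variation, chromosome structure (all sites
live on one synthetic chromosome), or doublets formed with degraded nuclei.

A second, fragment-level generator writes a toy `fragments.tsv.gz` in which
each designed locus carries three staggered overlapping fragments, so the
preprocessing chain can be verified against exact per-cell HCLC truth.

## Verification

`scripts/acceptance.py` simulates 20 independent 20,000-cell libraries per
target (disjoint seeds per target) and reports: mean estimated prevalence
at 5% true doublets (t1) and at 25% (t2), both accurate to within 3
percentage points, and the mean realized false discovery proportion of the
Bayesian-FDR rule at level 0.2 with 10% doublets (t3), which stays below
the level within Monte-Carlo error.  The test suite additionally checks the
sweep line against per-base brute force, the estimation chain against a
`0.9 N(0,1) + 0.1 N(4,1)` oracle with closed-form answers, and the
integration round-trip identity.

## Limitations

- **Truncation must stay below the singlet bulk.**  The model tolerates
  any `x_min` that removes only the junk pile.  Once candidates cut into
  the singlet bulk itself, the Box–Cox exponent chases the truncated
  left edge, the transformed tail compresses, and `pi0` is driven to 1 —
  posteriors collapse and the ranking degrades sharply rather than
  gracefully.  Consequently the posterior AUROC is *not* uniformly stable
  over the whole `0..Q1` candidate range on a clean library (where Q1 is
  deep inside the singlet bulk); the cross-entropy elbow is designed to
  stop at the pile edge, far below that regime.
- **Both tails are flagged.**  The two-group posterior is large wherever
  `f_hat` exceeds `pi0_T f0`, including a left-hand junk pile retained at
  small `x_min`.  Multiplet calls are right-sided by construction, but the
  posterior column itself should not be read as "multiplet probability"
  for cells far left of the singlet mode; truncate the pile instead.
- **Single-library variance.**  Prevalence counts excess mass outside the
  fitted singlet normal; on one library it can land several percentage
  points from the truth, and the realized FDP of a single library scatters
  around the nominal level.  Averages across libraries are calibrated.
- **The zero assumption is load-bearing.**  If multiplets plus junk make
  up a large share of retained cells (roughly a third or more), the
  central window is contaminated, `sigma0` inflates, and prevalence is
  underestimated; the method targets libraries where singlets dominate the
  central percentiles.
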