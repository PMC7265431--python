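# Methods

## The intrinsic mass spacing model

A time-of-flight analyser samples ion arrival on a uniform clock, and flight
time is proportional to sqrt(m/z). Every m/z sample of a scan therefore lies
on the lattice

```
m/z(i) = [ alpha * (i + gamma) + beta ]^2 ,   i integer
```

with `alpha` the sqrt(m/z) clock spacing and `beta`, `gamma` offsets. The
parameterisation is degenerate: only `alpha` and the combined offset
`alpha*gamma + beta` affect the values, so all stored and reported parameters
are canonicalised to `gamma = 0` with `beta` in `(-alpha/2, alpha/2]`, which
makes indices absolute and comparable across scans.

### Assumptions

- Profile data: the m/z axis of each scan is a subset of one lattice. Peaks
  already centroided off the grid violate this and are rejected, not rounded.
- The lattice may drift slowly scan-to-scan (thermal drift of the TOF
  clock), so `(alpha, beta)` are stored per scan, with per-window medians as
  a compact summary.
- Intensities are non-negative integers (detector counts) fitting in
  unsigned 32 bits; writing larger values raises rather than truncates.
- Lattice indices fit in unsigned 32 bits; a fitted spacing that would need
  larger indices is treated as "no representable lattice".

## Lattice estimation from m/z values alone

Successive differences of sqrt(m/z) are integer multiples of `alpha`, so
estimation is an approximate greatest-common-divisor problem. Two regimes
occur and cannot be distinguished a priori from the smallest differences, so
both are solved and the better-fitting lattice kept:

1. **Exact regime** (values on the lattice to float rounding). A
   nearest-integer Euclid GCD fold over all differences, with explicit error
   tracking: each remainder's error is the input error amplified by the
   quotient (seeded at 4 ulps of the largest sqrt(m/z)); a remainder within
   its own error of zero means "exact multiple"; before a quotient would
   push the divisor's relative error past 1e-7, the divisor — itself a
   multiple of the true spacing — is re-tightened by least squares against
   all consistent differences. Without this, a single large quotient
   amplifies rounding error enough that later exact multiples look like
   fresh remainders and the fold collapses.
2. **Noisy regime** (values scattered around lattice points). The minimum of
   many noisy unit-spacing differences is biased low, so the candidate is
   seeded at the median of the near-minimum cluster (differences within 5%
   of the minimum, used only when the cluster has at least 3 members) and
   its spread provides the noise scale. A set-wide Euclid iteration then
   alternates least-squares refinement over unambiguous multiples (a
   multiple `k` is only unambiguous while `k` times the candidate's relative
   uncertainty stays below 1/4) with residue extraction.

Each candidate is polished by alternating least squares of sqrt(m/z) against
integer indices with index reassignment. Selection prefers candidates that
pass the acceptance checks before comparing residuals, because a finer
spacing always lowers the raw residual (overfit).

Two rejection rules guard against spurious lattices:

- **Tolerance**: worst reconstruction residual must be within 5 ppm
  (default), the scale below which instrument m/z accuracy is meaningless.
- **Resolution**: the residual must also be below half the fitted lattice's
  own quantisation cell (`alpha/sqrt(m/z)` in relative terms). Uniform
  off-lattice scatter fills the cell of whatever fine spacing is fitted to
  it, so half-cell residuals mean "not a lattice"; genuine lattice data sit
  far inside their cell.

Scans with fewer than 3 values are underdetermined and are placed on a seed
lattice (e.g. the previous scan's) when one is available; data-free scans
have no identifiable parameters at all, so lossless-equality comparisons
mask them when a tolerance is in use.

## Storage

One HDF5 file per run; one group per acquisition window (`ms1`,
`ms2-000` ...). Each group stores compressed sparse rows as three uint32
datasets — `retentionTimeIdx` (exclusive end offsets per scan), `imsCoord`,
`intensity` — plus per-scan `IMSAlphaPerScan`/`IMSBetaPerScan` (float64) and
summary attributes (median `IMSAlpha`/`IMSBeta`, `IMSGamma`, timing and
precursor-window bounds). Gzip compression is applied to all datasets. The
exact layout is pinned by `src/toffee/format_manifest.json` and checked byte
for byte in the acceptance suite. Round-tripping mzML preserves intensities
exactly and m/z to a relative error of 1e-12 (measured far below that; the
bound allows for one square/square-root cycle in float64).

## In-silico dilution

A peptide's *foreground* is the raw integer triplet footprint inside its
retention-time and m/z query box, taken from a run where the peptide is
present. Injection adds `round_half_away(factor * intensity)` to the
background run's grid cell by cell, so total intensity is conserved exactly
(background total plus the sum of scaled-rounded foreground counts), and
measured apex intensity is linear in the factor up to integer rounding
(bounded by half a count per touched cell). Rounding half away from zero is
used everywhere a real count becomes an integer, so dilution by 1/2 of odd
counts does not systematically lose mass relative to the same rule applied
elsewhere.

## Re-quantification peak model

For a peptide with fragments `j`, intensity over retention time `t` and m/z
`m` is modelled as

```
F_j(t, m) = (1/t) * a_j / (sigma_t * sqrt(2*pi))
          * exp( -(log t - log t0)^2 / (2 sigma_t^2)
                 -(m - m0_j)^2 / (2 sigma_m^2) ) + C_j
```

log-normal in time (elution profiles are right-skewed; the 1/t Jacobian
makes `a_j` exactly the area under the elution curve, i.e. the re-quantified
intensity), Gaussian in m/z, with a constant background `C_j` fitted for MS1
channels only (MS2 windows are much cleaner after precursor isolation).
Shared shape parameters `(t0, sigma_t, sigma_m)` couple all fragments of a
peptide. Fitting uses `scipy.optimize.least_squares` (trust-region
reflective) with positivity bounds; initial values come from raster moments.
Outlier fits are flagged per cohort (minimum 10 peptides) by robust z-score
— median and 1.4826·MAD per feature (sigma_t, sigma_m, t0 deviation from
expected, m0 deviation from library), threshold 5.

## Isotope imaging

Isotope channels are `mz + k * 1.0033548378 / charge` (the C13−C12 mass
difference). An image stack holds one raster per channel: precursor
isotopes from MS1, fragments from the matching MS2 window, over the query's
retention-time and ppm windows.

## Synthetic data generator

The generator emulates:

- SWATH-style cycles: one MS1 scan plus one scan per MS2 window per cycle
  (default 3 windows of 100 Da, 3 s cycle time);
- TOF lattice sampling with `alpha = 7.5e-5` sqrt(Da) per step (about
  6.7 ppm per step at m/z 500, typical of TOF instruments), optional smooth
  per-scan drift of `alpha`/`beta` bounded by 1e-6 fractionally (low-
  frequency sinusoids, emulating thermal drift);
- peptide signals from the analytic peak model above, sampled exactly on the
  scan's lattice and integer-rounded, with isotope envelopes and fragments
  placed in the correct windows;
- uniform background noise with Poisson-distributed sample counts per scan
  (default rate 50 per window, mean intensity 4).

It does not emulate: centroiding, detector saturation or dead time,
interference/chimeric spectra, charge-state or retention-time prediction
errors, ion mobility, or realistic peptide chemistry (sequences are labels;
m/z values are drawn, not computed from composition). Ground truth (exact
injected totals and per-peptide placements) is returned alongside the run
and is exact by construction, not by simulation fidelity.

## Numerical choices

- All index/count rounding uses round-half-away-from-zero, symmetric and
  independent of the value's parity (unlike banker's rounding), so repeated
  scaling does not bias totals.
- Least squares on `(alpha, beta)` uses centred normal equations; indices
  reach 1e6, so centring avoids the conditioning loss of the raw normal
  matrix.
- Sparse-row arithmetic is done in int64 and validated against uint32 bounds
  on write.
- Lossless m/z comparison uses rtol = 1e-12; parameters are float64 and the
  only non-representable step is the square/square-root cycle.

## Limitations

- Estimation needs at least 3 m/z values per scan (or a seed lattice);
  windows whose scans are all empty have unidentifiable parameters.
- A scan whose true spacing is below `sqrt(mz_max) / (2^32 - 1)` cannot be
  represented in uint32 indices and is rejected.
- The noisy-regime estimator assumes scatter small relative to `alpha`
  (sub-ppm); heavily perturbed data are rejected by the resolution rule
  rather than estimated.
- The peak model assumes a single elution apex per query window; co-eluting
  isomers fit as one peak.
- Dilution injection assumes foreground and background share the window
  scheme and compatible lattices; it maps by m/z, not by raw index.
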