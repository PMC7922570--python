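# Methods

This note documents the models, conventions and design choices behind
`milkmir`, and what its synthetic-data tests do and do not establish.

## Spectral data model

Spectra live on a `WavenumberGrid`: a strictly increasing axis in cm⁻¹
partitioned into uniformly spaced contiguous segments. The instrument
grid is 1060 points from 925 to 5008 cm⁻¹ (spacing 4083/1059 ≈ 3.8556
cm⁻¹). After informative-region retention the grid has three segments,
and every segment-local operation (differencing, integration, smoothing,
peak seeding) is confined to its segment — nothing crosses a gap.

**Region retention.** Published region boundaries (3061–2803, 1797–1681,
1612–925 cm⁻¹) are rounded grid coordinates, so membership uses an edge
tolerance of half a grid spacing by default: point *p* is kept when
`low − Δ/2 ≤ p ≤ high + Δ/2` for some region. On the instrument grid this
retains exactly 278 wavenumbers (179 + 31 + 68). The tolerance is
configurable; columns are stored ascending (descending display is a
rendering concern).

**Outlier screen.** A 2-component PCA of column-standardized spectra;
samples are flagged when their squared Mahalanobis distance in the
(PC1, PC2) plane exceeds the χ²(2) quantile (default 0.999). The screen
is advisory: removal requires an explicit flag, since a clean trial
shows all samples clustered at the origin.

## Pretreatments and averaging

* **First derivative (FD)**: a one-step finite difference
  `(vᵢ₊₁ − vᵢ)/Δ` — the "derivative window of 1" convention, with no
  polynomial smoothing. Output values sit on midpoints of adjacent input
  points, so each segment loses one point (278 → 275). Band positions
  derived downstream are reported on the integrated (midpoint) grid and
  matched to library centers with a tolerance larger than one spacing.
* **Vector normalization (VN)**: each spectrum divided by its Euclidean
  norm over the retained columns; idempotent and scale invariant. Zero
  rows raise an error naming the sample.
* Four variants are analysed in parallel: raw, VN = VN(raw),
  FD = FD(raw), VN-FD = VN(FD(raw)).
* **Window averaging**: per-cow unweighted mean over weeks 1–3
  (short-term) or 8–10 (long-term), applied *after* pretreatment — the
  order matters for VN variants and is pinned by a regression test. Cows
  with at least one sample in the window are averaged over what they
  have; cows with none are dropped with a warning.

## PCA

Correlation-matrix (standardized) PCA, not covariance: published
eigenvalue tables use the eigenvalue ≥ 1 rule and their
eigenvalue-to-percent ratios equal the variable count, both of which
presuppose unit-variance variables. Standardization uses divisor n−1.
With fewer cows than wavenumbers the decomposition runs through the SVD
of the standardized matrix (at most n−1 nonzero eigenvalues; eigenvalues
sum to ≤ p). Sign indeterminacy is resolved by orienting each loading so
its largest-magnitude entry is positive, making loading spectra
reproducible run to run.

**Retention.** The operative rule is eigenvalue ≥ 1 alone. Reported
tables retain components explaining less than 1% of variance whenever
their eigenvalue clears 1, contradicting a joint "≥1 and ≥1%" phrasing;
the percent floor is therefore exposed (`pct_min`) but off by default.

## Fixed-effects testing of scores

After per-cow averaging no repeated measures remain, so the trial model
`Y = μ + trt + start + block(start) + e` is ordinary least squares with
all effects fixed, sum-to-zero coded, block nested within start (block
labels recur across the two start periods). For the full 48-cow design
(4 treatments × 2 starts × 6 blocks) the residual df is 33; analyses of
published summary rows take the reported df as an input rather than
reproducing it, since dropped cows are not reconstructable.

* **Type-III tests**: each effect's F compares the full model against
  the model with that effect's columns removed,
  `F = [(SSE_r − SSE_f)/df_e]/MSE_f`; on balanced data this coincides
  with classical ANOVA (tested against a sequential-projection oracle).
* **LS means**: with sum-to-zero coding, equal-weight averaging over
  start and block levels reduces the treatment-i LS mean to
  μ̂ + trt̂ᵢ; SEs come from the corresponding quadratic form in the OLS
  coefficient covariance; tests are two-sided t with residual df.
* **Scheffé adjustment**: a pairwise contrast with statistic t among g
  levels gets p = P(F₍g−1,ν₎ ≥ t²/(g−1)); never below the raw p, equal
  to it at g = 2. α = 0.05 throughout. No cross-component multiplicity
  correction is applied — matching the analysed procedure — and reports
  flag this as a caveat; with ~16 retained components per variant a null
  trial still shows *some* significant component in roughly half of
  replicates, which is why the per-component error rate is the
  calibrated quantity.

## Interpretation of loading spectra

Loadings from raw/VN models are read directly. Loadings from FD/VN-FD
models are first integrated (cumulative trapezoid within each segment,
each segment starting at 0), which undoes the differencing up to a
per-segment constant and turns derivative wiggles back into band-like
humps.

* **Noise**: `1.4826 · median|second difference| / √6` — the second
  difference of a smooth signal is negligible while white noise of SD σ
  has second differences of SD σ√6, and the MAD factor makes the
  estimate robust to real bands.
* **Peak deconvolution**: pseudo-Voigt profiles
  `h·[η·Lorentz + (1−η)·Gauss]` (shared FWHH, zero baseline), the
  standard open approximation of the Voigt profile; the exact
  convolution adds nothing testable here since the surface is parameter
  recovery, not profile identity. Candidates are seeded at minima of the
  Savitzky–Golay second derivative (window 5, quadratic); "high"
  sensitivity lowers the prominence threshold from 0.5 to 0.1 of the
  second derivative's SD. Peaks are added one at a time with a full
  nonlinear refit (lmfit) until the residual RMS falls to twice the
  noise estimate or `max_peaks` is reached.
* **Spiking series**: band centers are minima of the mean smoothed
  second derivative whose absorbance grows monotonically with the added
  concentration (Spearman ρ > 0.9) *and* whose growth exceeds 3× the
  estimated noise SD — without the amplitude floor, chance-monotone
  noise (probability 1/24 at four levels) produces spurious centers.
  Side minima of strong bands can still appear; the ±5 cm⁻¹ assignment
  tolerance absorbs them.
* **Assignment**: every library molecule with a milk or aqueous band
  center within the tolerance (default 5 cm⁻¹ ≈ 1.3 grid spacings) is
  listed, ranked by |Δ|; ambiguity is reported, never forced to a unique
  molecule. Unmatched features can carry broad-region annotations
  (lactose 1000–1200, CH stretch 2800–3000). One aqueous citrate band
  is published as a range (1581–1566) and is stored as its two
  endpoints.

## Synthetic trials

The generator emulates the trial the pipeline expects: 48 cows, 4
treatments × 12, two start periods of 6 blocks with one cow per treatment
per block (RCBD), 10 weekly samples per cow.

Concentrations follow
`baseline × lognormal(0, cow_sd) × (1 + drift·week) × treatment multiplier`
per analyte (cow_sd = 0.10, drift = 0.003/week); spectra are Beer–Lambert
sums of per-analyte pseudo-Voigt band sets over a fixed smooth milk
background, scaled by a per-cow gain `exp N(0, 0.02)` plus a per-cow
offset (SD 0.01) and tilt (SD 0.005) — the broad instrumental/matrix
factors that VN and FD are designed to remove — plus white noise of SD
1e-4 AU (typical FTIR milk-analyzer noise). Minor-component band centers
come from the packaged library; per-band relative intensities weight each
molecule's most prominent milk band highest (1405 cm⁻¹ for BHB, 1239 for
acetone). Six fixed broad "matrix constituent" factors with per-cow
weights stand in for the many other milk components, giving every
retained wavenumber correlated biological variance. These scales were
chosen so the synthetic eigenvalue structure matches what real trials
report — a structure-dominated spectrum (top components ≈ 95–99%
cumulative) retaining roughly 4 (raw), 9 (VN), 20 (FD) and 16 (VN-FD)
components — rather than a flat noise spectrum.

The default treatment effect is the negative-energy-balance signature:
TR3 multiplies BHB, acetone, citrate and free fatty acids by (1+δ) and
lactose by (1−δ) with δ = 1.5 × cow_sd = 0.15. The composition table
(fat, protein, lactose, urea, BHB) is derived from the same
concentrations that build the spectra, before spectral noise. All
randomness flows from one seed through per-cow `SeedSequence` children,
so identical seeds give bit-identical trials and any subset is
reproducible.

**What the synthetic tests show — and don't.** Closed-loop experiments
(200 replicates each) establish that the pipeline's per-component type-I
error is nominal, that a 1.5-cow-SD TR3 shift is detected on the
long-term VN-FD variant in ≥ 80% (empirically ≈ 99%) of trials, and that
the detected component's integrated loading reproduces the expected sign
pattern (positive carboxylate/BHB/FFA/CH-stretch mass, negative lactose
mass, up to the global orientation fixed by the sign rule). They do not
establish performance on real spectra: the generator has linear mixing,
Gaussian factors, no water-vapor or CO₂ interference, no band shifts or
nonlinearity at high absorbance, and an effect size chosen for test
power — the true trial effect was sub-clinical and its magnitude is
unknown.

## Numerical conventions and degenerate inputs

Variance divisors are n−1 throughout. Constant spectral columns make
standardization undefined and raise an error listing the offending
wavenumbers; zero-norm rows, single-point segments, empty averaging
windows, empty region selections and rank-deficient designs all raise
typed errors rather than propagating NaNs. Simulation sizes in the test
suite (200 replicates, 48 cows, 1060-point spectra) were chosen to give
stable binomial bands at modest cost.
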