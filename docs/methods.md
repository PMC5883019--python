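# Methods

## Forward model and time axis

A decay histogram is modeled as the unit-sum IRF convolved (linear,
non-periodic) with a sum of 1–3 exponentials, scaled so the signal term
integrates to a photon budget, plus a constant background C per bin.
Lifetimes are in ns throughout; the CLI accepts `ps`/`ns` suffixes.

The acquisition bin width is not a property of the decay model itself but of
the electronics; the default axis is 256 bins over 12.5 ns (the repetition
period of an 80 MHz Ti:sapphire laser), i.e. ≈48.8 ps per bin, and is
configurable. Linear convolution truncated at the window is the default; a
periodic ("incomplete decay") mode is available via `evaluate_model(...,
periodic=True)` for lifetimes long enough to wrap the window, but is
unnecessary for the ≤2.5 ns lifetimes studied here. The model exponentials
are sampled at bin-start times; generator and fitter share this
discretization, so it cancels in recovery studies.

The synthetic IRF is a discrete Gaussian (default FWHM 220 ps) centered at
10% of the window — only the width of the real instrument response is
specified by measurement, so a Gaussian is the minimal assumption. An IRF
shift parameter (fractional bins, linear interpolation) can be co-fitted to
absorb small timing offsets; it defaults to off because the synthetic IRF
is exactly aligned.

## Fitting

Levenberg–Marquardt (lmfit/MINPACK) on weighted residuals. Two weightings:

* `neyman` — residuals scaled by 1/√max(counts, 1). The convention of
  commercial TCSPC fitting software; the default for whole-solution decays,
  whose peak counts (≥3000, typically ~20 000 at the 5×10⁵-photon default
  budget) put it safely in its asymptotic regime. It carries the known
  downward lifetime bias of order 1–2% near the 3000-count gate, measured
  in the test suite and visible as a small but statistically significant
  mean error at high replicate counts.
* `poisson_mle` — signed square-root Poisson deviance residuals, whose
  least-squares minimum is the Poisson maximum-likelihood estimate. Unbiased
  down to very low counts; the default for per-pixel cellular fits, where
  3×3-binned decays peak at only ~15–50 counts and Neyman weighting would
  bias the bound lifetime by several percent.

Reported reduced χ² always uses the Neyman form Σ(y−ŷ)²/max(y,1)/(n−p)
regardless of the fit objective, so model-selection comparisons are on a
common scale. On correctly specified Poisson data with nonzero background
its median over replicates is ≈1 (0.8–1.2 asserted in tests). Bins with
near-zero expectation (before the rising edge, when C≈0) contribute ~0
to χ² but still count in n, so decays with no background can sit slightly
below 1.

Initial values: lifetimes (0.4, 2.0, 3.5) ns unless fixed; amplitudes split
equally on the data's photon scale; C from the mean of bins preceding the
rising edge (first crossing of 10% of peak); shift 0. Bounds: τ ∈ [0.05, 10]
ns, amplitudes ≥ 0, C ≥ 0. After fitting, components are sorted by lifetime
ascending and amplitudes renormalized to fractions. Fitting uses no
randomness; results are bit-reproducible.

Model order selection tries candidate component counts in ascending order
and keeps a higher order only if it lowers reduced χ² by more than 5%
(configurable) — the "no improvement → keep the simpler model" rule.

Quality gates use peak bin counts as the SNR statistic: 3000 for
whole-solution decays, 15 for 3×3-binned cellular decays. Peak counts are
the natural photon-limited quality measure for a binned TCSPC curve; no
other definition is assumed.

## Solution design and binding equilibria

Designing a solution for a target free fraction α₁ uses the site occupancy
F = α₁L/(α₁L + K_D) and [E] = (1−α₁)L/(F·S). The numerator is the bound
ligand concentration (1−α₁)·L — the only dimensionally consistent reading
of "total minus free" — and under it the design is the exact inverse of the
forward equilibrium (round-trip property asserted to 1e-9).

The forward single-enzyme equilibrium solves the mass balance
L_free + S·E·L_free/(L_free+K_D) = L in closed form, using the
cancellation-free branch of the quadratic formula when enzyme is in large
excess. The competitive two-enzyme case solves the analogous balance by
Brent root-finding on [0, L]. K_D and S are required inputs: published
values vary with buffer, temperature and isoform, and no bundled constant
should be mistaken for authoritative.

## Two-enzyme unmixing and regression

Mixture decays are fitted with all three lifetimes fixed at (0.45, 1.2,
1.6) ns — free NADH, NADH–MDH, NADH–LDH — leaving only amplitudes,
background (and optionally shift) free. The measured LDH share
α_LDH/(α_LDH+α_MDH) is regressed on the true concentration share
[LDH]/([LDH]+[MDH]) with the intercept forced to zero. For a through-origin
line, R² is reported in the uncentered form 1 − SS_res/Σy² (the convention
of common graphing software when the intercept is fixed; a centered R²
would differ and can be negative). The slope's 95% CI uses the t
distribution with n−1 degrees of freedom; both the slope-zero p-value and
the ordinary Pearson-correlation p-value are reported, since "the
regression was significant" can refer to either.

Ground-truth amplitudes for simulated mixtures take the free amplitude from
the measured per-mixture values of the published design table and split the
bound amplitude between the two enzymes in proportion to concentration —
the proportionality the regression is designed to validate. The
competitive-binding solver can generate an equilibrium-based truth instead.

## Imaging pipeline

Per-pixel decays are pooled over a sliding (2r+1)×(2r+1) window (default
r=1, i.e. 3×3), truncated at image edges, via an exact summed-area table.
Pixels passing the peak-count gate are fitted with the two-component model,
both lifetimes free (the intracellular environment shifts the free lifetime,
so it is not fixed as in solutions); failed or gated pixels are NaN.
Intensity maps integrate the unbinned per-pixel decay; the redox ratio
NAD(P)H/FAD is computed per pixel without binning, NaN where FAD is zero.
Per-cell statistics are means over cytoplasm pixels (cell label minus
nucleus label, background = label 0), NaNs excluded; cells with fewer than
10 valid pixels (configurable) are dropped with a warning. Group means are
reported normalized to the control-group mean. Segmentation is an input:
the generator's ground-truth masks are the canonical path, and the bundled
Otsu-threshold labeler is a convenience only.

## Statistics

Welch's unequal-variance t-test (Satterthwaite degrees of freedom,
two-sided) compares lifetime variables between groups; the ratio-paired
t-test — a one-sample t on log(after/before) — compares paired
multiplicative quantities such as normalized redox ratios. Degenerate
conventions: identical zero-variance groups give p=1; a constant non-unit
ratio gives p=0. Type-I error of both tests is calibrated in the test suite
against 2000 null draws at 5 replicates per group (Welch) and 4 pairs
(ratio-paired); at 3 replicates per group the Welch approximation itself is
conservative (~3% empirical rate), which is a property of the test, not of
this implementation.

## Synthetic data

The generator emulates: Poisson shot noise around the exact forward-model
expectation (no detector dark-count structure beyond C, no afterpulsing,
dead time, pile-up, bleaching or drift); the solution photon regime (default
budget 5×10⁵ photons per pooled decay, peak counts far above the 3000
gate); and cell scenes of non-overlapping elliptical cells (rejection
sampling, capped attempts) with concentric elliptical nuclei. Per-cell
parameters are drawn from truncated normals — α₁ ~ N(0.75, 0.03),
τ₁ ~ N(0.6, 0.1) ns, τ₂ ~ N(2.7, 0.2) ns, redox ratio ~ N(1.0, 0.1) —
placed inside reported cellular ranges (bound lifetime ≈2.4–2.9 ns); they
are plausible stand-ins, since real joint α/τ distributions are not
published numerically. Default budgets: 150 expected photons per cytoplasm
pixel (nucleus 50, background 0.5), so a 3×3-binned cytoplasm decay peaks
near 30 counts and passes the 15-count gate. The FAD channel is drawn
Poisson with per-pixel mean equal to the expected NAD(P)H intensity divided
by the cell's true redox ratio.

Everything derives from one integer seed; scene generation, solution draws
and the full pipeline are bit-identical across runs with the same seed.

## Test and acceptance problem sizes

Tests exercise the image pipeline on 32–72 px frames with 2–4 cells and the
default per-pixel budgets; recovery conclusions (cell-mean bound lifetime
within 3% of truth, rank order preserved) are properties of the count
regime, which matches the full-size defaults, not of the frame size.
Solution-level recovery uses 10–20 Poisson replicates per condition.
`scripts/acceptance.py` uses the full solution protocol (4 mixtures × 3
replicates; 10 seeds per lifetime recovery; 16 bead simulations) and runs
in seconds.

## Known limitations

* The reconvolution fit is model-equivalent to, but not bit-identical with,
  commercial TCSPC software whose deconvolution and fit-range settings are
  not public.
* The Neyman-weighted lifetime bias (above) is inherent to that weighting;
  use `poisson_mle` for low-count work.
* No global multi-pixel fitting, no phasor analysis, no FAD lifetime
  fitting, and no modeling of optics (PSF) or photophysics beyond Poisson
  counting.
* Passing tests on synthetic scenes shows the estimator chain is correct in
  the stated noise model; it does not certify performance on real cells,
  where IRF asymmetry, autofluorescence backgrounds and segmentation errors
  add structure the generator omits.
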