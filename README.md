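# flimcarbon

Analysis toolkit for NAD(P)H fluorescence lifetime imaging (FLIM) of cellular
carbon metabolism: TCSPC decay simulation, iterative-reconvolution
multi-exponential fitting, fixed-lifetime unmixing of NADH bound to competing
enzymes, NADH–enzyme binding-equilibrium solution design, and a per-cell
optical-redox-ratio imaging pipeline. A synthetic-data generator with full
ground truth stands in for the microscope, so every stage is testable without
instrument data.

## Who this is for

Microscopists and image analysts working with time-correlated single photon
counting (TCSPC) FLIM of the metabolic cofactors NAD(P)H and FAD, who need a
scriptable, tested alternative to GUI fitting software for:

* fitting photon-arrival histograms to reconvolution decay models,
* designing NAD(P)H–enzyme calibration solutions with prescribed
  free-to-bound ratios,
* quantifying the relative amounts of NADH bound to two enzymes in one
  sample, and
* turning FLIM image stacks into per-cell cytoplasm statistics.

## The model

A TCSPC histogram records photon counts per arrival-time bin (256 bins by
default, 12.5 ns window). Fluorescence from a mixture of emitters decays as

```
I(t) = IRF(t) * [ α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) (+ α₃ e^(−t/τ₃)) ] + C
```

where `*` is convolution with the instrument response function (IRF,
Gaussian with 220 ps FWHM by default), αᵢ are fractional amplitudes
(Σαᵢ = 1), τᵢ lifetimes, and C a constant background. Free NAD(P)H has a
short lifetime τ₁ (≈0.45 ns in solution); protein-bound NAD(P)H a longer
τ₂ that depends on the binding enzyme (≈1.2 ns for malate dehydrogenase,
≈1.6 ns for lactate dehydrogenase, ≈2.5 ns for G6PDH). The
amplitude-weighted mean lifetime is τ_m = α₁τ₁ + α₂τ₂.

Parameters are estimated by Levenberg–Marquardt minimization of weighted
residuals (Neyman 1/max(counts,1) weights, or a Poisson-deviance objective
for low-count data), with any subset of lifetimes fixed. Holding all three
lifetimes fixed turns the three-component fit into an unmixing of free NADH
and NADH bound to each of two enzymes; the measured LDH share
α_LDH/(α_LDH+α_MDH) is compared to the true concentration share by a
regression forced through the origin (slope m, uncentered R²).

Solution design inverts the single-site binding equilibrium: for a target
free fraction α₁, site occupancy F = α₁L/(α₁L + K_D) and the required
enzyme concentration is (1−α₁)L/(F·S), with L the NAD(P)H concentration,
K_D the dissociation constant and S the binding sites per enzyme.

The imaging pipeline fits each pixel of a 3×3-binned NAD(P)H stack (peak
counts below 15 are gated out), integrates per-pixel intensity, forms the
optical redox ratio I_NAD(P)H/I_FAD without binning, and averages every map
over each cell's cytoplasm (cell mask minus nucleus mask).

## Worked example

```python
import numpy as np
from flimcarbon import (MultiExpModel, make_irf, simulate_solution_decay,
                        simulate_mixture_series, unmix_mixtures)
from flimcarbon.fitting import FitConfig, fit_decay

irf = make_irf()                                   # 220 ps FWHM, 256 bins
truth = MultiExpModel.from_arrays([0.6, 0.4], [0.45, 1.6])
hist, _ = simulate_solution_decay(truth, irf, photons=5e5, seed=1)
fit = fit_decay(hist, irf, FitConfig(n_components=2, fixed_taus=(0.45, None)))
print(np.round(fit.model.alphas, 3), np.round(fit.model.taus, 3),
      round(fit.reduced_chi_squared, 2))
# [0.597 0.403] [0.45  1.588] 0.74

decays, _ = simulate_mixture_series(irf=irf, replicates=3, seed=1)
table, reg = unmix_mixtures(decays, irf)
print(f"m = {reg.slope:.3f}, R^2 = {reg.r_squared:.4f}")
# m = 0.972, R^2 = 0.9997
```

The first fit recovers the simulated bound fraction (0.403 vs 0.4) and
bound lifetime (1.588 ns vs 1.6 ns) from a Poisson-noise decay with ~20 000
peak counts; the reduced χ² near 1 says the two-component model describes
the data. The second block simulates the four-mixture LDH/MDH series three
times, unmixes each decay with fixed lifetimes, and regresses the measured
LDH share on the true one: a slope near 1 and R² near 1 mean the amplitude
fractions track the enzyme proportions.

A `flimcarbon` command-line tool wraps the same functions
(`fit`, `design`, `simulate`, `unmix`, `cells`); try
`flimcarbon design --ligand 50uM --alpha1 0.5 --kd 25uM --sites 2`.

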