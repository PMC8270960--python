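# Methods

## Model and procedure

A ring complex viewed along its symmetry axis is modeled as a set of coaxial
shells; shell s has n_s identical subunits at radius r_s, so its intensity
as a function of polar angle θ at that radius is periodic with fundamental
angular frequency n_s.  The pipeline estimates n per shell:

1. **Centering.**  Median background subtraction, negative residuals
   clipped, intensity centroid as the initial estimate.  Refinement
   minimizes the intensity-weighted circular variance of the radial position
   of the shell's intensity peak over θ, searched on a 0.1 px grid within
   ±3 px of the centroid (staged steps 1.0 → 0.25 → 0.1 px).  The metric is
   evaluated on a copy smoothed with a Gaussian at the subunit-blob scale
   (σ = 1.5 px) and restricted to a ±8 px radial window around the dominant
   shell of the rotationally averaged radial profile.  Both choices are
   robustness measures, not fits: the window keeps the metric single-shell
   (a global radial argmax hops between shells of a multi-shell ring as θ
   sweeps through their subunit gaps), and the smoothing suppresses
   per-pixel noise that otherwise limits the metric near SNR ~ 2.
2. **Polar resampling.**  Bilinear interpolation (bicubic behind a flag) on
   an (n_r × n_θ) grid over the radial band; out-of-frame samples are
   zero-filled, counted, and warned about above 1%.  θ = 0 is the +x axis,
   increasing counterclockwise; bins are half-open on [0, 2π).
3. **Spectrum.**  Each radius row is mean-subtracted; P(k) = |FFT/N|² per
   row, averaged over rows (incoherent, the default) or computed on the
   collapsed mean profile (coherent).  Incoherent averaging is preferred
   because relative angular phase between shells — or between the leading
   and trailing edge of one thick shell — cancels coherent averages.  The
   autocorrelation route (FFT of the circular ACF) is mathematically
   identical by Wiener–Khinchin and is kept as an independent cross-check;
   its tiny negative coefficients from rounding are clipped to zero.
4. **Call.**  Order = argmax of P(k) over the candidate range.  Exact power
   ties resolve to the lower order (the conservative stoichiometry claim)
   and are flagged ambiguous.  Confidence = peak/median power over the
   range; threshold 3.0 by default.  A rival candidate within 10% of the
   peak also flags the call ambiguous — for blob trains of low order
   (n ≲ 5) this fires systematically, because the blob envelope is nearly
   flat at small k and the harmonic 2n genuinely carries >90% of the
   fundamental's power; the recovered order is still correct.  A
   harmonic-sum scorer (power summed over multiples of each candidate) is
   available behind a flag but is not the default: within a narrow
   biological candidate range the fundamental dominates, and the harmonic
   comb of a low candidate can alias that of a high one.

## Parameters

| parameter | default | meaning |
|---|---|---|
| band (r_min, r_max) | user-set, px | radial band selecting one shell |
| n_theta | 720 | angular bins; must be ≥ 4·k_hi (2× Nyquist margin) |
| n_r | 32 | radial samples across the band |
| candidate_range | (2, 40) | inclusive order range searched |
| confidence_threshold | 3.0 | peak/median power needed to assign |
| spectrum_source | per-radius | incoherent per-radius power averaging |

The band has no universal default because it is a property of the specimen;
the packaged fixtures use bands centered on their known shell radii with
±8–20 px margins.

## Synthetic phantoms

Subunits are isotropic Gaussian blobs (amplitude a, footprint σ) placed at
angles φ + 2πj/n on a circle; shells sum; optional per-pixel white Gaussian
noise and a Gaussian low-pass envelope follow.  SNR is defined as a/σ_noise
(peak blob amplitude over per-pixel noise standard deviation).  Populations
draw each particle's order from stated proportions, jitter the center with a
Gaussian (default σ = 1 px), rotate uniformly on [0, 2π), and add noise; one
seeded generator is consumed in a documented order (all labels, then per
particle jitter → rotation → noise) so truth tables are bit-reproducible.

Fixture registry: `sring34` is a single 34-fold shell at r = 120 px on a
512² frame (1 Å/px, i.e. a 24 nm ring); `msring_shells` adds 23- and
11-fold shells at radii 0.4 and 0.6 of the outer radius.  The radii ratios
are emulation choices, not measurements.

What the phantoms do *not* emulate: CTF oscillations (only a Gaussian
envelope), structured/correlated background, lobed or tilted subunit
shapes, shell thickness profiles, and particle-picking errors.  Passing
tests therefore demonstrate the correctness and noise robustness of the
angular-harmonic readout, not end-to-end performance on micrographs.

## Numerical choices

- Bilinear polar resampling; measured rotation-equivariance floor ~1% of
  signal RMS at blob σ = 2 px.  Bicubic (behind the flag) reaches ~2×10⁻⁴
  and is what the 10⁻³-level equivariance property is asserted with.  Power
  spectra, being phase-insensitive, are rotation-invariant to ≤10⁻³ even
  with bilinear resampling.
- Class-average rotation uses cubic-spline resampling: averaging is
  sensitive to interpolation blur (bilinear leaves ~1.7% residual on a
  two-copy test; cubic ~0.03%).
- Alignment reference is the first assigned member; rotations are found by
  circular cross-correlation of angular profiles, refined parabolically to
  sub-bin precision, and reduced modulo 2π/n.
- Degenerate inputs raise: blank/flat images ("no ring signal"), empty
  stacks, zero-variance profiles under unit ACF normalization, annuli with
  no radius rows, candidate ranges violating k_lo ≥ 2 or k_hi ≤ n_θ/4.
- Chi-square comparison pools orders with expected count < 1 into adjacent
  orders; only the statistic and df are reported, never a verdict.

## Problem sizes used in the checks

The packaged verification runs use 512² fixtures for the single-ring and
subsymmetry readouts, a 39-phantom sweep (orders 2–40, 128² frames) for
exact recovery, 250 particles at SNR 2 for assigned-call accuracy, and
1000 particles at SNR 3 for mixture-percentage recovery — sizes chosen to
give stable statistics at desk scale.

## Limitations

- The candidate range is a user responsibility; the argmax call is only
  meaningful when the true order lies inside it.
- Percentages are computed over assigned particles only; heavily
  noise-degraded datasets can bias distributions if misassignment
  correlates with order.
- No translational alignment against a reference and no CTF correction;
  inputs are assumed to be reasonably centered, flat-backgrounded particle
  images or class averages.
- Printed one-decimal percentages need not sum to exactly 100 after
  rounding.
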