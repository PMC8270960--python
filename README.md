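# ringsym

Rotational symmetry determination for ring-shaped macromolecular complexes
imaged end-on by electron microscopy.

Many molecular machines are built from rings of identical subunits — the
flagellar basal body's MS ring and C ring are the motivating examples — and
a central structural question is the subunit count n, i.e. the ring's
Cn rotational symmetry.  When end-on views resolve the individual subunit
blobs around the circumference, n can be read out directly from single
particles or 2D class averages, without imposing any symmetry during 3D
reconstruction.  `ringsym` implements that readout as a tested, reusable
pipeline, together with a phantom generator that provides ground-truth rings
so every stage is verifiable without micrograph data.

## Method

For an image I(x, y) of a ring centered at c:

1. **Center** the ring: intensity centroid after median background
   subtraction, refined to sub-pixel precision by minimizing the circular
   variance of the ring's radial peak position over angle.
2. **Polar resampling**: bilinear interpolation of I onto a grid
   p(r_i, θ_j) = I(c + r_i (cos θ_j, sin θ_j)) over a radial band
   [r_min, r_max] selecting one shell, with θ ∈ [0, 2π) in n_θ bins.
3. **Angular autocorrelation** of the zero-mean angular signal a(θ):
   ACF(Δ) = (1/N) Σ_θ a(θ) a(θ+Δ), circular in Δ.
4. **Rotational power spectrum**: P(k) = |â(k)|², the squared modulus of the
   k-th Fourier coefficient — equivalently the Fourier transform of the ACF
   (Wiener–Khinchin); both routes are implemented and cross-checked.  By
   default per-radius spectra are averaged incoherently over the band,
   which is robust to radial phase shifts between shells.
5. **Symmetry call**: n = argmax_k P(k) over a candidate range [k_lo, k_hi],
   with confidence = peak/median power over the range (assigned when ≥ 3 by
   default; ambiguous when a rival candidate is within 10% of the peak).

A Cn ring of subunit blobs concentrates power at k = n and its multiples,
so the fundamental dominates inside any biologically narrow candidate range.
Scanning the call over radial annuli localizes *subsymmetries* — different
orders at different radii of the same complex, such as a 34-fold outer ring
enclosing 23- and 11-fold inner zones.

Population tools classify whole particle stacks, tabulate symmetry
distributions (counts and percentages over assigned particles), compare two
distributions (per-order deltas plus a pooled chi-square statistic), and
build rotationally aligned per-order class averages.

## Worked example

Render the three-shell phantom (23-, 11- and 34-fold shells at radii 48, 72
and 120 px) and scan annuli centered on each shell:

```sh
$ ringsym simulate --fixture msring_shells --out msring.mrc --seed 1
$ echo '[[40,56],[64,80],[112,128]]' > annuli.json
$ ringsym scan-radius msring.mrc --annuli annuli.json --krange 5 40 --ntheta 720 --out scan.tsv
annulus [40, 56] px: order=23 status=assigned confidence=1094297.52
annulus [64, 80] px: order=11 status=assigned confidence=410488.66
annulus [112, 128] px: order=34 status=assigned confidence=3497568.05
```

Each annulus recovers the order of the shell it contains; the confidence is
the ratio of the winning harmonic's power to the median power over the
candidate range (enormous here because the phantom is noiseless).

A population workflow — 200 noisy particles drawn from a 33/34/35-fold
mixture (20% / 66% / 14%), classified and tabulated:

```sh
$ ringsym simulate --orders "33:0.2,34:0.66,35:0.14" -m 200 --snr 3 \
    --out pop.mrc --truth truth.tsv --seed 2
$ ringsym analyze pop.mrc --rmin 36 --rmax 52 --krange 30 40 --out calls.tsv
analyzed 200 particles, 200 assigned -> calls.tsv
$ ringsym population calls.tsv --out dist.json
33-fold: 42 (21.0%)
34-fold: 127 (63.5%)
35-fold: 31 (15.5%)
assigned 200 of 200 particles
```

The recovered percentages track the generating mixture to within multinomial
sampling noise at this population size.

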