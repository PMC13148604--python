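# Methods

## Model and conventions

The filter acts on a flat-field-corrected frame *f* = *I*/*I*₀. Its Fourier
transfer function is 1/(1 + ℓ‖**q**‖²) with unit DC gain, followed by a
logarithm on the pixels where the filtered intensity is positive. Under the
homogeneous-object TIE model with ℓ = *z*δλ/(4πβ), −*p*<sub>ℓ</sub>/μ is the
projected thickness (μ = 4πβ/λ). Conventions fixed by this package:

* **Frequency convention.** ‖**q**‖ is angular spatial frequency by default
  (2π × FFT cycle frequency / pixel size), so ℓ‖**q**‖² is dimensionless
  when ℓ is in squared length units; a `cyclic` convention (no 2π) is
  selectable in `FilterParams` since published ℓ values do not always state
  which convention they assume. All synthetic work uses pixel size 1, i.e.
  ℓ in squared pixels.
* **Boundaries.** Filtering is a circular convolution (the discrete Fourier
  definition); an optional symmetric-padding flag softens wrap-around for
  frames with strong edge gradients.
* **Invalid pixels.** Non-positive intensities in *I* or *I*₀ are masked
  out, never clipped; before an FFT, masked-out pixels are filled with the
  valid-pixel mean (zero for the split difference). Pixels whose filtered
  intensity is non-positive cannot support the logarithm and are masked out
  of *p*<sub>ℓ</sub> — no epsilon clipping, so the noise statistics stay
  unbiased.
* **Sign.** *p*<sub>ℓ</sub> = +ln(filtered ratio); the thickness-positivity
  criterion therefore asks for a non-*positive* profile of *p*<sub>ℓ</sub>.

## Spectral statistics

The frame is split into complementary half-images (even/odd rows by default;
columns and checkerboard are offered — checkerboard for isotropy-sensitive
work). Both halves keep the parent pixel size for ring construction: they
share one grid, so the FRC is well defined, and the halved sampling along the
split axis is deliberately ignored for the *r*-normalization.

Rings are equal-width bins of the normalized radius *r* = ρ/ρ<sub>max</sub>
over (0, 1], where ρ<sub>max</sub> is the Nyquist radius of the grid; the DC
sample and corner samples with *r* > 1 belong to no ring. The default ring
count is half the minimum image extent, capped at 256.

* **NPS.** Single-realization periodogram of the split difference
  *n* = *u* − *v*, scaled so total spectral power equals the mean square of
  *n*, ring-averaged and multiplied by the frame area (units intensity² ×
  area). Expectation is approximated by ring averaging only — no multi-frame
  ensemble. No factor-½ correction of the split-difference NPS is applied by
  default: the selection functional φ is a normalized ratio and is invariant
  to it; pass an explicit `area` for absolute reporting.
* **φ(ℓ).** Fraction of the noise-power mass |S<sub>*r*</sub>|W(*r*) in
  rings whose *center* radius exceeds r̂ (band membership by ring centers;
  the spec of the band edge at exactly r̂ is below the ring resolution
  anyway). φ ∈ [0, 1]; zero total power gives φ = 0.
* **FRC.** Plain normalized ring cross-correlation. Rings with vanishing
  norms are NaN (undefined), not 0. The even/odd halves are offset by half a
  (subsampled) pixel, which deterministically lowers the plain FRC at high
  frequency even without noise; `split_shift_phase` provides the standard
  phase-ramp compensation and `compute_curves(..., shift_corrected=True)`
  applies it. It is off by default to keep the plain definition.
* **Consistency bound.** The bound is a pluggable function of the ring's
  extremal Fourier magnitudes (m, M), pooled over both halves. The default,
  B = 2mM/(m² + M²), is the worst-case cosine between two coefficient
  vectors whose per-sample magnitudes are confined to [m, M] — an
  approximation standing in for the exact published bound, whose closed form
  was not available when this package was written. Consistency
  c(*r*) ≥ B(*r*) is always *reported* (per-ring flags plus a fraction),
  never silently assumed.

## Selectors

* **NPS/ε bisection.** Smallest ℓ with φ(ℓ) ≤ ε over a bracket (default
  [0, 10⁸]). φ decays monotonically with ℓ; this is verified on a coarse
  probe grid and, if violated, the selector warns and falls back to a dense
  512-point log-grid scan. Bisection runs on a log scale (with a positive
  floor of 10⁻¹⁴ × the upper bracket when the lower bound is 0) to relative
  tolerance 10⁻³ on ℓ, at most 60 iterations; the feasible end of the final
  bracket is returned, so the result is feasible by construction. Defaults
  ε = 0.01 and r̂ = 0.5: r̂ = 0.5 is the conservative half-Nyquist cutoff;
  ε = 0.01 ("1% of the noise power may stay above the cutoff") is this
  package's default, chosen as a strict but reachable suppression level —
  both are exposed as parameters and CLI flags.
* **Fuzzy interval.** [ℓ<sub>r̂+Δr</sub>, ℓ<sub>r̂</sub>] with Δ*r* = 0.1 by
  default; raising the cutoff relaxes the criterion, so the interval is
  ordered by construction of φ's monotonicity in r̂.
* **Merit curves.** The grid is 128 points over [10⁻², 10⁸] in working
  units, organized as eight equal logarithmic subintervals sampled with a
  common density (a uniform geometric mesh). The step *h* between the two
  filtered frames is the local grid spacing — uniform in log ℓ — so
  *f*(ℓ) ≈ |∂p/∂ln ℓ| Δln ℓ; a fixed-step mode can be had by passing an
  explicit arithmetic grid. *f* uses the standard deviation over jointly
  valid pixels; *g* is the Pearson (mean-centered) correlation, insensitive
  to additive offsets — two jointly constant frames count as perfectly
  correlated (g = 1), a single zero-variance frame against a varying one is
  undefined and raises. ℓ<sub>std</sub> is the grid argmax of *f* restricted
  to (0, ℓ̂<sub>nps</sub>] (the cap is computed internally when not given),
  ℓ<sub>corr</sub> the grid argmin of *g*; ties break toward the smallest ℓ
  (favoring resolution retention); extrema at a grid boundary raise a
  warning rather than an error. An optional 3-point quadratic refinement in
  log ℓ sharpens the extremum off-grid; plain argmax/argmin is the default
  since the elbow definition is the stated objective.
* **Thickness criterion.** Smallest ℓ with max *p*<sub>ℓ</sub> ≤ slack
  (default 0) along a chosen row, bisected like the NPS criterion; an
  absolute tolerance of 10⁻¹⁰ absorbs FFT round-off in the comparison.
  Residual edge overshoot keeps the profile positive for ℓ below the
  generating parameter and vanishes at it, which is what makes the criterion
  sharp on the synthetic forward model.

All selectors are deterministic given their inputs; the pipeline report is
byte-identical across reruns of one configuration.

## Synthetic data

The generator emulates a single-material synchrotron projection under the
linearized TIE: a feature-superposition thickness map *T* (discs, rods,
annuli), the contact image exp(−μ*T*), and the *exact inverse* of the
filter's low pass — multiplication of the spectrum by (1 + ℓ<sub>true</sub>
‖**q**‖²) — to produce the edge-enhanced frame. Filtering that frame at
ℓ<sub>true</sub> returns −μ*T* to FFT precision, the module's central
oracle. Poisson sample and flat frames use independent substreams of one
seed; every output is a pure function of the spec.

Default conditions (chosen once as a realistic desk-scale projection):
128² pixels of unit size, μ·T ≈ 0.5 at the thickest feature (≈ 60%
transmission), ℓ<sub>true</sub> = 100 squared pixels, 10⁴ expected photons
per pixel, and a 6-pixel Gaussian edge blur — the smallest blur keeping the
clean intensity strictly positive, since sharper edges under the inverse
filter would produce negative intensities outside the linearized model's
validity (and the masked pixels they force would leave a spurious flat NPS
floor). The two-material variant for histogram-separability work uses one
disc with mild phase contrast (ℓ<sub>true</sub> = 5, 3-pixel blur) so the
background intensity distribution stays unimodal. The forward model is
deliberately not a Fresnel propagator: it is the model class for which the
filter is exact, which makes selector behavior interpretable; consequences
of model mismatch (partial coherence, detector MTF, non-TIE propagation)
are *not* probed by these tests.

## Metrics

The local-contrast map is a blockwise coefficient of variation (population
standard deviation over mean, valid pixels only); blocks with non-positive
mean and partial boundary blocks are masked, and the map is invariant under
global positive rescaling. The histogram separation score takes the two most
prominent local maxima of a 3-bin-smoothed histogram and divides their
distance by a pooled robust width (scaled median absolute deviation of the
pixels assigned to the nearer mode, so edge-transition pixels do not swamp
the width). It is a qualitative separability indicator, undefined (None)
with fewer than two modes.

## Problem sizes used in the test suite

Unit and acceptance tests run on 16²–128² frames, 20–128-point parameter
grids, a 512-point dense-scan oracle, and up to 50-seed Monte Carlo checks —
sizes at which every statistical band (4–5 standard errors) is meaningful
while the whole suite stays fast.

## Known limitations

* The per-ring FRC of a *single* noisy realization fluctuates around its
  structural plateau by order 1/√|S<sub>*r*</sub>|, and the even/odd split
  caps high rings below 1 (half-sample offset and aliasing, only partly
  removable by the phase correction). The idealized picture — every ring's
  correlation rising monotonically to 1 with ℓ — holds for the expectation,
  not per realization; the corresponding strict per-ring regression test is
  expected to fail and is kept as an honest record of this limit. The
  *aggregate* statistics the selectors actually use (φ and the high-band
  NPS mass) are monotone to tight tolerance.
* Stationary, isotropic noise is assumed by the ring averaging; ring
  artifacts, detector anisotropy or strong shading violate it.
* The consistency bound's default form is an approximation (see above).
* The thickness criterion is sharp only when some profile pixels have
  exactly zero thickness next to an edge; heavy edge blur hides small
  overshoots below the slack level and biases the recovered ℓ low.
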