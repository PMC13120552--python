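# Methods

This note documents the models implemented in `tomoeval`, the defaults and
why they were chosen, and what the synthetic pipeline does and does not
emulate.

## Phantom

The built-in phantom is a modified Shepp–Logan arrangement of nine
emitting ellipses on a 256 mm field of view: a large body/background
ellipse `SRC0` (75 × 100 mm semi-axes), two rotated side ellipses
`SRC1`/`SRC2`, a central ellipse `SRC3`, and five small hotspots
`SRC4`–`SRC8` (down to 2.5 mm semi-axes). Specific activities are 5 for
the side ellipses, 10 for the central ellipse and hotspots, and either 5
(variant 1) or 20 (variant 2) for the background; variant 2 realizes the
deliberately low-contrast background:side:hotspot ratio 20:5:10. There is
no skull: the attenuating medium is uniform water coincident with `SRC0`.

Rasterization conventions:

* image center = (0, 0) mm, x rightward, y upward; pixel values are
  sampled at pixel centers; the default 256-pixel grid gives 1 mm pixels;
* ellipse rotation is counter-clockwise about the ellipse center, applied
  to the (x, y) semi-axes;
* later-listed ellipses **override** earlier ones. Override (rather than
  additive) semantics is the only reading consistent with the 20:5:10
  ratio of variant 2, where the side ellipses read 5 on top of a
  background of 20.

`mu_water` defaults to 0.0146 mm⁻¹, the linear attenuation coefficient of
water near 159 keV (the ¹²³I photopeak); it is a physical-constant choice
and fully configurable.

The three default RoIs are rectangles chosen to probe distinct failure
modes: an edge box straddling the top boundary of `SRC3` (boundary
sharpness), a hotspot box enclosing the `SRC6`–`SRC8` cluster (local
intensity recovery), and a background box at (30..50, −65..−45) mm inside
`SRC0` and away from every source (noise stability). Their geometry is a
package choice — any boxes can be supplied — and they are pairwise
disjoint by construction.

## Forward model

The projector is an analytic stand-in for Monte Carlo photon transport.
Each detector bin accepts only rays perpendicular to the detector face
(ideal-collimator parallel-beam geometry). A ray is sampled at equally
spaced points (step = half a pixel), each sample reads the image by
bilinear interpolation, and the line integral is the step-weighted sample
sum. Attenuation enters per sample as exp(−∫μ dl) along the remainder of
the ray toward the detector (midpoint rule), which keeps the attenuated
operator linear in the emission image. The same assembly produces the
sparse system matrix used by the reconstructors, so forward simulation
and reconstruction share one discretization exactly (adjoint = matrix
transpose).

Default acquisition: 128 projections over 360° (angular step 2.8125°),
256 detector bins at the pixel pitch, and an expected 5 × 10⁶ detected
counts in total — a realistic planar-study statistics level of roughly
4 × 10⁴ counts per projection; fractions 1/8, 1/4, 1/2 scale it. Counting
noise replaces each bin of the count-scaled noise-free sinogram with an
independent Poisson draw; the per-bin variance σᵢ² is the expected count,
floored at one count so χ² weighting never divides by zero.

The standardized products are:

* **Source**: the rasterized phantom;
* **Detector**: source × angle-averaged survival probability
  (exp(−∫μ dl) averaged over acquisition angles, evaluated on the
  projector's ray grid and interpolated to pixel centers);
* **Ideal**: the noise-free attenuated sinogram at the expected count
  scale ("infinite statistics"), and as Ideal image its converged
  attenuation-aware MLEM reconstruction (iteration cap 200). The
  framework needs a fixed, documented operator for this reference; any
  converged, attenuation-aware reconstruction serves the role, and the
  recipe is recorded with the output;
* **Realistic**: the detector-blurred (1-D Gaussian along the bin axis,
  width configurable), Poisson-noisy acquisition and its reconstruction by
  the same recipe. Reconstructed images are rescaled back from the count
  scale to the source's specific-activity units.

Not emulated: Compton scatter, septal penetration, energy windows, dead
time, depth-dependent collimator response. Consequently the simulated
Ideal image differs from the Source through attenuation only, and
passing tests demonstrate correct behavior of the evaluation machinery on
attenuation-plus-counting-noise data, not fidelity to a full
scanner simulation.

## Reconstruction

Both reconstructors act on the shared sparse system matrix P.

**ART** is the relaxed Kaczmarz row action
`f ← f + λ (Sᵢ − ⟨Pᵢ,f⟩)/‖Pᵢ‖² Pᵢ`, sweeping all rays in an
angle-interleaved order (angles visited with a stride near the golden
ratio of the angle count, to decorrelate successive hyperplane
projections and reduce streaking). Relaxation defaults to λ = 0.5;
negativity is clipped at the end of each full sweep, not per ray, which
preserves the within-sweep update algebra. Zero-norm rays are skipped
with a warning.

**MLEM** is the multiplicative update
`f_j ← f_j/s_j · Σᵢ P_ij gᵢ/(Pf)ᵢ` with sensitivity `s_j = Σᵢ P_ij`.
The default start is a uniform positive image scaled so its forward
projection carries the data's total counts (scale-matched starts reach
χ² stationarity noticeably faster than an arbitrary constant). Pixels
with zero sensitivity are frozen at zero; the forward-projection
denominator is floored at 10⁻¹² of its maximum.

Both stop when the reduced χ² between the re-projected estimate and the
data (counting-statistics variances) is stationary: all of the trailing
`window` successive relative changes below `tol`. Defaults `tol = 10⁻³`
over `window = 3` — the criterion is standard, the numbers are package
choices. On the default 256-grid study the noisy MLEM run reaches
stationarity after roughly 200–250 iterations with a reduced χ² well
below 2, i.e. in the noise-limited regime.

## Metrics

* NMSE = Σ(X−Y)²/ΣY²; PSNR = 10 log₁₀(max(Y)²/MSE) (+∞ for identical
  inputs); CC = Pearson correlation; SSIM = Gaussian-windowed (11-pixel,
  σ = 1.5) mean structural similarity with the reference's data range;
  CNR = (μ_signal − μ_background)/σ_background on the test image, hotspot
  RoI vs background RoI by default.
* χ² diagnostics use σᵢ² = expected counts per bin; pixels with invalid
  variance are excluded and flagged. The reduced χ² is the mean over
  valid pixels; the RoI variant also reports the summed form, which is
  additive over disjoint masks.
* **SCI**: inputs are mean-normalized first, making the residual mean
  exactly zero, hence the luminance component ≡ 0 (reported anyway as a
  sanity row). Contrast and structure are global (whole-array) statistics
  between the residual R and the normalized reference Y, with SSIM-style
  stabilizers C = (kL)², k = (0.01, 0.03), L = data range of the
  normalized reference. The structure numerator uses |cov(R,Y)|: the
  index measures the *amount* of organized residual structure, and
  whether a method over- or under-shoots where the reference is bright is
  irrelevant to that amount. With the signed covariance the index would
  change sign across the convergence trajectory (early, smooth MLEM
  iterates undershoot hotspots, giving negative correlation) instead of
  decaying to zero from above. A windowed alternative (Gaussian-windowed
  component maps, averaged) is available behind the ``windowed`` flag;
  in both variants the index equals the product of the reported
  components exactly. Caveat: in fluctuation-dominated regimes
  (e.g. noisy ART output) a low SCI reflects noise masking coherent
  structure, not superior fidelity — interpret alongside the χ² and
  difference maps.
* **Intensity histograms** use NB = 256 equal-width bins spanning the
  joint range of the mean-normalized pair, raw pixel counts per bin (the
  comparison statistic is printed unweighted, so no frequency scaling),
  and the unweighted reduced χ² (1/NB)Σ(S_X − S_Y)².
* **Jackknife**: delete-one standard error over n ≥ 3 units,
  SE = √(((n−1)/n)Σ(θ̂₍ᵢ₎ − θ̄)²). Units are single projection angles for
  sinogram-domain metrics and 16-row image bands for image-domain metrics
  (the method prescribes no resampling unit; rows blocks keep the deleted
  fraction and the spatial correlation scale comparable between domains).

For RoI-localized metrics, pixel-statistics metrics use exactly the
masked pixels; SSIM and the SCI are evaluated on the mask's bounding box,
since sliding windows need spatial context (for the default rectangular
RoIs this is identical to the mask itself).

## Numerical and scale choices

* Test-suite and acceptance problem sizes: unit tests run on 32–65 pixel
  grids where closed forms are sharp; the convergence and sensitivity
  studies run at the full 256-pixel/128-projection configuration, which
  one MLEM iteration handles in ~0.1 s via the cached sparse matrix.
* The pixel-driven projector conserves mass per view to ~0.1% on smooth
  images; single-pixel sources show a few-percent angular ripple (the
  worst case for a bilinear footprint), and rasterized discs match the
  continuous chord-length profile to a few percent away from tangent
  rays. Tolerances in the tests reflect these discretization scales.
* Determinism: every stochastic step takes an explicit integer seed
  (`numpy.random.default_rng`); case-study reports embed the
  configuration hash and seed, and a rerun with the same hash is
  bit-identical.

## Known limitations

* No scatter or collimator-response physics; the Detector/Ideal images
  are attenuation-only references.
* 2-D only; the slice-thickness of a physical acquisition has no
  analogue here.
* The Ideal-image recipe (converged MLEM) injects the reconstruction
  operator's own discretization into the reference; comparisons between
  two *different* algorithms against this reference are still
  well-defined, but absolute residuals partially reflect the shared
  operator.
* RoI geometry defaults are package choices; studies that depend on RoI
  placement should fix and report their own boxes.
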