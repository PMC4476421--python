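# Methods

## Pipeline model

One acquisition frame is processed independently of all others (streaming:
memory is bounded by the frame size, results per frame are order-independent).
The stages, in order:

1. **Photoelectron conversion.** `N_e = (I − I_bias)/G_eff`, clamped at 0.
   Negative excursions below the bias carry no photon information and a
   Poisson count cannot be negative, so clamping keeps the noise model valid.
   All arithmetic is double precision.
2. **Noise model.** Shot noise of a background of `N_bg` photoelectrons has
   standard deviation `F·√N_bg`. `F` is the amplifier excess noise factor:
   `√2` for an EMCCD at high gain (the default), 1.0 for a noiseless
   amplifier.
3. **Background map.** Per-pixel local background: a median filter over a
   `(2·ceil(R_airy)+1)²` window followed by heavy Gaussian smoothing
   (σ = 4·R_airy), floored at 10⁻³ e⁻ so SNR divisions are always defined.
   A PSF-sized emitter elevates only a minority of any such window, so the
   median tracks the background underneath emitters while remaining unbiased
   on emitter-free shot noise (measured bias ≤ ~1.6% at means 10–100; a
   min(pixel, median) suppression step was evaluated and rejected because it
   biases the estimate low by 6–13% on pure Poisson frames). Boundary
   handling is reflective everywhere, to avoid dark rims that would inflate
   edge SNR. The estimator sits behind a single function so an annulus-based
   per-candidate variant can be swapped in.
4. **Smoothing.** Gaussian low-pass, σ = 1.0 px by default — below σ_PSF so
   the PSF shape survives. Candidate search and scoring run on the smoothed
   frame; fitting runs on the raw photoelectron frame.
5. **Candidate search.** Local maxima within the Airy radius
   `R_airy = 0.61·λ·M/(NA·μ)` px. Equal-valued connected plateaus count once
   (lexicographically smallest member) and only when no pixel within the
   radius of any member is brighter. Candidate pairs closer than `R_airy` are
   both discarded (strictly closer; a pair at exactly the radius survives) —
   overlapping PSFs cannot be fitted as single emitters and multi-emitter
   deconvolution is out of scope.
6. **ROI and scores.** ROI = pixels within `ceil(σ_PSF)` (Euclidean) of the
   peak whose smoothed value exceeds the local background, peak always
   included; signal = smoothed − background, clamped at 0. Scores:
   `SNR_eff` = ROI mean of per-pixel SNR; `CNR_eff` = ROI signal sum over the
   shot noise of the **whole** PSF disk (so a shrunken ROI cannot inflate
   contrast); `Q = min(SNR_eff, CNR_eff)`. Acceptance requires `CNR_eff > 3`
   (Rose criterion, strict, not user-configurable) and `Q ≥ q_threshold`.
7. **Fitting.** Unweighted least squares (Levenberg–Marquardt) of a 2D
   Gaussian over a square window of half-size `ceil(2·σ_PSF)` (> 95% of the
   PSF mass while limiting neighbour contamination). Model 1 fixes both
   widths to σ_PSF; model 2 fits one width; model 3 fits σ_x, σ_y
   independently. The offset is a free parameter in all models, initialised
   at the local background; position starts at the background-subtracted
   intensity centroid of the window (truncation bias < 0.05 px for an
   in-focus spot), amplitude at peak − background. Convergence: relative
   parameter tolerance 10⁻⁶, bounded iteration count; non-convergent or
   singular fits are rejected. The residual function is isolated so a
   Poisson-weighted variant could be added.
8. **Post-fit filters.** Variable-width fits must satisfy
   `0.5 px ≤ σ ≤ PWT·σ_PSF` (the lower bound operationalises the pixel-size
   limit: a narrower "spot" is a sampling artifact). All fits must reach a
   Pearson correlation `r ≥ 0.5` (configurable) between model and data over
   the window. A Thompson-style precision estimate
   `√((σ² + a²/12)/N + 8π·σ⁴·b²/(a²·N²))` is exported per localization but is
   not a default filter.
9. **Rendering.** 2D histogram at 10 nm bins by default (well below the
   80–120 nm structures of interest), or unit-integral Gaussian splatting
   (σ = 20 nm, truncated at 4σ and renormalised so each emitter contributes
   exactly unit mass). Line profiles project pixel mass in a band onto the
   axis perpendicular to a segment and are normalised to their maximum.

Coordinates: 0-based pixel indices, pixel centres at integers, `x` = column,
`y` = row; nm = px × (pixel size / magnification), origin at the centre of
pixel (0, 0).

## Key parameters

| parameter | default | units | role |
|---|---|---|---|
| `q_threshold` | 2.0 | – | the single mandatory user parameter; high-SNR data are insensitive over a wide range, low-SNR data need it tuned (≈1 works well in the low-SNR benchmark) |
| `rose_cnr_min` | 3 (fixed) | – | Rose detectability criterion |
| `model` | 1 | – | 1 is recommended for in-focus (TIRF, 2D-projected) data; 2–3 tolerate defocus |
| `pwt` | 3.0 | – | width tolerance of models 2–3; raising it accepts more (possibly defocused) emitters at the cost of localization precision |
| `pearson_r_min` | 0.5 | – | goodness-of-fit floor |
| `smooth_sigma_px` | 1.0 | px | pre-detection noise reduction |
| `excess_noise_factor` | √2 | – | EMCCD electron multiplication noise |
| optics | 64 nm px, λ 665 nm, NA 1.49 | | give R_airy ≈ 4.25 px, σ_PSF ≈ 1.46 px |

## Simulator

The generator emulates the three benchmark regimes used throughout: mean 500
signal photons per emitter (Poisson-distributed per emitter — "average"
implies a distribution) on a uniform background of 10 (high SNR) or 50
(low SNR) photons/pixel, optionally with a superimposed Gaussian-profile
background peaking at 50 photons at the frame centre with FWHM half the frame
size (read as FWHM, σ = frame/4.71). Each photon lands at a position drawn
from the 2D Gaussian PSF and is binned to its nearest pixel; the expected
background is added, Poisson shot noise is imposed on the total, and the
photoelectron image is mapped to camera counts as `pe·gain + bias` (the exact
inverse of the conversion) and quantised to 16 bits. Gain is applied
deterministically — no stochastic electron-multiplication cascade — so the
realised counts are exactly Poisson; an excess-noise cascade would be a
realism extension, not part of the benchmark conditions. Emitters are placed
uniformly with a 3·σ_PSF edge margin; overlaps are allowed and left to the
isolation filter. Frame size defaults to 256 px with a mean of 40 emitters
per frame (the benchmark's 200,000 emitters in ~5,000 frames at desk scale);
the seed fully determines the output.

What the simulator does **not** model: blinking kinetics and repeated
localization of one fluorophore, non-Gaussian (Airy/vectorial) PSFs, defocus,
drift, sCMOS pixel-dependent noise, read noise, EM-gain stochasticity.
Passing benchmarks on these data therefore demonstrates the correctness of
the identification/localization logic under the stated noise model, not
performance on every real-microscope artifact.

## Measurement conventions used in validation

- **Mean signal photons per emitter** is estimated by aperture photometry:
  sum of background-subtracted photoelectrons over a 3σ disk around each
  isolated true emitter (neighbours > 6σ away), divided by the enclosed-mass
  fraction `1 − e^{−4.5} ≈ 0.9889` of a Gaussian inside 3σ. Without the
  correction the raw disk sum underestimates the photon budget by ~1.1% by
  construction.
- **Background level** is the mean converted photoelectron value outside 3σ
  emitter disks; PSF tails beyond 3σ contribute < 0.01 e⁻/px at benchmark
  density.
- **Gaussian-background peak** is recovered by least-squares fitting
  `peak·exp(−r²/2s²)` (centred; peak and s free) to the emitter-masked
  average of 200 frames minus the uniform level.
- **Matching** for Jaccard/Precision/Recall/RMSD is greedy nearest-pair
  within-frame with a 128 nm default tolerance (2× pixel size). The greedy
  rule equals the optimal assignment whenever points are separated by more
  than twice the tolerance; the tolerance is always reported with the scores
  and results at different tolerances are never comparable. The external
  challenge tool this protocol mirrors does not publish its radius, so these
  defaults are documented rather than claimed identical.

## Problem sizes

Validation runs at desk scale: the end-to-end floor uses 500 frames of
256 px with ~40 emitters/frame (≈20,000 emitters); parameter recovery uses
2,000 Monte-Carlo spots; oracle equivalence uses 1,000 random 32×32 cases;
calibration measurements use ≥2,000 emitters (signal), 100 frames
(background) and 200 frames (Gaussian background). Full-scale runs (5,000
frames) are a configuration change, not a code change.

## Known limitations

- Scores are computed on the smoothed frame but normalised by the raw shot
  noise `F·√N_bg`, following the stated processing order; smoothing lowers
  both signal amplitude and realised noise, so `Q` is a conservative,
  slightly compressed detectability scale — at low SNR true emitters sit
  near Q ≈ 1.5–2, which is why the threshold must be chosen per regime.
- Unweighted least squares is used rather than maximum likelihood; at very
  low photon counts MLE would be more efficient.
- Overlapping emitters are discarded, not deconvolved; densities far above
  ~40 emitters per 256² frame will lose recall through the isolation filter.
- The evaluation matches greedily; in pathological clusters the optimal
  assignment could differ (bounded by the tolerance in any case).
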