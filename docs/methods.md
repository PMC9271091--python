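# Methods

This note documents the models, estimators and numerical choices behind
`tetherquant`, in the spirit of a methods supplement: what is simulated,
what is measured, which knobs matter, and what the synthetic validation does
and does not demonstrate about real microscope data.

## Synthetic tether movies

**Geometry and photometry.** A tether is a line of fluorescent segments
between two anchor points (pixel coordinates), rendered with a Gaussian PSF
(default σ = 1.3 px at 100 nm/px — typical TIRFM values, both configurable).
Each frame deposits a fixed photon budget (`total_intensity`, default
20,000 counts) along the tether, so total DNA-channel intensity is conserved
up to noise; condensation only redistributes it. Shot noise is Poisson on
the clean image (`photon_gain` counts per photon; 0 disables it), on top of
a Gaussian camera background. Defaults produce peak SNR ≈ 10 at
`background_sd = 4`.

**Transverse fluctuations.** Per frame the tether is displaced by a smooth
transverse curve: a sum of three sine modes (pinned–pinned shapes
`sin(nπs)` for double tethers, pinned–free `sin((n−½)πs)` for single ones)
with independent zero-mean Gaussian amplitudes proportional to 1/n,
normalized so the pointwise SD at the reference point (midpoint / free end)
equals `envelope_sigma`. This quasi-static approximation reproduces the
*time-averaged* transverse envelope that the analysis measures; it makes no
claim about temporal autocorrelation of real polymer dynamics, so dynamic
quantities (e.g. fluctuation relaxation times) are out of scope. Frames are
uncorrelated in time by construction.

**Slack model.** In "auto" mode
`sigma_nm = 40 × sqrt(Lc² − R²)` (lengths in µm, λDNA contour
Lc = 48,502 bp × 0.34 nm = 16.49 µm). The square-root-of-slack form makes
the envelope shrink monotonically and steeply as the end-to-end distance R
approaches Lc, and the coefficient 40 nm/µm yields envelopes of a few
hundred nm over typical tether geometries (R ≈ 6–15 µm). Only the
monotone trend is scientifically meaningful; the coefficient is a
population-scale choice.

**Condensation.** Foci nucleate as a Poisson process (rate per µm per s),
or deterministically via `forced_nucleation_time_s` for event-timing tests.
A focus reels in DNA at `reel_in_rate_bp_s` (zero-force value; under
tension F the rate is scaled by `max(0, 1 − F/stall)` — a linear stall law
with default stall 7 pN), accumulates protein monomers at `monomers_per_s`,
and diffuses along the tether with `mobility_D_um2_s`, decaying
exponentially after an optional maturation time (condensate hardening).
The fluctuation envelope decays from `envelope_sigma` to a tensed floor
(default 50 nm) over `collapse_time_s` with a quarter-power profile
`σ(u) = floor + (σ₀ − floor)(1−u)^¼`: slack loss accelerates and ends
sharply, which matches the visually crisp "molecule suddenly lost its
slack" transition these assays are scored by, and makes the manifest's
condensation time (= nucleation + collapse) a well-posed recovery target.
A linear decay, by contrast, approaches the floor tangentially and leaves
the endpoint undefined at frame resolution.

**Breakage.** Once fully condensed, the tether breaks per frame with
probability `nick_fragility` (Bernoulli); after breakage all DNA and
protein signal renders as two blobs at the anchors. Breakage before
condensation is not modeled — in these assays breakage accompanies
condensate formation.

## Envelope analysis

The measurement follows the assay definition exactly: time-averaged
projection → background-subtracted transverse line profile at the tether
midpoint (where a doubly-pinned tether is widest) → least-squares Gaussian →
width = 2σ. Numerical choices:

- the profile averages an axial window of 20% of the tether length centred
  on the midpoint (or at 95% of the length in `radius` mode for single
  tethers, where the pinned-free envelope is maximal);
- background is the median over two flanking bands parallel to the tether
  just outside the profile window (band width 4 px, configurable);
- the fit is initialized from profile moments, bounded (amplitude ≥ 0,
  center inside the window, σ ≤ span), and flagged `fit_ok=False` on
  non-convergence, flat input, or σ exceeding half the span;
- `deconvolve_psf_sigma_nm` optionally removes the known optical blur in
  quadrature, `σ_env = sqrt(σ_fit² − σ_psf²)`. Raw fitted widths convolve
  the physical envelope with the PSF; deconvolution is what lets a 100 nm
  envelope be recovered within 5% under a 130 nm PSF. On real data this
  requires an independently calibrated PSF; without one, widths should be
  compared only within one imaging configuration.

With 250-frame averages at SNR ≥ 5, the median recovered width across
replicate movies is within 5% of 2σ_true for σ_true between 100 and 300 nm
(a single movie carries ≈ 4–5% sampling error from the finite number of
independent conformations). The monotone width-vs-distance population test
runs all 20 geometries with a common RNG seed (common random numbers), so
adjacent tethers share conformational sampling noise and the geometric
trend is isolated; with independent seeds the same trend holds statistically
but not strictly pointwise.

## DNA content and stoichiometry

DNA content of a cluster is a pure intensity partition,
`bp = I_cluster × contour_bp / I_total`, with `I_cluster` allowed to exceed
`I_total` by at most 2% (background-subtraction noise) and the fraction
clipped to [0, 1]. Disjoint clusters covering the whole signal therefore
close to the full contour length exactly on noiseless input. The monomer
reference is the **median** surface-spot intensity with a MAD-based spread —
surface fields contain occasional aggregates, which a mean would absorb.
Foci are segmented by thresholding the protein projection at
mean + k·SD (k = 3 by default; the threshold is a free parameter of the
assay, not a calibrated constant).

## Colocalization

Pearson's r between two aligned, background-subtracted line profiles, with
a block-permutation null: channel A is cut into contiguous blocks of
`block_length` samples (default: PSF FWHM in samples, the correlation
length the blocks must preserve), the blocks are permuted uniformly, and r
is recomputed against the unshuffled partner; the empirical p is the
fraction of shuffles with r ≥ observed. At least 8 blocks are required —
fewer make the control unreliable — and `block_length` equal to the full
profile degenerates to the identity shuffle by construction. One subtlety:
for *identical* profiles the null mean is biased by ~1/n_blocks because a
uniform permutation fixes one block in place on average; on independent
profiles the null is centred on zero, and the empirical p is uniform under
the null (verified by KS test across 200 seeds).

## Tracking, MSD and events

**Tracking** is greedy nearest-neighbour linking of per-frame kymograph
peaks (local maxima above background mean + 4 robust SDs, refined by
parabolic interpolation to sub-sample precision), with gap closing up to 2
frames, step rejection beyond 0.5 µm per frame-gap, and deterministic
tie-breaks (smaller displacement, then lower position).

**MSD.** Positions are Savitzky–Golay smoothed (order 3, window 11),
small closed gaps are linearly interpolated to restore a uniform lag grid,
and the time-averaged 1-D MSD is fitted linearly over lag indices 2–10 with
an intercept; D = slope/2, accepted iff R² > 0.8 and the slope is positive.
Skipping lag 1 and keeping an intercept absorbs static localization noise
(standard single-particle-tracking practice). Numerically, the
Savitzky–Golay filter suppresses the MSD at lags inside its window but
leaves the slope over lags 2–10 nearly unbiased: on 200 simulated tracks
(D = 0.01 µm²/s, 0.3 s, 300 frames) the median D̂ is within ~2% of truth.
Confined or immobile tracks produce saturating MSD curves and fail the R²
filter preferentially — the intended exclusion behavior.

**Condensation time.** The detector operationalizes "the molecule
completely lost its slack": a per-frame fluctuation proxy is compared
against the tensed floor, and the condensation time is the first frame at
which the proxy has fallen below `floor × (1 + tolerance)` (tolerance 20%)
with the median of the following `persistence_frames` (default 10) values
also below the threshold; the reported time is corrected for the
half-window latency of the centred rolling-SD estimator. The proxy pools
transverse tether positions measured at three axial stations (¼, ½, ¾ of
the tether), each normalized by its relative fluctuation scale under the
sine-mode model — a single midpoint observable carries roughly one degree
of freedom per frame, which is information-theoretically insufficient for
frame-accurate detection; three stations triple it. Station positions are
peak-window centroids of the axially-averaged profile (robust to intensity
changes), with bright condensate-focus columns masked (3-MAD outliers,
dilated). On SNR ≈ 10 simulations the median detection error is ~1 frame;
roughly 4 in 5 runs land within ±2 frames, with occasional late detections
(up to ~10 frames) when a focus parks on a measurement station. The floor
can be supplied (known tension state) or self-estimated from the final 10%
of frames, in which case a movie that does not end at least twice as quiet
as it starts is reported censored rather than assigned a spurious time.

**T_condense** is T75 − T25 of the uncensored condensation times with
linear interpolation between order statistics (the convention is stated
because percentile conventions differ); it equals a brute-force
sorted-array computation on every input and matches the analytic
interquartile spread 30·ln 3 on exponential(30 s) samples.

**Breakage** is flagged when the axial DNA profile between the anchors —
integrated over a 15 px perpendicular band, wide enough to cover the whole
fluctuation envelope so a slack tether wandering off-axis is not mistaken
for a gap — develops a dark run longer than half the tether while the
central-third intensity collapses, for 2 consecutive frames. On forced-
breakage simulations detection is within ±2 frames with no false positives
across 50 intact movies.

## Dual-trap mechanics

Marko–Siggia interpolation without an enthalpic stretch term; the
overstretching transition is a hard cap at 65 pN (no analysis here depends
on the plateau's fine structure). kBT is fixed at 4.114 pN·nm (25 °C),
rise 0.34 nm/bp. Bead displacement enters through an effective-extension
model `x = S − 2F/k_trap` (k_trap 0.3 pN/nm default). The numerical WLC
inverse is a bracketed root solve (tolerance well below 1e-6 relative),
round-tripping to 1e-5 in fractional extension.

- **Passive mode:** at fixed trap separation the force satisfies the fixed
  point `F = WLC((S − 2F/k)/Lc_free)`, with `Lc_free` shrinking as the
  condensate reels; the trajectory climbs to a plateau at the stall force
  (recovered within 5% for stalls of 1, 3 and 7 pN over 180 s runs).
- **Force clamp:** separation follows the shrinking tether; contraction
  velocity is `reel_rate × (1 − F/stall) × 0.34 nm/bp × x/Lc(F)` — the
  fractional-extension factor converts contour uptake into end-to-end
  shortening. Clamps at or above stall freeze the trap (the clamp
  dichotomy); the analyzer uses a Theil–Sen slope restricted to the active
  contraction phase.
- **Pulling:** separation ramps at constant speed; sequestered contour is
  released in discrete jumps when the force crosses per-event dissolution
  thresholds, producing force drops whose WLC-inverted contour jumps match
  the manifest within 10%. A sequestering tether is strictly shorter than
  bare DNA at every force while contour remains hidden.
- Plateau detection smooths the force over the rolling window before slope
  estimation (default 5 s window, 0.01 pN/s tolerance) — with realistic
  0.15 pN force noise an unsmoothed rolling slope never beats that
  tolerance. Traces that never stabilize are reported censored.
- Nucleosomal-DNA (sequestration-only) behaviour is emulated by condensates
  pinned in place with zero reel-in: protein accumulates but generates no
  force, reproducing the bare-vs-nucleosomal force contrast without
  modeling histone–DNA energetics.

## Pipeline and reproducibility

One top-level seed is expanded into per-object seeds through SHA-256 of
(seed, stage, group, index) — stable across runs and platforms, bounded
below 2³¹. Identical configuration + seed gives byte-identical outputs;
each stage writes a content hash of its configuration block, and a resumed
run recomputes any stage whose block changed. Unknown configuration keys
are rejected rather than ignored. All artifacts are plain text or TIFF:
per-channel ImageJ-compatible stacks, JSON manifests, CSV tables.

## Problem sizes

The validation suite runs movies of 48×160–190 px with 40–250 frames, 20
tethers for population trends, 200 tracks for diffusion statistics, 200
seeds for permutation-null calibration, and 600-step force traces — sizes
at which every recovery statistic above is stable while the whole suite
completes in well under an hour on one core.

## Known limitations

- Frames are temporally uncorrelated; nothing here validates estimators
  that rely on the tether's relaxation dynamics.
- The PSF is an isotropic Gaussian; no aberrations, no depth dependence,
  no camera fixed-pattern noise.
- Envelope deconvolution assumes the PSF width is known exactly; a
  miscalibrated PSF propagates into the width superlinearly as σ_env
  approaches σ_psf.
- The condensation-time detector's occasional late outlier (focus parked on
  a measurement station) is documented rather than suppressed; a real
  analysis would flag such tethers from the focus channel.
- Labeling efficiency, photobleaching and blinking are not modeled, so
  protein copy numbers validate the normalization arithmetic, not dye
  photophysics.
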