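# Methods

This note documents the models behind meltkit, the defaults that matter,
what the synthetic data do and do not emulate, and the numerical choices a
maintainer would want spelled out. Every number quoted here is computed by
the test suite or by `scripts/acceptance.py`; none is asserted from memory.

## 1. The localization index

For the pixel sample x₁…xₙ of one segmented cell in one frame and channel,

    index = (mean of the k largest values − mean) / sd,
    k = max(1, ⌈f·n⌉),  f = 0.01 by default,

with the sample (n−1) standard deviation. The top fraction f = 1% reflects
the empirical footprint of a clustered kinetochore focus relative to a
whole yeast cell. Two properties pin the definition down:

* **Affine invariance.** index(a·x + b) = index(x) for a > 0, exactly (to
  floating tolerance); the statistic is insensitive to gain and offset.
* **One-hot closed form.** For k = 1 and a single bright pixel among n,
  index = (1 − 1/n)·√n regardless of the bright value — 9.9 at n = 100.
  This is the finite-n ceiling of the statistic for k = 1.

Choices the definition leaves open, fixed here: ceiling-with-floor-one for
k (guarantees a nonempty top set), (n−1) standard deviation (the closed
forms above are stated under it), and mean/sd computed over the cell's own
pixels only. Samples below `min_pixels` (default 50) or with zero variance
are recorded as gaps, never interpolated.

### Null calibration

Under "perfect delocalization" the pixel sample is approximately i.i.d.
Gaussian and the index concentrates, for large n, at the standardized
upper-tail conditional mean φ(z₁₋f)/f = 2.665 at f = 0.01. The null
depends on n (at n = 100 the top set is a single order statistic and the
Monte-Carlo mean is ≈ 2.51; the null sd shrinks as n grows), so
`calibrate_null` estimates mean, sd and quantiles per pixel count by
seeded Monte Carlo, including a dense upper-tail grid (to p = 0.99995)
interpolated linearly in Gaussian z-space for thresholds at arbitrary
levels.

Real camera data deviate from the ideal Gaussian null in a known way:
shot noise at mean count λ has skewness 1/√λ (≈ 0.045 at the default
λ ≈ 500), which shifts the index null upward by a few hundredths — small,
but material for tail thresholds. `calibrate_null_camera` therefore
calibrates the same statistic on scaled-Poisson + read-noise samples at
the observed in-cell mean count; the pipeline classifies against this
physically matched null. The widely used empirical delocalization baseline
of ≈ 3.7 for wide-field yeast movies is *not* reproduced by either ideal
null; it is retained as `EMPIRICAL_BASELINE` for use as an optional fixed
threshold but is never treated as calibrated ground truth.

### Per-cycle localization calls

A cell cycle is the half-open interval [bud_i, bud_{i+1}) between
consecutive budding events (half-open avoids double-counting the shared
frame). A cycle is called **localized** when its index *maximum* strictly
exceeds the null threshold. Because the maximum runs over ~30 per-frame
indices that are independent under the null, comparing it against a raw
per-frame 0.99 quantile would mislabel 1 − 0.99³⁰ ≈ 26% of purely
delocalized cycles. `classify_cycle` therefore uses the family-wise
threshold: the null quantile at level q^(1/n_frames), making q (default
0.99) the probability that a null cycle is correctly left uncalled. The
raw per-frame rule remains available (`per_cycle=False`).

### Co-localization timing

`coloc_lag` reports the lag maximizing the Pearson correlation of two
index series (pairwise-complete over gaps, minimum 10 overlapping frames).
The series are periodic with the cell-cycle period, so a search window of
a full period would alias lag 0 with ±period; the pipeline uses
max_lag = 10 frames (a third of the default period).

## 2. Synthetic microscopy

The generator emulates what the index analysis assumes, not optics:
elliptical cells (aspect ratio 1.0–1.4, geometric-mean radius 2.55–2.85 µm
at 0.1 µm/pixel, i.e. ~2000–2550 pixels per cell) with uniform diffuse
fluorescence (background 200, diffuse 300 counts), centroid jitter
(σ = 0.3 px/frame), seeded budding every 30 frames, and a Gaussian focus
(amplitude 800 counts, σ = 1.5 px; total flux A·2πσ², conserved to <2%
on the pixel grid) present during the cycle fraction [0.05, 0.40) after
each budding event. Noise is Poisson photons scaled by the camera gain
plus Gaussian read noise (σ = 3), clipped 16-bit. One master seed drives
geometry, focus jitter and noise through separate substreams;
identical (config, seed) reproduces stacks bit for bit.

Buds appear with 10% of the mother's area at a 3-px "neck" gap (the bud
circle is positioned by bisection against the mother's sampled boundary,
so the clearance is exact), grow linearly to 40% over one period, move
rigidly with the mother, and are removed at the mother's next budding
event — the daughter "leaves the field". Frame time is abstract: the
period is 30 frames because no acquisition interval is canonical.

Deliberately absent: point-spread blur, photobleaching, z-structure,
cell-to-cell intensity variability, segmentation-resistant crowding, and
real bud-neck morphology. Passing tests therefore demonstrate the
correctness and calibration of the *statistics* under the stated noise
model, not robustness to every imaging artifact.

Presets: `wildtype` (both channels carry the focus — reader and
kinetochore marker co-localize) and `mutant` (reader channel diffuse,
A = 0; marker unchanged).

## 3. Segmentation and tracking

Segmentation is deliberately plain and fully specified: Gaussian smoothing
(σ = 1 px) → Otsu threshold (256 bins) → hole filling → removal of regions
< 200 px → 4-connected labeling. The threshold comes from the image, so
any positive affine intensity map yields identical regions. A frame whose
threshold would put more than 35% of pixels in the foreground is treated
as containing no cells (a pure-noise frame has no bimodal histogram and
would otherwise shatter into spurious regions); constant frames likewise
return an empty mask.

Tracking is greedy nearest-centroid matching between consecutive frames
within `max_displacement` (default 10 px), ties broken by smaller area
difference then lower label; unmatched regions start new tracks. Stricter
matching can only split tracks, never merge them. A budding event is a new
track whose first region is < 0.3× an adjacent established cell's area,
with boundary distance ≤ 3 px (computed as min pixel-center distance − 1,
so regions separated by the generator's 3-px neck qualify). On default
wild-type scenes this recovers ≥ 90% of true budding events within ±1
frame and mean per-cell IoU ≥ 0.8 (measured ≈ 0.999); the residual misses
are buds whose birth area sits just under the min-area floor for a frame.

## 4. Single-site ITC model

Concentrations after injection i, with cumulative injected volume dVᵢ and
active cell volume V₀ (200 µl unless configured otherwise), follow the
perfusion-cell convention:

    M_t = M₀(1 − dVᵢ/2V₀)/(1 + dVᵢ/2V₀),
    X_t = X₀(dVᵢ/V₀)/(1 + dVᵢ/2V₀).

The bound-site fraction θ is the [0, 1] root of
S·θ² − (X_t + S + K_D)·θ + X_t = 0 with S = n·M_t (clamped against
rounding; verified to 1e−10 against a brentq root-finder oracle), the
cumulative heat is Qᵢ = n·θᵢ·M_t·ΔH·V₀ (µcal with mol/l, µl, cal/mol),
and the observed heat of injection i is

    dQᵢ = Qᵢ − Qᵢ₋₁ + (vᵢ/V₀)(Qᵢ + Qᵢ₋₁)/2 + q_dil.

Subtracting the dilution constant and the displaced-volume terms, the dQᵢ
telescope exactly to Q_N.

Fitting minimizes squared residuals over (n, log₁₀K, ΔH, q_dil) —
log-K for conditioning — via Levenberg–Marquardt (lmfit), standard errors
from the local curvature with the delta method for K_D. Initialization:
n from the molar ratio at the steepest change of the heat curve, ΔH from
first-quartile heats above the late-injection baseline, K_D from a neutral
c = 10. A fit whose saturation amplitude |n·ΔH·M₀·V₀| is below 3× the
residual sd of a constant-only fit is flagged `no_binding` (this is what
an unphosphorylated-peptide titration produces). Noiseless round trips
recover (n, K_D, ΔH) to 1e−6 relative.

Only the dissociation constants of the reference system are published;
stoichiometry, enthalpy, noise and baseline are not. Recovery experiments
therefore fix n = 1, ΔH = −12 kcal/mol, q_dil = −0.1 µcal, and noise
sd = 1% of the largest model injection heat — arbitrary but fixed and
stated. At the standard protocol the Wiseman parameter c = n·M₀/K_D spans
6 (K_D = 5 µM) to 150 (200 nM), inside the classically fittable range;
recovery degrades as c leaves roughly [1, 1000] (shallow curves at low c,
step-like curves at high c), which is documented rather than asserted.

## 5. Motif scanning

The strict consensus M-[E/D]-[L/I/V/M]-T and the relaxed variant
[M/I/L/V]-[E/D]-[L/I/V/M]-T are both provided because annotated repeats
exist whose first residue is not methionine (the fourth repeat of the
reference receptor begins with isoleucine and matches only the relaxed
class). Neither variant is privileged. Matching is exhaustive over all
4-mer windows, overlapping hits allowed, 1-based protein coordinates,
phospho-site = start + 3; non-standard characters are rejected with the
offending position named. The scanner is tested for exact agreement with
an independent regex-lookahead oracle on random sequences.

## 6. Problem sizes and determinism

Default study conditions: scenes of 6 cells × 95 frames × 2 channels at
520×520 px (≈ 11 complete cycles per scene); null calibration at 20,000
Monte-Carlo replicates per pixel-count grid point; ITC recovery at 25
seeded replicates per affinity. End-to-end discrimination is evaluated on
two seeds per scenario. All randomness flows from explicit integer seeds
through `numpy` `SeedSequence` substreams; reports and output files are
byte-identical across reruns of the same configuration.

## 7. Known limitations

* The segmenter is a defined stand-in, not a reimplementation of any
  published cell-segmentation tool; equivalence with the software used for
  the original movies cannot be tested (that program is unpublished).
* The ≈ 3.7 empirical baseline remains unexplained by the ideal models
  here; candidate causes (whole-image statistics, an effective top
  fraction below 1%, camera skew at lower counts) are discussed in the
  module docstrings but not adjudicated.
* The ITC module covers a single site class only — no competitive,
  multi-site, or global fits, and no raw power-trace integration.
* Mother–daughter lineage beyond bud assignment is out of scope, as are
  metaphase/anaphase staging and spindle-position readouts.
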