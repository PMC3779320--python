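# meltkit

Quantitative tools around the recruitment of the Bub1–Bub3 spindle-assembly
checkpoint complex to phosphorylated MELT repeats of the kinetochore
scaffold Spc105/Knl1 in budding yeast. The package bundles three analyses
that are usually done with ad-hoc scripts:

1. **Kinetochore localization index for time-lapse fluorescence movies.**
   For the pixel intensities of one segmented cell in one frame,

   *index* = (mean of the brightest ~1% of pixels − mean) / sd.

   A delocalized fluorophore gives roughly Gaussian pixel intensities, so
   the index fluctuates around the standardized upper-tail conditional mean
   φ(z₀.₉₉)/0.01 ≈ 2.67 (large cells); a kinetochore focus skews the
   distribution right and drives the index up. The package calibrates the
   null by Monte Carlo per pixel count (ideal-Gaussian and camera-noise
   variants), segments and tracks synthetic yeast movies, detects budding
   events, computes per-cycle index maxima/minima, calls each cell cycle
   localized or delocalized, and times two-channel co-localization by
   cross-correlation. A seeded synthetic-scene generator with full ground
   truth (masks, bud events, focus positions) backs every step.

2. **Single-site ITC binding analysis.** The 1:1 isotherm with
   perfusion-cell dilution bookkeeping, a thermogram simulator at the
   standard protocol (30 µM cell species, 400 µM syringe, 35 × 2 µl
   injections, 25 °C), and a least-squares fitter over (n, log₁₀K, ΔH,
   q_dil) in the statsmodels mold: `SingleSiteBindingModel(...).fit()`
   returns a results object with estimates, standard errors, and a
   `summary()` table. The reported affinities of the system (wild-type
   complex 200 nM and 1.3 µM for the second and fourth phospho-repeat;
   R217A 2.7 µM; R239A 5 µM; Bub3 alone 2 µM) ship as
   `REFERENCE_AFFINITIES` and drive parameter-recovery experiments.

3. **MELT-consensus scanning.** M-[E/D]-[L/I/V/M]-T (strict) and a relaxed
   first class [M/I/L/V], over plain strings or FASTA records, reporting
   1-based coordinates and the phospho-acceptor threonine.

## Worked example

```python
from meltkit import (BindingParams, default_protocol, fit_single_site,
                     fold_change, simulate_thermogram)

protocol = default_protocol()          # 30 µM cell, 400 µM syringe, 35 x 2 µl
truth = BindingParams(kd=200e-9)       # wild-type reader affinity
tg = simulate_thermogram(protocol, truth, noise_sd=0.1, seed=0)
fit = fit_single_site(tg, protocol)
print(fit.summary())
```

```
Single-site binding model (isothermal titration calorimetry)
==============================================================
Observations (injections used): 35
Converged: True    No binding: False
Sum of squared residuals: 0.50133 ucal^2
--------------------------------------------------------------
parameter             estimate         std err
n (sites)                1.005         0.00434
K_D (M)              1.986e-07        1.95e-08
dH (cal/mol)          -11922.7            89.6
q_dil (ucal)            -0.116           0.026
--------------------------------------------------------------
Wiseman c = 151.8
```

The fitted K_D of 199 nM recovers the generating 200 nM within its ~20 nM
standard error; n ≈ 1 confirms the single-site stoichiometry, and the
Wiseman parameter c = n·M₀/K_D ≈ 150 indicates a well-conditioned titration.
Comparing against a simulated phosphate-pocket mutant:

```python
mut = fit_single_site(simulate_thermogram(protocol, BindingParams(kd=5e-6),
                                          noise_sd=0.1, seed=0), protocol)
print(f"fold change: {fold_change(fit, mut):.1f}x")   # fold change: 26.6x
```

On the imaging side, one command runs scene synthesis → segmentation →
tracking → budding detection → localization index → per-cycle calls →
co-localization and prints a JSON report:

```bash
meltkit report --scenario wildtype --seed 1 --outdir out/wt
meltkit report --scenario mutant   --seed 1
```

In the wild-type scenario every cell cycle is called localized in both
channels and the two channels co-localize at zero lag; in the mutant
scenario (reader channel diffuse) no cycle is called localized while the
kinetochore-marker channel still is. `meltkit melt-scan --fasta seqs.fasta`
lists consensus matches, and `meltkit itc-suite --seed 1` tabulates the
recovery of all five reference affinities plus the no-binding
(unphosphorylated peptide) control.

## Layout

```
src/meltkit/
  scenes.py        synthetic two-channel yeast time-lapse + ground truth
  segmentation.py  Otsu-based per-frame segmentation
  tracking.py      greedy nearest-centroid tracking, budding detection
  locindex.py      localization index + Monte-Carlo null calibration
  cycles.py        per-cycle statistics, peaks, calls, co-localization
  itc.py           single-site ITC model / simulator / fitter
  motifs.py        MELT-consensus scanner
  pipeline.py      end-to-end orchestration + ITC recovery suite
  cli.py           subcommands (simulate, segment, track, index, cycles,
                   coloc, itc-sim, itc-fit, itc-suite, melt-scan, report)
docs/methods.md    model assumptions, parameter choices, limitations
```
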