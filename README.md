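# torsionprofiles

Torsion-motif torsional-angle distributions (tmTADs): extraction,
parametrization, and statistical comparison across environments.

The torsional preferences of acyclic single bonds drive the conformational
behavior of drug-like molecules, and they are *environment-specific*: a
motif's angle distribution extracted from crystal structures can differ
sharply from the same motif's distribution in vacuum, water, or hexane
ensembles. This package implements the machinery needed to quantify that:

* an **ordered SMARTS torsion hierarchy** (atom maps 1–4, central map-2/3
  bond constrained single and non-ring) with validation, class metadata
  (C–C, C–O, C–S, N–C, S–N, S–S, plus a general G–G fallback), and
  population-based filtering;
* **profile extraction** with first-match-per-bond semantics (each bond is
  claimed by the highest-priority matching pattern, with *all* atom
  mappings recorded), relative-energy pruning of conformer ensembles
  (default 25 kJ/mol), and **enantiomer mirror augmentation** — a SMARTS
  motif carries no stereochemistry, so an observed torsion θ is recorded
  together with 360° − θ (10° contributes {10°, 350°});
* **wrapped mirrored Gaussian fitting** of accumulated profiles. With
  angles *x* in radians, each detected peak *b*ᵢ ∈ [0, π] contributes

  P(x) = Σᵢ aᵢ ( exp[−(((x − bᵢ + π) mod 2π − π)/cᵢ)²]
               + exp[−((((2π − x) − bᵢ + π) mod 2π − π)/cᵢ)²] ),

  i.e. a 2π-periodic Gaussian at *b*ᵢ plus its mirror at 2π − *b*ᵢ, so the
  model is symmetric and has multiplicity ≤ 6 (≤ 3 peaks in [0, π]). A
  smooth periodic-image form that agrees pointwise is provided for use in
  gradient-based conformer generation. Amplitudes and widths are fitted by
  bounded least squares with peak locations held fixed; a peak at 0 or π,
  where the mirror terms coincide, has its amplitude halved in the model;
* **normalized statistical distances** between angle samples: the circular
  second-order Wasserstein distance W₂ (quadratic-cost optimal transport
  with ground distance d(x,y) = min(|x−y|, 360°−|x−y|), normalized by the
  180° antipodal maximum) and ω, the square root of the two-sample
  Cramér–von Mises criterion on 10,000-point bootstrap resamples,
  normalized by the criterion's fully-separated maximum. Profiles are
  called significantly different when W₂ > 0.03 or ω > 0.07.

## Worked example

Fit a sampled two-peak profile (`examples/03_fit_wrapped_gaussians.py`):

```python
import numpy as np, torsionprofiles as tp

true = tp.FitParameters([(1.0, np.radians(60.0), 0.35), (0.6, np.radians(160.0), 0.30)])
sample = tp.sample_angles(true, 50_000, seed=11)
hist = tp.accumulate(tp.augment_mirror(sample.angles), n_bins=360)
fit = tp.fit_histogram(hist, sigma_deg=5.0, max_peaks=3)
```

prints

```
rms residual: 0.0059
peak at   59.5 deg (true  60.0): a = 0.502 (true 0.532), c = 21.27 deg (true 20.05)
peak at  160.5 deg (true 160.0): a = 0.296 (true 0.319), c = 18.32 deg (true 17.19)
```

Both peak locations come back within the 1° histogram grid and amplitudes
and widths within ~10%; the small broadening is the expected quadrature
effect of the 5° smoothing filter. Comparing the four diagnostic scenario
pairs (`examples/04_compare_profiles.py`):

```
scenario                  W2   omega  significant?
same_distribution     0.0271  0.0128  no
peak_split            0.0929  0.0959  W2, omega
peak_broadening       0.0625  0.0482  W2
height_reversal       0.2653  0.1357  W2, omega
```

Two resamples of one distribution stay below both significance thresholds,
while real shape changes are flagged; W₂ is milder than ω on the nearby
peak split because the transported mass travels only a short distance.

The other examples cover library loading/matching
(`examples/01_library_and_matching.py`) and SDF extraction with energy
pruning (`examples/02_extract_histograms.py`). A thin CLI wraps the same
pipeline: `torsionprofiles extract | fit | compare | simulate`.

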