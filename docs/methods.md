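# Methods

## Problem and scope

A torsion motif is a four-atom dihedral environment defined by a SMARTS
pattern with atom maps 1–4 whose central (map-2/map-3) bond is a single,
non-ring bond. Accumulating the observed dihedral angles of every bond
matched by one motif across many molecules yields that motif's
torsional-angle distribution (tmTAD). This package covers the desk-side
part of the workflow: hierarchy representation and validation, matching
and angle extraction from conformer ensembles supplied as SDF (or built
synthetically), density parametrization, and statistical comparison.
Conformer *generation* and force-field/implicit-solvent minimization are
upstream of this package: ensembles arrive as coordinates plus potential
energies in kJ/mol.

## Hierarchy and matching

The library is an ordered list; order encodes priority. During extraction
each acyclic single bond is assigned to the first pattern (lowest rank)
whose central mapped bond matches it — later patterns never see that bond
— while *all* distinct atom mappings of the claiming pattern onto that
bond are recorded, so a symmetric motif contributes one angle per mapping
rather than an arbitrary representative. Validation requires exactly the
atom maps {1,2,3,4}, a central bond whose SMARTS query asserts order 1
positively and ring membership negatively (disjunctive bond expressions
such as the default single-or-aromatic bond are rejected as
under-constrained), and consistency between the declared hierarchy class
and the central atoms' elements where the SMARTS pins them down (the G–G
fallback class is exempt). SMARTS using the `N_lp` lone-pair extension are
rejected by name: they require a nonstandard parser and their published
adaptations are not reproducible here.

Curation of raw entries splits multi-component structures into one record
per connected component, completes hydrogens explicitly, and drops
components containing elements outside {H, C, N, O, F, Cl, Br, I, S, P}
or lacking a carbon–carbon bond.

Filtering drops patterns below a match-count threshold (default 50) and
whole classes (default the G–G fallback, whose distributions superpose
many underlying profiles); survivors keep their relative order, so
filtering is idempotent and commutes with first-match semantics.

## Angles, pruning, augmentation, binning

Dihedrals use the standard signed IUPAC convention mapped to [0°, 360°);
reversing the quadruple leaves the angle unchanged and mirroring the
coordinates maps θ to 360° − θ. Collinear triples raise an error. The
specific sign convention is immaterial downstream because of mirror
augmentation: since SMARTS carry no stereochemistry, a motif matches a
structure and its (isoenergetic) mirror image alike, so every observed θ
is recorded together with 360° − θ. Augmented histograms are therefore
exactly mirror-symmetric, bin-for-bin (k ↔ n−1−k), except for angles
falling exactly on a bin edge under the half-open binning convention
(edge angles belong to the bin on their right).

Computed ensembles are pruned at a relative potential energy cutoff,
default 25 kJ/mol above the ensemble minimum; the minimum-energy conformer
is always retained and pruned sets are nested in the cutoff. Crystal
ensembles hold the observed conformer(s) without energies and bypass
pruning. Conformers contribute independently; no per-molecule reweighting
or free-energy correction is applied.

Histograms default to 1° bins (n_bins = 360): fine enough to resolve
nearby peak positions, coarse enough that typical profiles populate bins
densely.

## Fitting

Pipeline per histogram: (1) symmetrize exactly — counts plus reversed
counts, removing residual finite-data asymmetry; (2) circular Gaussian
smoothing (wrap-around convolution, default σ = 5°) and normalization to
a unit-integral density on the bin-center grid in radians; (3) periodic
peak detection; (4) bounded least squares.

The model is a sum of one to three wrapped mirrored Gaussians: triplet
(aᵢ, bᵢ, cᵢ) places a 2π-periodic Gaussian of amplitude aᵢ and width cᵢ
at bᵢ ∈ [0, π] *and* at its mirror 2π − bᵢ. At most three peaks in [0, π]
means at most six density maxima over the circle. Two evaluators exist:
the wrapped (modulo / nearest-periodic-image) form, and a smooth form
summing the four periodic/mirror images at bᵢ, −bᵢ, 2π − bᵢ, 2π + bᵢ,
which is differentiable on (0, 2π) — the property needed if the fits are
used for energies and gradients in conformer generation. The two agree
pointwise to better than 1e−9 for widths c ≲ 0.6 rad (≈ 34°); the
residual discrepancy is the neglected images beyond ±2π, of size
exp(−(π/c)²), which is also the accuracy limit of *any* finite
sum-of-images form. Realistic torsion peak widths are well below this.

When a peak sits at b = 0 (equivalently 2π) or at b = π, the Gaussian and
its mirror coincide and would double the height; the model halves such a
triplet's amplitude (`overlap_scaled`), so a fitted `a` always reads as
the density's peak height.

Peak detection pads the grid circularly and runs SciPy's `find_peaks`
with plateau handling; plateau midpoints are used so a maximum straddling
the 0/2π seam (a two-bin plateau on the bin-center grid) resolves to
exactly 0. Peaks in (π, 2π) are mirror images and are folded back;
folded duplicates landing within one bin are merged. Detected locations
within half a bin of 0 or π snap to the boundary so overlap scaling
triggers exactly. If more than `max_peaks` (default 3) survive, the most
prominent are kept, ties broken toward lower angles. The prominence floor
defaults to 1% of the maximum density; both knobs are exposed because
there is no single canonical choice.

The fit minimizes squared residuals between the model and the smoothed
*density* (not raw counts — a documented choice; densities make residuals
comparable across sample sizes) over the full [0, 2π) grid, with b fixed
at the detected locations, a ∈ [0, ∞), c ∈ [10⁻³, π]. Initialization:
a from the density at the peak, c from the half-width at half-maximum
(HWHM = c·√ln2). Amplitudes pinned at zero trigger a spurious-peak
warning; optimizer failure raises with the residual trace.

Known bias: smoothing broadens peaks in quadrature (fitted c ≈
√(c² + 2σ_s²) with σ_s the filter width in radians), so with σ = 5° a
true width of 20° is recovered ≈ 6% high and the amplitude
correspondingly low. This sits inside the 10% round-trip tolerance; no
deconvolution is attempted.

## Statistical distances

**W₂.** For 1D distributions on the circle with quadratic cost and ground
distance d(x,y) = min(|x−y|, 360−|x−y|), optimal transport reduces to
minimizing, over a cut (rotation) parameter α, the L² distance between
the quantile functions extended periodically (one extra turn adds 360°).
The implementation evaluates the cost exactly on the common refinement of
both samples' (shifted) quantile breakpoints and minimizes over α — the
cost is convex piecewise-linear in α, so a coarse scan plus bounded
scalar minimization is reliable. No installed package provides the
second-order circular case, so this is implemented here and tested
against closed forms: two point masses a circular distance d apart give
exactly W₂ = d; the antipodal configuration gives the 180° maximum used
for normalization. An alternative linear-support normalization (maximum
360°) can be swapped by changing the single `W2_MAX_DEG` constant.

**ω.** The two-sample Cramér–von Mises criterion depends on sample sizes,
so both samples are bootstrap-resampled to a fixed size (default 10,000)
before evaluating SciPy's two-sample statistic on the linear support
[0, 360) — the empirical-CDF criterion is not circular, which is accepted
as part of the metric's definition here. ω = √(criterion / maximum),
clipped to [0, 1], where the maximum is obtained by brute force from the
fully separated two-point-mass configuration at the bootstrap size (it
equals n/4 for equal sizes n in the large-n limit; the cached brute-force
value is asserted against this). The square-root-of-normalized-criterion
convention is an assumption, documented as such. Each sample's resampling
RNG is derived from the global seed plus a hash of that sample's own
sorted content, which makes ω symmetric in its arguments and exactly zero
for identical inputs while remaining reproducible.

Significance uses strict inequalities: W₂ > 0.03, ω > 0.07; boundary
values are "not significant" (a documented convention — the thresholds
are empirical, so the boundary case is arbitrary either way).

Pairwise comparison across environments computes both metrics for every
unordered environment pair and every pattern with at least `min_samples`
(default 300) angles on both sides, returns per-pair empirical CDFs of
each metric over patterns, and ranks pairs by mean metric value as a
proxy for CDF dominance (a dominating CDF has the smaller mean; when
CDFs cross, the mean is a pragmatic summary).

## Synthetic fixtures

The generator draws angles from the normalized model density by inverse
CDF on a 4096-point grid — deterministic given the seed, with
piecewise-linear CDF error far below sampling noise (empirical KS
distance < 0.01 at n = 100,000). Four diagnostic scenario pairs probe the
metrics' sensitivities: same distribution (two independent draws from one
two-peak model), peak split (one peak vs. the same mass split 15° either
side), peak broadening (widths doubled), and height reversal (amplitudes
1.0/0.5 swapped). Scenario parameters and the default 2,000 angles per
side are fixture constants chosen to make each effect visible above
sampling noise; they are invented for this package. Toy molecules
(≤ 30 heavy atoms) are constructed so that each bundled published motif
matches exactly one central bond, plus negative controls (benzene has no
acyclic bond; butadiene's terminal CH₂ groups fail the CX3H0
requirement of the diene motif).

What the fixtures do *not* emulate: the chemical-space composition and
population biases of real structure databases, crystal packing, solvent
effects, or force-field bias. Passing tests demonstrate correctness of
the machinery — matching semantics, estimator math, normalizations — not
the field-scale conclusions one would draw from real ensembles.

## Problem sizes and defaults

Round-trip fitting tests use 50,000 sampled angles; metric property
checks use a few hundred angles per sample and 200 random pairs; scenario
comparisons use 2,000 angles per side with the full 10,000-point
bootstrap. Defaults throughout: energy cutoff 25 kJ/mol, 360 bins, σ = 5°,
≤ 3 peaks, 10,000 bootstrap points, thresholds 0.03 / 0.07, minimum 300
angles per compared profile. The whole suite runs in well under a minute
on one CPU.

## Known limitations

* Hierarchy-class assignment is input metadata with a consistency check,
  not derived from the SMARTS (not all patterns determine it).
* The peak-detection periodicity adjustment (circular padding + plateau
  midpoints) and the prominence floor are this package's documented
  choices; other reasonable variants would move detected peaks by at most
  the grid resolution.
* ω's bootstrap-then-linear-CDF construction ignores circular topology; a
  profile concentrated across the seam is handled by the mirror symmetry
  of real torsion profiles but a deliberately seam-straddling asymmetric
  sample would be penalized slightly differently than a rotated copy.
* The W₂ normalization maximum (180°) assumes the circular ground metric;
  swap `W2_MAX_DEG` for linear-support conventions.
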