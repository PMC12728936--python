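"""Wrapped mirrored Gaussian fitting of torsion profiles.

An accumulated torsion histogram is expected to be symmetric under
theta -> 2*pi - theta (mirror augmentation enforces this in the large-data
limit; residual asymmetry reflects limited data).  The fitting procedure

1. symmetrizes the histogram exactly (counts plus mirrored counts),
2. applies a circular 1D Gaussian filter and normalizes to a density,
3. detects up to three peaks of the periodic density in [0, pi]
   (the domain endpoints are eligible: symmetry makes them stationary),
4. fits amplitudes a_i and widths c_i of a sum of wrapped mirrored
   Gaussians, with peak locations b_i held fixed.

Each (a_i, b_i, c_i) triplet contributes a wrapped Gaussian at b_i *and*
its mirror at 2*pi - b_i, so at most three triplets give a density with at
most six maxima over the full circle (multiplicity <= 6).

Two evaluators are provided: the wrapped (modulo, nearest periodic image)
form, and a smooth sum-of-four-images form that is differentiable on
(0, 2*pi) and agrees with the wrapped form to better than 1e-9 for widths
c below ~0.6 rad (the neglected images beyond +-2*pi contribute
exp(-(pi/c)^2) at most).  When a peak sits at b=0 (equivalently 2*pi) or at
b=pi, the Gaussian and its mirror coincide; the amplitude of such a triplet
is halved inside the model (``overlap_scaled``) so that the fitted ``a``
still reads as the peak height of the density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize, signal

from .extraction import TorsionHistogram

TWO_PI = 2.0 * np.pi

#: b values closer than this (radians) to 0 or pi are treated as boundary
#: peaks whose mirror term coincides with the main term.
BOUNDARY_TOL = 1e-9


class FitError(RuntimeError):
    """Raised when the nonlinear least-squares fit fails to converge."""


@dataclass
class SmoothedProfile:
    """A smoothed, unit-integral density on a uniform grid over [0, 2*pi)."""

    grid: np.ndarray      # radians, bin centers
    density: np.ndarray   # non-negative, integrates to ~1

    @property
    def bin_width(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass(frozen=True)
class PeakSet:
    locations: tuple[float, ...]   # radians in [0, pi], ascending
    prominences: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.locations)


@dataclass
class FitParameters:
    """1-3 (a, b, c) wrapped-mirrored-Gaussian triplets.

    a: amplitude (>= 0), b: peak location in [0, pi] radians, c: width in
    radians (> 0).  ``overlap_scaled`` marks whether boundary-peak
    amplitudes are halved inside the model evaluation.
    """

    triplets: list[tuple[float, float, float]]
    overlap_scaled: bool = True
    residual: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not 1 <= len(self.triplets) <= 3:
            raise ValueError("1 to 3 triplets required")
        for a, b, c in self.triplets:
            if a < 0:
                raise ValueError("amplitudes must be non-negative")
            if c <= 0:
                raise ValueError("widths must be positive")
            if not -BOUNDARY_TOL <= b <= np.pi + BOUNDARY_TOL:
                raise ValueError("peak locations must lie in [0, pi]")


# -- symmetrize / smooth ------------------------------------------------------

def symmetrize(hist: TorsionHistogram) -> TorsionHistogram:
    """Mirror the histogram at pi: counts'[k] = counts[k] + counts[n-1-k].

    The result is exactly mirror-symmetric and has twice the total count.
    """
    counts = hist.counts + hist.counts[::-1]
    return TorsionHistogram(hist.pattern_id, hist.environment, counts, hist.augmented)


def smooth(hist: TorsionHistogram, sigma_deg: float = 5.0) -> SmoothedProfile:
    """Circular Gaussian filter, then normalization to a unit-integral density.

    ``sigma_deg`` is the filter standard deviation in degrees; wrap-around
    boundary conditions preserve total mass, so a uniform histogram maps to
    the uniform density 1/(2*pi).
    """
    if sigma_deg <= 0:
        raise ValueError("sigma_deg must be positive")
    n = hist.n_bins
    width_deg = 360.0 / n
    smoothed = ndimage.gaussian_filter1d(hist.counts.astype(float), sigma=sigma_deg / width_deg, mode="wrap")
    grid = (np.arange(n) + 0.5) * (TWO_PI / n)
    total = smoothed.sum() * (TWO_PI / n)
    density = smoothed / total if total > 0 else smoothed
    return SmoothedProfile(grid, density)


# -- peak detection -----------------------------------------------------------

def detect_peaks_periodic(
    profile: SmoothedProfile,
    max_peaks: int = 3,
    prominence_frac: float = 0.01,
) -> PeakSet:
    """Local maxima of the periodic density, restricted to [0, pi].

    The grid is padded circularly before running SciPy's ``find_peaks`` so
    that maxima straddling the 0/2*pi seam are seen; plateau midpoints are
    used so that the symmetric two-bin plateaus produced by a peak exactly
    at 0 or pi resolve to the boundary angle itself.  Peaks in (pi, 2*pi)
    are mirror images of peaks in (0, pi) and are folded back.  If more
    than ``max_peaks`` remain, the most prominent are kept, ties broken
    toward lower angles.  A flat profile yields an empty set.
    """
    y = np.asarray(profile.density, dtype=float)
    n = y.size
    if np.ptp(y) < 1e-15 * max(1.0, np.abs(y).max()):
        return PeakSet((), ())
    pad = n // 2
    ext = np.concatenate([y[-pad:], y, y[:pad]])
    prominence = prominence_frac * y.max()
    idx, props = signal.find_peaks(ext, prominence=prominence, plateau_size=(1, None))
    centers: list[tuple[float, float]] = []
    for i, p in enumerate(idx):
        mid = 0.5 * (props["left_edges"][i] + props["right_edges"][i])
        pos = (mid - pad) % n  # fractional circular bin index
        theta = ((pos + 0.5) * (TWO_PI / n)) % TWO_PI
        if pad <= p < pad + n:  # count each circular peak once
            centers.append((theta, float(props["prominences"][i])))
    bin_w = TWO_PI / n
    half_bin = 0.5 * bin_w
    folded: list[tuple[float, float]] = []
    for theta, prom in centers:
        if theta > np.pi:
            theta = TWO_PI - theta
        if theta < half_bin:
            theta = 0.0
        elif abs(theta - np.pi) < half_bin:
            theta = float(np.pi)
        folded.append((float(theta), prom))
    # merge mirror duplicates: a peak and its fold land within one bin
    folded.sort()
    peaks: list[tuple[float, float]] = []
    for theta, prom in folded:
        if peaks and theta - peaks[-1][0] <= bin_w * 1.01:
            t0, p0 = peaks[-1]
            peaks[-1] = (theta, prom) if prom > p0 else (t0, p0)
        else:
            peaks.append((theta, prom))
    if len(peaks) > max_peaks:
        peaks.sort(key=lambda t: (-t[1], t[0]))  # prominence desc, angle asc
        peaks = sorted(peaks[:max_peaks])
    return PeakSet(tuple(t for t, _ in peaks), tuple(v for _, v in peaks))


# -- model evaluation ---------------------------------------------------------

def _effective_amplitudes(params: FitParameters) -> list[tuple[float, float, float]]:
    out = []
    for a, b, c in params.triplets:
        if params.overlap_scaled and (b <= BOUNDARY_TOL or abs(b - np.pi) <= BOUNDARY_TOL):
            a = 0.5 * a
        out.append((a, b, c))
    return out


def evaluate_model_modulo(params: FitParameters, x: np.ndarray | float) -> np.ndarray:
    """Wrapped (modulo) form: each triplet contributes the nearest periodic
    image of a Gaussian at b and of its mirror at 2*pi - b."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for a, b, c in _effective_amplitudes(params):
        d1 = np.mod(x - b + np.pi, TWO_PI) - np.pi
        d2 = np.mod((TWO_PI - x) - b + np.pi, TWO_PI) - np.pi
        total = total + a * (np.exp(-((d1 / c) ** 2)) + np.exp(-((d2 / c) ** 2)))
    return total


def evaluate_model(params: FitParameters, x: np.ndarray | float) -> np.ndarray:
    """Smooth four-image form, differentiable on (0, 2*pi).

    Sums, per triplet, Gaussians at the periodic/mirror images b, -b,
    2*pi - b and 2*pi + b; manifestly satisfies P(x) = P(2*pi - x) and
    agrees pointwise with the modulo form up to images beyond +-2*pi.
    """
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for a, b, c in _effective_amplitudes(params):
        total = total + a * (
            np.exp(-(((x - b) / c) ** 2))
            + np.exp(-(((TWO_PI - x - b) / c) ** 2))
            + np.exp(-(((x + b) / c) ** 2))
            + np.exp(-(((TWO_PI - x + b) / c) ** 2))
        )
    return total


# -- fitting ------------------------------------------------------------------

def _initial_widths(profile: SmoothedProfile, peaks: PeakSet) -> list[float]:
    """Half-width-at-half-maximum seed for each peak, clipped to sane bounds."""
    y, grid = profile.density, profile.grid
    n = y.size
    widths = []
    for b in peaks.locations:
        i0 = int(round(b / TWO_PI * n - 0.5)) % n
        half = 0.5 * y[i0]
        w = profile.bin_width
        for step in range(1, n // 2):
            if y[(i0 + step) % n] < half or y[(i0 - step) % n] < half:
                w = step * profile.bin_width
                break
        # HWHM of exp(-(x/c)^2) is c*sqrt(ln 2)
        widths.append(float(np.clip(w / np.sqrt(np.log(2.0)), 5e-2, np.pi / 2)))
    return widths


def fit_wrapped_mirrored_gaussians(
    profile: SmoothedProfile,
    peaks: PeakSet,
    overlap_scaled: bool = True,
) -> FitParameters:
    """Fit a_i and c_i by least squares on the full [0, 2*pi) grid.

    Peak locations b_i stay fixed at the detected positions.  Amplitudes
    are bounded below by 0 and widths confined to [1e-3, pi]; the residual
    reported is the root-mean-square misfit against the smoothed density.
    An amplitude pinned at 0 triggers a spurious-peak warning.
    """
    k = len(peaks)
    if not 1 <= k <= 3:
        raise FitError(f"need 1-3 peaks to fit, got {k}")
    y, grid = profile.density, profile.grid
    n = y.size
    a0 = []
    for b in peaks.locations:
        i0 = int(round(b / TWO_PI * n - 0.5)) % n
        a0.append(max(float(y[i0]), 1e-6))
    c0 = _initial_widths(profile, peaks)

    def residuals(theta: np.ndarray) -> np.ndarray:
        trip = list(zip(theta[:k], peaks.locations, theta[k:]))
        model = evaluate_model_modulo(FitParameters(trip, overlap_scaled), grid)
        return model - y

    lb = [0.0] * k + [1e-3] * k
    ub = [np.inf] * k + [np.pi] * k
    x0 = np.clip(np.array(a0 + c0), lb, ub)
    res = optimize.least_squares(residuals, x0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12)
    if res.status <= 0:
        raise FitError(f"least-squares did not converge: {res.message}; residual trace: {res.fun}")
    a_fit, c_fit = res.x[:k], res.x[k:]
    if np.any(a_fit < 1e-9):
        warnings.warn("fitted amplitude at lower bound 0: spurious peak?", stacklevel=2)
    triplets = [(float(a), float(b), float(c)) for a, b, c in zip(a_fit, peaks.locations, c_fit)]
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return FitParameters(triplets, overlap_scaled, residual=rms)


def fit_histogram(
    hist: TorsionHistogram,
    sigma_deg: float = 5.0,
    max_peaks: int = 3,
    prominence_frac: float = 0.01,
) -> FitParameters:
    """Convenience pipeline: symmetrize -> smooth -> detect -> fit."""
    profile = smooth(symmetrize(hist), sigma_deg)
    peaks = detect_peaks_periodic(profile, max_peaks, prominence_frac)
    if len(peaks) == 0:
        raise FitError(f"no peaks detected for {hist.pattern_id!r}")
    return fit_wrapped_mirrored_gaussians(profile, peaks)
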