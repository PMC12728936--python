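"""Normalized statistical distances between torsion-angle samples.

Two complementary metrics quantify how different two torsion profiles are:

* the second-order Wasserstein distance W2 (optimal transport with
  quadratic cost) between the two empirical distributions on the circle
  [0, 360), with circular ground distance
  d(x, y) = min(|x - y|, 360 - |x - y|).  W2 penalizes probability mass
  according to the squared distance it has to travel, so it emphasizes
  global shifts over local reshaping;
* omega, the square root of the two-sample Cramer-von Mises criterion
  computed on bootstrap resamples of fixed size, which integrates the
  squared gap between the two empirical CDFs and is therefore more
  sensitive to local changes (peak splitting, height changes).

Both are normalized by their theoretical maxima -- 180 degrees for W2 (two
antipodal point masses) and the fully separated two-point-mass
configuration for the CvM criterion -- so values live in [0, 1].  Two
distributions are flagged significantly different when the normalized W2
exceeds 0.03 or normalized omega exceeds 0.07 (strictly; boundary values
are not significant).

For 1D distributions on the circle, W2 reduces to a minimization over the
"cut" (rotation) parameter of the quantile-function distance on the
unrolled line; the objective is convex in the cut, so a coarse scan plus
bounded scalar minimization finds the optimum.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Maximum circular W2 in degrees: two point masses 180 degrees apart.
W2_MAX_DEG = 180.0

W2_THRESHOLD = 0.03
OMEGA_THRESHOLD = 0.07
DEFAULT_N_BOOT = 10_000
#: Minimum sample size for data-set level profile comparisons.
MIN_SAMPLES = 300


@dataclass(frozen=True)
class AngleSample:
    """A bag of torsion angles (degrees in [0, 360)) from one environment."""

    angles: np.ndarray
    environment: str = "other"
    pattern_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.angles, dtype=float)
        object.__setattr__(self, "angles", np.mod(arr, 360.0))

    def __len__(self) -> int:
        return int(self.angles.size)


@dataclass(frozen=True)
class DistanceResult:
    w2_norm: float
    omega_norm: float
    w2_significant: bool
    omega_significant: bool
    n_boot: int
    seed: int


def _require_nonempty(*samples: AngleSample) -> None:
    for s in samples:
        if len(s) == 0:
            raise ValueError("distance undefined for an empty angle sample")


# -- circular second-order Wasserstein ---------------------------------------

def _transport_cost(alpha: float, xa: np.ndarray, xb: np.ndarray) -> float:
    """Exact quadratic transport cost for cut parameter ``alpha``.

    Evaluates the integral over mass q of
    ``(F_a^{-1}(q) - G_b^{-1}(q - alpha))^2`` with both quantile functions
    extended periodically (one extra turn adds 360 degrees).  Segments are
    the common refinement of both (shifted) breakpoint sets, on which both
    quantile functions are constant, so the sum is the integral exactly.
    """
    n, m = xa.size, xb.size
    shifted = np.mod(np.arange(m) / m + alpha, 1.0)
    qs = np.unique(np.concatenate([np.arange(n + 1) / n, shifted, [0.0, 1.0]]))
    mids = 0.5 * (qs[:-1] + qs[1:])
    w = np.diff(qs)
    fa = xa[np.minimum((mids * n).astype(int), n - 1)]
    u = mids - alpha
    k = np.floor(u)
    frac = u - k
    gb = xb[np.minimum((frac * m).astype(int), m - 1)] + 360.0 * k
    return float(np.sum(w * (fa - gb) ** 2))


def wasserstein2(a: AngleSample, b: AngleSample) -> float:
    """Normalized circular second-order Wasserstein distance in [0, 1].

    Computes the exact empirical W2 on the circle via the quantile
    formulation, minimized over the cut parameter, and divides by the
    180-degree theoretical maximum.
    """
    _require_nonempty(a, b)
    xa = np.sort(a.angles)
    xb = np.sort(b.angles)
    coarse = np.linspace(-1.0, 1.0, 201)
    costs = [_transport_cost(al, xa, xb) for al in coarse]
    i = int(np.argmin(costs))
    lo = coarse[max(i - 1, 0)]
    hi = coarse[min(i + 1, coarse.size - 1)]
    res = optimize.minimize_scalar(
        _transport_cost, bounds=(lo, hi), args=(xa, xb),
        method="bounded", options={"xatol": 1e-7},
    )
    best = min(float(res.fun), costs[i])
    w2_deg = float(np.sqrt(max(best, 0.0)))
    return float(np.clip(w2_deg / W2_MAX_DEG, 0.0, 1.0))


def wasserstein2_degrees(a: AngleSample, b: AngleSample) -> float:
    """Unnormalized circular W2 in degrees."""
    return wasserstein2(a, b) * W2_MAX_DEG


# -- Cramer-von Mises ---------------------------------------------------------

@lru_cache(maxsize=32)
def cvm_max_statistic(n: int, m: int) -> float:
    """Theoretical maximum of the two-sample CvM criterion at sizes (n, m).

    Obtained by brute force from the fully separated degenerate
    configuration (all of one sample at one point, all of the other at a
    distant point), which maximizes the integrated squared ECDF gap; the
    large-n limit is n*m / (2*(n+m)).
    """
    res = stats.cramervonmises_2samp(np.full(n, 10.0), np.full(m, 200.0), method="asymptotic")
    return float(res.statistic)


def _content_seed(seed: int, x: np.ndarray) -> np.random.Generator:
    """RNG keyed by the global seed and the sample's own sorted content, so
    the bootstrap protocol is symmetric in the two arguments."""
    key = zlib.crc32(np.ascontiguousarray(np.sort(x), dtype="<f8").tobytes())
    return np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), key]))


def cramer_von_mises(
    a: AngleSample,
    b: AngleSample,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> float:
    """Normalized bootstrap two-sample Cramer-von Mises distance in [0, 1].

    Each sample is resampled with replacement to ``n_boot`` points (the
    criterion depends on sample sizes, so fixing them makes values
    comparable across profiles); the criterion is computed on the
    resamples and mapped to omega = sqrt(criterion / maximum), clipped to
    [0, 1].  Reproducible given ``seed``, and symmetric in the arguments
    because each sample's resampling RNG is derived from the seed plus that
    sample's own content.
    """
    _require_nonempty(a, b)
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    ra = _content_seed(seed, a.angles).choice(a.angles, size=n_boot, replace=True)
    rb = _content_seed(seed, b.angles).choice(b.angles, size=n_boot, replace=True)
    if np.array_equal(np.sort(ra), np.sort(rb)):
        return 0.0
    t = float(stats.cramervonmises_2samp(ra, rb, method="asymptotic").statistic)
    tmax = cvm_max_statistic(n_boot, n_boot)
    return float(np.clip(np.sqrt(max(t, 0.0) / tmax), 0.0, 1.0))


# -- classification and pairwise comparison -----------------------------------

def classify(
    w2_norm: float,
    omega_norm: float,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    w2_threshold: float = W2_THRESHOLD,
    omega_threshold: float = OMEGA_THRESHOLD,
) -> DistanceResult:
    """Attach significance flags: strict inequality against the thresholds."""
    return DistanceResult(
        w2_norm=float(w2_norm),
        omega_norm=float(omega_norm),
        w2_significant=bool(w2_norm > w2_threshold),
        omega_significant=bool(omega_norm > omega_threshold),
        n_boot=n_boot,
        seed=seed,
    )


def compare_samples(
    a: AngleSample,
    b: AngleSample,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    w2_threshold: float = W2_THRESHOLD,
    omega_threshold: float = OMEGA_THRESHOLD,
) -> DistanceResult:
    """Both normalized metrics plus significance flags for one sample pair."""
    w2 = wasserstein2(a, b)
    om = cramer_von_mises(a, b, n_boot=n_boot, seed=seed)
    return classify(w2, om, n_boot, seed, w2_threshold, omega_threshold)


def pairwise_compare(
    profiles: Mapping[str, Mapping[str, AngleSample]],
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
    min_samples: int = MIN_SAMPLES,
    w2_threshold: float = W2_THRESHOLD,
    omega_threshold: float = OMEGA_THRESHOLD,
) -> tuple[pd.DataFrame, dict[tuple[str, str], dict[str, np.ndarray]], list[tuple[str, str]]]:
    """Compare every unordered environment pair for every pattern.

    ``profiles`` maps pattern_id -> environment -> AngleSample.  Patterns
    missing an environment of a pair, or with fewer than ``min_samples``
    angles on either side, are skipped for that pair (logged).  Returns

    * a table with one row per (pattern, pair) comparison,
    * per-pair empirical CDF supports (sorted metric values over patterns)
      for each metric,
    * environment pairs ranked from most to least similar by mean metric
      value (a proxy for CDF dominance: a CDF lying to the left has the
      smaller mean).
    """
    envs = sorted({e for per_env in profiles.values() for e in per_env})
    if len(envs) < 2:
        raise ValueError("pairwise comparison needs at least two environments")
    rows = []
    for pid, per_env in profiles.items():
        for env_a, env_b in itertools.combinations(envs, 2):
            if env_a not in per_env or env_b not in per_env:
                logger.info("pattern %s: missing environment for pair (%s, %s); skipped",
                            pid, env_a, env_b)
                continue
            sa, sb = per_env[env_a], per_env[env_b]
            if len(sa) < min_samples or len(sb) < min_samples:
                logger.info("pattern %s (%s vs %s): fewer than %d samples; skipped",
                            pid, env_a, env_b, min_samples)
                continue
            r = compare_samples(sa, sb, n_boot, seed, w2_threshold, omega_threshold)
            rows.append({
                "pattern_id": pid, "env_a": env_a, "env_b": env_b,
                "n_a": len(sa), "n_b": len(sb),
                "w2_norm": r.w2_norm, "omega_norm": r.omega_norm,
                "w2_sig": r.w2_significant, "omega_sig": r.omega_significant,
                "seed": seed,
            })
    table = pd.DataFrame(rows, columns=[
        "pattern_id", "env_a", "env_b", "n_a", "n_b",
        "w2_norm", "omega_norm", "w2_sig", "omega_sig", "seed",
    ])
    cdfs: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for (env_a, env_b), grp in table.groupby(["env_a", "env_b"]):
        cdfs[(env_a, env_b)] = {
            "w2": np.sort(grp["w2_norm"].to_numpy()),
            "omega": np.sort(grp["omega_norm"].to_numpy()),
        }
    ranking = sorted(
        cdfs, key=lambda pair: float(np.mean(cdfs[pair]["w2"]) + np.mean(cdfs[pair]["omega"]))
    )
    return table, cdfs, ranking
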