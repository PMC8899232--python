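"""Significance testing for entrainment maps.

Parametric tests: the nested-regression F-test for GC and the Rayleigh test
for PLV/ITC.  Nonparametric: surrogate/permutation nulls built by shuffling
one partner's data in ways that destroy the tested dependence while
preserving marginal structure —

* ``segment_shuffle_within_trials`` — the epoch is cut into contiguous
  segments (the metric's own window length) whose within-trial order is
  permuted; recommended for strongly event-locked effects.
* ``trial_shuffle`` — person B's trials are re-paired against person A's.
* ``time_scramble`` — person B is circularly shifted by a random offset per
  trial; the guard against spurious locking between two oscillators that
  merely share a dominant frequency.

Multiple comparisons are handled by Bonferroni, max-statistic (pixel) or
cluster-mass permutation correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .sequential import ARFit

SCHEMES = ("segment_shuffle_within_trials", "trial_shuffle", "time_scramble")


# ---------------------------------------------------------------------------
# Parametric tests
# ---------------------------------------------------------------------------

def gc_f_test(fit: ARFit, n_obs: int | None = None):
    """Nested-regression F-test of each GC direction.

    ``F = ((RSS_restricted - RSS_full) / p) / (RSS_full / (n - 2p - 1))``
    against F(p, n - 2p - 1), upper tail.  Returns ``{"x->y": (F, p), "y->x":
    (F, p)}``; x->y tests whether x's past improves the prediction of y.
    """
    n = fit.n_obs if n_obs is None else n_obs
    p = fit.order
    df_den = n - 2 * p - 1
    if df_den <= 0:
        raise ValueError("non-positive denominator degrees of freedom")
    out = {}
    for name, tgt in (("x->y", 1), ("y->x", 0)):
        rss_r, rss_f = fit.rss_uni[tgt], fit.rss_biv[tgt]
        f_stat = max((rss_r - rss_f), 0.0) / p / (rss_f / df_den)
        out[name] = (float(f_stat), float(stats.f.sf(f_stat, p, df_den)))
    return out


def rayleigh_test(value: float, n: int) -> float:
    """Rayleigh-test p-value for a resultant length (PLV/ITC) from n phasors.

    Uses the standard small-sample approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))`` with ``R = n *
    value``; monotone decreasing in ``value``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    value = float(value)
    r2 = (n * value) ** 2
    arg = 1.0 + 4.0 * n + 4.0 * (n**2 - r2)
    p = np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n))
    return float(min(p, 1.0))


def plv_threshold(n: int, alpha: float) -> float:
    """Critical PLV/ITC value from the large-sample Rayleigh form,
    ``sqrt(-ln(alpha)/n)``; values above it are significant at alpha."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return float(np.sqrt(-np.log(alpha) / n))


def bonferroni(p_values, m: int):
    """Bonferroni-adjusted p-values ``min(1, p * m)``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, np.asarray(p_values, dtype=float) * m)


# ---------------------------------------------------------------------------
# Permutation nulls
# ---------------------------------------------------------------------------

@dataclass
class SurrogateNull:
    """Permutation distribution of a map-valued metric.

    ``null_values`` has shape (n_perm,) + map shape; ``p_map`` is the
    pointwise ``(1 + #{null >= observed}) / (n_perm + 1)`` (tail-adjusted for
    two-sided statistics), never exactly 0.
    """

    scheme: str
    n_perm: int
    observed: np.ndarray
    null_values: np.ndarray
    p_map: np.ndarray
    seed: int
    tail: str = "upper"
    meta: dict = field(default_factory=dict)


def _segment_boundaries(n_samples: int, seg_len: int):
    starts = np.arange(0, n_samples - seg_len + 1, seg_len)
    return [(s, s + seg_len) for s in starts]


def permute_b(b: np.ndarray, scheme: str, rng: np.random.Generator,
              seg_len: int | None = None) -> np.ndarray:
    """One surrogate of person B's data (trials first, time last)."""
    n_trials = b.shape[0]
    n_samples = b.shape[-1]
    if scheme == "trial_shuffle":
        if n_trials < 2:
            raise ValueError("trial_shuffle needs at least 2 trials")
        return b[rng.permutation(n_trials)]
    if scheme == "time_scramble":
        out = np.empty_like(b)
        shifts = rng.integers(1, n_samples, size=n_trials)
        for k in range(n_trials):
            out[k] = np.roll(b[k], shifts[k], axis=-1)
        return out
    if scheme == "segment_shuffle_within_trials":
        if seg_len is None or seg_len < 1:
            raise ValueError("segment_shuffle requires a segment length")
        bounds = _segment_boundaries(n_samples, seg_len)
        if len(bounds) < 2:
            raise ValueError("epoch too short for more than one segment")
        out = b.copy()
        used = len(bounds) * seg_len
        for k in range(n_trials):
            order = rng.permutation(len(bounds))
            segs = [b[k][..., s:e] for s, e in bounds]
            out[k][..., :used] = np.concatenate([segs[j] for j in order], axis=-1)
        return out
    raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


def build_null(
    a: np.ndarray,
    b: np.ndarray,
    metric,
    scheme: str,
    n_perm: int = 1000,
    seed: int = 0,
    seg_len: int | None = None,
    tail: str = "upper",
) -> SurrogateNull:
    """Permutation null for ``metric(a, b) -> ndarray``.

    Only person B's array is permuted (one-partner scheme); ``a`` and ``b``
    must carry trials on axis 0 and time on the last axis.  ``seg_len`` (in
    samples) is required for the segment-shuffle scheme and should equal the
    metric's own analysis window.  ``tail`` is ``"upper"`` for non-negative
    increase-type statistics (PLV/ITC/GC/PTE) or ``"two"`` for correlations.
    """
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    if tail not in ("upper", "two"):
        raise ValueError("tail must be 'upper' or 'two'")
    rng = np.random.default_rng(seed)
    observed = np.asarray(metric(a, b), dtype=float)
    null_values = np.empty((n_perm,) + observed.shape)
    for i in range(n_perm):
        null_values[i] = metric(a, permute_b(b, scheme, rng, seg_len))
    if tail == "upper":
        exceed = (null_values >= observed).sum(axis=0)
    else:
        exceed = (np.abs(null_values) >= np.abs(observed)).sum(axis=0)
    p_map = (1.0 + exceed) / (n_perm + 1.0)
    return SurrogateNull(
        scheme=scheme, n_perm=n_perm, observed=observed,
        null_values=null_values, p_map=p_map, seed=seed, tail=tail,
        meta={"seg_len": seg_len},
    )


# ---------------------------------------------------------------------------
# Multiple-comparison correction
# ---------------------------------------------------------------------------

def correct_pixel(null: SurrogateNull, alpha: float = 0.05) -> np.ndarray:
    """Max-statistic (pixel-level) correction: the observed map is thresholded
    at the (1 - alpha) quantile of the per-permutation map-maximum
    distribution.  Controls the family-wise error rate at alpha."""
    flat = null.null_values.reshape(null.n_perm, -1)
    stat = np.abs(flat) if null.tail == "two" else flat
    maxima = stat.max(axis=1)
    thr = np.quantile(maxima, 1.0 - alpha)
    obs = np.abs(null.observed) if null.tail == "two" else null.observed
    return obs > thr


@dataclass
class ClusterRecord:
    """A contiguous suprathreshold region of the map (4-connectivity)."""

    pixels: np.ndarray  # (n_pixels, ndim) indices
    mass: float
    p: float


def _cluster_masses(stat_map: np.ndarray, thr_map: np.ndarray):
    """Label suprathreshold pixels (4-connectivity) and return (labels,
    masses) with mass = sum of the statistic over each cluster."""
    supra = stat_map > thr_map
    structure = ndimage.generate_binary_structure(stat_map.ndim, 1)
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return labels, np.array([])
    masses = ndimage.sum_labels(stat_map, labels, index=np.arange(1, n + 1))
    return labels, masses


def correct_cluster(
    null: SurrogateNull, pixel_alpha: float = 0.05, cluster_alpha: float = 0.05
):
    """Cluster-mass permutation correction on a 2-d map.

    Pixels exceeding their own pointwise (1 - pixel_alpha) null quantile are
    grouped by 4-connectivity; each cluster's mass (sum of the statistic) is
    compared to the null distribution of the per-permutation maximum cluster
    mass.  Returns the clusters surviving ``p <= cluster_alpha``.
    """
    if null.observed.ndim != 2:
        raise ValueError("cluster correction expects a 2-d (freq x time) map")
    stat = np.abs(null.null_values) if null.tail == "two" else null.null_values
    obs = np.abs(null.observed) if null.tail == "two" else null.observed
    thr_map = np.quantile(stat, 1.0 - pixel_alpha, axis=0)

    null_max = np.zeros(null.n_perm)
    for i in range(null.n_perm):
        _, masses = _cluster_masses(stat[i], thr_map)
        if masses.size:
            null_max[i] = masses.max()

    labels, masses = _cluster_masses(obs, thr_map)
    records = []
    for ci, mass in enumerate(masses, start=1):
        p = (1.0 + (null_max >= mass).sum()) / (null.n_perm + 1.0)
        if p <= cluster_alpha:
            records.append(ClusterRecord(
                pixels=np.argwhere(labels == ci), mass=float(mass), p=float(p)
            ))
    return records
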