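"""Fuzzy C-means primitives shared by every clustering driver.

Pixels are treated as scalar intensities on the normalized [0, 1] scale and
flattened row-major, so pixel k of an H×W image sits at (k // W, k % W).
Membership matrices are ``(c, N)`` float arrays: entry ``(i, k)`` is the degree
with which pixel k belongs to cluster i.  A *fuzzy partition* additionally has
every pixel column summing to 1.

The alternating-optimization loop here is plain FCM: memberships are the
inverse-distance-ratio update

    mu_ik = 1 / sum_j (d(x_k, v_i) / d(x_k, v_j))^(2/(m-1))

and centers are the mu^m-weighted intensity means.  The fuzzifier m > 1
controls partition softness (m -> 1 approaches hard k-means; m = 2 is the
conventional default for intensity segmentation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("csifcm")

#: Names of the implemented clustering drivers.
ALGORITHMS = ("fcm", "ifcm", "csfcm", "csifcm")


class DegenerateClusterWarning(UserWarning):
    """A cluster received all-zero weights in a center update."""


@dataclass
class ClusteringConfig:
    """Hyperparameters for all four clustering drivers.

    Parameters
    ----------
    n_clusters : int
        Number of tissue classes / segments c.
    fuzzifier : float
        Fuzziness exponent m > 1.
    p, q : float
        Exponents weighting the intuitionistic (or plain fuzzy) membership and
        the conditional spatial membership in the weighted combination.
        Non-negative, not both zero.
    yager_alpha : float
        Yager complement parameter in (0, 1]; 1 recovers the standard
        complement and switches off hesitation.
    window_size : int
        Odd side length of the square neighborhood window.
    tolerance : float
        Termination threshold on the max absolute change of the monitored
        membership matrix between iterations.
    max_iter : int
        Iteration cap; hitting it flags the result as not converged.
    seed : int
        Seed for the random initial partition.
    algorithm : str
        One of ``fcm``, ``ifcm``, ``csfcm``, ``csifcm``.
    """

    n_clusters: int = 4
    fuzzifier: float = 2.0
    p: float = 1.0
    q: float = 2.0
    yager_alpha: float = 0.85
    window_size: int = 3
    tolerance: float = 1e-5
    max_iter: int = 100
    seed: int = 0
    algorithm: str = "csifcm"

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.fuzzifier <= 1:
            raise ValueError("fuzzifier m must be > 1")
        if self.p < 0 or self.q < 0:
            raise ValueError("p and q must be >= 0")
        if self.p == 0 and self.q == 0:
            raise ValueError("p and q must not both be zero")
        if not (0 < self.yager_alpha <= 1):
            raise ValueError("yager_alpha must lie in (0, 1]")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ValueError("window_size must be an odd integer >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")


@dataclass
class SegmentationResult:
    """Output of a clustering driver.

    ``membership`` is the final monitored membership matrix (mu for FCM,
    normalized mu* for IFCM, z for csFCM, w for csIFCM) with pixel columns
    summing to 1.  ``labels`` is the per-pixel argmax of that matrix reshaped
    to the image, ``centers`` the final cluster intensities, and ``trace`` the
    per-iteration ``(iteration, max_delta, objective)`` log (objective is the
    FCM cost evaluated with the monitored membership; it is the formal
    objective only for plain FCM).
    """

    membership: np.ndarray
    centers: np.ndarray
    labels: np.ndarray
    n_iterations: int
    converged: bool
    trace: list[tuple[int, float, float]] = field(default_factory=list)


def initialize_partition(n_pixels: int, c: int, seed: int) -> np.ndarray:
    """Seeded random fuzzy partition: ``(c, n_pixels)``, columns summing to 1.

    Entries are strictly positive uniform draws renormalized per pixel, so the
    same seed always reproduces the same matrix.
    """
    if c < 1:
        raise ValueError("c must be >= 1")
    if n_pixels < c:
        raise ValueError(f"need at least as many pixels ({n_pixels}) as clusters ({c})")
    rng = np.random.default_rng(seed)
    u = rng.random((c, n_pixels))
    # guard against an exact 0.0 draw; columns must stay strictly positive
    u = np.clip(u, 1e-12, None)
    return u / u.sum(axis=0, keepdims=True)


def fcm_membership(pixels: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Distance-ratio membership update for scalar intensities.

    ``pixels`` is a flat ``(N,)`` intensity array, ``centers`` a ``(c,)``
    array.  The distance is the absolute intensity difference.  A pixel that
    coincides exactly with one or more centers gets crisp membership 1 on the
    first such cluster (deterministic tie-break), 0 elsewhere.
    """
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    pixels = np.asarray(pixels, dtype=float).ravel()
    centers = np.asarray(centers, dtype=float).ravel()
    if not np.all(np.isfinite(centers)):
        raise ValueError("centers must be finite")
    d = np.abs(pixels[None, :] - centers[:, None])  # (c, N)
    zero = d == 0.0
    zero_cols = zero.any(axis=0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
    mu = np.empty_like(d)
    ok = ~zero_cols
    mu[:, ok] = inv[:, ok] / inv[:, ok].sum(axis=0, keepdims=True)
    if zero_cols.any():
        mu[:, zero_cols] = 0.0
        first = np.argmax(zero[:, zero_cols], axis=0)
        mu[first, np.nonzero(zero_cols)[0]] = 1.0
    return mu


def update_centers(
    pixels: np.ndarray,
    weights: np.ndarray,
    m: float,
    previous: np.ndarray | None = None,
) -> np.ndarray:
    """Weighted-mean center update: v_i = sum_k w_ik^m x_k / sum_k w_ik^m.

    A cluster whose weights are all zero is degenerate: its center is held at
    ``previous`` (and a :class:`DegenerateClusterWarning` issued) when previous
    centers are supplied, otherwise a ``ValueError`` is raised.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2 or weights.shape[1] != pixels.size:
        raise ValueError("weights must be (c, N) matching the pixel count")
    wm = weights**m
    denom = wm.sum(axis=1)
    dead = denom == 0.0
    if dead.any():
        if previous is None:
            raise ValueError(f"cluster(s) {np.nonzero(dead)[0].tolist()} have all-zero weights")
        warnings.warn(
            f"degenerate cluster(s) {np.nonzero(dead)[0].tolist()}: center held at previous value",
            DegenerateClusterWarning,
            stacklevel=2,
        )
    centers = np.empty(weights.shape[0])
    live = ~dead
    centers[live] = (wm[live] @ pixels) / denom[live]
    if dead.any():
        centers[dead] = np.asarray(previous, dtype=float).ravel()[dead]
    return centers


def fcm_objective(
    pixels: np.ndarray, membership: np.ndarray, centers: np.ndarray, m: float
) -> float:
    """FCM cost J = sum_i sum_k mu_ik^m d(x_k, v_i)^2 (non-negative)."""
    pixels = np.asarray(pixels, dtype=float).ravel()
    membership = np.asarray(membership, dtype=float)
    centers = np.asarray(centers, dtype=float).ravel()
    if membership.shape != (centers.size, pixels.size):
        raise ValueError("membership shape must be (n_centers, n_pixels)")
    d2 = (pixels[None, :] - centers[:, None]) ** 2
    return float((membership**m * d2).sum())


def run_fcm(image: np.ndarray, config: ClusteringConfig) -> SegmentationResult:
    """Plain FCM on a normalized 2-D image.

    Alternates membership and center updates from a seeded random partition
    until the max absolute membership change drops to the tolerance or the
    iteration cap is hit.  The objective is non-increasing along the run.
    """
    from .algorithms import defuzzify  # local import to avoid a cycle

    image = np.asarray(image, dtype=float)
    x = image.ravel()
    c, m = config.n_clusters, config.fuzzifier
    mu_prev = initialize_partition(x.size, c, config.seed)
    centers = update_centers(x, mu_prev, m)
    trace: list[tuple[int, float, float]] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mu = fcm_membership(x, centers, m)
        centers = update_centers(x, mu, m, previous=centers)
        delta = float(np.abs(mu - mu_prev).max())
        obj = fcm_objective(x, mu, centers, m)
        trace.append((it, delta, obj))
        logger.debug("fcm iter=%d max|dmu|=%.3e J=%.6e", it, delta, obj)
        mu_prev = mu
        if delta <= config.tolerance:
            converged = True
            break
    labels = defuzzify(mu_prev).reshape(image.shape)
    return SegmentationResult(mu_prev, centers, labels, it, converged, trace)
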