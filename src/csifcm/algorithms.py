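"""End-to-end clustering drivers: FCM, IFCM, csFCM and csIFCM.

All four drivers share the same skeleton — seeded random fuzzy partition,
initial centers from that partition, then alternating updates until the
monitored membership matrix stops moving (max absolute entrywise change below
the tolerance) or the iteration cap is reached.  They differ in the membership
that drives the center update and the stopping rule:

========  =============================================  ==================
driver    per-iteration membership pipeline              monitored matrix
========  =============================================  ==================
fcm       mu                                             mu
ifcm      mu -> (lambda, pi) -> mu* (renormalized)       mu*
csfcm     mu, v -> h -> u -> z = mu^p u^q / sum          z
csifcm    mu, v -> h -> u* ; mu -> (lambda, pi) -> mu*   w
          -> w = mu*^p u*^q / sum
========  =============================================  ==================

The intuitionistic layer (Yager non-membership, hesitation, mu*) always
operates on the plain distance-ratio membership mu — the same transform IFCM
applies — while the spatial conditional u* enters only through the weighted
combination.  This composition makes the reduction chain exact: at alpha = 1
hesitation vanishes and mu* = mu, so csIFCM reproduces csFCM's weighted
membership z iteration by iteration, and IFCM reproduces FCM.

Centers carried across iterations are the joint centers (g for csIFCM, t for
csFCM); the auxiliary centers v computed mid-iteration feed only the
conditional membership of that same iteration.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ClusteringConfig,
    SegmentationResult,
    fcm_membership,
    fcm_objective,
    initialize_partition,
    logger,
    run_fcm,
    update_centers,
)
from .operators import (
    conditional_membership,
    hesitation_degree,
    intuitionistic_membership,
    spatial_condition,
    yager_nonmembership,
)

__all__ = [
    "weighted_membership",
    "run_ifcm",
    "run_csfcm",
    "run_csifcm",
    "defuzzify",
    "segment",
]


def weighted_membership(
    primary: np.ndarray, secondary: np.ndarray, p: float, q: float
) -> np.ndarray:
    """Weighted combination w = primary^p * secondary^q, renormalized per pixel.

    Serves both csFCM (primary = mu, secondary = u) and csIFCM (primary = mu*,
    secondary = u*).  A pixel whose products vanish for every cluster gets the
    uniform fallback 1/c (logged), so columns always sum to 1.
    """
    primary = np.asarray(primary, dtype=float)
    secondary = np.asarray(secondary, dtype=float)
    if primary.shape != secondary.shape:
        raise ValueError("primary and secondary memberships must share a shape")
    if p < 0 or q < 0 or (p == 0 and q == 0):
        raise ValueError("p, q must be >= 0 and not both zero")
    prod = primary**p * secondary**q
    denom = prod.sum(axis=0, keepdims=True)
    dead = denom[0] == 0.0
    if dead.any():
        logger.info(
            "weighted_membership: %d pixel(s) with all-zero products; uniform fallback",
            int(dead.sum()),
        )
        prod[:, dead] = 1.0
        denom = prod.sum(axis=0, keepdims=True)
    return prod / denom


def defuzzify(membership: np.ndarray) -> np.ndarray:
    """Crisp labels by per-pixel argmax; ties go to the lowest cluster index."""
    return np.argmax(np.asarray(membership), axis=0)


def _prepare(image: np.ndarray, config: ClusteringConfig):
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    x = image.ravel()
    part = initialize_partition(x.size, config.n_clusters, config.seed)
    centers = update_centers(x, part, config.fuzzifier)
    return image, x, part, centers


def run_ifcm(image: np.ndarray, config: ClusteringConfig) -> SegmentationResult:
    """Intuitionistic FCM: Yager-lifted membership drives the center update.

    Per iteration: mu from the current centers, lambda/pi/mu* = mu + pi, then
    mu* is renormalized per pixel (its raw columns sum to more than 1 whenever
    hesitation is positive) and used for both the center update and the
    stopping rule.
    """
    image, x, prev, centers = _prepare(image, config)
    m, alpha = config.fuzzifier, config.yager_alpha
    trace: list[tuple[int, float, float]] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mu = fcm_membership(x, centers, m)
        lam = yager_nonmembership(mu, alpha)
        pi = hesitation_degree(mu, lam)
        mstar = intuitionistic_membership(mu, pi)
        mstar = mstar / mstar.sum(axis=0, keepdims=True)
        centers = update_centers(x, mstar, m, previous=centers)
        delta = float(np.abs(mstar - prev).max())
        obj = fcm_objective(x, mstar, centers, m)
        trace.append((it, delta, obj))
        logger.debug("ifcm iter=%d max|dmu*|=%.3e", it, delta)
        prev = mstar
        if delta <= config.tolerance:
            converged = True
            break
    labels = defuzzify(prev).reshape(image.shape)
    return SegmentationResult(prev, centers, labels, it, converged, trace)


def run_csfcm(image: np.ndarray, config: ClusteringConfig) -> SegmentationResult:
    """Conditional spatial FCM.

    Per iteration: mu and auxiliary centers v (plain FCM updates), window mean
    h of mu, conditional membership u = h × membership(v), weighted membership
    z = mu^p u^q renormalized, joint centers t from z.  Stops on max|dz|.
    """
    image, x, prev, centers = _prepare(image, config)
    m, p, q, win = config.fuzzifier, config.p, config.q, config.window_size
    trace: list[tuple[int, float, float]] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mu = fcm_membership(x, centers, m)
        v = update_centers(x, mu, m, previous=centers)
        h = spatial_condition(mu, image.shape, win)
        u = conditional_membership(x, v, h, m)
        z = weighted_membership(mu, u, p, q)
        centers = update_centers(x, z, m, previous=v)
        delta = float(np.abs(z - prev).max())
        obj = fcm_objective(x, z, centers, m)
        trace.append((it, delta, obj))
        logger.debug("csfcm iter=%d max|dz|=%.3e", it, delta)
        prev = z
        if delta <= config.tolerance:
            converged = True
            break
    labels = defuzzify(prev).reshape(image.shape)
    return SegmentationResult(prev, centers, labels, it, converged, trace)


def run_csifcm(image: np.ndarray, config: ClusteringConfig) -> SegmentationResult:
    """Conditional spatial intuitionistic FCM — the full pipeline.

    Per iteration: mu and auxiliary centers v, window mean h, conditional
    spatial membership u* = h × membership(v), intuitionistic lift of mu
    (Yager non-membership lambda, hesitation pi, mu* = mu + pi), weighted
    intuitionistic membership w = mu*^p u*^q renormalized, joint centers g
    from w.  Stops when max|dw| drops to the tolerance.
    """
    image, x, prev, centers = _prepare(image, config)
    m, p, q = config.fuzzifier, config.p, config.q
    win, alpha = config.window_size, config.yager_alpha
    trace: list[tuple[int, float, float]] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        mu = fcm_membership(x, centers, m)
        v = update_centers(x, mu, m, previous=centers)
        h = spatial_condition(mu, image.shape, win)
        ustar = conditional_membership(x, v, h, m)
        lam = yager_nonmembership(mu, alpha)
        pi = hesitation_degree(mu, lam)
        mstar = intuitionistic_membership(mu, pi)
        w = weighted_membership(mstar, ustar, p, q)
        centers = update_centers(x, w, m, previous=v)
        delta = float(np.abs(w - prev).max())
        obj = fcm_objective(x, w, centers, m)
        trace.append((it, delta, obj))
        logger.debug("csifcm iter=%d max|dw|=%.3e", it, delta)
        prev = w
        if delta <= config.tolerance:
            converged = True
            break
    labels = defuzzify(prev).reshape(image.shape)
    return SegmentationResult(prev, centers, labels, it, converged, trace)


_DRIVERS = {
    "fcm": run_fcm,
    "ifcm": run_ifcm,
    "csfcm": run_csfcm,
    "csifcm": run_csifcm,
}


def segment(image: np.ndarray, config: ClusteringConfig) -> SegmentationResult:
    """Run the driver named by ``config.algorithm`` on a normalized image."""
    return _DRIVERS[config.algorithm](image, config)
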