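"""Neighborhood conditioning and intuitionistic fuzzification operators.

Two operator families turn plain FCM into its spatial / intuitionistic
variants:

* **spatial conditioning** — ``h`` averages each cluster's membership over a
  square window around every pixel, and the conditional membership ``u*``
  rescales the distance-based membership by that local agreement, so isolated
  noisy pixels inherit the tendency of their neighborhood;
* **intuitionistic fuzzification** — the Yager complement
  ``lambda = (1 - u^alpha)^(1/alpha)`` yields a non-membership that is not the
  plain complement of membership; the residual ``pi = 1 - u - lambda`` is the
  hesitation degree, and the intuitionistic membership ``mu* = u + pi``
  lifts membership by exactly that uncertainty.

For ``alpha = 1`` the Yager complement collapses to ``1 - u``, hesitation
vanishes, and every intuitionistic variant reduces to its fuzzy ancestor.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import fcm_membership


def spatial_condition(
    membership: np.ndarray, image_shape: tuple[int, int], window_size: int = 3
) -> np.ndarray:
    """Window-mean membership h_ik over the square neighborhood of each pixel.

    ``membership`` is ``(c, N)`` with pixels flattened row-major from
    ``image_shape``.  At image borders the window shrinks: the mean is taken
    over the in-image pixels only (their count is the cardinality R).
    ``window_size = 1`` is the identity.
    """
    if window_size < 1 or window_size % 2 == 0:
        raise ValueError("window_size must be an odd integer >= 1")
    membership = np.asarray(membership, dtype=float)
    h, w = image_shape
    if membership.ndim != 2 or membership.shape[1] != h * w:
        raise ValueError("membership must be (c, N) with N = prod(image_shape)")
    if window_size == 1:
        return membership.copy()
    kernel = np.ones((window_size, window_size))
    counts = ndimage.correlate(
        np.ones((h, w)), kernel, mode="constant", cval=0.0
    )
    out = np.empty_like(membership)
    for i in range(membership.shape[0]):
        plane = membership[i].reshape(h, w)
        sums = ndimage.correlate(plane, kernel, mode="constant", cval=0.0)
        out[i] = (sums / counts).ravel()
    return out


def conditional_membership(
    pixels: np.ndarray, centers: np.ndarray, h: np.ndarray, m: float
) -> np.ndarray:
    """Conditional spatial membership u* = h × (distance-ratio membership).

    The neighborhood agreement ``h`` rescales the FCM membership computed from
    ``centers``; columns then sum to at most 1 (exactly 1 where h is 1).
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("h must lie in [0, 1]")
    mu = fcm_membership(pixels, centers, m)
    if h.shape != mu.shape:
        raise ValueError("h shape must match the membership shape")
    return h * mu


def yager_nonmembership(u: np.ndarray, alpha: float) -> np.ndarray:
    """Yager complement lambda = (1 - u^alpha)^(1/alpha) for alpha in (0, 1].

    Boundary behavior: lambda(0) = 1, lambda(1) = 0.  For alpha <= 1 the
    complement is dominated by 1 - u, which keeps the intuitionistic
    constraint u + lambda <= 1 and hence hesitation non-negative; alpha > 1
    would violate it and is rejected.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if alpha > 1:
        raise ValueError("alpha > 1 would make the hesitation degree negative")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ValueError("membership values must lie in [0, 1]")
    return np.clip((1.0 - u**alpha) ** (1.0 / alpha), 0.0, 1.0)


def hesitation_degree(u: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Hesitation pi = 1 - u - lambda; requires u + lambda <= 1."""
    u = np.asarray(u, dtype=float)
    lam = np.asarray(lam, dtype=float)
    s = u + lam
    if np.any(s > 1.0 + 1e-12):
        raise ValueError("u + lambda exceeds 1: not an intuitionistic fuzzy pair")
    return np.clip(1.0 - s, 0.0, 1.0)


def intuitionistic_membership(u: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Intuitionistic membership mu* = u + pi (equivalently 1 - lambda)."""
    u = np.asarray(u, dtype=float)
    pi = np.asarray(pi, dtype=float)
    out = u + pi
    if np.any(out > 1.0 + 1e-12):
        raise ValueError("u + pi exceeds 1")
    return np.clip(out, 0.0, 1.0)
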