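"""Synthetic benchmark inputs: Shepp-Logan head phantom and piecewise-constant
synthetic MRI slices with noise and intensity inhomogeneity.

The phantom is the classic 10-ellipse head model rendered analytically on an
n×n grid over the unit square [-1, 1]²: each pixel's intensity is the sum of
the additive intensities of the ellipses containing its center.  Two ellipse
tables are shipped — the original low-contrast one and the higher-contrast
"modified" variant that standard tooling returns by default.  Ground truth
for c classes is obtained from the noise-free composite: the c most populous
distinct intensity levels become class representatives (sorted ascending) and
every pixel is assigned the class of its nearest representative, ties going to
the darker class.  For the modified table at c = 4 this yields background plus
the dark interior ellipses, brain-interior gray matter, the bright internal
features, and the skull/scalp shell.

The synthetic MRI generator is a stand-in for real T1-weighted slices: it
emulates their two stated confounders — additive Gaussian noise and a smooth
multiplicative bias field — on concentric regions with prescribed class means.
It does not model MR physics (no k-space sampling, Rician noise or partial
volume), so results on it speak to noise/inhomogeneity robustness only.
"""

from __future__ import annotations

import warnings

import numpy as np

# (intensity, semi-axis a, semi-axis b, x0, y0, rotation phi in degrees)
SHEPP_LOGAN_ELLIPSES = (
    (2.0, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.98, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-0.02, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-0.02, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (0.01, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (0.01, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (0.01, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (0.01, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (0.01, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (0.01, 0.0230, 0.0460, 0.06, -0.605, 0.0),
)

MODIFIED_SHEPP_LOGAN_ELLIPSES = tuple(
    (a_new, a, b, x0, y0, phi)
    for (a_new, (_, a, b, x0, y0, phi)) in zip(
        (1.0, -0.8, -0.2, -0.2, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1), SHEPP_LOGAN_ELLIPSES
    )
)

_VARIANTS = {
    "original": SHEPP_LOGAN_ELLIPSES,
    "modified": MODIFIED_SHEPP_LOGAN_ELLIPSES,
}


def render_ellipses(size: int, ellipses) -> np.ndarray:
    """Sum ellipse intensities per pixel on a size×size grid over [-1, 1]²."""
    # pixel-center axes matching the MATLAB phantom() convention
    ax = (np.arange(size) - (size - 1) / 2.0) / ((size - 1) / 2.0)
    x = ax[None, :]
    y = -ax[:, None]  # row 0 is the top of the head
    img = np.zeros((size, size))
    for amp, a, b, x0, y0, phi in ellipses:
        t = np.deg2rad(phi)
        ct, st = np.cos(t), np.sin(t)
        xr = (x - x0) * ct + (y - y0) * st
        yr = -(x - x0) * st + (y - y0) * ct
        img += amp * ((xr / a) ** 2 + (yr / b) ** 2 <= 1.0)
    return img


def quantize_levels(composite: np.ndarray, n_classes: int) -> np.ndarray:
    """Deterministic ground-truth labels from a piecewise-constant composite.

    The ``n_classes`` most populous distinct intensity levels (deduplicated at
    1e-9) become class representatives, sorted ascending; every pixel takes
    the class of the nearest representative, ties to the darker class.
    """
    flat = np.round(np.asarray(composite, dtype=float) / 1e-9) * 1e-9
    levels, counts = np.unique(flat, return_counts=True)
    if levels.size < n_classes:
        raise ValueError(
            f"composite has only {levels.size} distinct levels; need >= {n_classes}"
        )
    reps = np.sort(levels[np.argsort(counts)[::-1][:n_classes]])
    dist = np.abs(flat[..., None] - reps[None, :])
    # argmin takes the first (darker) representative on exact ties
    return np.argmin(dist, axis=-1)


def generate_phantom(
    size: int, n_classes: int = 4, variant: str = "modified"
) -> tuple[np.ndarray, np.ndarray]:
    """Shepp-Logan head phantom with quantized ground-truth labels.

    Returns the min–max normalized image in [0, 1] and an integer label map
    with ``n_classes`` classes.  Fully deterministic (no RNG).
    """
    from .preprocessing import normalize_intensities

    if size < 32:
        raise ValueError("size must be >= 32")
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {sorted(_VARIANTS)}")
    composite = render_ellipses(size, _VARIANTS[variant])
    # snap float residue from summed signed intensities (e.g. 1 - 0.8 - 0.2)
    # to the same 1e-9 grid the quantizer uses, so level 0 is exactly 0
    composite = np.round(composite / 1e-9) * 1e-9
    labels = quantize_levels(composite, n_classes)
    return normalize_intensities(composite), labels


def bias_field(size: int, amplitude: float) -> np.ndarray:
    """Smooth multiplicative shading 1 + amplitude·cos-bump, peaking centrally."""
    ax = np.linspace(-1.0, 1.0, size)
    surface = np.outer(np.cos(np.pi * ax / 2.0), np.cos(np.pi * ax / 2.0))
    return 1.0 + amplitude * surface


def generate_synthetic_mri(
    size: int = 128,
    class_means: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8),
    noise_variance: float = 0.02,
    bias_amplitude: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant slice: concentric regions, bias field, Gaussian noise.

    ``class_means`` must be strictly increasing in [0, 1]; class k occupies the
    k-th ring from the outside (the brightest class is the central disc,
    mimicking the dark-background/bright-interior layout of a T1 slice).  The
    image is corrupted by a multiplicative bias field ``1 + amplitude·surface``
    and additive zero-mean Gaussian noise, then clipped to [0, 1]; the returned
    ground truth is the pre-corruption label map.  Reproducible by seed.
    """
    from .preprocessing import add_gaussian_noise

    means = np.asarray(class_means, dtype=float)
    if np.any(np.diff(means) <= 0) or means.min() < 0 or means.max() > 1:
        raise ValueError("class_means must be strictly increasing within [0, 1]")
    if not (0 <= bias_amplitude < 0.5):
        raise ValueError("bias_amplitude must lie in [0, 0.5)")
    sigma = np.sqrt(noise_variance)
    if sigma > 0 and np.any(np.diff(means) < 2 * sigma):
        warnings.warn(
            "class mean separation below 2 sigma; classes will overlap heavily",
            UserWarning,
            stacklevel=2,
        )
    c = means.size
    ax = np.linspace(-1.0, 1.0, size)
    r = np.sqrt(ax[None, :] ** 2 + ax[:, None] ** 2)
    # rings of equal radial width; outermost (incl. corners) is class 0
    ring = np.clip((c * (1.0 - np.clip(r, 0.0, 1.0))).astype(int), 0, c - 1)
    labels = ring
    clean = means[labels] * bias_field(size, bias_amplitude)
    image = add_gaussian_noise(np.clip(clean, 0.0, 1.0), noise_variance, seed)
    return image, labels
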