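# Methods

## Scope and data model

The package segments single 2-D grayscale slices by clustering pixel
*intensities* — each pixel is a scalar on the min–max normalized [0, 1]
scale, flattened row-major (`k = row·width + col`). Feature vectors, 3-D
neighborhoods, kernelized distances and bias-field *correction* are out of
scope; the distance everywhere is the absolute intensity difference, squared
inside the objective. Multi-channel inputs are reduced by ITU-R 601 luminance
before normalization.

## The four drivers

All drivers start from the same seeded random fuzzy partition (strictly
positive uniform draws, columns renormalized to 1) and initial centers
computed from it, then iterate until the max absolute entrywise change of the
monitored membership matrix is ≤ ε or `max_iter` is reached (non-convergence
is flagged on the result, never raised).

* **FCM** — alternating membership/center updates; monitored matrix μ. The
  objective `J = Σ μ^m d²` is non-increasing along the run (asserted in
  tests with 1e−9 slack).
* **IFCM** — μ is lifted through the Yager complement
  (`λ = (1−μ^α)^{1/α}`, `π = 1−μ−λ`, `μ* = μ+π = 1−λ`); because μ* columns
  sum to more than 1 whenever hesitation is positive, μ* is renormalized per
  pixel before it drives the center update and the stopping rule.
* **csFCM** — per iteration: μ and auxiliary centers v by the plain FCM
  updates, window mean h of μ, conditional membership `u = h · μ(v)`,
  weighted membership `z ∝ μ^p u^q` (renormalized), joint centers t from z.
  Monitored matrix z; the centers carried to the next iteration are t.
* **csIFCM** — csFCM's spatial pipeline plus the intuitionistic lift:
  `w ∝ μ*^p u*^q` with `μ* = 1 − λ(μ)` and `u* = h · μ(v)`; joint centers g
  from w; monitored matrix w.

### Where the intuitionistic layer attaches

The printed equations of this method family are ambiguous about whether the
Yager chain operates on the conditional spatial membership u\* or on the
plain membership μ (the non-membership equation uses u\*, the combination
equation uses u without the star). We attach it to μ — the same transform
IFCM applies — and let u\* enter only through the weighted product. This is
the only composition under which the reduction chain is exact: at α = 1,
π ≡ 0 and μ\* = μ, so csIFCM's w equals csFCM's z *iteration by iteration*
(and IFCM equals FCM); had the chain operated on u\*, w would collapse to
`u*^(p+q)` and the equivalence would fail. The reduction is asserted to
1e−12 in the tests. It also keeps every matrix inside [0, 1] and preserves
`u + λ + π = 1` exactly.

### Numerical conventions

* Zero distance in the membership update (pixel exactly at a center): crisp
  membership 1 on the first such cluster by index, 0 elsewhere.
* Degenerate cluster (all-zero weights) in a center update: center held at
  its previous value, with a warning — not an exception.
* All-zero product column in the weighted membership: uniform fallback 1/c
  for that pixel, logged.
* Defuzzification: per-pixel argmax, ties to the lowest cluster index.
* Window averaging uses direct summation (`scipy.ndimage.correlate` with a
  ones kernel) over the *in-image* part of the window; at borders the window
  shrinks and the divisor R is the actual in-image neighbor count. No
  padding or reflection.
* α is restricted to (0, 1]: for α > 1 the Yager complement would make the
  hesitation degree negative, violating the intuitionistic constraint
  0 ≤ μ + λ ≤ 1.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_clusters` c | 4 | tissue classes (background/CSF, GM, WM-like bright features, skull shell) |
| `fuzzifier` m | 2 | partition softness; the literature default — experiments in this family rarely state it |
| `p`, `q` | 1, 2 | exponents of μ\* and u\* in w; 1/2 is the reported grid-search optimum, and the shipped `sweep-pq` harness reruns that search on synthetic data |
| `yager_alpha` α | 0.85 | hesitation strength; α = 1 switches the intuitionistic layer off; the source experiments call it "self-chosen" without reporting a value |
| `window_size` | 3 | square neighborhood side; 3×3 is the conventional spatial-FCM choice |
| `tolerance` ε | 1e−5 | stopping threshold on max \|Δ membership\| |
| `max_iter` | 100 | iteration cap |

## Synthetic data

**Phantom.** The 10-ellipse Shepp-Logan head phantom is rendered
analytically (per-pixel point-in-ellipse sums over [−1, 1]², MATLAB-style
pixel-center axes); both the original low-contrast and the default
higher-contrast *modified* intensity tables are shipped. Ground truth for
c = 4: the composite is snapped to a 1e−9 grid, the four most populous
distinct levels (0, 0.2, 0.3, 1.0 for the modified table — background plus
dark internal ellipses, brain interior, bright internal features, skull
shell) become class representatives, and every pixel takes the class of its
nearest representative, ties to the darker class. The rule is deterministic
and versioned here because the benchmark's published form never defines its
segment masks.

A consequence worth knowing: ellipse overlaps create tiny "sliver" levels
(0.1 = dark+bright overlap, ≈0.14 % of pixels) lying *exactly* halfway
between the representatives 0.0 and 0.2. Purely pixelwise drivers (FCM,
IFCM) label them by whichever converged center is marginally nearer — the
brighter one, by ~2e−5 — while the spatial drivers pull them to the darker
neighborhood class that the ground truth records. Noise-free recovery is
therefore exactly 1.0 for csFCM/csIFCM but 0.9986 for FCM/IFCM on the
phantom, with every error confined to sliver pixels (asserted in tests); on
the synthetic MRI, whose classes are exact constants, all four drivers
recover the truth exactly. csFCM/csIFCM additionally have a seed-dependent
degenerate fixed point on the noise-free phantom (a merged 0.2/0.3 cluster,
~1 seed in 3) — initialization sensitivity is a known limitation of this
algorithm family and is left visible.

**Synthetic MRI.** Concentric equal-width rings with strictly increasing
class means (default 0.2/0.4/0.6/0.8, outermost darkest), corrupted by a
smooth multiplicative bias field `1 + A·cos(πx/2)cos(πy/2)` (intensity
inhomogeneity) and additive zero-mean Gaussian noise (default variance 0.02),
clipped to [0, 1]; ground truth is the pre-corruption label map. It emulates
exactly the two confounders the method targets and nothing else — no MR
physics (k-space, Rician noise, partial-volume mixing), no anatomy. Passing
tests on it demonstrate noise/inhomogeneity robustness of the clustering
machinery, not clinical segmentation quality.

**Noise convention.** "x % Gaussian noise" is read as zero-mean Gaussian
with variance x/100 on the [0, 1] scale (the `imnoise` convention); the
variance is an explicit parameter so any other reading can be run. Noise is
added *after* normalization and the result clipped to [0, 1], which keeps
all distance computations on the normalized scale; clipping does fold the
background noise distribution at 0, which measurably shifts its mean
(≈ +0.04 at variance 0.01).

## The phantom benchmark and its honest limits

`run_phantom_benchmark` (and `scripts/acceptance.py`) runs all four drivers
on the noisy 256×256 phantom over 10 seeds (noise and initialization seeds
spawned from one base seed; all algorithms share each seed's noisy image and
initial partition). Measured mean overall accuracies at variance 0.01:
csIFCM 0.762 > csFCM 0.760 > FCM 0.702 > IFCM 0.696 — the expected ranking,
with the spatial variants ~6 points ahead and the plain intuitionistic lift
slightly *behind* FCM, the same ranking the published phantom table shows.

The absolute values are bounded by physics, not implementation: at variance
0.01 (σ = 0.1) the adjacent class levels (0 ↔ 0.2 ↔ 0.3) are only 1–2 σ
apart, and assigning every noisy pixel to its *nearest true class level* —
an upper bound for any pixelwise intensity rule — already caps accuracy at
0.744. A 3×3 spatial average could in principle push further (≈ σ/3 for
interior pixels), but in this weighting the pixel's own membership enters w
with total exponent p+q = 3 against the neighborhood's q = 2, so strongly
corrupted pixels are not overridden. Published figures in the 0.90–0.96
range for this benchmark are therefore only reachable under a much smaller
effective noise level and/or a different (undefined) ground-truth
quantization; this package keeps the stated conditions and reports what they
actually produce.

Problem sizes used throughout: 256×256 for the benchmark (10 seeds,
~25 s total), 96×96 for noise-free recovery checks, 10×10 random fixtures
(100 trials) for the brute-force oracle comparisons.

## Evaluation details

Matching is optimal one-to-one assignment (Hungarian) on the c×c contingency
table — greedy matching would be order-dependent. Metrics are one-vs-rest
per ground-truth segment after matching: Dice ρ, fpr and fnr normalized by
the ground-truth segment size (fpr is deliberately *not* clipped at 1), TPR
= TP/|S1|, and FPR with denominator N (negatives) by default — the printed
FP/P variant in parts of this literature conflicts with the standard
definition, so it is available behind `fpr_denominator="positives"`. The
"true positive ratio" column equals 1 − fnr identically. Empty ground-truth
segments yield NaN metrics rather than errors. Overall segmentation accuracy
is the fraction of pixels whose matched label equals the truth over *all*
pixels.
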