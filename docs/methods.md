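# Methods

## Model and procedure

All metrics are functionals of 256-bin intensity histograms (0–255) of the
pixels selected by an ROI; spatial arrangement never enters. For a
histogram with probabilities `p_i`, Shannon entropy is
`H = -Σ p_i log2 p_i` bits, with `0·log 0 = 0`, so `0 ≤ H ≤ 8` for 8-bit
data. Channel-specific entropies `H_R, H_G, H_B` feed the derived metrics

```
Δ(X−Y) = |H_X − H_Y|          (raw deltas, per ROI)
Aᴿ     = (H_G + H_B)/2 − H_R  (signed)
Iᴾ     = (Δ(R−G) + Δ(R−B) + Δ(G−B)) / 3
```

and every metric (channel means, SDs, entropies, deltas, Aᴿ, Iᴾ, plus
grayscale/composite entropy) is normalized as lesional − perilesional.
Normalized deltas are kept **signed** (lesional |Δ| minus perilesional
|Δ|), and because the mean is linear, the normalized Iᴾ equals both the
difference of the two raw Iᴾ values and the mean of the signed normalized
deltas — so a lesion whose channel divergence is *smaller* than its
surrounding skin's gets a negative normalized Iᴾ. This is the only reading
under which a benign reference can print a negative normalized index, and
it is the one implemented.

Assumptions: 8-bit-per-channel input; the perilesional ROI is drawn from
clinically normal skin contiguous to the lesion under the same
illumination (it is a baseline, not a second lesion); ROIs are supplied by
the user (mask images or polygons) — no automatic segmentation.

## Conversion conventions

Published histogram tools differ in their grayscale dialect, so both are
explicit:

- `unweighted_mean` (default): per-pixel `(R+G+B)/3`, round-half-up, in
  exact integer arithmetic.
- `itu601_weighted`: `0.299·R + 0.587·G + 0.114·B`, round-half-up.

The composite "RGB histogram" is, by default, the histogram of the
per-pixel unweighted channel mean — bit-identical to the unweighted
grayscale plane. That identity is deliberate: it is the mechanism by which
global grayscale and composite-RGB entropies agree on any image, i.e. why
global entropy is blind to chromatic structure. An alternative `stacked`
dialect (bin-wise sum of the three channel histograms, total count 3n) is
available by flag; it is *not* blind in the same way and is provided for
comparison only.

Polygon ROIs use 0-based pixel coordinates, even-odd fill, and include a
pixel when its center lies in the closed polygon (boundary centers
included). This is pinned so masks are bit-reproducible. Overlapping
lesional/perilesional masks are tolerated with a logged warning since
manual masks may touch; the analysis itself does not require disjointness.

## Statistics conventions

- SD uses the population formula (divide by n).
- Skewness is `m3/σ³`; kurtosis defaults to raw `m4/σ⁴` with an excess
  (−3) option. Both are NaN (serialized as null) for constant ROIs.
- All computation is at full precision; only report writers and the
  table-verification harness round (half-away-from-zero to the printed
  decimals).
- Residual percentages between two lesions use
  `residual / |reference| × 100` and are undefined (null, never 0) when
  the reference is zero; they inflate whenever the benign reference
  approaches zero, so they are reported, not interpreted.

## Printed-table verification

The worked example's printed values are vendored in
`polychromia.reference_tables` and every reproducible cell is re-derived
from its own printed inputs (`polychromia verify-tables`). Three classes
of cells are excluded as irreproducible from their printed inputs and are
documented in that module: the per-ROI red-asymmetry row (computed
upstream from unrounded entropies), one residual-percentage cell that does
not follow from its own row, and the per-ROI delta scale versus the
normalized-table delta scale, which disagree by two orders of magnitude
and are therefore verified only as separate internally-consistent systems,
never chained. Integer residual percentages are accepted within one
percentage point because the source's rounding of those cells is neither
exactly half-up nor truncation.

## Synthetic scene generator

Each scene is an elliptical lesion on a skin background with a
perilesional elliptical ring, every region sampling per-channel Gaussian
mixtures. Inter-channel coupling uses one shared standard-normal latent
per pixel mixed with independent per-channel draws
(`z = ρ·z_shared + √(1−ρ²)·z_own`); the mixture component is selected from
one shared uniform per pixel, so `ρ = 1` with identical per-channel specs
yields bit-identical planes. Values are rounded then clipped to [0, 255];
clipped mass accumulates at the extremes, which is negligible for the
presets (component means sit well inside the range). Scenes are
deterministic functions of their config including the seed.

Preset constants (frozen):

| parameter | nevus | melanoma |
|---|---|---|
| scene | 160×160 px, ellipse semi-axes 45×34 at center, ring width 14 | same |
| skin (shared) | single component per channel, means (182, 152, 128), sd 6 | same |
| lesion | one component per channel, means (95, 78, 70), sd 8 | three components per channel, channel-specific means 55–205, sds 12–30 |
| coupling ρ | 0.95 | 0.3 |

The nevus preset emulates a chromatically uniform pigmented lesion
(narrow, unimodal, correlated channels → normalized metrics near zero);
the melanoma preset emulates polychromia (broad, multimodal, decorrelated
channels → large normalized Iᴾ). The scene size and the 100-paired-seed
ensemble used in tests and in `scripts/acceptance.py` were chosen as the
smallest sizes at which the preset statistics are stable (the full
ensemble renders in a few seconds).

What the generator does **not** emulate: skin texture, illumination
gradients, specular highlights, camera noise and compression, hair, or the
irregular borders of real lesions. Passing the synthetic suite shows that
the metrics separate the two chromatic regimes the presets encode, not
that they separate real melanomas from real nevi; the printed-table
checks, conversely, verify the arithmetic of the published worked example
but rest on two lesions only.

## Numerical choices and degenerate inputs

- Entropy via `scipy.stats.entropy(counts, base=2)`; tests cross-check
  against an independent per-pixel summation oracle at 1e-12.
- Empty ROIs, shape mismatches, non-8-bit inputs and invalid scene
  geometry raise typed errors; an alpha channel is dropped with a warning.
- Grayscale rounding for the unweighted mean is exact integer
  `(2s+3) // 6`, avoiding float ties.
- Report JSON is written with sorted keys so identical inputs give
  byte-identical output.

## Known limitations

- Two-ROI, single-image design: no cohort statistics, no diagnostic
  thresholds, no ROC analysis — the metrics are descriptive.
- RGB only; no HSV/Lab chromaticity spaces.
- The Iᴾ scale depends on ROI size through histogram sampling noise:
  smaller ROIs have noisier channel entropies and hence inflated raw
  deltas. Perilesional normalization compensates only partially when the
  two ROIs differ greatly in size.
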