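# Methods

## Design geometry

A 60-nt barcode is tiled by probes of length 25 at offsets 0, 7, 14, 21,
28, 35 (six probes, TP1–TP6). Coordinates are 0-based half-open; probes are
stored as reverse complements of the barcode top strand so that the reverse
complement of a probe recovers its window verbatim (the round-trip tests
rely on this fixed orientation; the simulator is orientation-agnostic
because it addresses probes by ID). Two windows at offsets a, b share
max(0, 25 − |a − b|) nt: 18/11/4/0/0 for the canonical step series. When
(L − 25) mod 7 = 0 the union of windows covers the barcode exactly.

Half-hairpin probes are the reverse complement of the 21-nt shRNA stem,
optionally extended to 25 nt by the reverse complement of the first 4 nt of
the common mir-30 flank appended at the probe 3′ end. The stem is used as
given in the manifest; whether the sense or antisense stem strand is the
appropriate hybridization target is a convention of the manifest, not
something the package infers.

A layout places, per subarray: 6 tiling probes × 3 replicates per construct
(18 features/barcode), plus 4 half-hairpin replicates when a stem is
present; negative-control constructs (barcodes absent from every pool)
contribute their tiling and half-hairpin probes in triplicate. The chip has
8 subarrays of identical content. Probe IDs are
`{construct}:TP{k}:r{rep}:s{subarray}` — stable and parseable. The
simulator and the quantifier operate on the canonical subarray-1 feature
set and pair test/reference features by probe identity; the abstraction is
that each sample is hybridized to one subarray of identical probe content.

## Signal model

Expected feature signal: `f(affinity × abundance) + background_residual`,
with `f` the identity or, when a surface capacity smax is set, the Langmuir
form `f(x) = smax·x/(smax + x)`.

* **Affinities** are log-normal with median 1 and log-scale
  `affinity_sigma` (default 1.0 — probe-to-probe signals spanning roughly
  two orders of magnitude at ±2σ, i.e. "very different hybridization
  properties" between tiling probes of one barcode). Log-affinities of two
  tiling probes from the same barcode are correlated with coefficient
  `overlap_rho × shared_nt/25`; the triangular overlap kernel is positive
  semi-definite, so mixing it with the identity gives a valid correlation
  matrix for any `overlap_rho ∈ [0, 1]` (default 0.6). Replicate features
  and subarray copies of a probe share one affinity: affinity is a property
  of the probe sequence.
* **Noise** is per-feature multiplicative log-normal with unit mean and
  coefficient of variation `noise_cv` (default 0.2), so sample means
  converge to expected signals. Positive-valued intensities with roughly
  constant CV are the standard working assumption for array data.
* **Background residual** — what remains after the instrument's local
  background subtraction — is additive half-normal with scale
  `background_level` (default 20 raw units). It is what the negative
  controls measure and what the k-fold thresholds cut.
* **Scale.** Screens use `abundance_scale = 1000` (expected t_zero signal
  of a median-affinity probe; genomic-DNA input, mid-range of a CCD
  readout). Dilution experiments default to `abundance_scale = 1e5`:
  plasmid PCR pools are high-input material, and resolving a 1e-2 dilution
  requires the full-scale signal to sit well above the background residual.
  With these defaults the 10-fold threshold removes a few percent of
  probes in a screen — enough to exercise the filter cascade without
  dominating it.

Engineered pools follow the seven-subpool dilution scheme: subpool-0 stays
equimolar in every pool; subpools 1–6 carry per-pool factors between 9e-1
and 1e-6 across three test pools. Negative selection multiplies a
construct's t_end abundance by 2^(log2_effect); affinities are shared
between the paired t_zero/t_end samples of every replicate, so in the
linear regime they cancel from the ratio exactly.

What the generator does **not** emulate: PCR amplification bias (the
self-annealing of half-hairpin sequences can be mimicked by lowering their
affinities, not mechanistically), viral titer/MOI/copy-number arithmetic,
spatial artifacts, and probe-level cross-hybridization between different
barcodes (barcodes are random and treated as orthogonal). Passing tests
therefore demonstrate correctness of the decoding cascade under the stated
noise model, not performance on any particular real array platform.

## Decoding cascade

1. **Per-sample median normalization** first (each sample divided by its
   own median signal), so thresholds are comparable across subarrays.
2. **Median background** per sample from negative-control features (probes
   of constructs absent from every pool).
3. **Detection threshold**: a feature passes iff signal > k × median
   background, strictly — ties fail. k = 4 for plasmid-pool references,
   k = 10 for the t_zero screen reference, which buys the dynamic range
   needed to quantify depletion.
4. **Ratios**: per probe and experiment, replicate features whose
   *reference* signal passed the threshold are averaged within each sample,
   then one log₂(test/reference) ratio is formed. Test signals are floored
   at 1 raw intensity unit per feature before averaging (the floor is
   rescaled through the normalization), so empty test pools give finite,
   very small positive ratios instead of −∞. Averaging signals before the
   ratio (rather than averaging per-feature ratios) is the more robust
   choice under the floor rule and is fixed here.
5. **Subpool-0 renormalization** (dilution experiments): every linear ratio
   of an array is divided by the mean linear ratio of subpool-0 constructs
   on that array (median selectable); the subpool-0 mean is exactly 1
   afterwards.
6. **Filtering**: a probe survives only with ≥ 4 of the at most 9
   underlying replicate signal ratios (3 features × 3 replicate
   experiments); a construct is reported only with ≥ 2 surviving probes
   ("more than one tiling probe"). Half-hairpin detection requires ≥ 3 of
   4 replicate features above threshold ("more than two replica"). Every
   exclusion is logged with a reason; included + excluded partition the
   input set. Because replicate features collapse to one ratio per
   (probe, experiment), the per-(probe, experiment) contributing feature
   count is carried alongside the ratio and the four-of-nine rule
   thresholds on its sum.
7. **Aggregation**: per-probe mean over experiments, per-construct mean
   over surviving per-probe means.

The dilution summary reports, per engineered factor: mean and standard
deviation of the linear ratios (σ left blank for n < 3), the count of
analyzable (construct, pool) observations, and a two-sided p against the
equimolar group — by default a moderated two-sample t on the log₂ scale
(group variances shrunk with the same prior fit, Welch–Satterthwaite df
augmented by the prior df), with a plain Welch t selectable. Which of the
two the original analysis used is not determinable; both are exposed.

## Moderated statistics

The probe-level linear model with a t_end-vs-t_zero contrast is
implemented in its paired-equivalent form: a one-sample moderated t on the
per-probe log₂ ratios of each construct. Hyperparameters (d₀, s²₀) come
from a closed-form method-of-moments fit on log s²_g — digamma-corrected
means and a trigamma inversion solved by Newton iteration — with no
optimization loop. When the observed spread of log variances does not
exceed what sampling alone predicts, d₀ = ∞ and every posterior variance
equals the mean observed variance (complete shrinkage); forcing d₀ = 0
recovers the ordinary one-sample t exactly. Constructs with fewer than two
ratio values are skipped and logged; an all-zero variance set is an error.

BH adjustment is delegated to statsmodels' `fdr_bh` and cross-checked in
the tests against an independent sort/cummin/unsort oracle. Hits are
constructs with negative mean log₂ and significance below α = 0.05;
BH-adjusted p is the default scale with raw p selectable, since a fixed
"p < 0.05" rule is ambiguous between the two.

## Diagnostics

Correspondence analysis uses the standard χ² decomposition: proportions P,
standardized residuals (P − rcᵀ)/√(rcᵀ), SVD, and **symmetric principal
coordinates** for both rows and columns (both clouds scaled by the singular
values) — the variant that supports plotting barcodes and probes in one
projection with the centroid at the origin. Total inertia × grand total
equals Pearson's χ², which the tests verify against a brute-force loop.
Which CA normalization the original software used is not stated anywhere;
symmetric scaling is this package's documented choice.

Position correlation: pairwise-complete squared Pearson correlations of
per-position log₂ ratios across constructs (pairwise-complete because the
filter cascade leaves ragged missingness), grouped by overlap class —
Δ7→18 nt (5 pairs), Δ14→11 nt (4), Δ21→4 nt (3), Δ28/Δ35→0 nt (3). With
saturation on, per-probe affinity no longer cancels from the t_end/t_zero
ratio, so overlap-correlated affinities produce an overlap-ordered r²
pattern mechanistically; with saturation off and shared affinities the
ratios are affinity-free and the pattern flattens. The package's
acceptance-style checks therefore use the linear regime for exact recovery
and the saturating regime for the correlation pattern, as two separate
study conditions.

## Problem sizes and seeds

The test suite runs on synthetic data generated at import-free fixture
time: 50-construct dilution pools for exact recovery (abundance scale 1e9
so that even 1e-6 dilutions stay above the 1-unit floor), 100-construct
pools at noise_cv 0.2 for stochastic recovery, a 100-construct screen with
10 constructs depleted 4-fold for recall/FDR, a 300-construct saturating
screen for the correlation diagnostics, 500 × 9 null draws for type-I
calibration, and 1e5 barcodes for the affinity-correlation Monte Carlo.
These sizes give sub-percent Monte-Carlo error on every asserted quantity
while keeping the whole suite in a few seconds. All randomness flows
through explicitly seeded `numpy` generators; identical scenario + seed
reproduces bit-identical tables, and `run_pipeline` embeds no timestamps
so reruns are checksum-identical.

## Known limitations

* Cross-hybridization between distinct barcodes is not modeled, so the
  detection-rate figures of real arrays (where probe sequences were not
  pre-screened) are outside the simulator's reach.
* The background residual is homoscedastic across features; real local
  backgrounds are spatially structured.
* The moderated two-sample variant used in the dilution summary augments
  Welch df by the prior df as a pragmatic approximation; its calibration
  is adequate for ranking dilution steps but it is not a published exact
  reference distribution.
* Saturation uses one global smax; per-probe capacities would blur, not
  remove, the qualitative compression and correlation effects.
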