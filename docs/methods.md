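# Methods

## Statistical kernel

All inference reduces to four primitives implemented in
`thermoconn.statcore` and reused everywhere:

- **Fisher r-to-z**: z = arctanh(r). Correlations at ±1 (possible on
  short synthetic series) are clipped to ±(1 − 10⁻⁷) so z stays finite
  without perturbing realistic values.
- **Student t-tests**: one-sample t = (x̄ − μ₀)/(s/√n), df = n − 1;
  two-sample *pooled-variance* t with df = n₁ + n₂ − 2. The pooled
  (equal-variance) form is used rather than Welch because the study's
  group comparisons report n₁ + n₂ − 2 degrees of freedom (17 + 15 − 2 =
  30). p-values come from the exact t CDF (`scipy.special.stdtr`), not a
  normal approximation — sample sizes are small throughout.
- **Benjamini–Hochberg FDR**: step-up rule, rejecting the k* smallest
  p-values where k* = max{k : p₍ₖ₎ ≤ k·q/m}. Rejection is decided on
  that comparison directly rather than on `adjusted_p ≤ q`, because the
  two differ in the last floating-point ulp for grid-valued p (e.g.
  p = 0.1, k/m = 3/6, q = 0.2). Adjusted p-values use the standard
  monotone reverse-cummin construction. Ties are handled by stable sort.
- **Pearson correlation** with p from t = r√(n−2)/√(1−r²), df = n − 2.

## Temporal preprocessing

Order: discard the first 10 volumes → per-region linear detrend →
ideal band-pass → confound regression. The band-pass is a pure
frequency mask on the real FFT (retain bins with low ≤ f ≤ high, zero
everything else including DC), with no padding or tapering — the
deterministic frequency-mask approach of the resting-state toolkits
this replicates. Spectral leakage from the finite series is accepted
and documented. Nuisance regressors are *not* themselves band-passed
before regression (the source procedure is silent; this is the simpler
default). Subject exclusion fires on max |translation| > 1 mm or
max |rotation| > 1° — strict inequalities, so a subject exactly at
threshold is retained.

For the synthetic regional pipeline the confound set is an intercept,
the six realignment parameters, and the global (across-region) mean
signal. White-matter and CSF signals have no analogue in region-level
synthetic data and are therefore absent; with real voxel data they
would enter the same `ConfoundSet` interface.

## Seed maps and cluster correction

Grids are axis-aligned (world = index · voxel_size + origin); no
oblique affines, which synthetic fixtures do not need. Gaussian
smoothing is separable with σ = FWHM/(2√(2 ln 2)) per axis, reflective
boundaries (mass-conserving). Cluster connectivity defaults to 26
(faces + edges + corners), the AFNI-family convention, configurable to
6 or 18. Voxel thresholding is two-tailed (|t|), since both increased
and decreased coupling are of interest; suprathreshold voxels are
split by sign before labeling so each cluster has a direction. Peak =
maximum |t| in the cluster, ties broken by lexicographically smallest
voxel index.

The Monte Carlo extent threshold fills the mask with white Gaussian
noise, smooths to the target FWHM, standardizes within the mask,
thresholds two-tailed at the voxel p, and records the maximum cluster
size; the returned extent is the smallest k whose exceedance fraction
is below α. Standardizing the simulated field within the mask makes
the z-unit threshold equivalent to the p-based threshold applied to
data. The 30-voxel extent on a 3 mm grid (810 mm³) can either be taken
as a fixed operating point or recomputed per mask by the simulation;
both paths are supported.

## Dual-criterion edge inference

Criterion (1) — edges significantly nonzero "within the group" — is
anchored, by default, to *at least one* group, with each group's
4005-edge family FDR-corrected separately. Requiring both groups would
structurally exclude exactly the edges a stressor destroys (present in
controls, abolished under heat), contradicting the phenomenon of
interest; a strict `both` mode exists for sensitivity analysis.
Criterion (2) is BH-FDR over the between-group family. The two
families are corrected independently, never jointly. Edges with
non-finite values or zero variance in either group are dropped from
all families with a logged count.

The per-subject altered-edge count N_alt is *not* defined in the
source literature; the implemented surrogate counts finding edges on
which a subject's z deviates from the control mean by more than 1.96
control SDs in the finding's direction. The multiple is a parameter.
Correlations of N_alt with outcomes therefore test the package's own
operationalization, and no claim is made that they reproduce any
particular published coefficient.

## Synthetic-data generator

The generator's defaults are the study conditions: 200 volumes at
TR = 2 s (10 discarded downstream → 190 analyzed), 90 regions, 15 HT
vs 17 NC analyzed subjects, signal band 0.01–0.08 Hz, base inter-region
correlation 0.2. Group differences are planted on the Fisher-z scale
(z_base + Δz, mapped back through tanh) because that is the scale on
which inference happens; the default recovery set is ten edges at
|Δz| = 0.5, seven decreases and three increases, mirroring the
preponderance of connectivity losses under heat stress. The target
correlation matrix is repaired to the nearest positive semi-definite
correlation matrix by eigenvalue clipping at zero followed by
re-normalization to unit diagonal — simple and deterministic.

Regional signals are built by frequency-masking white noise into the
band, re-standardizing, and mixing through the symmetric square root
of the group covariance, then adding a per-region linear drift
(slope ~ N(0, 0.005) per volume) and white noise (SD 0.3, about 9% of
signal variance). This guarantees in-band energy like filtered
resting-state data. Voxel fixtures live on a 26×31×26 grid at 3 mm
(origin −36, −90, −24 mm — a posterior-medial MNI-like bounding box
that contains the PCC/PCu seed): sphere and block voxels share a
band-limited latent time course plus unit noise, groups differ only in
the block's coupling, and each volume is smoothed to 4 mm FWHM.

ANT trials follow the 3 cue × 2 target design, 36 trials × 6 runs =
216 per subject, balanced within run. RTs are log-normal
(σ_log = 0.15) around the condition mean — positive skew with no
negative values, as empirical RT distributions show — truncated at the
2000 ms deadline with truncated trials flagged as non-responses.
Condition means compose from three effects: no-cue = center + alerting,
spatial = center − orienting, incongruent = congruent + executive. The
default group difference is a +40 ms executive shift (between-subject
SD 30 ms); in the orchestrated pipeline each HT subject's executive
cost additionally tracks their standardized N_alt with a 22.5 ms/SD
slope, which produces a population brain-behavior correlation near
0.6 — an emulation of the kind of coupling the analysis is designed to
detect, not a reproduction of any measured value.

Physiology draws pre/post rectal temperature and weight marginals at
the emulated group moments (HT post 37.87 ± 0.27 °C, weight loss
0.51 ± 0.18 kg; NC stable). Pre/post values are drawn independently —
only group-level moments are emulated, not within-subject
correlation, so per-subject ΔT dispersion is wider than a repeated-
measures design would give. Motion tables are small-amplitude random
walks (step SD 0.015, clipped at ±0.6) with designated subjects given
a 1.5 mm translation excursion so they trip the exclusion rule.

All generators are pure functions of `(seed, stream...)` tuples via
`numpy.random.SeedSequence`; identical arguments give bit-identical
output regardless of execution order.

### What the generator does not emulate

No hemodynamic response function, no cardiac/respiratory noise, no
motion spike artifacts coupled into the signal, no spatial
autocorrelation structure beyond Gaussian smoothing, Gaussian
covariance only (no heavy tails or nonstationarity). Passing recovery
tests therefore demonstrates that the *inference machinery* is correct
under its assumptions — not that the pipeline is robust to every
artifact of real scanner data.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to make the
statistical checks meaningful while staying fast: planted-edge
recovery aggregates 20 simulated studies (each 32 subjects × 190
retained volumes × 90 regions) and null calibration 50; the Monte
Carlo cluster threshold uses 1000 iterations on the 26×31×26 fixture
grid; permutation cross-checks use 20 000 draws; voxel-map recovery
uses 6 subjects per group at T = 100. The orchestrated pipeline's
voxel stage defaults to 6 subjects per group and 300 Monte Carlo
iterations, all configurable.

## Known limitations

- The altered-edge count definition is a documented surrogate (above).
- The ideal band-pass assumes the series length as given; very short
  series (< 3 cycles of the low band edge) trigger a warning, not an
  error.
- AlphaSim-style correction is the only cluster inference offered; no
  Gaussian-random-field, TFCE, or permutation cluster options.
- Anatomical labeling of cluster peaks and atlas-aware region names are
  out of scope; records carry coordinates and integer region ids only.
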