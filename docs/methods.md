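# Methods

## Problem and approach

A network of fixed air-quality stations records pollutant concentrations and
meteorological variables every hour. The question a duty forecaster or
source-tracing analyst actually asks is not "which variables are correlated
over the whole archive" but "which variable, and which neighbouring station,
is most strongly associated with the object pollutant *right now*". dynagra
answers this with a rolling correlation analysis whose two ingredients are:

1. an **entropy-adaptive sliding window** that lengthens when recent data are
   smooth and shortens when they fluctuate, and
2. **grey relational analysis (GRA)**, a grey-system similarity score on the
   geometric closeness of (normalised) curves, yielding a correlation degree
   in (0, 1].

Both are recomputed at every hour, producing a correlation-degree time
series per pair instead of a single static number.

## Adaptive window

At time t, the L0 most recent valid values of the object series strictly
before t form the decision segment d_1..d_L0 (default L0 = 10; the method
requires L0 ≥ 10). With segment mean m:

- fluctuation scalars: z_i = |d_{i+1} − d_i| / |m| (i = 1..L0−1). The
  magnitude of the mean is used so the scalars stay nonnegative for signed
  (e.g. anomaly-scale) inputs; if m = 0 the raw |Δd| are used instead, which
  preserves the ordering of fluctuations without a division blow-up.
- fluctuation probabilities: p_i = z_i / Σz. A constant segment (Σz = 0) has
  no change distribution; it is flagged degenerate and treated as maximal
  smoothness: L = Lmax.
- entropy and proportion: H = −Σ p_i log2 p_i, s = H / log2(L0),
  with stability thresholds s_min = min p_i and s_max = max p_i. The
  reference entropy log2(L0) is used as stated by the method even though
  only L0−1 probabilities exist, so s < 1 strictly.
- decision: L = L0 if s_min < s < s_max; L = round(L0/s) if s ≥ s_max
  (even change spread → lengthen); L = round(s·L0) if s ≤ s_min
  (concentrated change → shorten). Boundary equalities are assigned to the
  non-identity branches so the point-mass case (H = 0, s = 0) always
  shortens. L is rounded half-up (window lengths are counts) and clamped
  into [Lmin, Lmax]; defaults Lmin = 10 and Lmax = 10% of the series length
  (floored at L0 so short panels remain analysable).

The correlation itself is then computed on the trailing L values ending at
and **including** t, while the decision segment **excludes** t. This
alignment is the only one under which (a) the first computable time point is
t = L0 + 1 and (b) a fixed window equal to the whole series length
reproduces the static whole-period degree exactly. At the earliest time
points the decided L may exceed the available history; the window is then
truncated to the points that exist and the record carries the effective
length.

The window is decided from the object series alone (`window_mode: object`).
A pairwise-maximum mode (`pairwise_max`) is available; the station-matrix
computation always uses the pairwise maximum so the matrix is symmetric by
construction.

## Grey relational analysis

Sequences are min–max scaled onto [0, 1] independently within the analysis
window before comparison (initial-value scaling and no scaling are available
by config). Min–max was chosen because the GRA deviation statistics are
range-sensitive and the scaling gives the coefficient the floor
ρ/(1+ρ) whenever the minimum deviation is 0. A constant sequence, whose
scaling is 0/0, maps to the mid-range value 0.5. Normalisation happens
per window, matching the recurrence (a global variant is a config switch).

With deviations Δ_k(i) = |y(i) − x_k(i)| and two-level extrema Δmin, Δmax
taken over **all** comparison sequences,

    ξ_k(i) = (Δmin + ρ·Δmax) / (Δ_k(i) + ρ·Δmax),   r_k = mean_i ξ_k(i),

with resolution ratio ρ = 0.5 by default (the conventional choice; exposed
as a flag, 0 < ρ < 1). If Δmax = 0 every comparison equals the reference and
r = 1, the natural limit.

**Pairwise vs joint scoring.** Because ξ depends only on Δ/Δmax, the
single-pair degree is invariant to rescaling of the deviations: a pair with
small, noise-shaped deviations and a pair with large, noise-shaped
deviations score alike. Consequently the pairwise degree separates *shape*
but is nearly blind to coupling *strength*. With several comparison
sequences the extrema are shared, deviations compete on one scale, and the
degrees order candidates by how closely each tracks the reference. The
variable engine therefore scores its candidate set jointly (and this is the
mode used for per-time ranking and parameter recovery), while the point
engine defaults to pairwise scoring so that a station's degree does not
depend on which other stations were requested (`joint=True` opts in to
shared extrema). The cross-station matrix uses the pairwise form for the
same set-independence reason.

## Contrast methods

- **static** — one whole-period GRA degree per pair. GRA rather than Pearson
  keeps the baseline on the same (0, 1] scale as the dynamic methods
  (Pearson via `estimator="pearson"`).
- **FSW-GRA** — the same recurrence with the window frozen at a fixed
  length; default 24 h, the conventional daily window for hourly
  air-quality data.
- **ASW-PC** — Pearson partial correlation on the adaptive window. Computed
  by inversion of the joint correlation matrix; when that matrix is exactly
  singular because the object or associated series is a linear combination
  of the controls (e.g. a control equal to their sum), the equivalent
  residual-regression definition is used, which remains well defined there.
  Collinearity among the controls themselves raises a degeneracy error
  naming the offending pair. Windows shorter than (number of controls + 3)
  are skipped with a logged warning. When no controls are given it reduces
  to rolling Pearson correlation.

## Missing data

Gaps are explicit NaNs on a complete hourly grid. The decision segment uses
the L0 most recent *valid* object values. The correlation window spans L
calendar hours; rows missing in any involved series are dropped, and the
step is skipped with a logged warning when more than `max_gap_fraction`
(default 10%) of the window is lost, or fewer than two rows remain.

## Synthetic scenarios

The generator emulates a nine-station grid (a central station plus eight
satellites at 500–1000 m with known bearings) over 240 hourly points —
a ten-day study period — with five variables: a source pollutant, two
coupled pollutants, an independent nuisance pollutant and a meteorological
driver. Structure:

- source S(t): AR(1) with coefficient 0.8 and unit innovations, plus a
  diurnal sinusoid and a slower multi-day component whose amplitude/phase
  differ per season template (summer/winter/spring);
- satellite copies of the source: α_p·S(t − lag_p) + local AR(1) noise
  (coefficient 0.5, innovation sd `noise_sd`, default 0.3 — mild relative
  to the source's marginal sd of about 2);
- coupled variables: β_v·S(t − lag_v) + local AR(1) noise, attenuated by
  α_p away from the centre;
- nuisance: independent AR(1); meteorological driver: phase-shifted diurnal
  sinusoid + noise;
- optional regime switch: the station coupling map is replaced from a given
  hour onward, with the ground truth recorded in the panel metadata.

All randomness flows through one seeded generator; a scenario is fully
reproducible from its seed. The generator is a statistical stand-in, not an
atmospheric model: it has no advection, no wind-driven transport, no
chemistry, and its couplings are linear and instantaneous-plus-lag. Passing
tests therefore demonstrate that the machinery recovers known statistical
structure (coupling order, change points, smoothness contrasts), not that it
resolves real plume dynamics.

## Evaluation instruments

- **Fluctuation entropy of a degree series** applies the window pipeline's
  scalar→probability→entropy chain to a whole correlation-degree series and
  normalises by log2(len−1), giving a score in [0, 1]. A high score means
  the series' changes are spread evenly through time (persistently
  dynamic); a low score means change concentrates in a few jumps. A
  constant series is degenerate and scores 1 by convention (documented
  here because the opposite convention is equally defensible; the score is
  only used comparatively). On regime-switch scenarios the adaptive-window
  GRA scores higher than the fixed-window variant in ~95% of seeds — the
  comparative ordering of the two GRA methods is the claim the package
  tests; orderings involving the partial-correlation contrast are not
  asserted.
- **Deviation from static**: per-time dynamic degree minus the whole-period
  static degree, with mean and max-|·| summaries. On stationary scenarios
  the mean deviation stays within ±0.1 of zero.
- **Ranking at a time point**: candidates sorted by degree, ties broken
  lexicographically by (station, variable) id — ties are vanishingly rare
  in practice but the rule keeps output deterministic.

## Problem sizes

Tests and the acceptance script run on 240-hour panels (the ten-day study
design) with 50–100 seed replicates for the stochastic claims; each
replicate takes well under a second, so the ensembles are cheap and their
pass thresholds (95% rank recovery, 80% entropy ordering, |mean deviation|
< 0.1) were fixed together with the generator defaults.

## Known limitations

- The pairwise degree's strength-blindness (above) is a property of the
  relational coefficient, not an implementation artifact; rankings should
  use joint scoring.
- Single imputation-free gap policy: windows with heavy gaps are skipped
  rather than interpolated.
- No spatial weighting: distances/bearings are metadata for interpretation
  only.
- The entropy reference log2(L0) (instead of log2(L0−1)) slightly biases
  s downward; it is kept for fidelity to the method's definition and only
  shifts the lengthen-branch threshold marginally.
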