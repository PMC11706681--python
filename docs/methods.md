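# Methods

This note documents the models, conventions and defaults behind
`rootmitosis`, the choices made where several were defensible, and what the
synthetic experiments do and do not show about real imaging data.

## Data model

An event table holds one row per detected division: root identifier,
condition label, frame index, and the event's 3D centre of mass in absolute
micrometres. The frame index is authoritative; time in hours is always
recomputed as `frame_index * delta_t_h` (default 0.25 h — one stack every
15 minutes). The first imaged frame is taken as t = 0 of the experiment
(for regenerating roots, the excision time); the package does not model any
lag between perturbation and the start of imaging.

There is no persistent anatomical landmark across frames in this kind of
recording, so absolute coordinates are never interpreted; only relative
distances within a frame are used. Temporal bins for post-perturbation
analyses are half-open — [0, 6), [6, 24), [24, 72), [72, ∞) hours — so
every non-negative time belongs to exactly one bin; a time of exactly 6 h
falls in the 6–24 h bin.

## Burst statistics

A burst is a frame whose count is at least one standard deviation above the
mean of the reference series, and its size is that frame's count. Three
conventions are deliberate and configurable:

* **Pooling scope** (default per condition): the threshold is computed on
  the pooled per-frame counts of all roots of a condition, giving one
  threshold per condition. Per-root thresholds are available
  (`pooling="per-root"`).
* **SD flavour**: sample standard deviation (n−1), the default of the
  mainstream statistics stacks this field uses.
* **Comparison operator**: inclusive (count ≥ threshold). Frames with zero
  events are never bursts, so a degenerate threshold of 0 marks exactly the
  non-empty frames.

### Poisson null for burst sizes

Two related tools are provided and kept distinct on purpose.

`mode_matched_poisson(mode)` is the classical *display* overlay: the
Poisson whose most probable value equals the observed burst-size mode. Any
rate in [mode, mode+1) has that mode; the midpoint λ = mode + ½ is used.

`fit_poisson_tail` + `compare_to_poisson(..., min_size=threshold)` is the
*test*. A burst-size sample is, by construction, the ≥-threshold tail of
the count distribution. Comparing it against an untruncated Poisson
therefore rejects essentially always — the null puts mass below the
threshold where the sample cannot — regardless of whether the underlying
counts are Poisson. That rejection is a thresholding artifact, not
evidence of correlated divisions. The well-posed question is "could these
burst sizes be the tail of a single Poisson?", answered by a
truncated-Poisson maximum-likelihood fit on the burst support and a
discrete one-sample K-S statistic with the null renormalised to that
support. Calibration on synthetic data (100 seeds): series that *are*
Poisson pass at α = 0.01 in ≥95% of seeds, while series with injected
bursts (2% of frames, ~20 extra events) are flagged in ≥90%. The p-value
uses the asymptotic Kolmogorov distribution and is conservative for
discrete data and fitted parameters — conservatism that works in favour of
not over-calling structure.

## Periodogram

The spectral stage is a plain FFT periodogram: mean removal, no window, no
averaging, one-sided density normalisation on the native Fourier grid of
the record. This is the minimal defensible reading of "standard spectral
analysis"; Welch averaging or tapering would trade bias for variance and
are intentionally not defaults. Two consequences matter for interpretation:

* **Parseval**: Σ PSD·Δf equals the variance of the mean-removed series to
  1e-8 relative tolerance; this is asserted on every tested input.
* **Grid resolution**: a 168-h record resolves periods only at 168/k h. A
  true 16-h modulation falls exactly between the k = 10 (16.8 h) and k = 11
  (15.27 h) bins; the reported top period is the grid neighbour that wins
  the leakage split. Tests therefore compare against a closed-form DFT
  oracle rather than assuming which neighbour wins.

Peaks are local maxima of the PSD (DC excluded), sorted by descending
power. `white_noise_threshold` gives the Bonferroni-corrected level
`mean(PSD) · ln(M/α)` that the maximum of M exponential white-noise
ordinates exceeds with probability ≤ α; peaks below it should not be
reported as periodicities. When a condition has several roots, per-root
PSDs are averaged on the shared grid (the convention is recorded in the
analysis metadata); computing on concatenated or summed series are
alternatives the data do not adjudicate.

Gapped series are not supported: the grid must be complete (zero-filling
with a warning is the documented workaround; a Lomb–Scargle variant would
be the principled extension).

## Spatial clustering

Events are clustered frame by frame — never across frames, since nothing
identifies "the same place" in consecutive frames — with DBSCAN on
Euclidean distance in raw micrometres. The radius is derived from tissue
geometry rather than tuned: a division is modelled as a 6 × 4 × 4 µm
cuboid cell with maximum diagonal √68 ≈ 8.24 µm, and ε is three cell
diameters. The default uses the printed-rounding chain 3 × 8.24 = 24.72 µm
exactly; the unrounded 3·√68 ≈ 24.7386 µm is one call away
(`epsilon_from_diameter(ARABIDOPSIS_CELL.diameter, 3)`) and differs by
<0.1%.

`min_samples = 2` (the count includes the point itself) is the default:
it makes DBSCAN exactly the connected-components clustering of the
ε-neighbourhood graph, i.e. "events within three cell diameters of each
other belong to one cluster", with no core/border asymmetry. Singletons are
noise, not size-1 clusters, and are excluded from size distributions and
centres of mass. Labels are canonical (numbered by first member's input
index), so the labelling is permutation-stable; for `min_samples > 2`
border points are attached deterministically to the first claiming cluster
in index order, the one genuinely order-dependent corner of DBSCAN.

Cluster centres are unweighted member means; pairwise centre distances are
computed within frames and pooled across frames within a temporal bin for
distribution comparisons.

## Two-sample comparisons

The K-S statistic is the exact supremum of the ECDF difference over the
union of sample points (count data are heavily tied; evaluating anywhere
else understates D). The p-value evaluates the asymptotic Kolmogorov
distribution at √(n₁n₂/(n₁+n₂))·D; an exact option exists for
n₁·n₂ ≤ 10 000. Reports flag samples with >50% ties, where the asymptotic
p is approximate. No multiple-testing correction is applied; the number of
performed comparisons is reported so users can apply their own. Verdict
wording: p < 0.001 "highly significant", p < 0.01 "significant",
p < 0.05 "marginally significant". Cells with fewer than 3 values on
either side are reported as insufficient data, not tested. Per-frame count
samples are pooled across the roots of a condition (concatenated per-root
frame vectors); this convention is recorded in the report.

Type-I calibration: over 2 000 null simulations at n₁ = n₂ = 100 the
asymptotic test rejects at α = 0.05 between 3% and 7% of the time.

## Synthetic generator

The generator exists so that every stage has a ground truth. Temporal:
counts at frame t are Poisson with rate
λ(t) = λ_base·(1 + A·cos(2π·tΔt/P)), plus, with per-frame probability
`burst_rate`, an extra Poisson(`burst_size_mean`) increment. Both burst
parameters may switch values at `burst_onset_h`, so an effect can appear
only after a chosen time while the pre-onset process stays identical to a
control — the construction used to emulate a late-onset regeneration
effect. Spatial: a Thomas process per frame — parents uniform in a box,
max(1, Poisson(µ)) offspring per parent until the frame's budget is spent,
isotropic Gaussian displacement σ, clipped to the box. Temporal and
spatial processes are independent; real tissue presumably couples them,
and no such coupling is injected (a documented limitation). The box
domain (not a root-shaped cylinder) is adequate because only relative
distances are analysed; clipping instead of rejection keeps event counts
exact and its bias is negligible for σ ≪ domain.

Default study conditions (chosen once to mirror the qualitative structure
of intact vs regenerating recordings): 672 frames at 0.25 h; λ_base = 4
(count mode 3–4); intact bursts 5% of frames with ~10 extra events
throughout, and a 24-h modulation of amplitude 0.3 (an entrained light
cycle); regenerating identical before 24 h, then 20% burst frames with ~14
extra events, and a 16-h modulation of amplitude 0.5. Spatially σ = 4 µm
and 3 events per cluster on average (clusters of 2–4) in a 120 µm box.

Seeding: a global seed expands into per-root substreams keyed by
(seed, condition, root ordinal); identical seeds give bit-identical tables
and adding roots never perturbs existing ones.

### What the synthetic experiments show — and don't

Parameter-recovery results (injected period recovered as top peak; DBSCAN
cluster counts tracking multi-offspring parents within 20%; Poisson vs
bursty burst-size discrimination; the late-onset divergence pattern across
temporal bins) validate the *analysis machinery* under the generator's
assumptions: Poisson noise, frame-independent positions, well-separated
clusters in the recovery regime. They do not validate segmentation or
tracking (out of scope), nor guarantee the same power on real data, where
baseline drift, heavier-tailed bursts and space–time coupling are all
plausible. In particular, the spatial recovery experiment deliberately
uses a sparse 400 µm domain: with parents packed closer than ε (as in the
dense 120 µm default box), neighbouring clusters merge and no clustering
method can recover parent counts — a resolution limit, not an algorithmic
one.

## Numerical notes

* Event files round-trip byte-exactly: floats are written shortest-repr
  and parsed with a correctly rounded parser.
* All outputs of a run are byte-deterministic given (input, config, seed);
  timestamps exist only in `run_meta.json`.
* Degenerate inputs: empty tables are an explicit error for analysis, an
  empty labelling for clustering; constant series give a threshold equal to
  the constant and an all-zero PSD; zero-variance samples are rejected by
  the KDE with a pointer to histograms.
* The KDE uses Gaussian kernels with Scott's-rule bandwidth on a grid
  spanning the sample range ± 3 bandwidths.
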