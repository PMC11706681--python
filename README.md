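# rootmitosis

Spatiotemporal statistics of cell-division (mitotic) events in time-lapse
imaging of plant root tips — built for comparing proliferation dynamics
between **intact** and **regenerating** *Arabidopsis* roots, where a
tracking pipeline has already reduced each division to a 3D centre of mass
and a frame index (typically one image stack every 15 minutes for up to
7 days).

It is a library first: import it, feed it an event table (CSV/TSV with
`root_id, condition, frame_index, x_um, y_um, z_um`), and get burst
statistics, periodograms, spatial clusters and condition comparisons. A
thin `rootmitosis` CLI wraps the simulate → analyse → compare workflow, and
`examples/` holds one short narrative script per capability.

## What it computes

For per-root count series *n(t)* (divisions per frame):

* **Bursts** — a burst is a frame with *n(t)* ≥ mean + 1 SD of the series
  (pooled across the roots of a condition by default); its size is *n(t)*.
* **Poisson null** — if divisions were independent, burst sizes would be the
  tail of a Poisson count distribution. The package provides the classical
  mode-matched overlay (λ = mode + ½) and a well-posed tail test: a
  truncated-Poisson maximum-likelihood fit on the burst support plus a
  discrete one-sample Kolmogorov–Smirnov statistic.
* **Periodogram** — plain FFT power spectral density of the mean-removed,
  unwindowed series, reported against period in hours, satisfying Parseval's
  identity (Σ PSD·Δf = variance); peak extraction with a Bonferroni-corrected
  white-noise significance level.

For event positions (µm, per frame):

* **DBSCAN clustering** with a geometry-derived radius: a division event is
  modelled as a 6 × 4 × 4 µm cuboid cell of diameter √68 ≈ 8.24 µm, and
  ε = 3 diameters = 24.72 µm with `min_samples = 2`, which makes the
  clustering exactly the connected components of the ε-neighbourhood graph
  (singletons are noise).
* **Cluster summaries** — per-frame cluster counts, size distributions,
  centres of mass and pairwise centre distances.

Between conditions:

* **Two-sample K-S tests** (tie-correct ECDF supremum; asymptotic Kolmogorov
  p with effective n = n₁n₂/(n₁+n₂), exact option for small samples) for
  events per frame, burst sizes and centre distances, in the pooled window
  and the post-perturbation bins 0–6 h, 6–24 h, 24–72 h and >72 h.

A synthetic generator (`rootmitosis.synthetic`) produces full study tables —
Poisson baseline + burst episodes + optional sinusoidal modulation in time,
a Thomas (Neyman–Scott) cluster process in space — with ground-truth
bookkeeping, so every stage is testable without imaging data.

## Worked example

```python
from rootmitosis import run_comparisons
from rootmitosis.synthetic import intact_defaults, regenerating_defaults, simulate_table

table = simulate_table(intact_defaults(1), regenerating_defaults(1), 4)
report = run_comparisons(table)
print(report.to_text())
```

prints (abridged):

```
window   metric                   D          p    n1    n2  verdict
all      events_per_frame     0.133   3.93e-21  2688  2688  highly significant (ties>50%)
0-6h     events_per_frame     0.083      0.893    96    96  not significant (ties>50%)
6-24h    events_per_frame     0.059      0.697   288   288  not significant (ties>50%)
24-72h   events_per_frame     0.158   1.05e-08   768   768  highly significant (ties>50%)
>72h     events_per_frame     0.155   1.93e-16  1536  1536  highly significant (ties>50%)
```

Read: the simulated regenerating roots share the intact dynamics for the
first 24 h (large p in the first two bins), then develop an excess of
large division bursts, so the per-frame count distributions diverge
(vanishing p from 24 h on) — a late-onset transition rather than an
immediate wound response. The D column is the maximum ECDF separation; the
ties flag marks heavily tied count samples where the asymptotic p is
approximate.

More examples: `examples/burst_statistics.py`, `examples/periodicity.py`
(recovers a 16-h modulation as the top periodogram peak, 16.8 h on the
168-h Fourier grid), `examples/spatial_clusters.py`,
`examples/condition_comparison.py`, `examples/cli_pipeline.sh`.

## Command line

```bash
rootmitosis simulate --seed 1 --roots 4 --out out/sim
rootmitosis analyse --events out/sim/events.csv --out out/analysis
rootmitosis compare out/sim --out out/comparison
```

`analyse` writes a bundle of re-readable CSVs (counts, bursts, periodogram,
clusters, centre distances) plus `summary.json` and `run_meta.json`
recording every effective convention (ε, min_samples, pooling scope, SD
flavour, spectral options).

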