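"""Burst detection and the Poisson null on a simulated count series.

Simulates one root's per-frame division counts, computes the burst
threshold (mean + 1 SD of the whole series), lists the bursts, and asks
whether their sizes could be the tail of a single Poisson — the signature
question for deciding whether divisions are temporally uncorrelated.
"""

import math

import numpy as np

from rootmitosis import FrameSeries, compare_to_poisson, detect_bursts, simulate_counts
from rootmitosis.synthetic import intact_defaults
from rootmitosis.temporal import burst_threshold, fit_poisson_tail, mode_matched_poisson

cfg = intact_defaults(seed=1)
series = FrameSeries("intact_1", "intact", simulate_counts(cfg), cfg.delta_t_h)

threshold = burst_threshold(series)
bursts = detect_bursts(series, threshold)
print(f"threshold = mean + 1 SD = {threshold:.2f} events/frame")
print(f"{len(bursts)} bursts; largest: {bursts.sizes.max()} divisions in one frame")

# classical overlay: Poisson with the same mode as the burst sizes
mode = int(np.bincount(bursts.sizes).argmax())
overlay = mode_matched_poisson(mode)
print(f"mode-matched Poisson overlay: lambda = {overlay.lam} (mode {overlay.mode})")

# well-posed test: are the burst sizes consistent with a Poisson tail?
m = math.ceil(threshold)
null = fit_poisson_tail(bursts.sizes, m)
cmp_ = compare_to_poisson(bursts.sizes, null, min_size=m)
print(f"truncated-Poisson MLE lambda = {null.lam:.2f}")
print(f"one-sample K-S vs Poisson tail: D = {cmp_.d_stat:.3f}, p = {cmp_.p_value:.3g}")
print("-> large p: bursts are what a noisy Poisson baseline already produces;")
print("   small p: burst sizes carry structure beyond independent divisions.")
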