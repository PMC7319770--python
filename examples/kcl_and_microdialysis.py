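"""Depolarization (KCl puff) responses and in vivo microdialysis normalization.

First quantifies a slow synthetic KCl-evoked dopamine response over the
standard window (from the start of the 10 s puff to 200 s after it). Then
normalizes a microdialysis time series to the mean concentration of its
76th-120th minute reference window and prints the natural-log copy used for
statistics on lognormal dopamine levels.
"""

import math

import numpy as np

from dopaquant.traces import Trace, kcl_response, normalize_microdialysis

# --- KCl puff: slow exponential response, known analytic integral -----------
rate = 100.0  # Hz is ample for a tens-of-seconds response
t = np.arange(int(240 * rate)) / rate
tau = 30.0
response = np.where(t >= 10.0, 2.0 * np.exp(-(t - 10.0) / tau), 0.0)
trace = Trace(response, rate, 0.0, "uM")
peak, auc = kcl_response(trace, puff_start_s=10.0, puff_duration_s=10.0)
analytic = 2.0 * tau * (1 - math.exp(-210.0 / tau))
print(f"KCl response: peak {peak:.3f} µM, AUC {auc:.2f} µM·s "
      f"(analytic {analytic:.2f})")

# --- microdialysis: 15-min fractions, normalized to the 76-120 min window ---
rng = np.random.default_rng(5)
times = np.arange(15.0, 241.0, 15.0)
baseline = np.exp(rng.normal(math.log(2.0), 0.15, times.size))   # ~2 nM, lognormal
baseline[times > 120] *= 0.33                                    # TTX drops levels
series = list(zip(times, baseline))
normalized, log_copy = normalize_microdialysis(series, reference_window_min=(76, 120))
pre = np.mean([v for tm, v in normalized if tm <= 120])
post = np.mean([v for tm, v in normalized if tm > 120])
print(f"normalized dopamine: pre-TTX mean {pre:.2f}, post-TTX mean {post:.2f} "
      f"({post / pre:.2f} of baseline)")
print(f"log-scale copy: first fraction {log_copy[0][1]:+.3f}, "
      f"last fraction {log_copy[-1][1]:+.3f} (log_e of normalized values)")
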