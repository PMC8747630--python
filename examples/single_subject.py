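"""Simulate one mild-AD subject preparing tea and print the text report.

The report shows the six KTA component scores (0 = independent, 1 = needed
verbal clues, 2 = needed physical assistance, 3 = not capable), the 0-18
total, and the three memory-problem counters: how often the subject forgot
an item (omission), confused it with the designated similar item, or
confused it with something else (commission).
"""

import numpy as np

from adlsim import build_activity, default_profile, report_single, score_trace, simulate_subject

activity = build_activity("tea")
profile = default_profile("cdr1")

rng = np.random.default_rng(7)
trace = simulate_subject(activity, profile, rng)
score = score_trace(trace, activity)

print(report_single(trace, score))
print()
print("Event log (one line per attempt):")
print(trace.to_jsonl())
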