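"""Refit the per-CDR presets from scratch (scaled-down demonstration).

The shipped presets in adlsim/data/profiles.yaml are calibration outputs:
per level, the retrieval threshold is placed on a first-attempt success
anchor and the behaviour utility gap is grid-searched until a simulated
cohort's mean KTA total matches the reference mean.  This demo uses a small
evaluation cohort (n=300) so it runs in ~15 s; the shipped presets were
produced with n=1000 (see docs/methods.md).
"""

from adlsim import LEVELS, calibrate, default_search_spec, load_reference_means

spec = default_search_spec()
spec.coarse_points = 13
spec.refine_rounds = 2
spec.refine_points = 7
spec.n_threshold_fit = 5000

result = calibrate(load_reference_means(), activity="tea", n_per_eval=300,
                   search_spec=spec, seed=1)

print(f"{'level':8s} {'threshold':>10s} {'utility gap':>12s} {'target':>8s} {'achieved':>9s}")
for level in LEVELS:
    p = result.profiles[level]
    print(f"{level:8s} {p.threshold:10.3f} {p.gap_for('default'):12.2f} "
          f"{result.targets[level]:8.2f} {result.achieved_means[level]:9.2f}")
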