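"""Backfit a recording and extract the temporal microstate parameters.

Every sample is assigned to the template of maximal absolute spatial
correlation; maximal constant-label runs become microstate segments, from
which mean duration (ms), occurrence (1/s), coverage (%) and the
observed/expected transition percentages are computed.
"""

import numpy as np

import eegstates as es

cfg = es.GeneratorConfig(n_channels=32, sampling_rate=250.0, duration=120.0,
                         noise_sigma=0.0, mean_segment_duration=80.0, seed=4)
rec, gt = es.simulate_subject(cfg)
epochs = es.epoch(es.rereference_average(rec), 2.0)
templates = es.TemplateSet(maps=gt.templates, channel_names=rec.channel_names)

seg, params, table = es.segment_and_parameterize(epochs, templates)

print("class  duration(ms)  occurrence(/s)  coverage(%)")
for k, name in enumerate("ABCD"):
    print(f"  {name}    {params.duration_ms[k]:10.1f}  {params.occurrence_per_s[k]:12.2f}"
          f"  {params.coverage_pct[k]:10.1f}")
print(f"coverage sums to {params.coverage_pct.sum():.6f}% (identity)")
print(f"GEV of the labelling: {params.gev_total:.4f} "
      "(1.0 on noise-free data backfit with the generating maps)")
print("observed transition percentages (rows: from, cols: to):")
print(np.round(table.observed_pct, 1))
print("expected under segment-label independence:")
print(np.round(table.expected_pct, 1))
print("durations sit near the configured 80 ms; deviations reflect the "
      "geometric segment-length law, not estimation bias.")
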