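"""Segment a synthetic 50 Hz deployment and extract the six dive variables.

Renders one deployment as raw sensor streams, downsamples depth to 5 Hz,
detects dives (0.5 m departure, >= 1 m maximum, interpolated crossings),
drops the first five minutes, and computes the per-dive feature table.
"""

import divehmm
from divehmm import srkw
from divehmm.features import SensorRecord, build_feature_table
from divehmm.segmentation import detect_dives, downsample_depth, exclude_initial

cfg = srkw.reference_config(seed=7, dives_per_deployment=(80, 80))
cfg.deployments = cfg.deployments[:1]
rec = divehmm.generate_deployment_signals(cfg, srkw.reference_emissions())[0]

sensor = SensorRecord(rec.deployment_id, rec.sample_rate, rec.time_s,
                      rec.depth_m, rec.acc, rec.heading_deg, rec.roll_deg)
series = downsample_depth(sensor.depth_series(), 5.0)
dives = exclude_initial(detect_dives(series))
table = build_feature_table(dives, sensor, rec.clicks,
                            {"sex": cfg.sex[rec.deployment_id],
                             "age_class": "adult", "year": 2012})

print(f"record: {rec.time_s[-1] / 3600:.2f} h at {rec.sample_rate:.0f} Hz")
print(f"dives detected: {len(dives)} (of {len(rec.truth)} constructed; "
      "those starting in the first 300 s are excluded)")
print(table[["dive_index", "duration_s", "max_depth_m", "jerk_peak",
             "roll_med_deg", "heading_var", "buzz", "slow_click"]]
      .head(8).to_string(index=False))

# Each row is one dive: jerk peak is computed over the bottom phase
# (>= 70% of max depth), everything else over the whole dive; the buzz and
# slow-click flags come from inter-click-interval rules (<= 10 ms, > 100 ms)
# within click bouts.
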