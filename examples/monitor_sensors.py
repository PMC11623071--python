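"""Sensor gating and actuation on synthetic greenhouse streams.

Generates a drying-soil moisture stream and a CO2 stream with dropouts and
outliers, cleans them, and shows the pump/fan decisions with the exact
switch points.
"""

from plantwatch import monitor_stream
from plantwatch.synthetic import StreamSpec, make_sensor_stream

moisture = make_sensor_stream(
    StreamSpec("moisture", duration_s=60, base=32.0, drift_per_s=-0.4, seed=1)
)
co2 = make_sensor_stream(
    StreamSpec(
        "co2", duration_s=60, base=35.0, drift_per_s=0.6,
        jitter_sigma=1.0, dropout_prob=0.05, outlier_prob=0.03, seed=2,
    )
)

result = monitor_stream(moisture + co2)
print(
    f"readings: {result.cleaned.n_input}, dropped "
    f"(missing or out of physical range): {result.cleaned.n_dropped}"
)

last = {}
for d in result.decisions:
    if last.get(d.device) != d.state:
        state = "ON " if d.state else "OFF"
        print(f"t={d.timestamp:5.0f}s  {d.device:12s} -> {state}  ({d.trigger})")
        last[d.device] = d.state

# The pump turns ON when moisture first drops to 20 % (the low-pass gate's
# boundary); the fan turns ON once CO2 reaches 50 ppm.  Missing samples and
# impossible values never actuate anything.
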