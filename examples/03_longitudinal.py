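"""Track a speaker's language profile over time.

Builds a longitudinal descriptor series from repeated assessments of one
speaker, prints the age / A / R / Q table, and renders both the overlaid
radar chart and the Q-over-age line graph (SVG files in example_output/).
"""

from pathlib import Path

from voxplp import (
    AxisValues,
    PlotSpec,
    RadarConfig,
    SpeakerRecord,
    longitudinal_series,
    render_q_timeseries,
    render_radar,
    save_figure,
)

# biannual assessments: the repertoire grows and becomes more balanced
assessments = [
    ("3:04", AxisValues(tact=4, mand=1, echoic=1, sequelic=1)),
    ("3:10", AxisValues(tact=6, mand=4, echoic=4, sequelic=4)),
    ("4:05", AxisValues(tact=9, mand=8, echoic=8, sequelic=8)),
    ("4:11", AxisValues(tact=12, mand=10, echoic=12, sequelic=8)),
    ("5:05", AxisValues(tact=12, mand=12, echoic=12, sequelic=12)),
]

config = RadarConfig(property_radius=12)
series = longitudinal_series(
    assessments, config, speaker=SpeakerRecord(speaker_id="example-child")
)
frame = series.to_frame()
print(frame.round(2).to_string(index=False))
print("\nThe repertoire expands (A rises) and ends perfectly balanced (R = 0),")
print("so the first moment Q rises at every assessment.")

out = Path("example_output")
out.mkdir(exist_ok=True)
spec = PlotSpec(profiles=tuple((age, v) for age, v in assessments))
save_figure(render_radar(spec, config), out / "longitudinal_radar.svg")
save_figure(render_q_timeseries(series, baseline_end="3:04"), out / "q_over_age.svg")
print(f"\nwrote {out}/longitudinal_radar.svg and {out}/q_over_age.svg")
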