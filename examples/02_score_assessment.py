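"""Score a VOX assessment matrix and test functional independence.

Uses the bundled single-round assessment of a 3-year-old boy with ASD:
six speaker-selected response forms probed under each of the four operant
conditions.  Column totals become the radar axis values; Cochran's Q asks
whether emission rates genuinely differ across the conditions.
"""

from voxplp import RadarConfig, describe, operant_totals, related_samples_test
from voxplp.fixtures import assessment_dataset

dataset = assessment_dataset()
print(dataset.response_matrix().to_string())

totals = operant_totals(dataset)
print(f"\noperant totals: {totals.as_dict()}")

# C = 6: six response forms, so at most six emissions per operant condition
d = describe(totals, RadarConfig(property_radius=6))
print(f"area A = {d.area:.2f}, R = {d.centroidal_distance:.2f}, Q = {d.first_moment:.2f}")

res = related_samples_test(dataset)
print(
    f"\nCochran Q = {res.statistic:.4f}, df = {res.df}, p = {res.p_value:.4f}"
)
if res.significant(0.05):
    print("Emission rates differ across operants at the .05 level: the")
    print("repertoire is disproportionate (here: strong tact/echoic, weak mand/sequelic).")
else:
    print("No significant differences across operants: a balanced repertoire.")
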