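"""Compare language profiles across speakers.

Contrasts the bundled cross-sectional descriptor records: a child with a
minimal single-quadrant profile (tact and sequelic only) against a
neurotypical peer with a large, balanced profile, one month apart in age.
"""

from voxplp import compare_profiles
from voxplp.fixtures import cross_speaker_records

records = {r["speaker"].speaker_id: r for r in cross_speaker_records()}
for sid, rec in records.items():
    d = rec["descriptors"]
    sp = rec["speaker"]
    print(
        f"{sid}: age {sp.age_label}, A = {d.area:7.2f}, "
        f"R = {d.centroidal_distance:.2f}, Q = {d.first_moment:8.2f}"
    )

cmp = compare_profiles(
    records["child-C"]["descriptors"], records["child-D"]["descriptors"]
)
print(f"\nchild-C minus child-D: dA = {cmp.delta_area:.2f}, dQ = {cmp.delta_first_moment:.2f}")
print("Nearly the whole property space separates these two repertoires —")
print("one needs explicit conditioning of distinct operants, the other is on track.")
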