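# voxplp

Polygonal language profiles: radar-chart shape descriptors for verbal
operant assessment data.

## What problem this addresses

A verbal operant experimental (VOX) analysis probes the same
speaker-selected verbal responses under four pure sources of stimulus
control — **tact** (labeling, evoked by a present nonverbal stimulus),
**mand** (requesting, evoked by the absence of a wanted stimulus),
**echoic** (vocal imitation, point-to-point correspondence with a verbal
stimulus) and **sequelic** (answering, verbal stimulus without
correspondence) — and records emission (1) or non-emission (0) of each
response under each condition. Practitioners working with children with
autism and other language disorders use such assessments to ask whether a
repertoire is *proportionate* across sources of control, because
disproportionate operant strength is thought to block the emergence of
untrained verbal relations.

`voxplp` turns the binary response matrix of such an assessment into a
**polygonal language profile (PLP)**: the per-operant totals are plotted on
the four half-axes of a radar chart (echoic on +x, mand on +y, sequelic on
−x, tact on −y) and joined into a closed polygon. The quadrant between two
adjacent axes represents convergent multiple control by that pair of
operants; the share of the polygon lying in each quadrant quantifies it.

## The descriptors

For axis values $v_1,\dots,v_n$ on $n$ evenly spaced axes (vertices
$(x_i, y_i)$, one per axis):

- **Area** $A = \tfrac12 \sin(2\pi/n)\sum_i v_i v_{i+1}$ (cyclic) — for the
  4-axis chart this is the quadrant base-times-height sum
  $\tfrac12\sum |x_i||y_{i+1}|$ and equals the shoelace area of the
  vertices. The maximal total area $\tilde A$ over all axis orderings is
  found by brute-force enumeration of the $(n-1)!/2$ distinct cyclic
  orders.
- **Centroid** $(\bar x, \bar y)$ with
  $\bar x = \sum A_i x_i / \sum A_i$, $\bar y = \sum A_i y_i / \sum A_i$,
  from the decomposition of the polygon into origin-anchored triangles
  (one per adjacent-axis pair, triangle centroids at signed coordinates).
  A perfectly balanced repertoire has its centroid at the origin.
- **Centroidal distance** $R = \sqrt{\bar x^2 + \bar y^2}$ — imbalance of
  the repertoire ("restricted stimulus control" when large).
- **First moment of area** $Q = A\,(C - R)$, where $C$ is the radius of
  the circle circumscribing the *property space* (the largest attainable
  profile; instrument-specific and always supplied explicitly).

The package also provides Cochran's Q as the related-samples test of
functional independence of the operants (asymptotic $\chi^2_{k-1}$
reference or a seeded within-row permutation test), longitudinal
descriptor series, cross-speaker profile comparison, a seeded synthetic
assessment generator, and deterministic SVG radar/time-series rendering.

## Worked example

```python
from voxplp import RadarConfig, describe, AxisValues

values = AxisValues(tact=12, mand=10, echoic=12, sequelic=8)
d = describe(values, RadarConfig(property_radius=12))
print(d.area, d.centroid, d.centroidal_distance, d.first_moment)
```

Running `python examples/01_worked_profile.py` prints:

```
axis values      : {'tact': 12, 'mand': 10, 'echoic': 12, 'sequelic': 8}
area A           : 220.00
centroid         : (1.33, -0.67)
centroidal dist R: 1.4907
first moment Q   : 2312.04   (C = 12)
quadrant areas   : (60.0, 40.0, 48.0, 72.0)
quadrant shares  : {'Q1': 0.273, 'Q2': 0.182, 'Q3': 0.218, 'Q4': 0.327}
```

The profile covers 220 square axis-units; its centroid sits 1.49
axis-units from the origin toward quadrant 4, so tact–echoic convergence
is the repertoire's greatest source of strength and mand–sequelic its
weakest. Scoring the bundled six-response assessment matrix
(`examples/02_score_assessment.py`) gives operant totals (tact 5, mand 2,
echoic 5, sequelic 1) and Cochran Q = 8.0526 (df 3, p = 0.0449): emission
rates differ across operants at the .05 level.

The other examples cover longitudinal series, cross-speaker comparison
and the power of the independence test; each prints what its numbers
mean. A thin CLI wraps the same library:

```sh
voxplp simulate --seed 5 --out trials.csv
voxplp compute trials.csv -C 6
voxplp test trials.csv
voxplp plot trials.csv -C 6 --out radar.svg
```

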