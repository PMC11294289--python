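# Methods

## The model

A VOX assessment yields a binary matrix: rows are speaker-selected
response forms (at least three per session in a complete assessment),
columns the four operant conditions (tact, mand, echoic, sequelic), cells
emission (1) or non-emission (0). Column totals are the axis values of one
polygonal language profile (PLP).

The radar chart is a Cartesian plane whose half-axes carry the operants.
The canonical orientation — echoic +x, mand +y, sequelic −x, tact −y — is
fixed by the semantics of the quadrants: Q1 (between echoic and mand) is
echoic∧mand convergence, Q2 mand∧sequelic, Q3 sequelic∧tact, Q4
tact∧echoic. The two perpendicular continua are intraverbal control
(echoic–sequelic, the x axis) and extraverbal control (mand–tact, the y
axis).

All descriptors derive from the decomposition of the PLP into
origin-anchored triangles, one per adjacent-axis pair:

- triangle area `A_i = |x_i·y_{i+1} − x_{i+1}·y_i| / 2`; for axes at 90°
  this is `v_i·v_{i+1}/2` (base times height over two);
- triangle centroid = mean of its three vertices at *signed* coordinates;
- polygon area `A = Σ A_i = ½·sin(2π/n)·Σ v_i·v_{i+1}` (cyclic);
- polygon centroid = area-weighted mean of triangle centroids, which for a
  star-shaped polygon about the origin (always the case for non-negative
  axis values) equals the true polygon centroid and the shoelace/Green's
  theorem centroid;
- centroidal distance `R = ‖centroid‖`;
- first moment of area `Q = A·(C − R)` against the property-space radius
  `C`.

The area formula is implemented as the adjacent-product sum rather than a
literal transcription of the stacked-fraction notation sometimes used to
typeset it; the two agree on every worked example and the product-sum
generalizes cleanly to n axes.

### The property radius C

`C` is the maximum attainable value on any axis — an instrument property
(e.g. number of response forms × rounds), not a property of the data. It
is therefore a **required, explicit configuration value with no default**.
The bundled descriptor tables are all mutually consistent with `C = 12`
(solving `Q = A(C − R)` for `C` in each of the nine rows gives 12 to
within rounding), so the fixtures expose `inferred_property_radius() ==
12.0`; that inference is documented, not hard-coded into the library.
Values exceeding `C` trigger a warning by default (`radius_policy="error"`
upgrades it); a centroid outside the property circle (`R > C`) is rejected
unless `permissive=True`, which returns a negative Q with a warning.

### Axis-ordering search

The maximal total area `Ã` is found by enumerating all `(n−1)!/2` cyclic
orderings up to rotation and reflection (brute force, capped at n = 10;
n = 4 has only 3). Ties break toward the ordering lexicographically
closest to canonical in normal form (first axis fixed, direction chosen),
so the canonical order is returned whenever it attains the maximum —
which it does in all bundled examples. `ordering_mode="canonical"`
(default) keeps semantic axis positions and merely reports `Ã`;
`"maximize"` re-orders the axes before computing descriptors.

### Degenerate profiles

An all-zero profile has `A = 0`; its centroid and `R` are reported as
`None` (undefined, not zero) and `Q = 0` under any convention. A
single-quadrant profile (two adjacent nonzero axes) is valid: it is one
triangle of the decomposition.

### Aggregation over sessions

Multi-session assessments can be scored as raw summed frequencies
(default) or per-session means; reported non-integer areas in archival
tables suggest mean-type aggregation is in real use, so both are explicit
options (`aggregation="sum" | "mean"`), never a silent choice.

## The independence test

The related-samples comparison of emission percentages across the four
conditions is Cochran's Q,

    Qc = (k−1) · (k·ΣC_j² − N²) / (k·N − ΣR_i²),

with `C_j` condition totals, `R_i` response-row totals, `N` the grand
total, referred to χ² with `k−1` df. Rows that are all-0 or all-1 are
uninformative and provably leave the statistic unchanged; if *every* row
is constant the statistic is undefined (0/0) and the result carries
`degenerate=True` with p = 1. Because single-round assessments are tiny
(often 3–6 rows), a seeded within-row permutation test is provided as an
exact-style alternative (`method="permutation"`); the test suite checks
that it converges to the asymptotic p-value on larger matrices (60 rows,
tolerance 0.02). The significance threshold defaults to .05 and is a
parameter, not a constant. The literature names the test family rather
than a specific statistic; Cochran's Q is the standard such test for
binary related samples, and the statsmodels implementation serves as an
independent cross-check in the tests, never as the implementation.

## Synthetic data

`generate_synthetic(SyntheticSpec(...))` emulates exactly the structure of
a real assessment table: `n_responses` forms × 4 conditions ×
`n_sessions`, each cell an independent Bernoulli draw with a per-operant
emission probability, from a seeded `numpy` generator (identical seed ⇒
identical dataset, byte-stable through the CSV writer). Defaults are six
response forms, one session, probabilities (0.8, 0.3, 0.8, 0.2) — a
disproportionate tact/echoic-dominant repertoire of the kind the
assessment is designed to flag. What it does **not** model: within-row
dependence beyond the marginal rates (real responses probed under four
conditions are correlated within a form), session-order and carryover
effects, and prompting hierarchies. Passing tests on synthetic data
therefore demonstrate correctness of the scoring and descriptor
machinery, not clinical validity of the assessment itself.

Problem sizes used in the test suite were chosen to keep every check
sharp at desk scale: 1,000 random profiles for the shoelace equivalence,
50,000 Monte-Carlo points for the centroid cross-check, exhaustive
enumeration of orderings up to n = 6 and of all 2×4 binary matrices for
the test statistic, and 100 seeded replicates of n = 1000 assessments for
the power check.

## Numerical choices

- Axis unit vectors snap components below 1e−12 to zero so quarter-turn
  vertices are exact (`(12, 0)`, not `(12, 6e−16)`).
- All computation is double precision; rounding to 2 decimals happens only
  at the reporting layer (human-readable CSV, printed summaries). The JSON
  descriptor format keeps full precision and round-trips exactly.
- Scaling: multiplying all axis values by k scales A by k², centroid and R
  by k. Q is **not** scale-equivariant unless C is rescaled too — C is an
  instrument constant, so comparing Q across instruments requires equal C
  (enforced by `compare_profiles`).
- Reported descriptor rows whose printed Q was evidently computed from
  unrounded internal values are flagged in the fixtures
  (`q_divergent=True`); consistency tests on those cells allow 0.5 slack
  on top of the printed-input rounding band, and the ambiguously typeset
  area row is flagged `area_inferred=True`.

## Visualization

Charts are drawn on a plain Cartesian plane (not matplotlib's polar axes)
so polygon edges are straight lines, with a shared linear scale whose
maximum is C — the property circle then circumscribes the plot. The
centroid marker "c" appears only for single-profile charts; overlays
suppress it, and exceeding the overlay limit (default 5, encoding the
readability guidance for radar charts) logs a warning rather than failing.
SVG output is byte-deterministic for fixed input (pinned hash salt, no
date metadata, text kept as text elements) and is the structurally tested
format; PNG export is provided for convenience.

## Known limitations

- The geometry assumes non-negative axis values on evenly spaced axes;
  profiles are star-shaped about the origin by construction, and no
  attempt is made to handle self-intersecting or free-form polygons.
- Higher-order descriptors (moment of inertia, convexity, compactness,
  variance) are deliberate extension points, not implemented.
- The asymptotic χ² reference for Cochran's Q is anti-conservative at very
  small n; prefer the permutation method below ~10 informative rows.
- Clinical interpretation (treatment selection, prompt hierarchies) is out
  of scope: the package quantifies profiles, it does not recommend.
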