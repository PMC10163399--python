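# Methods

## Data model

A formula is an ordered, duplicate-free list of herb identifiers with a
subset flagged as principal herbs (Junyao).  Herb identity is exact
Pinyin-string equality; no normalization merges prepared and raw forms of
the same plant (Gancao vs. Zhigancao).  Any merging rule would amount to
invented pharmacology, so the distinction is preserved even though it
means, e.g., that Bazhentang is *almost* but not exactly the union of
Sijunzitang and Siwutang in the shipped fixture.  Formulas without a
flagged principal herb are accepted with a warning (so plain set systems
can be laid out); they group last in the icicle plot under a sentinel
bucket and contribute no top-level principal.

Herb attributes form a 23-column binary schema in fixed order: Siqi
(cold, hot, warm, cool, calm), Wuwei (pungent, sweet, sour, bitter,
salty, tasteless, astringent), Guijing (liver, heart, spleen, lung,
kidney, bladder, large intestine, small intestine, stomach, gallbladder,
pericardium meridians).

The shipped fixture covers seven classic tonic formulas (31 herbs).  Its
attribute table is hand-curated from standard materia-medica properties
and is *synthetic* in the sense that it is not an export of any attribute
database; it exists so that every stage of the pipeline is runnable and
testable from the repository alone.

## Embedding and distances

Herb similarity is computed in a 2D projection of the attribute vectors,
not in the raw 23-dimensional space: projected distances are what the
reader of the herb map perceives, and raw Hamming-like distances between
sparse binary vectors are heavily tied and harder to compare visually.

The default projector is UMAP with `n_neighbors=5`, `min_dist=0.3`,
Euclidean metric, `random_state=seed` (default 42).  No hyperparameters
are sacred here; the values are chosen for herb sets of roughly 30–80
points (small enough that a local neighborhood of 5 is meaningful) and
are recorded in config and logs.  Each formula group is embedded
separately — attribute geometry is only used *within* a group, and
cross-group color or position comparisons are not meaningful.

UMAP with a fixed `random_state` is deterministic for a fixed library
version but not across versions, so a fully deterministic linear fallback
(`method="pca"`) is provided: the first two principal axes with signs
fixed so each axis's largest-magnitude loading is positive.  Structural
oracle tests run on the fallback; the nonlinear method is tested for
seed-determinism and neighborhood preservation (trustworthiness against
a random layout).

Duplicate attribute vectors are kept as distinct herbs; their projected
points (and therefore colors) coincide, which is the honest rendering of
indistinguishable attribute profiles.

## Similarity layout

The ordering primitive is the greedy nearest-neighbour chain ("similarity
sequence"): start from a chosen or seeded-random element, then repeatedly
append the unplaced herb nearest to the last one.  Ties break by input
order, making the layout reproducible for a fixed seed.  The chain is
O(n²), which is irrelevant at this scale; no attempt is made at optimal
seriation (TSP-style or dendrogram leaf ordering), since the greedy chain
already produces the intended adjacent-similarity effect and is easy to
reason about.

Arrangement of principal herbs: every herb that is the sole principal of
some formula becomes top-level; the top-level list is ordered by the
similarity sequence.  Each remaining formula reuses the first listed herb
among its principals, or (if none is listed) adds a seeded-random one.
Columns group contiguously by top-level herb; groups follow the top-level
sequence; within a group, columns sort by ascending principal count.  A
column's remaining principals sort by distance to its top-level herb.

The principal region is padded to the *global* maximum principal count,
so the first nonprincipal row is the same in every column.  The
alternative — padding per top-level subgroup — would make subgroup blocks
more compact but break the single horizontal line at which nonprincipal
herbs start, which is the cue the comparison workflow relies on.

Arrangement of remaining herbs: the leftmost column's nonprincipal herbs
are chained starting from the herb nearest its top-level principal.  Each
later column first copies the row of every herb shared with the column
immediately to its left (two shared herbs cannot collide because they
held distinct rows there), then fills the remaining herbs top-to-bottom
into free rows, sorted by ascending *minimum* distance to the left
column's herb set.  Minimum distance is the simplest reading of
"distance to the adjacent column"; mean or nearest-aligned-row variants
would also be defensible but are not implemented.

Row-exact alignment can leave blank (pad) rows inside a column when a
shared herb sits deep in its left neighbour; a `compact` mode squeezes
the gaps out and keeps only relative order.

The quality measure used in tests and reporting is the count of
(adjacent-column, herb) pairs occupying equal rows; the similarity layout
is required never to fall below the raw input-order layout on this count.
This is a regression guard for the implementation, not a theorem: the
input-order baseline can align herbs by coincidence, but by construction
the similarity layout aligns every nonprincipal herb shared between
neighbours.

## Shared-herb matrix and statistics

M[i,j] is the exact intersection cardinality under string identity,
computed as B·Bᵀ for the binary membership matrix B.  The diagonal is the
formula's own size; it is excluded from pairwise statistics and from the
heat-map normalization, so the darkest color goes to the largest
*overlap* rather than the largest formula.  Pairwise mean and SD are over
unordered pairs (n(n−1)/2 of them) with the sample (n−1) SD; a
single-formula group reports them as absent, and a single pair reports
the SD as absent.

## Color encoding

Anchor colors use the five-element mapping (wood→green/liver,
fire→red/heart, earth→yellow/spleen, metal→white/lung,
water→black/kidney).  The shipped palette

    wood  #7A9E7E  (Baishao)    fire  #C08081  (Danggui)
    earth #C3AE76  (Baizhu)     metal #C2C2BC  (Jiegeng)
    water #6E6E78  (Shudihuang)

is deliberately muted: `check_palette` reports the UCS lightness range
and maximum chroma and warns above 45 lightness units and 30 chroma units
— bounds that a palette of mid-lightness, low-chroma colors satisfies and
fully saturated primaries do not.  Users override both anchors and
bounds; picking representative herbs is domain knowledge, not something
the package automates.

Color math runs in CAM02-UCS, reached from sRGB through linear RGB and
CIEXYZ (D65), the CIECAM02 appearance model, and the UCS transform
(J′ = 1.7J/(1+0.007J), M′ = ln(1+0.0228·M)/0.0228, a′ = M′cos h,
b′ = M′sin h).  Viewing conditions are fixed and recorded in output
metadata: D65 white as implied by the sRGB primaries, average surround
(F=1, c=0.69, N_c=1), background luminance factor Y_b=20, adapting
luminance L_A = 64/(5π) ≈ 4.07 cd/m² (the sRGB reference ambient).  The
forward model reproduces the four published CIE numerical verification
examples to printed precision, and the analytic inverse round-trips the
whole sRGB cube to ~1e-13, far inside the ΔE < 0.5 tolerance asserted in
tests.  Out-of-gamut colors are clamped per channel — simple and
reproducible, at the cost of some hue shift for strongly clamped cells —
and every pipeline run reports the clamped fraction.

Each UCS channel is interpolated over the embedding plane with a radial
basis function.  The default kernel is linear, matching the Euclidean
distance semantics of the embedding; gaussian, cubic and thin-plate
kernels are available.  Each kernel carries the lowest legal polynomial
degree (a constant term for the linear kernel).  This is a deliberate
choice: with no polynomial term the channel weights need not sum to zero,
and the field then grows linearly away from the anchors, pushing most of
the rasterized colormap out of gamut (measured 37–58% clamped cells on
the fixture); with the constant term the far field is bounded and
clamping drops to ≈0%.  The constant term does not disturb the properties
users rely on — the field is still exact at every anchor, the value
midway between two anchors is still the channel-wise UCS average (closed
form: the two weights are ±(f₁−f₂)/2D and the constant is the mean), and
ΔE along the segment between two anchors is still monotone.

The continuous colormap is the field evaluated on a raster over the
*embedding* bounding box (not just the anchor hull) plus a 10% margin;
herb colors are evaluated pointwise, so no raster is needed when only the
formula views are wanted.  Coincident anchor points with different colors
make the interpolation system singular and raise an error naming the
herbs involved.

## Rendering

SVG and HTML are emitted from plain strings with two-decimal float
formatting and stable element order, so output is byte-identical across
runs for identical inputs — the end-to-end determinism contract covers
seed → embedding → layout → colors → markup.  Principal herb labels are
blue, bold, with a soft white halo ("glow", a Gaussian-blur merge
filter); formula names sit in italics at a fixed offset below their
column, so column height itself is a reading cue.  The matrix view uses
a sequential colormap (YlGnBu) normalized to the off-diagonal maximum.

Static highlighting replaces interactive brushing: selected formulas are
outlined blue solid; formulas containing the selected herbs are outlined
red dashed.  Herb selection uses *all*-herbs containment by default
(matching the prescription-decomposition workflow: selecting the four
herbs of Siwutang should highlight only formulas embedding all of
Siwutang), with an `any_mode` union option.

## Synthetic data generator

`simulate_group` emulates the statistical shape of a textbook category:
default 20 formulas over a 58-herb pool, herbs per formula from a
discretized log-normal with median 7.5 truncated to [2, 15] (sigma set so
the maximum sits near the 99th percentile), principal counts 1–4 with
median 1, and a preferential-attachment herb sampler (weight 1 + usage)
so that popular herbs recur and pairwise overlaps are nonzero.  Attribute
flags are independent Bernoulli draws (p=0.2 per flag) with at least one
flag forced per block.  Anchors are the five herbs nearest (Hamming) to
per-element archetype vectors.

What the generator does *not* emulate: real co-occurrence structure
(herb pairs that travel together for pharmacological reasons), correlated
attribute blocks (e.g. hot herbs being disproportionately pungent), or
any relationship between a formula's principal herbs and its members'
attributes.  Passing tests on synthetic groups therefore demonstrates
structural correctness of the algorithms (invariants, determinism,
oracle agreement) — not that the visual output is as informative as it
is on real, structured data.  With `overlap_weight=0` the sampler is
uniform without replacement, giving the exact hypergeometric expectation
|A||B|/pool for pairwise overlaps, which the tests use as a closed-form
check.

## Numerical and degenerate-input choices

- Ties in every distance sort break by input order (stable argsort).
- An empty group yields an empty layout; a single herb yields a
  single-element similarity sequence; a single anchor yields a constant
  color field.
- The PCA fallback handles zero-variance inputs by leaving the missing
  axes at zero.
- UMAP needs at least 4 points; smaller inputs raise an error that
  advises the fallback projector.
- Seeds: every random draw (top-level start, random principal picks,
  generator) comes from a `numpy` generator seeded by the caller; UMAP
  receives the embedding seed.  Derived seeds stay below 2³¹.

## Problem sizes

Tests run the structural property sweeps on 100 generated groups of 8
formulas over a 30-herb pool (plus the 7-formula fixture), the greedy
ordering against exhaustive permutation enumeration up to 7 points, and
the color round trip on a 1,000-color lattice; the acceptance script runs
the full pipeline twice on the fixture and once on a 20-formula synthetic
category.  These sizes exercise every code path at the scale the method
targets (tens of formulas, tens of herbs) while keeping the whole suite
fast.

## Known limitations

- Intersections of three or more formulas are not computed or shown;
  they can only be inferred by chained pairwise comparison.
- The herb map shows relative distances, not the attributes themselves;
  two herbs can be close for different attribute reasons.
- Per-channel gamut clamping can shift hue for colors far outside the
  gamut; chroma-preserving gamut mapping is not implemented.
- Exact UMAP coordinates are stable only within a library version; use
  the PCA fallback where cross-environment bit-stability matters.
- The fixture's attribute table is curated, not authoritative; analyses
  of real herb pharmacology should supply their own attribute table.
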