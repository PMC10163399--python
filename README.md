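# formulaviz

Visualization of traditional Chinese medicine (TCM) formulas as set
systems.  A TCM formula is a named combination of herbal medicines; a
textbook category (e.g. tonic formulas) contains a few dozen formulas over
a shared pool of herbs, each herb carrying 23 binary pharmacological
attributes — Siqi (5 thermal properties), Wuwei (7 flavors) and Guijing
(11 meridian orientations).  `formulaviz` turns such data into three
linked, static views aimed at students and teachers of formula
composition:

1. **Formula view** — an icicle plot with one column per formula and one
   cell per herb.  Principal herbs (Junyao) sit in a padded top region;
   column and cell order come from a similarity-based layout so that
   equal herbs in adjacent columns align vertically.
2. **Shared-herb matrix** — the formula-by-formula co-occurrence matrix
   M[i,j] = |F_i ∩ F_j| as a heat map.
3. **Herb map** — a 2D embedding of the herbs over a continuous colormap,
   with each herb's color derived from its position.

## Method

Each herb is encoded as a binary vector **P** ∈ {0,1}²³ in fixed schema
order (Siqi ‖ Wuwei ‖ Guijing) and projected to a 2D point **p** with UMAP
(a deterministic PCA fallback is available).  All similarity computations
use the Euclidean distance d(u, v) = ‖**p**_u − **p**_v‖ between projected
points.

The layout is a greedy two-step arrangement built on the *similarity
sequence* S = (s₁, …, sₙ) of a herb set: s₁ is a (seeded) random start and
each sᵢ is the unplaced herb nearest to sᵢ₋₁.  Step one assigns every
formula a top-level principal herb (sole principals first, ordered by the
similarity sequence; multi-principal formulas reuse a listed herb or add
one at random), groups columns by top-level herb and sorts each group by
ascending principal count, padding the principal region to the global
maximum.  Step two orders the leftmost column's remaining herbs by the
similarity sequence, then walks left to right: herbs shared with the
previous column keep its row, the rest fill free rows sorted by minimum
distance to the previous column.

Herb colors come from a perceptual, data-driven pipeline: five anchor
herbs receive hand-picked colors inspired by the five-element tradition
(wood/green, fire/red, earth/yellow, metal/white, water/black), the
colors are converted sRGB → CIEXYZ → CIECAM02 → CAM02-UCS, each UCS
channel is interpolated over the embedding plane with a linear radial
basis function, and the field is evaluated at every herb's point (and on
a grid, for the continuous colormap).  Euclidean distance in CAM02-UCS
approximates perceived color difference, so color differences between
herbs mirror their attribute distances.  Out-of-gamut results are clamped
per channel and the clamp fraction is reported.

## Worked example

The package ships a seven-formula tonic fixture (with a hand-curated
*synthetic* attribute table; the published attribute database is not
redistributable):

```python
import formulaviz as fv

group, attrs, anchors = fv.load_fixture()
stats = fv.compute_stats(group)
print(f"{stats.n_formulas} formulas, {stats.n_herbs} herbs, "
      f"{stats.n_principal} distinct principal herbs")

M = fv.compute_matrix(group)
print("Bazhentang ∩ Siwutang =", M.count("Bazhentang", "Siwutang"))

bundle = fv.build_views(
    group, attrs, anchors,
    embedding_config=fv.EmbeddingConfig(method="umap", seed=42),
    layout_seed=42,
)
print("column order:", [c.formula for c in bundle.layout.columns])
print("principal region rows:", bundle.layout.principal_rows)
print("aligned shared-herb pairs:",
      fv.count_aligned_pairs(bundle.layout), "(similarity) vs",
      fv.count_aligned_pairs(fv.input_order_layout(group)), "(input order)")

hl = fv.Highlights(herbs=["Shudihuang", "Baishao", "Chuanxiong", "Danggui"])
print("formulas containing the lasso herbs:", hl.matched_formulas(group))
open("report.html", "w").write(bundle.report_html(highlights=hl))
```

prints

```
7 formulas, 31 herbs, 8 distinct principal herbs
Bazhentang ∩ Siwutang = 4
column order: ['Shengmaisan', 'Sijunzitang', 'Bazhentang', 'Shenlingbaizhusan', 'Siwutang', 'Dabuyinwan', 'Dihuangyinzi']
principal region rows: 4
aligned shared-herb pairs: 8 (similarity) vs 5 (input order)
formulas containing the lasso herbs: ['Bazhentang', 'Siwutang']
```

Reading the output: the four single- and low-principal Renshen formulas
group on the left and the Shudihuang formulas on the right; the principal
region is padded to four rows because Dihuangyinzi has four principal
herbs; the similarity layout aligns more shared herbs between neighbours
than the raw input order; and highlighting the four herbs of Siwutang
outlines exactly Bazhentang and Siwutang in `report.html` — Bazhentang is
the union of Sijunzitang's and Siwutang's compositions (up to the
prepared/raw licorice distinction, which the package deliberately keeps).

The same pipeline is available from the shell:

```sh
formulaviz render --seed 42 --highlight-herb Shudihuang \
    --highlight-herb Baishao --highlight-herb Chuanxiong \
    --highlight-herb Danggui --out report.html
formulaviz stats            # group statistics as JSON
formulaviz simulate --out-dir fixtures/ --seed 7
```

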