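# tonguecbir

Content-based retrieval of tongue images by fused color and texture
features.

Tongue inspection is a core diagnostic step in traditional Chinese
medicine: clinicians judge disease state from tongue color (pink, pale,
purple, purple-red, yellow or white coating) and surface texture
(cracks, teeth prints, coating thickness). Clinical archives accumulate
thousands of such photographs, and retrieving visually similar cases by
manual annotation does not scale and inherits each annotator's
subjectivity. `tonguecbir` ranks a tongue-image database directly by
image content instead, for use by researchers building
tongue-diagnosis support tools and as a self-contained reference
implementation of the underlying descriptors.

## Method

Two complementary descriptors are extracted per image:

* **Dominant-color descriptor** `F = {(c_i, μ_i)}`, a palette of HSV
  cluster centers with coverage fractions `μ_i = n_i/(M·N)`, `Σμ_i = 1`.
  Clustering is a generalized Lloyd (LBG) algorithm seeded from a
  nine-region HSV quantizer (regions covering > 15 % of the pixels
  nominate initial centers) and refined with split/merge passes:
  clusters with within-error above `T1` are split LBG-style, centers
  closer than `T2` are pooled by count-weighted means. Distances are
  weighted squared HSV distances, hue circular, weights (2, 1, 1).
* **Edge-histogram descriptor**: the gray image is tiled into 4×4
  subimages of 256 blocks each; five MPEG-7 edge filters classify every
  block (vertical / horizontal / 45° / 135° / nondirectional, threshold
  20), giving an 80-bin local histogram, a 5-bin global histogram
  (subimage mean), and a 65-bin semiglobal histogram over the 13
  standard subimage groups.

Matching fuses the two features. With color distance `d₁` (quadratic
dominant-color matching) and texture distance
`d₂ = Σ|EH_q−EH_t| + 5·Σ|GH_q−GH_t| + Σ|SGH_q−SGH_t|`, each is
normalized to a similarity `(max−d)/max ∈ [0, 1]` and combined as

```
d = ω₁·d₁ + ω₂·d₂,   (ω₁, ω₂) = (0.6, 0.4) by default
```

Retrieval returns the top-k entries by fused similarity; evaluation
reports precision `M/L` and recall `M/D` against class labels. See
`docs/methods.md` for the full model, parameter semantics, and design
rationale.

## Worked example

No clinical tongue database is publicly deposited, so the package ships
a seeded phantom generator whose classes carry the same color/texture
structure. Build a small labeled database, index it, and query it:

```sh
tonguecbir synth --classes combined6 --n 3 --seed 17 -o db
tonguecbir index db -o index.jsonl --labels db/labels.csv
tonguecbir query index.jsonl db/pink_vstripes_000.png --top-k 5
```

prints

```json
{
  "query_id": "pink_vstripes_000",
  "w_color": 0.6,
  "w_texture": 0.4,
  "results": [
    {"image_id": "pink_vstripes_000", "similarity": 1.0,
     "d_color": 0.0, "d_texture": 0.0},
    {"image_id": "pink_vstripes_002", "similarity": 0.8877328431106193,
     "d_color": 0.16252817621775417, "d_texture": 0.0},
    {"image_id": "pink_vstripes_001", "similarity": 0.8342867969239554,
     "d_color": 0.2399015474996806, "d_texture": 0.0},
    {"image_id": "pink_diag45_001", "similarity": 0.5867332513625166,
     "d_color": 0.01920615538980925, "d_texture": 68.0},
    {"image_id": "pink_diag45_000", "similarity": 0.514860404997762,
     "d_color": 0.12325584332082479, "d_texture": 68.0}
  ]
}
```

The query image ranks first with similarity exactly 1 (both
self-distances are 0); its two class mates follow — same stripe texture
(`d_texture = 0`), small color distance from the per-image hue jitter —
and only then come the same-colored but differently textured images,
pushed down by their texture distance of 68. Evaluating the whole
index,

```sh
tonguecbir evaluate index.jsonl --top-k 3
```

prints `{"top_k": 3, "n_images": 18, "precision": 1.0, "recall": 1.0}`:
with 3 images per class, every top-3 self-query retrieves exactly its
own class.

The same pipeline is available as a library:

```python
from tonguecbir import build_index, query, extract_main_colors

index = build_index(triples)          # (image_id, array_or_path, label)
result = query(index, image, w_color=0.6, w_texture=0.4, top_k=9)
```

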