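# nutriprofile

Data-driven nutrient profiling of packaged foods, built to answer one
question for product developers and public-health analysts: *what
nutrient composition must a product reach to be among the best x% of
its own category on the market?*

Given a flat table of products with declared contents of five nutrients
— saturated fat, total sugars, total sodium (disqualifying: lower is
better) and protein, fiber (qualifying: higher is better) — the package

1. **identifies category-relevant nutrients**: a nutrient matters for a
   category when more than half of its products exceed the regulatory
   "low in" / "source of" claim limit;
2. **refines heterogeneous categories**: each relevant nutrient's
   distribution is binned into 12 equal-width bins; bins that are
   locally convex (count above the mean of their neighbours) mark
   modes, and the category is split at midpoints between consecutive
   modes into distinct consumer offers;
3. **derives joint "best x%" thresholds** by the minimal common
   percentile: the smallest level p such that x% of products
   simultaneously sit at-or-better than every nutrient's empirical
   p-level cut (P_p for disqualifying, P_{100−p} for qualifying
   nutrients), with thresholds below a claim limit clamped to it and
   the search rerun;
4. **scores each product 0–100%** — the share of category peers it
   beats: a product meeting the 13% but not the 12% thresholds scores
   87%;
5. **validates** the score against an external ordinal rating (e.g.
   Health Star Rating stars) with a class-balance-weighted Spearman
   correlation and per-class boxplot summaries.

Missing declarations are informative and are never imputed; powders are
assessed as liquids via a fixed 1 g / 10 mL dilution; salt is converted
to sodium by the Na/NaCl molar-mass ratio when sodium is undeclared.

## Worked example

The shipped margarine-like fixture (850 synthetic products; three
planted salted offers of 267/293/290 products at 135/405/675 mg
sodium/100 g; unimodal saturated fat) re-enacts the whole pipeline:

```python
import nutriprofile as npf

df, truth = npf.margarine_fixture()
relevant = npf.relevant_nutrients(df)
# {Nutrient.SATURATED_FAT, Nutrient.TOTAL_SODIUM}: only these two exceed
# their claim limits in more than half of the products

sub = npf.analyzable_subset(df, relevant)          # 850 products kept
det = {n: npf.detect_modes(sub[n.value]) for n in relevant}
# saturated fat: 1 mode; sodium: 3 modes, cuts at 0.272 and 0.539 g/100 g
part = npf.split_category(sub, det, category="margarine")

high = sub[part.labels.str.endswith("3/3")]        # highly salted, n=290
t50 = npf.derive_thresholds(high, relevant, 50.0)
t15 = npf.derive_thresholds(high, relevant, 15.0)
```

With this data the 50% target lands on the common percentile
p = 69.7 with joint coverage 0.503 and thresholds
`{saturated_fat: 14.05 g, total_sodium: 0.693 g}` per 100 g; the 15%
target gives p = 37.6 and `{saturated_fat: 11.10 g, total_sodium:
0.666 g}`. `npf.threshold_report(t50, t15)` renders the reformulation
effort per nutrient as `saturated_fat: -21%, total_sodium: -4%` — to
move from the middle to the top 15% of this offer, saturated fat must
drop far more than sodium. Note p > x: nutrients must be cut jointly,
so the marginal percentile is laxer than the joint target (for two
independent nutrients and x = 50%, p → 100·√0.5 ≈ 70.7).

Scoring one product against the family of thresholds for x = 1..100:

```python
fam = npf.threshold_family(high, relevant)
npf.score_product({"saturated_fat": 11.86, "total_sodium": 0.617}, fam)
# ScoreResult(score=78, x_min=22, assessable=True): beats 78% of its offer
```

The same pipeline runs from the shell:

```sh
nutriprofile simulate --spec examples/margarine.yaml --seed 3 --out products.csv
nutriprofile run --config config.yaml          # all stages, artifacts as CSV/JSON
nutriprofile thresholds --input products.csv --targets 50,15 --out thresholds.json
```

## Layout

| path | contents |
|------|----------|
| `src/nutriprofile/core.py` | nutrient/basis types, claim limits, compliance |
| `src/nutriprofile/ingest.py` | CSV contract, cleaning, salt→sodium, powders, basis split |
| `src/nutriprofile/relevance.py` | category-relevant nutrients, analyzable subset |
| `src/nutriprofile/refine.py` | 12-bin convexity mode detection, category splitting |
| `src/nutriprofile/thresholds.py` | minimal-common-percentile search, clamping, reports |
| `src/nutriprofile/scoring.py` | threshold families, 0–100% product scores |
| `src/nutriprofile/validation.py` | weighted Spearman, class weights, agreement report |
| `src/nutriprofile/synth.py` | mixture-based synthetic product databases |
| `src/nutriprofile/pipeline.py`, `cli.py` | orchestration and the `nutriprofile` CLI |

See `docs/methods.md` for the model's assumptions, parameter defaults,
tie-break conventions and known limitations.
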