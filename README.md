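# foodprofiler

Quantifies what share of a food-and-beverage company's value sales comes
from products classified as **unhealthy** under the WHO European Region
nutrient profile model (first edition, 2015) — the model governments use
to decide which foods may be marketed to children. The intended users
are public-health analysts and organisations that need an objective,
reproducible basis for deciding whether engaging with a manufacturer
poses a conflict of interest.

## The method

1. **Classify products.** Every packaged product belongs to one of 20
   model categories. Some categories are never permitted to be marketed
   to children (chocolate and sugar confectionery; cakes and sweet
   bakery; edible ices; energy drinks; juices), some are always
   permitted (fresh/frozen fruit and vegetables; fresh/frozen meat and
   fish), and the rest are tested against per-100 g/ml maxima for
   energy, total fat, saturated fat, total sugars and salt, plus
   category-specific prohibitions on added sugars and non-sugar
   sweeteners (NSS) detected from the ingredient list. A product that
   fails any criterion is *unhealthy*; one that passes every criterion
   is *healthier*. Equality with a maximum passes.
2. **Link sales to products.** Market panels report annual value sales
   per *brand* (V_b, USD); composition databases hold individual
   *products*. Records are joined on normalized (company, country,
   brand); brands for baby food/infant formula, alcohol, non-food and
   whole fresh meat are excluded by rule, and brands with no
   composition match are excluded and accounted for.
3. **Allocate equally.** Each of a brand's n_b matched variants gets
   v_i = V_b / n_b.
4. **Aggregate.** Per company, category, and overall:

   `unhealthy_pct = 100 · Σ v_i[unhealthy] / Σ v_i[classifiable]`

   with unclassifiable sales (missing panel fields) excluded from the
   denominator and reported separately, and an optional per-$10 framing
   (`healthier dollars per $10 spent`) and engagement-threshold
   verdicts (e.g. "at most 49% / 25% / 10% unhealthy").

Because licensed sales and composition data cannot be redistributed,
the package includes a synthetic-market generator with planted ground
truth so the entire pipeline is testable end to end.

## Worked example

```bash
profiler simulate --out-dir market --seed 5 --n-companies 4
profiler run --products market/products.csv --sales market/sales.csv --out-dir out
```

prints

```
overall: 89.0% unhealthy, 11.0% healthier ($1.10 healthier per $10)
artifacts in out
```

The generator's defaults plant a market in which 89% of matched value
sales fail the model and 12.1% of sales value has no composition match;
the run recovers both: `out/summary.json` holds the overall report, the
coverage accounting (here 87.9% of sales matched, with per-country
rates), and pass/fail verdicts against the 49/25/10% engagement
cutoffs; `out/reports.csv` has one row per company, category and
overall; `out/run.log` lists every excluded, unmatched and
unclassifiable record with its reason.

The same thing from Python:

```python
from foodprofiler import GeneratorConfig, RunConfig, generate_market, run_pipeline, write_market

market = generate_market(GeneratorConfig(seed=5, n_companies=4))
paths = write_market(market, "market")
result = run_pipeline(RunConfig(products_path=paths["products"],
                                sales_path=paths["sales"], out_dir="out"))
print(result.summary["overall"]["unhealthy_pct"])   # 89.0
print(market.ledger.expected_unhealthy_pct)         # 89.0 (planted truth)
```

Custom threshold tables (other nutrient profile models) and sweetener
lexicons are plain YAML files; pass them with `--threshold-config` /
`--lexicon-config`. The packaged defaults are
`src/foodprofiler/data/who_euro_2015.yaml` and
`src/foodprofiler/data/sweetener_lexicon.yaml`.

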