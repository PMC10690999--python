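# Methods

## The classification model

The rules engine encodes the WHO European Region nutrient profile model
(first edition, 2015) as a data-driven threshold table
(`data/who_euro_2015.yaml`). Each of the 20 categories carries a
permission mode:

- **never_permitted** — chocolate and sugar confectionery; cakes and
  sweet bakery wares; edible ices; energy drinks; juices. Every product
  is unhealthy regardless of composition (`category_not_permitted`).
- **always_permitted** — fresh/frozen fruit, vegetables and legumes;
  fresh/frozen meat, poultry and fish. Every product is healthier.
- **threshold_evaluated** — per-100 g/ml maxima on a subset of
  {energy (kcal), total fat, saturated fat, trans fat, total sugars,
  salt}, plus optional prohibitions on added sugars and on non-sugar
  sweeteners (NSS). A product is unhealthy iff any present nutrient
  *strictly exceeds* its maximum or a prohibited ingredient class is
  present; equality with a maximum passes ("exceed" is read as strictly
  greater).

The table is editable and schema-checked at load: one rule per
category, numeric non-negative maxima drawn from a fixed nutrient
vocabulary, and at least one criterion per threshold-evaluated rule. A
rule may consist of prohibitions alone — the "other beverages" category
has no numeric maxima, only the added-sugar and NSS prohibitions, which
is why the schema requires "maxima or a forbid flag" rather than maxima
unconditionally.

**Units.** Panels are harmonized before evaluation: salt (g) is derived
from sodium as `sodium_mg × 2.5 / 1000` when absent, and energy (kcal)
from kJ as `energy_kj / 4.184`. Per-100 ml beverages are treated
identically to per-100 g solids; all thresholds apply per 100 g/ml.
Comparisons are raw floating-point after harmonization — no epsilon —
since config values are exact decimals and the boundary convention is
part of the model.

**Missing data.** A nutrient named in the rule's maxima that is still
absent after harmonization makes the product *unclassifiable*, unless
some other criterion already failed (a failure is decisive on its own).
Unclassifiable sales are excluded from every percentage denominator and
reported separately, the same treatment given to unmatched brands.
Trans fat is the exception: it is evaluated only when declared, because
standard label panels do not carry it; its absence never blocks
classification. The packaged table ships no trans-fat maxima; the
schema supports them for custom tables.

**Added sugars and NSS.** Label panels rarely declare added sugars, so
both prohibitions are evaluated by screening the free-text ingredient
list against an editable lexicon (`data/sweetener_lexicon.yaml`):
case-insensitive whole-token/phrase matching after punctuation and
diacritic normalization, with a negative-context list ("no added
sugar", "sugar snap peas", …) excised before matching so phrase
precedence prevents false positives. A declared `added_sugars_g > 0`
also sets the sugar flag. Transparent lexicon matching was chosen over
any statistical tagger because the term list is auditable and
per-market lexicons (other languages) can be swapped in; the default
list is English-only. Products with empty ingredient text are
*unscreenable*: their flags are false (not unclassifiable, which would
mass-exclude whole categories) and their count is reported in the
coverage block.

## Linkage and allocation

Sales records are excluded by rule before matching: baby food and
infant formula (outside the model's scope), alcohol and non-food
sectors (pet food, home care), and brands mapped to the whole
fresh/frozen meat category, for which sales data are not analysed. An
unknown sector tag warns and keeps the record.

Matching is an exact join on (company, country, normalized brand key);
the key is casefolded, diacritic-stripped and punctuation/whitespace
collapsed, so "COCA-COLA" and "Coca Cola" agree. Exact joining was
chosen over automatic fuzzy matching for auditability; a fuzzy-assist
helper (`suggest_matches`, stdlib sequence matching) only proposes
candidates for human review and never links records itself. Unmatched
brands are excluded from all denominators; the match report carries
their count, sales value and share, and per-country match rates.

Each matched brand's sales are split equally across its n_b matched
variants, v_i = V_b / n_b (product-level sales are generally
unavailable); allocations reconstitute brand sales to within 1e-6
relative tolerance. All reported proportions use matched sales only.

## Aggregation and reporting

Allocated sales are summed by verdict within scope (company, category,
overall); percentages are taken on classifiable matched sales, so
healthier + unhealthy = 100 identically. Human-readable output rounds
to one decimal; machine outputs (`reports.csv`, `summary.json`) keep
full precision. The per-$10 framing is `10 × healthier_pct / 100`
rounded to cents. Engagement verdicts compare a company's unhealthy
share to configured cutoffs (default 49, 25, 10) with an inclusive
"at most" comparison at the boundary — "minority of sales" phrasing is
ambiguous at equality, and ≤ is declared here as the package's
convention. Aggregation refuses to run when nothing matched.

## Synthetic markets and what they show

`generate_market` emulates the paired data sources: a product table
with per-100 g/ml panels and ingredient text, and a brand sales table.
Defaults mirror the study conditions: 20 companies, 3–10 brands each,
1–8 variants per brand, seven countries, a category mix dominated by
soft drinks, confectionery and snacks, a planted value-weighted
unhealthy share of 0.89, and 12.1% of sales value left without
composition records. Sales magnitudes are log-uniform on $1e5–$1e9;
only proportions matter downstream.

Mechanics: brand verdicts are drawn Bernoulli(target share) with at
least one brand of each verdict when the target is fractional; each
brand then receives a verdict-compatible category from the
renormalized mix (an unhealthy brand cannot sit in an always-permitted
category, nor a healthier brand in a never-permitted one — a mix that
admits no compatible category raises a generation error). Brands are
verdict-homogeneous so that scaling the unhealthy and healthier sales
groups separately makes the value-weighted unhealthy share equal the
target exactly (to machine precision; the pipeline and the ledger sum
in different orders, so tests compare at 1e-12 relative tolerance).
Planted unhealthy products in threshold-evaluated categories violate
one criterion chosen uniformly at random — including the added-sugar
and NSS prohibitions via planted ingredient text — so every failure
path of the engine is exercised; planted healthier products sit below
every maximum with clean ingredient text. Panels randomly encode salt
as sodium and energy as kJ to exercise unit harmonization. Identical
config and seed give byte-identical files.

What the generator does **not** emulate: realistic nutrient
correlations, brand-name collisions or translation noise between the
two tables, multilingual ingredient text, and mixed-healthiness brands.
Passing tests therefore demonstrate the pipeline's arithmetic,
bookkeeping and rule logic — not matching recall or lexicon coverage on
real extracts.

`generate_boundary_products` emits, for every threshold-evaluated
category and nutrient, probes exactly at the maximum (must pass), ε
above (must fail) and ε below (must pass), ε = 0.1 by default.

## Problem sizes

The test suite runs markets of 4–20 companies (roughly 100–650
products per market) and cross-checks the rules engine against an
independent brute-force re-implementation on 10,000 random products;
the acceptance script uses a 200-product single-category portfolio.

## Known limitations

- One category per brand on the sales side; a brand spanning categories
  must be split upstream.
- The default lexicon is English; detection quality on other languages
  depends on user-supplied lexicons.
- Single-year, single-currency runs; no deflation or cross-year trend
  machinery (diff successive runs instead).
- Score-based models (Nutri-Score, Health Star Rating, Ofcom points)
  are out of scope; the config format only covers threshold/permission
  models.
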