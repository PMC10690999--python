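"""Synthetic paired product-composition and brand-sales datasets.

Licensed market-research and composition data cannot be redistributed,
so every pipeline stage is exercised against generated markets with a
known ground truth: each brand is planted as wholly healthier or wholly
unhealthy, unhealthy products are constructed to violate at least one
criterion of their category's rule (or sit in a never-permitted
category), and brand sales are drawn log-uniformly then scaled group-wise
so the value-weighted unhealthy share equals the configured target
exactly. A fraction of sales value is emitted without composition
records to emulate unmatched brands. The ledger records the planted
truth for independent verification.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GenerationError
from .npm_rules import ThresholdTable, load_threshold_table

__all__ = [
    "GeneratorConfig",
    "GroundTruthLedger",
    "SyntheticMarket",
    "generate_market",
    "generate_boundary_products",
    "write_market",
    "DEFAULT_CATEGORY_MIX",
]

#: Study-like category mix: portfolios dominated by soft drinks,
#: confectionery, snacks and sweet bakery, with staples (bread, grains,
#: fruit and vegetables) a small share of revenue.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "confectionery": 0.12,
    "sweet_bakery": 0.08,
    "savoury_snacks": 0.09,
    "other_beverages": 0.12,
    "juices": 0.04,
    "energy_drinks": 0.03,
    "milk_drinks": 0.04,
    "edible_ices": 0.04,
    "breakfast_cereals": 0.05,
    "yoghurts_creams": 0.06,
    "cheese": 0.04,
    "ready_made_foods": 0.07,
    "butter_fats_oils": 0.03,
    "bread_products": 0.04,
    "pasta_rice_grains": 0.03,
    "processed_meat_fish": 0.04,
    "processed_fruit_veg": 0.04,
    "sauces_dips_dressings": 0.03,
    "fresh_frozen_fruit_veg": 0.01,
}

#: the study's seven markets, one leading market per world region
DEFAULT_COUNTRIES = ("AU", "BR", "CN", "IN", "ZA", "GB", "US")

_CLEAN_INGREDIENTS = (
    "wheat flour, water, yeast, salt",
    "oats, water",
    "tomatoes, olive oil, basil",
    "rice, water",
    "milk, cultures",
    "peas, water, salt",
)
_SWEET_INGREDIENTS = (
    "sugar, cocoa butter, milk solids, flavouring",
    "glucose syrup, water, colour",
    "water, sucrose, citric acid",
)
_NSS_INGREDIENTS = (
    "water, aspartame, flavouring",
    "carbonated water, sucralose, citric acid",
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic market."""

    n_companies: int = 20
    brands_per_company: tuple[int, int] = (3, 10)
    variants_per_brand: tuple[int, int] = (1, 8)
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    target_unhealthy_share: float = 0.89
    unmatched_fraction: float = 0.121
    countries: tuple[str, ...] = DEFAULT_COUNTRIES
    sales_range_usd: tuple[float, float] = (1e5, 1e9)
    year: str = "2020"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_companies < 1:
            raise GenerationError("n_companies must be >= 1")
        for name in ("brands_per_company", "variants_per_brand"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise GenerationError(f"{name} range must satisfy 1 <= lo <= hi")
        if not math.isclose(sum(self.category_mix.values()), 1.0, abs_tol=1e-9):
            raise GenerationError("category_mix probabilities must sum to 1")
        if any(p < 0 for p in self.category_mix.values()):
            raise GenerationError("category_mix probabilities must be non-negative")
        if not 0 <= self.target_unhealthy_share <= 1:
            raise GenerationError("target_unhealthy_share must be in [0, 1]")
        if not 0 <= self.unmatched_fraction < 1:
            raise GenerationError("unmatched_fraction must be in [0, 1)")
        lo, hi = self.sales_range_usd
        if not (0 < lo <= hi):
            raise GenerationError("sales_range_usd must be positive and ordered")


@dataclass(frozen=True)
class GroundTruthLedger:
    """Planted truth of one generated market."""

    target_unhealthy_share: float
    expected_unhealthy_pct: float
    expected_matched_pct: float
    per_country_matched_pct: Mapping[str, float]
    brand_verdicts: Mapping[str, str]
    brand_sales_usd: Mapping[str, float]
    n_products: int
    n_brands_matched: int
    n_brands_unmatched: int
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SyntheticMarket:
    products: pd.DataFrame
    sales: pd.DataFrame
    ledger: GroundTruthLedger


def _mix_for_verdict(
    mix: Mapping[str, float], table: ThresholdTable, verdict: str
) -> tuple[list[str], np.ndarray]:
    """Categories of the mix compatible with a planted verdict."""
    if verdict == "healthier":
        ok = [c for c, p in mix.items() if p > 0
              and table.rule_for(c).permission_mode != "never_permitted"]
    else:
        ok = [c for c, p in mix.items() if p > 0
              and table.rule_for(c).permission_mode != "always_permitted"]
    if not ok:
        raise GenerationError(
            f"category_mix has no category that can host a {verdict} product; "
            f"target_unhealthy_share is infeasible with this mix"
        )
    probs = np.array([mix[c] for c in ok], dtype=float)
    return ok, probs / probs.sum()


def _healthier_panel(rule, rng: np.random.Generator) -> dict[str, float]:
    """Panel satisfying every criterion of ``rule`` (margin below maxima)."""
    values: dict[str, float] = {}
    if rule.permission_mode == "always_permitted":
        return {
            "energy_kcal": float(rng.uniform(10, 600)),
            "total_fat_g": float(rng.uniform(0, 30)),
            "saturated_fat_g": float(rng.uniform(0, 10)),
            "total_sugars_g": float(rng.uniform(0, 30)),
            "salt_g": float(rng.uniform(0, 2)),
        }
    for nutrient, mx in rule.maxima.items():
        values[nutrient] = float(rng.uniform(0, 0.8 * mx))
    values.setdefault("energy_kcal", float(rng.uniform(10, 400)))
    values.setdefault("total_fat_g", float(rng.uniform(0, 20)))
    values.setdefault("saturated_fat_g", float(rng.uniform(0, 5)))
    values.setdefault("total_sugars_g", float(rng.uniform(0, 8)))
    values.setdefault("salt_g", float(rng.uniform(0, 1)))
    return values


def _unhealthy_panel(
    rule, rng: np.random.Generator
) -> tuple[dict[str, float], str]:
    """Panel (and violated criterion) that fails exactly one chosen criterion
    of ``rule``; never-permitted categories fail by category alone."""
    if rule.permission_mode == "never_permitted":
        panel = _healthier_panel(
            dataclasses.replace(rule, permission_mode="always_permitted"), rng
        )
        return panel, "category_not_permitted"
    criteria = sorted(rule.maxima)
    if rule.forbid_added_sugars:
        criteria.append("added_sugars")
    if rule.forbid_nss:
        criteria.append("nss")
    chosen = criteria[int(rng.integers(len(criteria)))]
    panel = {n: float(rng.uniform(0, 0.8 * mx)) for n, mx in rule.maxima.items()}
    if chosen in rule.maxima:
        panel[chosen] = float(rule.maxima[chosen] * 1.5 + 1.0)
    for name, default in (
        ("energy_kcal", rng.uniform(10, 400)),
        ("total_fat_g", rng.uniform(0, 20)),
        ("saturated_fat_g", rng.uniform(0, 5)),
        ("total_sugars_g", rng.uniform(0, 8)),
        ("salt_g", rng.uniform(0, 1)),
    ):
        panel.setdefault(name, float(default))
    return panel, chosen


def _ingredients_for(verdict: str, criterion: str, rng: np.random.Generator) -> str:
    if criterion == "added_sugars":
        return _SWEET_INGREDIENTS[int(rng.integers(len(_SWEET_INGREDIENTS)))]
    if criterion == "nss":
        return _NSS_INGREDIENTS[int(rng.integers(len(_NSS_INGREDIENTS)))]
    if verdict == "unhealthy" and criterion == "category_not_permitted":
        # never-permitted categories are mostly sweet goods; text is inert here
        return _SWEET_INGREDIENTS[int(rng.integers(len(_SWEET_INGREDIENTS)))]
    return _CLEAN_INGREDIENTS[int(rng.integers(len(_CLEAN_INGREDIENTS)))]


def _panel_row(panel: dict[str, float], rng: np.random.Generator) -> dict[str, float]:
    """Finish a panel row: filler nutrients plus unit-variant encoding
    (sometimes sodium instead of salt, kJ instead of kcal)."""
    row = dict(panel)
    row.setdefault("protein_g", float(rng.uniform(0, 20)))
    row.setdefault("carbohydrate_g", float(rng.uniform(0, 60)))
    row.setdefault("fibre_g", float(rng.uniform(0, 10)))
    if rng.random() < 0.25 and "salt_g" in row:
        row["sodium_mg"] = row.pop("salt_g") * 400.0
    if rng.random() < 0.25 and "energy_kcal" in row:
        row["energy_kj"] = row.pop("energy_kcal") * 4.184
    return row


def generate_market(
    config: GeneratorConfig, table: ThresholdTable | None = None
) -> SyntheticMarket:
    """Generate one synthetic market (products, sales, ground-truth ledger).

    Brand verdicts are drawn Bernoulli(target_unhealthy_share) — with at
    least one brand of each verdict when the target is strictly between 0
    and 1 — and each brand receives a verdict-compatible category from the
    renormalized mix. Brands are verdict-homogeneous, so scaling the two
    sales groups makes the value-weighted unhealthy share hit the target
    exactly. Identical config and seed reproduce identical output.
    """
    table = table if table is not None else load_threshold_table()
    for cat in config.category_mix:
        table.rule_for(cat)  # unknown category fails fast
    rng = np.random.default_rng(config.seed)
    p = config.target_unhealthy_share

    # brand skeleton
    brand_rows: list[dict] = []
    for ci in range(config.n_companies):
        company = f"Company{ci + 1:02d}"
        lo, hi = config.brands_per_company
        for _ in range(int(rng.integers(lo, hi + 1))):
            brand_rows.append({"company": company})
    n_brands = len(brand_rows)
    verdicts = np.where(rng.random(n_brands) < p, "unhealthy", "healthier")
    if 0 < p < 1:
        if n_brands < 2:
            raise GenerationError(
                "a fractional target_unhealthy_share needs at least two brands"
            )
        for v in ("unhealthy", "healthier"):
            if v not in verdicts:
                verdicts[int(rng.integers(n_brands))] = v

    product_rows: list[dict] = []
    pid = 0
    for bi, row in enumerate(brand_rows):
        verdict = str(verdicts[bi])
        cats, probs = _mix_for_verdict(config.category_mix, table, verdict)
        category = cats[int(rng.choice(len(cats), p=probs))]
        rule = table.rule_for(category)
        row.update(
            brand=f"Brand {bi + 1:04d}",
            country=config.countries[int(rng.integers(len(config.countries)))],
            npm_category=category,
            verdict=verdict,
            n_variants=int(
                rng.integers(config.variants_per_brand[0], config.variants_per_brand[1] + 1)
            ),
        )
        for _ in range(row["n_variants"]):
            pid += 1
            if verdict == "unhealthy":
                panel, criterion = _unhealthy_panel(rule, rng)
            else:
                panel, criterion = _healthier_panel(rule, rng), "none"
            product_rows.append(
                {
                    "product_id": f"P{pid:06d}",
                    "company": row["company"],
                    "country": row["country"],
                    "brand": row["brand"],
                    "npm_category": category,
                    **_panel_row(panel, rng),
                    "ingredients_text": _ingredients_for(verdict, criterion, rng),
                }
            )

    # sales: log-uniform draws, then group scaling to the exact target share
    lo, hi = config.sales_range_usd
    raw = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), n_brands)
    is_unhealthy = verdicts == "unhealthy"
    total = float(raw.sum())
    scaled = raw.copy()
    if 0 < p < 1:
        u_raw = float(raw[is_unhealthy].sum())
        h_raw = total - u_raw
        scaled[is_unhealthy] *= p * total / u_raw
        scaled[~is_unhealthy] *= (1 - p) * total / h_raw
    matched_total = float(scaled.sum())

    sales_rows = [
        {
            "company": row["company"],
            "country": row["country"],
            "brand": row["brand"],
            "sector_tag": "food",
            "npm_category": row["npm_category"],
            "value_sales_usd": float(scaled[bi]),
            "year": config.year,
        }
        for bi, row in enumerate(brand_rows)
    ]

    # unmatched brands: sales with no composition records
    n_unmatched = 0
    unmatched_by_country: dict[str, float] = {}
    if config.unmatched_fraction > 0:
        x_total = matched_total * config.unmatched_fraction / (1 - config.unmatched_fraction)
        n_unmatched = max(1, round(0.25 * n_brands))
        u_raw_draw = 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), n_unmatched)
        u_scaled = u_raw_draw * (x_total / float(u_raw_draw.sum()))
        all_cats = [c for c, q in config.category_mix.items() if q > 0]
        for ui in range(n_unmatched):
            country = config.countries[int(rng.integers(len(config.countries)))]
            value = float(u_scaled[ui])
            unmatched_by_country[country] = unmatched_by_country.get(country, 0.0) + value
            sales_rows.append(
                {
                    "company": f"Company{int(rng.integers(config.n_companies)) + 1:02d}",
                    "country": country,
                    "brand": f"Ghost Brand {ui + 1:04d}",
                    "sector_tag": "food",
                    "npm_category": all_cats[int(rng.integers(len(all_cats)))],
                    "value_sales_usd": value,
                    "year": config.year,
                }
            )

    # ledger: independent (numpy) arithmetic over the planted values
    unhealthy_value = float(scaled[is_unhealthy].sum())
    expected_unhealthy_pct = 100.0 * unhealthy_value / matched_total
    matched_by_country: dict[str, float] = {}
    for bi, row in enumerate(brand_rows):
        matched_by_country[row["country"]] = (
            matched_by_country.get(row["country"], 0.0) + float(scaled[bi])
        )
    unmatched_total = sum(unmatched_by_country.values())
    per_country = {}
    for country in sorted(set(matched_by_country) | set(unmatched_by_country)):
        m = matched_by_country.get(country, 0.0)
        u = unmatched_by_country.get(country, 0.0)
        per_country[country] = 100.0 * m / (m + u) if m + u > 0 else 100.0
    ledger = GroundTruthLedger(
        target_unhealthy_share=p,
        expected_unhealthy_pct=expected_unhealthy_pct,
        expected_matched_pct=100.0 * matched_total / (matched_total + unmatched_total),
        per_country_matched_pct=per_country,
        brand_verdicts={row["brand"]: str(verdicts[bi]) for bi, row in enumerate(brand_rows)},
        brand_sales_usd={row["brand"]: float(scaled[bi]) for bi, row in enumerate(brand_rows)},
        n_products=len(product_rows),
        n_brands_matched=n_brands,
        n_brands_unmatched=n_unmatched,
        seed=config.seed,
    )

    panel_cols = [
        "energy_kcal", "energy_kj", "total_fat_g", "saturated_fat_g", "trans_fat_g",
        "total_sugars_g", "added_sugars_g", "fibre_g", "protein_g", "carbohydrate_g",
        "salt_g", "sodium_mg",
    ]
    products = pd.DataFrame(product_rows).reindex(
        columns=["product_id", "company", "country", "brand", "npm_category",
                 *panel_cols, "ingredients_text"]
    )
    sales = pd.DataFrame(sales_rows)
    return SyntheticMarket(products=products, sales=sales, ledger=ledger)


def generate_boundary_products(
    table: ThresholdTable | None = None, epsilon: float = 0.1
) -> pd.DataFrame:
    """Boundary probes for every threshold-evaluated category and nutrient.

    For each maximum m, emits a product exactly at m (must pass), one at
    m + epsilon (must fail) and one at max(m - epsilon, 0) (must pass).
    The expected verdict and probed criterion ride along as extra columns.
    """
    table = table if table is not None else load_threshold_table()
    rows = []
    pid = 0
    for code in table.categories:
        rule = table.rule_for(code)
        if rule.permission_mode != "threshold_evaluated":
            continue
        for nutrient, mx in sorted(rule.maxima.items()):
            for value, expected in (
                (mx, "healthier"),
                (mx + epsilon, "unhealthy"),
                (max(mx - epsilon, 0.0), "healthier"),
            ):
                pid += 1
                row = {
                    "product_id": f"B{pid:05d}",
                    "company": "BOUNDARY",
                    "country": "XX",
                    "brand": "Boundary",
                    "npm_category": code,
                    "ingredients_text": "",
                    "expected_verdict": expected,
                    "boundary_criterion": nutrient,
                }
                for other in rule.maxima:
                    row[other] = 0.0
                row[nutrient] = value
                row.setdefault("energy_kcal", 100.0)
                rows.append(row)
    return pd.DataFrame(rows)


def write_market(market: SyntheticMarket, out_dir: str | Path) -> dict[str, Path]:
    """Write products.csv, sales.csv and ledger.json; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "products": out / "products.csv",
        "sales": out / "sales.csv",
        "ledger": out / "ledger.json",
    }
    market.products.to_csv(paths["products"], index=False)
    market.sales.to_csv(paths["sales"], index=False)
    paths["ledger"].write_text(
        json.dumps(market.ledger.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
    )
    return paths
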