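"""Brand-to-product linkage and equal-split sales allocation.

Market-research panels report value sales per *brand*; composition
databases hold *products* (a brand's flavour/size variants). The method
joins the two on normalized (company, country, brand) and, because
product-level sales are unavailable, splits each brand's annual value
sales V_b equally across its n_b matched variants: v_i = V_b / n_b.
Brands with no composition match are excluded from all denominators and
accounted for in the match report; brands outside the model's scope
(baby foods and infant formula, alcohol, non-food, whole fresh/frozen
meat) are excluded by rule before matching.
"""

from __future__ import annotations

import difflib
import re
import unicodedata
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .errors import AllocationError
from .npm_rules import ProductRecord

__all__ = [
    "BrandSalesRecord",
    "AllocatedSale",
    "MatchReport",
    "ExclusionRules",
    "DEFAULT_EXCLUSION_RULES",
    "normalize_brand_key",
    "apply_exclusions",
    "match_brands",
    "allocate_sales",
    "suggest_matches",
]

EXCLUSION_REASONS = (
    "baby_food_formula",
    "alcohol",
    "non_food",
    "whole_meat_unavailable",
    "none",
)

_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)
_WS_RE = re.compile(r"\s+")


def normalize_brand_key(label: str) -> str:
    """Deterministic brand key: casefolded, diacritic-stripped, punctuation
    and whitespace collapsed. Raises ``ValueError`` on an empty label."""
    if not label or not label.strip():
        raise ValueError("brand label is empty")
    text = unicodedata.normalize("NFKD", label)
    text = "".join(ch for ch in text if not unicodedata.combining(ch))
    text = _PUNCT_RE.sub(" ", text.casefold())
    key = _WS_RE.sub(" ", text).strip()
    if not key:
        raise ValueError(f"brand label normalizes to empty: {label!r}")
    return key


@dataclass(frozen=True)
class BrandSalesRecord:
    """One brand's annual value sales (V_b) in USD."""

    brand_key: str
    brand_label: str
    company: str
    country: str
    npm_category: str
    value_sales_usd: float
    sector_tag: str = "food"
    year: str = ""
    excluded_reason: str = "none"

    def __post_init__(self) -> None:
        if self.value_sales_usd < 0:
            raise ValueError(
                f"brand {self.brand_label!r}: negative sales {self.value_sales_usd}"
            )
        if self.excluded_reason not in EXCLUSION_REASONS:
            raise ValueError(f"unknown exclusion reason {self.excluded_reason!r}")


@dataclass(frozen=True)
class AllocatedSale:
    """A product's equal share v_i = V_b / n_b of its brand's sales."""

    product_id: str
    brand_key: str
    allocated_usd: float


@dataclass(frozen=True)
class MatchReport:
    """Accounting of the brand-product join, on by-rule-kept sales."""

    n_brands_total: int
    n_brands_matched: int
    n_brands_unmatched: int
    n_brands_excluded: int
    matched_sales_usd: float
    unmatched_sales_usd: float
    unmatched_sales_pct: float
    per_country_matched_pct: Mapping[str, float]
    unmatched_brands: tuple[str, ...] = ()


@dataclass(frozen=True)
class ExclusionRules:
    """Maps sector tags and category codes to exclusion reasons."""

    sector_reasons: Mapping[str, str] = field(default_factory=dict)
    category_reasons: Mapping[str, str] = field(default_factory=dict)
    known_sectors: frozenset[str] = frozenset()


#: The study's scope rules: baby foods and infant formula are outside the
#: model; pet food, home care and alcohol are not in scope; whole fresh and
#: frozen meat is excluded because sales data for it are unavailable.
DEFAULT_EXCLUSION_RULES = ExclusionRules(
    sector_reasons={
        "baby_food": "baby_food_formula",
        "infant_formula": "baby_food_formula",
        "alcohol": "alcohol",
        "low_alcohol": "alcohol",
        "pet_food": "non_food",
        "home_care": "non_food",
        "non_food": "non_food",
    },
    category_reasons={"fresh_frozen_meat_fish": "whole_meat_unavailable"},
    known_sectors=frozenset({"food", "soft_drinks", "beverages"}),
)


def apply_exclusions(
    sales: Iterable[BrandSalesRecord],
    rules: ExclusionRules = DEFAULT_EXCLUSION_RULES,
) -> tuple[list[BrandSalesRecord], list[BrandSalesRecord]]:
    """Partition sales records into (kept, excluded) under the scope rules.

    Excluded records come back tagged with exactly one reason. A sector tag
    that is neither excluded nor known raises a warning and keeps the record.
    """
    kept: list[BrandSalesRecord] = []
    excluded: list[BrandSalesRecord] = []
    for rec in sales:
        reason = rules.sector_reasons.get(rec.sector_tag)
        if reason is None:
            reason = rules.category_reasons.get(rec.npm_category)
        if reason is not None:
            excluded.append(replace(rec, excluded_reason=reason))
            continue
        if rules.known_sectors and rec.sector_tag not in rules.known_sectors:
            warnings.warn(
                f"brand {rec.brand_label!r}: unknown sector tag {rec.sector_tag!r}; kept",
                stacklevel=2,
            )
        kept.append(rec)
    return kept, excluded


def match_brands(
    sales: Sequence[BrandSalesRecord],
    products: Sequence[ProductRecord],
    n_brands_excluded: int = 0,
) -> tuple[dict[tuple[str, str, str], list[str]], MatchReport]:
    """Exact join of kept sales records onto products.

    The join key is the full (company, country, brand_key) triple — brand
    keys alone collide across companies and countries. Returns the match
    map and a :class:`MatchReport` whose percentages are computed on the
    kept sales total. Row order of either input does not affect the result.
    """
    by_key: dict[tuple[str, str, str], list[str]] = {}
    for prod in sorted(products, key=lambda p: p.product_id):
        by_key.setdefault((prod.company, prod.country, prod.brand_key), []).append(
            prod.product_id
        )

    matches: dict[tuple[str, str, str], list[str]] = {}
    unmatched: list[BrandSalesRecord] = []
    matched_sales = 0.0
    country_total: dict[str, float] = {}
    country_matched: dict[str, float] = {}
    for rec in sorted(sales, key=lambda r: (r.company, r.country, r.brand_key)):
        key = (rec.company, rec.country, rec.brand_key)
        country_total[rec.country] = country_total.get(rec.country, 0.0) + rec.value_sales_usd
        if key in by_key:
            matches[key] = list(by_key[key])
            matched_sales += rec.value_sales_usd
            country_matched[rec.country] = (
                country_matched.get(rec.country, 0.0) + rec.value_sales_usd
            )
        else:
            unmatched.append(rec)

    total_sales = sum(country_total.values())
    unmatched_sales = sum(r.value_sales_usd for r in unmatched)
    per_country = {
        c: (100.0 * country_matched.get(c, 0.0) / t if t > 0 else 100.0)
        for c, t in sorted(country_total.items())
    }
    report = MatchReport(
        n_brands_total=len(sales) + n_brands_excluded,
        n_brands_matched=len(matches),
        n_brands_unmatched=len(unmatched),
        n_brands_excluded=n_brands_excluded,
        matched_sales_usd=matched_sales,
        unmatched_sales_usd=unmatched_sales,
        unmatched_sales_pct=(100.0 * unmatched_sales / total_sales if total_sales > 0 else 0.0),
        per_country_matched_pct=per_country,
        unmatched_brands=tuple(r.brand_label for r in unmatched),
    )
    return matches, report


def allocate_sales(
    brand: BrandSalesRecord, matched_products: Sequence[str]
) -> list[AllocatedSale]:
    """Equal-split allocation: v_i = V_b / n_b for each matched variant."""
    if not matched_products:
        raise AllocationError(
            f"brand {brand.brand_label!r} has no matched products; "
            "route it to unmatched instead of allocating"
        )
    share = brand.value_sales_usd / len(matched_products)
    return [AllocatedSale(pid, brand.brand_key, share) for pid in matched_products]


def suggest_matches(
    unmatched_label: str,
    product_brand_labels: Iterable[str],
    limit: int = 5,
    cutoff: float = 0.75,
) -> list[str]:
    """Fuzzy-assist: propose candidate brand labels for human review.

    Never auto-matches — callers must confirm any proposal before adding a
    manual link. Similarity is normalized-key sequence matching.
    """
    key = normalize_brand_key(unmatched_label)
    candidates = {normalize_brand_key(lbl): lbl for lbl in product_brand_labels if lbl.strip()}
    hits = difflib.get_close_matches(key, list(candidates), n=limit, cutoff=cutoff)
    return [candidates[h] for h in hits]
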