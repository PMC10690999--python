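"""Sales-weighted healthier/unhealthy aggregation and engagement verdicts.

The primary outcome is, per company (and per category, and overall), the
share of matched value sales derived from unhealthy products:

    unhealthy_pct = 100 * sum(v_i : verdict_i = unhealthy) / classifiable sales

where v_i is the product's equal-split allocation. Unclassifiable sales
(missing panel data) are excluded from the denominator and reported
separately, mirroring the exclusion of unmatched brands. The per-$10
framing expresses the healthier share as dollars per ten dollars spent.
Engagement verdicts compare a company's unhealthy share against a
configured cutoff; the comparison is inclusive (at most) at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import AggregationError, ConfigurationError, IntegrityError
from .npm_rules import Classification, ProductRecord
from .portfolio_link import AllocatedSale, MatchReport

__all__ = [
    "PortfolioReport",
    "EngagementVerdict",
    "aggregate",
    "per_ten_dollars",
    "evaluate_engagement",
    "coverage_summary",
    "reports_frame",
]

SCOPES = ("company", "category", "overall")
OVERALL_KEY = "all"


@dataclass(frozen=True)
class PortfolioReport:
    """Sales-weighted verdict shares for one scope key."""

    scope: str
    key: str
    matched_sales_usd: float
    unhealthy_sales_usd: float
    healthier_sales_usd: float
    unclassifiable_sales_usd: float
    unhealthy_pct: float
    healthier_pct: float


@dataclass(frozen=True)
class EngagementVerdict:
    company: str
    threshold_pct: float
    unhealthy_pct: float
    passes: bool


def aggregate(
    classifications: Sequence[Classification],
    allocations: Sequence[AllocatedSale],
    products: Sequence[ProductRecord],
    scope: str,
) -> list[PortfolioReport]:
    """Sum allocated sales by verdict within ``scope`` and compute shares.

    Every allocation must have a classification (integrity error naming the
    product otherwise). Percentages are taken on classifiable matched sales;
    if a scope group has no classifiable sales its percentages are NaN. An
    entirely empty allocation set refuses to aggregate.
    """
    if scope not in SCOPES:
        raise ConfigurationError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    if not allocations:
        raise AggregationError("no allocated sales to aggregate (nothing matched?)")

    verdict_of = {c.product_id: c.verdict for c in classifications}
    meta = {p.product_id: p for p in products}

    rows: dict[str, dict[str, float]] = {}
    for alloc in allocations:
        verdict = verdict_of.get(alloc.product_id)
        if verdict is None:
            raise IntegrityError(
                f"allocation for product {alloc.product_id!r} has no classification"
            )
        prod = meta.get(alloc.product_id)
        if prod is None:
            raise IntegrityError(
                f"allocation for product {alloc.product_id!r} has no product record"
            )
        if scope == "company":
            key = prod.company
        elif scope == "category":
            key = prod.npm_category
        else:
            key = OVERALL_KEY
        acc = rows.setdefault(key, {"unhealthy": 0.0, "healthier": 0.0, "unclassifiable": 0.0})
        acc[verdict] += alloc.allocated_usd

    reports = []
    for key in sorted(rows):
        acc = rows[key]
        classifiable = acc["unhealthy"] + acc["healthier"]
        total = classifiable + acc["unclassifiable"]
        if classifiable > 0:
            unhealthy_pct = 100.0 * acc["unhealthy"] / classifiable
            healthier_pct = 100.0 * acc["healthier"] / classifiable
        else:
            unhealthy_pct = healthier_pct = float("nan")
        reports.append(
            PortfolioReport(
                scope=scope,
                key=key,
                matched_sales_usd=total,
                unhealthy_sales_usd=acc["unhealthy"],
                healthier_sales_usd=acc["healthier"],
                unclassifiable_sales_usd=acc["unclassifiable"],
                unhealthy_pct=unhealthy_pct,
                healthier_pct=healthier_pct,
            )
        )
    return reports


def per_ten_dollars(report: PortfolioReport) -> float:
    """Healthier dollars out of every $10 spent, rounded to cents.

    E.g. an 89% unhealthy share means $1.10 of every $10 buys a healthier
    product.
    """
    if report.matched_sales_usd <= 0:
        raise AggregationError(f"scope {report.key!r}: no matched sales")
    return round(10.0 * report.healthier_pct / 100.0, 2)


def evaluate_engagement(
    reports: Iterable[PortfolioReport],
    thresholds: Sequence[float],
) -> list[EngagementVerdict]:
    """One verdict per (company report, threshold): passes iff the unhealthy
    share is at most the cutoff (inclusive at the boundary)."""
    for t in thresholds:
        if not 0 <= t <= 100:
            raise ConfigurationError(f"engagement threshold outside [0, 100]: {t}")
    verdicts = []
    for rep in sorted(reports, key=lambda r: r.key):
        for t in thresholds:
            verdicts.append(
                EngagementVerdict(
                    company=rep.key,
                    threshold_pct=float(t),
                    unhealthy_pct=rep.unhealthy_pct,
                    passes=bool(rep.unhealthy_pct <= t),
                )
            )
    return verdicts


def coverage_summary(
    match_report: MatchReport,
    unclassifiable_sales_usd: float = 0.0,
) -> dict:
    """Coverage accounting emitted with every run.

    Reports per-country and overall matched-sales percentages plus the
    share of matched sales that could not be classified. Refuses to
    proceed when nothing at all matched.
    """
    total = match_report.matched_sales_usd + match_report.unmatched_sales_usd
    if total > 0 and match_report.matched_sales_usd == 0:
        raise AggregationError("no brand could be matched; aggregation cannot run")
    overall_matched_pct = 100.0 * match_report.matched_sales_usd / total if total > 0 else 0.0
    matched = match_report.matched_sales_usd
    return {
        "n_brands_total": match_report.n_brands_total,
        "n_brands_matched": match_report.n_brands_matched,
        "n_brands_unmatched": match_report.n_brands_unmatched,
        "n_brands_excluded": match_report.n_brands_excluded,
        "matched_sales_usd": matched,
        "unmatched_sales_usd": match_report.unmatched_sales_usd,
        "matched_sales_pct": overall_matched_pct,
        "unmatched_sales_pct": match_report.unmatched_sales_pct,
        "unclassifiable_sales_usd": unclassifiable_sales_usd,
        "unclassifiable_sales_pct": (100.0 * unclassifiable_sales_usd / matched if matched > 0 else 0.0),
        "per_country_matched_pct": dict(match_report.per_country_matched_pct),
    }


def reports_frame(reports: Iterable[PortfolioReport]) -> pd.DataFrame:
    """Flatten reports into a DataFrame (one row per scope/key)."""
    return pd.DataFrame([r.__dict__ for r in reports])


def plot_stacked_bars(reports: Sequence[PortfolioReport], path) -> None:
    """Simple stacked-bar export of healthier vs unhealthy shares."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    keys = [r.key for r in reports]
    unhealthy = [r.unhealthy_pct for r in reports]
    healthier = [r.healthier_pct for r in reports]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.4 * len(keys))))
    ax.barh(keys, unhealthy, color="#c0392b", label="unhealthy")
    ax.barh(keys, healthier, left=unhealthy, color="#27ae60", label="healthier")
    ax.set_xlabel("% of matched, classifiable value sales")
    ax.set_xlim(0, 100)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
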