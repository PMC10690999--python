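"""CSV/JSON input-output and the end-to-end pipeline runner.

Input tables are UTF-8, comma-separated CSV with a header row. Malformed
rows are rejected individually with line-numbered log messages; missing
required columns fail the whole read. ``run_pipeline`` chains the stages
(exclusions -> match -> screen -> classify -> allocate -> aggregate) and
writes ``reports.csv``, ``summary.json`` and ``run.log`` to the output
directory; the summary is structurally validated before it is written.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .aggregate_report import (
    PortfolioReport,
    aggregate,
    coverage_summary,
    evaluate_engagement,
    per_ten_dollars,
    reports_frame,
)
from .errors import InputError, IntegrityError
from .ingredient_screen import load_lexicon, screen_ingredients
from .npm_rules import (
    Classification,
    NutrientPanel,
    ProductRecord,
    classify_product,
    load_threshold_table,
)
from .portfolio_link import (
    DEFAULT_EXCLUSION_RULES,
    BrandSalesRecord,
    allocate_sales,
    apply_exclusions,
    match_brands,
    normalize_brand_key,
)

__all__ = ["RunConfig", "PipelineResult", "read_products", "read_sales", "run_pipeline"]

logger = logging.getLogger("foodprofiler")

PRODUCT_REQUIRED = ("product_id", "company", "country", "brand", "npm_category")
SALES_REQUIRED = ("company", "country", "brand", "sector_tag", "npm_category", "value_sales_usd")

PANEL_COLUMNS = (
    "energy_kcal", "energy_kj", "total_fat_g", "saturated_fat_g", "trans_fat_g",
    "total_sugars_g", "added_sugars_g", "fibre_g", "protein_g", "carbohydrate_g",
    "salt_g", "sodium_mg",
)


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # parser errors carry little structure
        raise InputError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing} (no header row?)")
    return frame


def read_products(path: str | Path) -> list[ProductRecord]:
    """Read and validate a product-composition table.

    Rows with non-numeric or negative nutrient values are rejected and
    logged with their line number; a duplicated product_id fails the read.
    """
    frame = _read_csv(path, PRODUCT_REQUIRED)
    dup = frame["product_id"][frame["product_id"].duplicated()].unique().tolist()
    if dup:
        raise InputError(f"{path}: duplicated product_id(s): {dup[:10]}")
    records: list[ProductRecord] = []
    n_rejected = 0
    for idx, row in frame.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            panel_values = {}
            for col in PANEL_COLUMNS:
                raw = row.get(col, "")
                if raw is not None and str(raw).strip() != "":
                    panel_values[col] = float(raw)
            record = ProductRecord(
                product_id=row["product_id"],
                brand_key=normalize_brand_key(row["brand"]),
                company=row["company"],
                country=row["country"],
                npm_category=row["npm_category"],
                panel=NutrientPanel(**panel_values),
                ingredients_text=str(row.get("ingredients_text", "") or ""),
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("%s line %d: row rejected: %s", path, line, exc)
            continue
        records.append(record)
    logger.info("%s: %d product records read, %d rejected", path, len(records), n_rejected)
    return records


def read_sales(path: str | Path) -> list[BrandSalesRecord]:
    """Read and validate a brand value-sales table.

    Duplicate (company, country, brand) rows fail the read; rows with
    non-numeric or negative sales are rejected and logged.
    """
    frame = _read_csv(path, SALES_REQUIRED)
    key = frame["company"] + "|" + frame["country"] + "|" + frame["brand"]
    dup = key[key.duplicated()].unique().tolist()
    if dup:
        raise InputError(f"{path}: duplicated (company, country, brand) row(s): {dup[:10]}")
    records: list[BrandSalesRecord] = []
    n_rejected = 0
    for idx, row in frame.iterrows():
        line = int(idx) + 2
        try:
            record = BrandSalesRecord(
                brand_key=normalize_brand_key(row["brand"]),
                brand_label=row["brand"],
                company=row["company"],
                country=row["country"],
                npm_category=row["npm_category"],
                value_sales_usd=float(row["value_sales_usd"]),
                sector_tag=row["sector_tag"],
                year=str(row.get("year", "") or ""),
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("%s line %d: row rejected: %s", path, line, exc)
            continue
        records.append(record)
    logger.info("%s: %d sales records read, %d rejected", path, len(records), n_rejected)
    return records


@dataclass(frozen=True)
class RunConfig:
    """Paths and options for one pipeline run."""

    products_path: str | Path
    sales_path: str | Path
    out_dir: str | Path
    threshold_path: str | Path | None = None
    lexicon_path: str | Path | None = None
    engagement_thresholds: tuple[float, ...] = (49.0, 25.0, 10.0)
    scopes: tuple[str, ...] = ("overall", "company", "category")
    log_level: str = "INFO"


@dataclass(frozen=True)
class PipelineResult:
    reports: dict[str, list[PortfolioReport]]
    coverage: dict
    summary: dict
    paths: dict[str, Path] = field(default_factory=dict)


def validate_summary(summary: dict) -> None:
    """Structural validation of summary.json before writing."""
    required = {
        "model": str,
        "overall": dict,
        "healthier_usd_per_10": float,
        "coverage": dict,
        "engagement_verdicts": list,
    }
    for key, typ in required.items():
        if key not in summary:
            raise IntegrityError(f"summary missing required key {key!r}")
        if not isinstance(summary[key], typ):
            raise IntegrityError(f"summary[{key!r}] has wrong type")
    overall = summary["overall"]
    for key in ("unhealthy_pct", "healthier_pct", "matched_sales_usd"):
        if not isinstance(overall.get(key), (int, float)) or isinstance(overall.get(key), bool):
            raise IntegrityError(f"summary overall.{key} must be numeric")
    if not math.isclose(
        overall["unhealthy_pct"] + overall["healthier_pct"], 100.0, abs_tol=1e-9
    ):
        raise IntegrityError("summary overall percentages do not sum to 100")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis and write artifacts to ``config.out_dir``.

    Raises package errors on failure; the CLI maps them to exit codes
    (2 for input/config problems, 3 for integrity problems).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        table = load_threshold_table(config.threshold_path)
        lexicon = load_lexicon(config.lexicon_path)
        sales = read_sales(config.sales_path)
        if not sales:
            raise InputError(f"{config.sales_path}: no valid sales records")
        products = read_products(config.products_path)

        kept, excluded = apply_exclusions(sales, DEFAULT_EXCLUSION_RULES)
        for rec in excluded:
            logger.info(
                "excluded brand=%r country=%s reason=%s",
                rec.brand_label, rec.country, rec.excluded_reason,
            )
        matches, match_report = match_brands(kept, products, n_brands_excluded=len(excluded))
        for label in match_report.unmatched_brands:
            logger.info("unmatched brand=%r reason=no_composition_match", label)

        matched_ids = {pid for pids in matches.values() for pid in pids}
        classifications: list[Classification] = []
        n_unscreenable = 0
        matched_products = [p for p in products if p.product_id in matched_ids]
        for prod in matched_products:
            screen = screen_ingredients(prod.ingredients_text, lexicon, prod.product_id)
            if not screen.screenable:
                n_unscreenable += 1
            cls = classify_product(prod, table, screen.has_added_sugar, screen.has_nss)
            if cls.verdict == "unclassifiable":
                logger.info("unclassifiable product=%s reason=%s", prod.product_id, cls.reason)
            classifications.append(cls)

        allocations = []
        for rec in kept:
            key = (rec.company, rec.country, rec.brand_key)
            if key in matches:
                allocations.extend(allocate_sales(rec, matches[key]))

        reports = {
            scope: aggregate(classifications, allocations, matched_products, scope)
            for scope in config.scopes
        }
        overall = reports.get("overall", aggregate(classifications, allocations, matched_products, "overall"))[0]
        coverage = coverage_summary(match_report, overall.unclassifiable_sales_usd)
        coverage["n_unscreenable_products"] = n_unscreenable
        verdicts = evaluate_engagement(
            reports.get("company", []), config.engagement_thresholds
        )

        summary = {
            "model": f"{table.model_name} ({table.version})",
            "overall": overall.__dict__,
            "healthier_usd_per_10": per_ten_dollars(overall),
            "coverage": coverage,
            "engagement_verdicts": [v.__dict__ for v in verdicts],
        }
        validate_summary(summary)

        all_reports = [r for scope in config.scopes for r in reports[scope]]
        paths = {
            "reports": out_dir / "reports.csv",
            "summary": out_dir / "summary.json",
            "log": out_dir / "run.log",
        }
        reports_frame(all_reports).to_csv(paths["reports"], index=False)
        paths["summary"].write_text(
            json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
        )
        logger.info(
            "overall unhealthy_pct=%.6f healthier_usd_per_10=%.2f",
            overall.unhealthy_pct, summary["healthier_usd_per_10"],
        )
        return PipelineResult(reports=reports, coverage=coverage, summary=summary, paths=paths)
    finally:
        logger.removeHandler(handler)
        handler.close()
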