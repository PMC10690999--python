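"""WHO Euro (2015) nutrient profile model as a data-driven rules engine.

The model assigns every pre-packaged food to one of 20 categories. A
category is either never permitted to be marketed to children
(confectionery, sweet bakery, edible ices, energy drinks, juices),
always permitted (fresh/frozen fruit and vegetables, fresh/frozen meat
and fish), or evaluated against per-100 g/ml nutrient maxima plus
optional prohibitions on added sugars and non-sugar sweeteners (NSS).
A product that fails any criterion is "unhealthy"; a product that
passes every criterion is "healthier". Equality with a maximum passes:
only strictly exceeding a threshold fails.

The threshold table is loaded from a YAML config; the packaged default
(``who_euro_2015``) transcribes the first edition of the WHO European
Region model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import ClassificationError, ConfigurationError

__all__ = [
    "NutrientPanel",
    "ProductRecord",
    "ThresholdRule",
    "ThresholdTable",
    "Classification",
    "load_threshold_table",
    "normalize_panel",
    "classify_product",
    "SODIUM_TO_SALT",
    "KJ_PER_KCAL",
]

#: grams of salt per mg of sodium: salt = sodium_mg * 2.5 / 1000
SODIUM_TO_SALT = 2.5 / 1000.0
#: kJ in one kcal
KJ_PER_KCAL = 4.184

PERMISSION_MODES = ("always_permitted", "never_permitted", "threshold_evaluated")

#: nutrient names a ThresholdRule may bound (all per 100 g/ml)
THRESHOLD_NUTRIENTS = (
    "energy_kcal",
    "total_fat_g",
    "saturated_fat_g",
    "trans_fat_g",
    "total_sugars_g",
    "salt_g",
)

#: nutrients evaluated only when present; absence never makes a product
#: unclassifiable (trans fats are not part of the standard label panel)
OPTIONAL_THRESHOLD_NUTRIENTS = frozenset({"trans_fat_g"})

CATEGORY_NOT_PERMITTED = "category_not_permitted"


@dataclass(frozen=True)
class NutrientPanel:
    """Per-100 g/ml nutrient declaration of one product. Missing = None."""

    energy_kcal: float | None = None
    energy_kj: float | None = None
    total_fat_g: float | None = None
    saturated_fat_g: float | None = None
    trans_fat_g: float | None = None
    total_sugars_g: float | None = None
    added_sugars_g: float | None = None
    fibre_g: float | None = None
    protein_g: float | None = None
    carbohydrate_g: float | None = None
    salt_g: float | None = None
    sodium_mg: float | None = None

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value is not None and value < 0:
                raise ValueError(f"nutrient {name} is negative: {value}")
        if self.energy_kcal is not None and self.energy_kj is not None:
            if abs(self.energy_kcal - self.energy_kj / KJ_PER_KCAL) > 1.0:
                raise ValueError(
                    "energy_kcal and energy_kj disagree by more than 1 kcal: "
                    f"{self.energy_kcal} kcal vs {self.energy_kj} kJ"
                )


@dataclass(frozen=True)
class ProductRecord:
    """One packaged product with its composition panel and ingredient text."""

    product_id: str
    brand_key: str
    company: str
    country: str
    npm_category: str
    panel: NutrientPanel
    ingredients_text: str = ""


@dataclass(frozen=True)
class ThresholdRule:
    """Permission mode and criteria for one WHO Euro category."""

    category_code: str
    permission_mode: str
    maxima: Mapping[str, float] = field(default_factory=dict)
    forbid_added_sugars: bool = False
    forbid_nss: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if self.permission_mode not in PERMISSION_MODES:
            raise ConfigurationError(
                f"category {self.category_code}: unknown permission_mode "
                f"{self.permission_mode!r}"
            )
        for nutrient, value in self.maxima.items():
            if nutrient not in THRESHOLD_NUTRIENTS:
                raise ConfigurationError(
                    f"category {self.category_code}: unknown nutrient in maxima: "
                    f"{nutrient!r}"
                )
            if value < 0:
                raise ConfigurationError(
                    f"category {self.category_code}: maximum for {nutrient} "
                    f"is negative: {value}"
                )
        has_criteria = bool(self.maxima) or self.forbid_added_sugars or self.forbid_nss
        if self.permission_mode == "threshold_evaluated" and not has_criteria:
            raise ConfigurationError(
                f"category {self.category_code}: threshold_evaluated rule has "
                "no maxima and no added-sugar/NSS prohibition"
            )
        if self.permission_mode != "threshold_evaluated" and has_criteria:
            raise ConfigurationError(
                f"category {self.category_code}: {self.permission_mode} rule "
                "must not carry maxima or prohibitions"
            )


@dataclass(frozen=True)
class ThresholdTable:
    """Complete category -> rule map for one nutrient profile model."""

    rules: Mapping[str, ThresholdRule]
    model_name: str = ""
    version: str = ""

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.rules)

    def rule_for(self, category_code: str) -> ThresholdRule:
        try:
            return self.rules[category_code]
        except KeyError:
            raise ClassificationError(
                f"unknown WHO Euro category: {category_code!r}"
            ) from None


@dataclass(frozen=True)
class Classification:
    """Verdict for one product: healthier, unhealthy, or unclassifiable."""

    product_id: str
    verdict: str
    failed_criteria: tuple[str, ...] = ()
    reason: str = ""


def default_threshold_path() -> Path:
    """Path of the packaged ``who_euro_2015`` threshold config."""
    return Path(str(resources.files("foodprofiler").joinpath("data/who_euro_2015.yaml")))


def load_threshold_table(
    config_path: str | Path | None = None,
    vocabulary: Iterable[str] | None = None,
) -> ThresholdTable:
    """Load and validate a threshold-table config.

    With no argument, loads the packaged WHO Euro (2015) table. When a
    ``vocabulary`` of category codes is given, every code must have exactly
    one rule. Raises :class:`ConfigurationError` naming the offending field
    on any schema violation or duplicated category.
    """
    path = Path(config_path) if config_path is not None else default_threshold_path()
    if not path.exists():
        raise ConfigurationError(f"threshold config not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    if not isinstance(raw, dict) or "categories" not in raw:
        raise ConfigurationError(f"{path}: missing top-level 'categories' list")
    entries = raw["categories"]
    if not isinstance(entries, list) or not entries:
        raise ConfigurationError(f"{path}: 'categories' must be a non-empty list")

    rules: dict[str, ThresholdRule] = {}
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict):
            raise ConfigurationError(f"{path}: categories[{i}] is not a mapping")
        code = entry.get("category_code")
        if not code or not isinstance(code, str):
            raise ConfigurationError(f"{path}: categories[{i}]: missing category_code")
        if code in rules:
            raise ConfigurationError(f"{path}: duplicate category {code!r}")
        mode = entry.get("permission_mode")
        if not isinstance(mode, str):
            raise ConfigurationError(f"{path}: category {code}: missing permission_mode")
        maxima = entry.get("maxima", {}) or {}
        if not isinstance(maxima, dict):
            raise ConfigurationError(f"{path}: category {code}: maxima must be a mapping")
        for nutrient, value in maxima.items():
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                raise ConfigurationError(
                    f"{path}: category {code}: maxima[{nutrient}] is not numeric"
                )
        for flag in ("forbid_added_sugars", "forbid_nss"):
            if not isinstance(entry.get(flag, False), bool):
                raise ConfigurationError(f"{path}: category {code}: {flag} must be boolean")
        unknown = set(entry) - {
            "category_code", "label", "permission_mode", "maxima",
            "forbid_added_sugars", "forbid_nss",
        }
        if unknown:
            raise ConfigurationError(
                f"{path}: category {code}: unknown field(s) {sorted(unknown)}"
            )
        rules[code] = ThresholdRule(
            category_code=code,
            permission_mode=mode,
            maxima={k: float(v) for k, v in maxima.items()},
            forbid_added_sugars=entry.get("forbid_added_sugars", False),
            forbid_nss=entry.get("forbid_nss", False),
            label=entry.get("label", ""),
        )
    if vocabulary is not None:
        absent = sorted(set(vocabulary) - set(rules))
        if absent:
            raise ConfigurationError(
                f"{path}: no rule for category(ies) {absent} of the vocabulary"
            )
    return ThresholdTable(
        rules=rules,
        model_name=str(raw.get("model_name", "")),
        version=str(raw.get("version", "")),
    )


def normalize_panel(panel: NutrientPanel) -> NutrientPanel:
    """Harmonize units: derive salt from sodium and kcal from kJ when absent.

    All originally present values are preserved; nothing else changes.
    """
    updates: dict[str, float] = {}
    if panel.salt_g is None and panel.sodium_mg is not None:
        updates["salt_g"] = panel.sodium_mg * SODIUM_TO_SALT
    if panel.energy_kcal is None and panel.energy_kj is not None:
        updates["energy_kcal"] = panel.energy_kj / KJ_PER_KCAL
    return replace(panel, **updates) if updates else panel


def classify_product(
    product: ProductRecord,
    table: ThresholdTable,
    sugar_flag: bool = False,
    nss_flag: bool = False,
) -> Classification:
    """Apply the product's category rule to its (normalized) nutrient panel.

    ``sugar_flag`` / ``nss_flag`` come from ingredient screening (see
    :mod:`foodprofiler.ingredient_screen`); a declared ``added_sugars_g > 0``
    also sets the sugar flag. A nutrient named in the rule's maxima that is
    still absent after unit normalization makes the product unclassifiable,
    unless another criterion already failed (a failure is decisive on its
    own). Equality with a maximum passes.
    """
    rule = table.rule_for(product.npm_category)
    if rule.permission_mode == "never_permitted":
        return Classification(product.product_id, "unhealthy", (CATEGORY_NOT_PERMITTED,))
    if rule.permission_mode == "always_permitted":
        return Classification(product.product_id, "healthier")

    panel = normalize_panel(product.panel)
    if panel.added_sugars_g is not None and panel.added_sugars_g > 0:
        sugar_flag = True

    failed: list[str] = []
    missing: list[str] = []
    for nutrient in sorted(rule.maxima):
        value = getattr(panel, nutrient)
        if value is None:
            if nutrient not in OPTIONAL_THRESHOLD_NUTRIENTS:
                missing.append(nutrient)
        elif value > rule.maxima[nutrient]:
            failed.append(nutrient)
    if rule.forbid_added_sugars and sugar_flag:
        failed.append("added_sugars")
    if rule.forbid_nss and nss_flag:
        failed.append("nss")

    if failed:
        return Classification(product.product_id, "unhealthy", tuple(failed))
    if missing:
        return Classification(
            product.product_id,
            "unclassifiable",
            reason="missing_nutrient:" + ",".join(missing),
        )
    return Classification(product.product_id, "healthier")
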