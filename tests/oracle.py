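"""Independent brute-force re-implementation of the classification rules.

Deliberately written against raw dicts rather than the package's types so
it shares no code path with the engine it cross-checks: it re-derives salt
from sodium and kcal from kJ itself and evaluates every criterion one by
one.
"""

from __future__ import annotations

import numpy as np


def brute_force_verdict(
    category: str,
    panel: dict[str, float | None],
    sugar_flag: bool,
    nss_flag: bool,
    rules: dict[str, dict],
) -> str:
    """Return healthier / unhealthy / unclassifiable for one raw product."""
    rule = rules[category]
    if rule["permission_mode"] == "never_permitted":
        return "unhealthy"
    if rule["permission_mode"] == "always_permitted":
        return "healthier"

    values = dict(panel)
    if values.get("salt_g") is None and values.get("sodium_mg") is not None:
        values["salt_g"] = values["sodium_mg"] * 2.5 / 1000.0
    if values.get("energy_kcal") is None and values.get("energy_kj") is not None:
        values["energy_kcal"] = values["energy_kj"] / 4.184
    if values.get("added_sugars_g") is not None and values["added_sugars_g"] > 0:
        sugar_flag = True

    any_failed = False
    any_missing = False
    for nutrient, maximum in rule.get("maxima", {}).items():
        v = values.get(nutrient)
        if v is None:
            if nutrient != "trans_fat_g":  # trans fats only evaluated when declared
                any_missing = True
        elif v > maximum:
            any_failed = True
    if rule.get("forbid_added_sugars") and sugar_flag:
        any_failed = True
    if rule.get("forbid_nss") and nss_flag:
        any_failed = True

    if any_failed:
        return "unhealthy"
    if any_missing:
        return "unclassifiable"
    return "healthier"


def rules_as_dicts(table) -> dict[str, dict]:
    """Dump a ThresholdTable to plain dicts for the oracle."""
    return {
        code: {
            "permission_mode": rule.permission_mode,
            "maxima": dict(rule.maxima),
            "forbid_added_sugars": rule.forbid_added_sugars,
            "forbid_nss": rule.forbid_nss,
        }
        for code, rule in table.rules.items()
    }


def random_raw_products(
    rng: np.random.Generator, categories: list[str], n: int
) -> list[dict]:
    """Random raw products spanning present/absent fields and both flags."""
    out = []
    for i in range(n):
        panel: dict[str, float | None] = {}
        for name, scale in (
            ("energy_kcal", 600.0),
            ("total_fat_g", 40.0),
            ("saturated_fat_g", 25.0),
            ("trans_fat_g", 3.0),
            ("total_sugars_g", 40.0),
            ("added_sugars_g", 20.0),
            ("salt_g", 3.0),
            ("sodium_mg", 1200.0),
            ("fibre_g", 10.0),
            ("protein_g", 25.0),
            ("carbohydrate_g", 70.0),
        ):
            panel[name] = float(rng.uniform(0, scale)) if rng.random() < 0.8 else None
        if panel["salt_g"] is not None and panel["sodium_mg"] is not None:
            panel["sodium_mg"] = None  # declared panels carry one or the other
        panel["energy_kj"] = (
            panel["energy_kcal"] * 4.184 if panel["energy_kcal"] is not None else None
        )
        if rng.random() < 0.5:
            if rng.random() < 0.5:
                panel["energy_kcal"] = None
            else:
                panel["energy_kj"] = None
        out.append(
            {
                "product_id": f"R{i:06d}",
                "category": categories[int(rng.integers(len(categories)))],
                "panel": panel,
                "sugar_flag": bool(rng.random() < 0.4),
                "nss_flag": bool(rng.random() < 0.2),
            }
        )
    return out
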