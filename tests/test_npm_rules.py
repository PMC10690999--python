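"""Rules-engine behaviour: table loading, unit normalization, classification."""

import dataclasses

import numpy as np
import pytest
import yaml

from foodprofiler import (
    Classification,
    ClassificationError,
    ConfigurationError,
    NutrientPanel,
    ProductRecord,
    classify_product,
    load_threshold_table,
    normalize_panel,
)
from foodprofiler.npm_rules import ThresholdRule

from .oracle import brute_force_verdict, random_raw_products, rules_as_dicts


def make_product(category, panel=None, pid="p1", **panel_kwargs):
    return ProductRecord(
        product_id=pid,
        brand_key="brand",
        company="Co",
        country="GB",
        npm_category=category,
        panel=panel if panel is not None else NutrientPanel(**panel_kwargs),
    )


ZERO_PANEL = dict(
    energy_kcal=0, total_fat_g=0, saturated_fat_g=0, total_sugars_g=0, salt_g=0
)


class TestLoadThresholdTable:
    def test_packaged_default_structure(self, table):
        assert len(table.categories) == 20
        assert table.rule_for("confectionery").permission_mode == "never_permitted"
        assert table.rule_for("fresh_frozen_fruit_veg").permission_mode == "always_permitted"
        # the five never-permitted categories
        never = {c for c in table.categories
                 if table.rule_for(c).permission_mode == "never_permitted"}
        assert never == {"confectionery", "sweet_bakery", "edible_ices",
                         "energy_drinks", "juices"}

    def test_missing_vocabulary_category_is_config_error(self, table, tmp_path):
        raw = yaml.safe_load(
            __import__("foodprofiler.npm_rules", fromlist=["default_threshold_path"])
            .default_threshold_path().read_text()
        )
        raw["categories"] = [c for c in raw["categories"]
                             if c["category_code"] != "cheese"]
        p = tmp_path / "partial.yaml"
        p.write_text(yaml.safe_dump(raw))
        with pytest.raises(ConfigurationError, match="cheese"):
            load_threshold_table(p, vocabulary=table.categories)

    def test_duplicate_category_is_config_error(self, tmp_path):
        p = tmp_path / "dup.yaml"
        entry = {"category_code": "cheese", "permission_mode": "threshold_evaluated",
                 "maxima": {"salt_g": 1.3}}
        p.write_text(yaml.safe_dump({"categories": [entry, dict(entry)]}))
        with pytest.raises(ConfigurationError, match="duplicate"):
            load_threshold_table(p)

    @pytest.mark.parametrize(
        "entry, match",
        [
            ({"permission_mode": "threshold_evaluated"}, "category_code"),
            ({"category_code": "x"}, "permission_mode"),
            ({"category_code": "x", "permission_mode": "sometimes"}, "permission_mode"),
            ({"category_code": "x", "permission_mode": "threshold_evaluated",
              "maxima": {"salt_g": "salty"}}, "not numeric"),
            ({"category_code": "x", "permission_mode": "threshold_evaluated",
              "maxima": {"unobtainium_g": 1}}, "unknown nutrient"),
            ({"category_code": "x", "permission_mode": "threshold_evaluated"},
             "no maxima"),
            ({"category_code": "x", "permission_mode": "never_permitted",
              "maxima": {"salt_g": 1}}, "must not carry"),
        ],
    )
    def test_schema_violations_name_the_field(self, tmp_path, entry, match):
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump({"categories": [entry]}))
        with pytest.raises(ConfigurationError, match=match):
            load_threshold_table(p)


class TestNormalizePanel:
    def test_salt_from_sodium(self):
        assert normalize_panel(NutrientPanel(sodium_mg=400)).salt_g == pytest.approx(1.0)

    def test_kcal_from_kj(self):
        assert normalize_panel(NutrientPanel(energy_kj=418.4)).energy_kcal == pytest.approx(100.0)

    def test_present_values_unchanged(self):
        panel = NutrientPanel(salt_g=0.5, sodium_mg=800, energy_kcal=100, energy_kj=418.4)
        assert normalize_panel(panel) == panel

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match="total_fat_g"):
            NutrientPanel(total_fat_g=-1)

    def test_inconsistent_energy_rejected(self):
        with pytest.raises(ValueError, match="disagree"):
            NutrientPanel(energy_kcal=100, energy_kj=500)


class TestClassifyProduct:
    def test_never_permitted_category_always_unhealthy(self, table):
        cls = classify_product(make_product("confectionery", **ZERO_PANEL), table)
        assert cls == Classification("p1", "unhealthy", ("category_not_permitted",))

    def test_zero_panel_passes_thresholds(self, table):
        cls = classify_product(make_product("breakfast_cereals", **ZERO_PANEL), table)
        assert cls.verdict == "healthier"
        assert cls.failed_criteria == ()

    def test_equality_with_maximum_passes(self, table):
        m = table.rule_for("breakfast_cereals").maxima["total_sugars_g"]
        cls = classify_product(
            make_product("breakfast_cereals", **{**ZERO_PANEL, "total_sugars_g": m}), table
        )
        assert cls.verdict == "healthier"

    def test_strictly_above_maximum_fails(self, table):
        m = table.rule_for("breakfast_cereals").maxima["total_sugars_g"]
        cls = classify_product(
            make_product("breakfast_cereals", **{**ZERO_PANEL, "total_sugars_g": m + 0.01}),
            table,
        )
        assert cls.verdict == "unhealthy"
        assert "total_sugars_g" in cls.failed_criteria

    def test_missing_required_nutrient_is_unclassifiable(self, table):
        panel = dict(ZERO_PANEL)
        panel.pop("total_sugars_g")
        cls = classify_product(make_product("breakfast_cereals", **panel), table)
        assert cls.verdict == "unclassifiable"
        assert "total_sugars_g" in cls.reason

    def test_failure_trumps_missing(self, table):
        # salt above its maximum decides even though sugars are absent
        cls = classify_product(
            make_product("breakfast_cereals", energy_kcal=0, total_fat_g=0, salt_g=5),
            table,
        )
        assert cls.verdict == "unhealthy"

    def test_sugar_and_nss_flags_fail_forbidding_category(self, table):
        prod = make_product("other_beverages", energy_kcal=1)
        assert classify_product(prod, table, sugar_flag=True).verdict == "unhealthy"
        assert classify_product(prod, table, nss_flag=True).verdict == "unhealthy"
        assert classify_product(prod, table).verdict == "healthier"

    def test_declared_added_sugars_sets_flag(self, table):
        prod = make_product("other_beverages", added_sugars_g=5.0)
        cls = classify_product(prod, table)
        assert cls.verdict == "unhealthy"
        assert "added_sugars" in cls.failed_criteria

    def test_sodium_declared_panel_classifies_on_salt(self, table):
        # 800 mg sodium = 2 g salt > 1.6 g cereals maximum
        prod = make_product("breakfast_cereals",
                            **{**{k: v for k, v in ZERO_PANEL.items() if k != "salt_g"},
                               "sodium_mg": 800})
        assert classify_product(prod, table).verdict == "unhealthy"

    def test_unknown_category_raises(self, table):
        with pytest.raises(ClassificationError, match="pemmican"):
            classify_product(make_product("pemmican", **ZERO_PANEL), table)

    def test_trans_fat_absence_does_not_block(self, table):
        rule = table.rule_for("butter_fats_oils")
        augmented = dataclasses.replace(rule, maxima={**rule.maxima, "trans_fat_g": 1.0})
        t2 = dataclasses.replace(table, rules={**dict(table.rules), "butter_fats_oils": augmented})
        prod = make_product("butter_fats_oils", saturated_fat_g=1, salt_g=0)
        assert classify_product(prod, t2).verdict == "healthier"
        bad = make_product("butter_fats_oils", saturated_fat_g=1, salt_g=0, trans_fat_g=2)
        assert classify_product(bad, t2).verdict == "unhealthy"


class TestProperties:
    def test_determinism(self, table):
        prod = make_product("yoghurts_creams", total_fat_g=1, saturated_fat_g=1,
                            total_sugars_g=5, salt_g=0.1)
        results = {classify_product(prod, table, True, False) for _ in range(5)}
        assert len(results) == 1

    def test_category_forcing_on_random_panels(self, table):
        rng = np.random.default_rng(11)
        for raw in random_raw_products(rng, ["confectionery", "fresh_frozen_fruit_veg"], 500):
            panel = NutrientPanel(**{k: v for k, v in raw["panel"].items()
                                     if k != "energy_kj"})
            verdict = classify_product(
                make_product(raw["category"], panel=panel, pid=raw["product_id"]),
                table, raw["sugar_flag"], raw["nss_flag"],
            ).verdict
            expected = ("unhealthy" if raw["category"] == "confectionery" else "healthier")
            assert verdict == expected

    def test_lowering_maxima_never_rescues_a_product(self, table):
        """Monotonicity: tightening any threshold cannot flip unhealthy -> healthier."""
        rng = np.random.default_rng(12)
        threshold_cats = [c for c in table.categories
                          if table.rule_for(c).permission_mode == "threshold_evaluated"]
        for raw in random_raw_products(rng, threshold_cats, 300):
            panel = NutrientPanel(**{k: v for k, v in raw["panel"].items()
                                     if k != "energy_kj"})
            prod = make_product(raw["category"], panel=panel, pid=raw["product_id"])
            before = classify_product(prod, table, raw["sugar_flag"], raw["nss_flag"]).verdict
            rule = table.rule_for(raw["category"])
            for nutrient in rule.maxima:
                tighter = dataclasses.replace(
                    rule, maxima={**rule.maxima, nutrient: rule.maxima[nutrient] * 0.5}
                )
                t2 = dataclasses.replace(
                    table, rules={**dict(table.rules), raw["category"]: tighter}
                )
                after = classify_product(prod, t2, raw["sugar_flag"], raw["nss_flag"]).verdict
                if before == "unhealthy":
                    assert after == "unhealthy"

    def test_agrees_with_brute_force_oracle(self, table):
        rng = np.random.default_rng(13)
        rules = rules_as_dicts(table)
        for raw in random_raw_products(rng, list(table.categories), 2000):
            panel = NutrientPanel(**raw["panel"])
            got = classify_product(
                make_product(raw["category"], panel=panel, pid=raw["product_id"]),
                table, raw["sugar_flag"], raw["nss_flag"],
            ).verdict
            want = brute_force_verdict(
                raw["category"], raw["panel"], raw["sugar_flag"], raw["nss_flag"], rules
            )
            assert got == want, raw


def test_threshold_rule_invariants():
    with pytest.raises(ConfigurationError):
        ThresholdRule("x", "threshold_evaluated", maxima={})
    with pytest.raises(ConfigurationError):
        ThresholdRule("x", "threshold_evaluated", maxima={"salt_g": -1})
    # a prohibition alone is a valid criterion (e.g. plain beverages)
    rule = ThresholdRule("x", "threshold_evaluated", forbid_nss=True)
    assert rule.forbid_nss
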