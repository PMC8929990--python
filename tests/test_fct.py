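"""Food-composition tables, sentinel resolution, and recipe arithmetic."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from dietrecall.errors import FCTError
from dietrecall.fct import (
    FCTable,
    FctContext,
    FoodItem,
    NEW_RECIPE_CODE,
    Recipe,
    RecipeRegistry,
    UNKNOWN_CODE,
    load_fct,
    recipe_nutrients_per_100g,
    register_recipe,
    resolve_code,
    write_fct,
)
from dietrecall.nutrivec import NUTRIENTS, NutrientVector


class TestNutrientVector:
    def test_componentwise_addition_and_scaling(self):
        a = NutrientVector(energy_kcal=100, protein_g=10, animal_protein_g=4)
        b = NutrientVector(energy_kcal=50, protein_g=2)
        s = a + b
        assert s.energy_kcal == 150 and s.protein_g == 12 and s.animal_protein_g == 4
        assert (a * 2.5).energy_kcal == 250

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"energy_kcal": -1.0},
            {"protein_g": 5.0, "animal_protein_g": 6.0},
            {"iron_mg": float("nan")},
        ],
    )
    def test_invalid_vectors_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NutrientVector(**kwargs)

    def test_negative_scale_rejected(self):
        with pytest.raises(ValueError):
            NutrientVector(energy_kcal=1.0).scaled(-1.0)


class TestLoadFct:
    def test_three_row_fixture_parses_field_for_field(self, tiny_fct):
        assert len(tiny_fct) == 3
        assert set(tiny_fct.items) == {"T001", "T002", "T003"}
        ugali = tiny_fct.get("T001")
        assert ugali.name == "maize ugali"
        assert ugali.food_group == "cereals"
        assert ugali.per100g.energy_kcal == 112.0
        assert ugali.per100g.folate_ug == 18.0
        fish = tiny_fct.get("T002")
        assert fish.edible_fraction == 0.8
        assert fish.per100g.animal_protein_g == 17.0

    def test_duplicate_code_error_names_both_rows(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "code,name,food_group,edible_fraction,energy_kcal\n"
            "X1,a,g,1.0,10\nX1,b,g,1.0,20\n"
        )
        with pytest.raises(FCTError, match=r"rows 2 and 3"):
            load_fct(path, "primary")

    def test_header_only_file_gives_empty_table(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("code,name,food_group,edible_fraction,energy_kcal\n")
        assert len(load_fct(path, "primary")) == 0

    def test_missing_nutrient_columns_default_to_zero_with_warning(
        self, tmp_path, caplog
    ):
        path = tmp_path / "partial.csv"
        path.write_text("code,name,food_group,edible_fraction,energy_kcal\nX1,a,g,1.0,10\n")
        with caplog.at_level("WARNING"):
            table = load_fct(path, "primary")
        assert table.get("X1").per100g.protein_g == 0.0
        assert any("defaulting to 0" in r.message for r in caplog.records)

    @pytest.mark.parametrize(
        "row,match",
        [
            ("X1,a,g,1.0,-5", "negative"),
            ("9999,a,g,1.0,5", "sentinel"),
            ("X1,a,g,1.4,5", "edible_fraction"),
        ],
    )
    def test_bad_rows_rejected(self, tmp_path, row, match):
        path = tmp_path / "bad.csv"
        path.write_text(f"code,name,food_group,edible_fraction,energy_kcal\n{row}\n")
        with pytest.raises(FCTError, match=match):
            load_fct(path, "primary")

    def test_tab_delimited_accepted(self, tmp_path):
        path = tmp_path / "fct.tsv"
        path.write_text(
            "code\tname\tfood_group\tedible_fraction\tenergy_kcal\nX1\ta\tg\t1.0\t10\n"
        )
        assert load_fct(path, "primary").get("X1").per100g.energy_kcal == 10.0

    def test_write_back_reload_reproduces_items_exactly(self, tiny_fct, tmp_path):
        out = tmp_path / "out.csv"
        write_fct(tiny_fct, out)
        reloaded = load_fct(out, "primary")
        assert reloaded.items == tiny_fct.items


class TestResolveCode:
    def test_direct_primary_hit(self, tiny_fct):
        r = resolve_code("T001", "maize ugali", tiny_fct)
        assert r.source == "primary_fct"
        assert r.item is tiny_fct.get("T001")

    def test_unknown_code_with_assignment_to_secondary(self, tiny_fct, secondary_fct):
        r = resolve_code(
            UNKNOWN_CODE,
            "octopus stew",
            tiny_fct,
            secondary_fct,
            assignments={"octopus stew": "K100"},
        )
        assert r.source == "secondary_fct"
        assert r.item.code == "K100"
        assert "assignment" in r.audit

    def test_unknown_code_without_assignment_is_unresolved(
        self, tiny_fct, secondary_fct
    ):
        r = resolve_code(UNKNOWN_CODE, "mystery dish", tiny_fct, secondary_fct)
        assert r.source == "unresolved" and r.item is None

    def test_new_recipe_code_without_recipe_has_distinct_audit(self, tiny_fct):
        r = resolve_code(NEW_RECIPE_CODE, "new dish", tiny_fct)
        assert r.source == "unresolved"
        assert "no recipe assigned" in r.audit

    def test_new_recipe_code_with_assigned_recipe(self, tiny_fct):
        recipes = RecipeRegistry(
            [Recipe.build("R01", "ugali remix", [("T001", 100.0)])]
        )
        r = resolve_code(
            NEW_RECIPE_CODE,
            "ugali remix",
            tiny_fct,
            assignments={"ugali remix": "R01"},
            recipes=recipes,
        )
        assert r.source == "recipe"
        assert r.item.per100g.allclose(tiny_fct.get("T001").per100g)

    def test_entry_id_assignment_takes_precedence_over_description(self, tiny_fct):
        r = resolve_code(
            UNKNOWN_CODE,
            "dish",
            tiny_fct,
            assignments={"dish": "T003", "P1:2019-03-12:4": "T001"},
            entry_id="P1:2019-03-12:4",
        )
        assert r.item.code == "T001"

    def test_resolution_is_deterministic(self, tiny_fct, secondary_fct):
        args = (UNKNOWN_CODE, "octopus stew", tiny_fct, secondary_fct)
        kwargs = {"assignments": {"octopus stew": "K100"}}
        first = resolve_code(*args, **kwargs)
        for _ in range(5):
            again = resolve_code(*args, **kwargs)
            assert again == first


class TestRecipeNutrients:
    def test_single_ingredient_100g_is_identity(self, tiny_fct):
        r = Recipe.build("R1", "plain ugali", [("T001", 100.0)])
        vec = recipe_nutrients_per_100g(r, tiny_fct)
        assert vec.allclose(tiny_fct.get("T001").per100g)

    def test_equal_mass_blend_is_componentwise_mean(self, tiny_fct):
        # both ingredients have edible fraction 1.0 so the mean is exact
        a = tiny_fct.get("T001").per100g
        b = NutrientVector(energy_kcal=200, protein_g=4.0, carb_g=40.0)
        table = FCTable("primary")
        table.add(tiny_fct.get("T001"))
        table.add(FoodItem("X9", "flour", "cereals", b, 1.0))
        r = Recipe.build("R2", "blend", [("T001", 50.0), ("X9", 50.0)])
        vec = recipe_nutrients_per_100g(r, table)
        for n in NUTRIENTS:
            assert math.isclose(
                getattr(vec, n), (getattr(a, n) + getattr(b, n)) / 2, rel_tol=1e-12
            )

    def test_cooked_weight_concentration_matches_hand_arithmetic(self, tiny_fct):
        # 200 g raw reduced to 100 g cooked: every component exactly doubles
        r = Recipe.build("R3", "reduced", [("T001", 200.0)], cooked_weight_g=100.0)
        vec = recipe_nutrients_per_100g(r, tiny_fct)
        expected = {  # hand-computed from the fixture row
            "energy_kcal": 224.0, "protein_g": 6.2, "fat_g": 1.0,
            "carb_g": 46.0, "fiber": 2.4, "calcium_mg": 16.0,
            "iron_mg": 1.8, "zinc_mg": 1.2, "folate_ug": 36.0,
        }
        for n, v in expected.items():
            assert math.isclose(getattr(vec, n), v, rel_tol=1e-12)

    def test_edible_fraction_applies_to_raw_ingredient_mass(self, tiny_fct):
        # 100 g as-purchased mango at EP 0.69 contributes 69 g edible
        r = Recipe.build("R4", "mango mash", [("T003", 100.0)])
        vec = recipe_nutrients_per_100g(r, tiny_fct)
        assert math.isclose(vec.energy_kcal, 60.0 * 0.69, rel_tol=1e-12)

    def test_unresolvable_ingredient_error_names_it(self, tiny_fct):
        r = Recipe.build("R5", "bad", [("NOPE", 100.0)])
        with pytest.raises(FCTError, match="NOPE"):
            recipe_nutrients_per_100g(r, tiny_fct)

    @given(k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, k):
        table = FCTable("primary")
        table.add(
            FoodItem(
                "A", "a", "g",
                NutrientVector(energy_kcal=120, protein_g=5, fat_g=3, carb_g=20),
                0.9,
            )
        )
        table.add(
            FoodItem(
                "B", "b", "g",
                NutrientVector(energy_kcal=60, protein_g=2, fat_g=1, carb_g=10),
                1.0,
            )
        )
        base = Recipe.build("R", "r", [("A", 120.0), ("B", 80.0)], cooked_weight_g=150.0)
        scaled = Recipe.build(
            "R", "r", [("A", 120.0 * k), ("B", 80.0 * k)], cooked_weight_g=150.0 * k
        )
        v0 = recipe_nutrients_per_100g(base, table)
        v1 = recipe_nutrients_per_100g(scaled, table)
        assert v0.allclose(v1, rel=1e-9)

    def test_weighted_mean_bounds_without_cooked_weight(self, tiny_fct):
        # each component lies within [min, max] of the EP-scaled ingredients
        r = Recipe.build("R6", "mix", [("T001", 30.0), ("T002", 140.0), ("T003", 60.0)])
        vec = recipe_nutrients_per_100g(r, tiny_fct)
        for n in NUTRIENTS:
            comps = [
                getattr(tiny_fct.get(c).per100g, n) * tiny_fct.get(c).edible_fraction
                for c in ("T001", "T002", "T003")
            ]
            assert min(comps) - 1e-9 <= getattr(vec, n) <= max(comps) + 1e-9

    def test_invalid_recipes_rejected(self):
        with pytest.raises(FCTError):
            Recipe.build("R", "empty", [])
        with pytest.raises(FCTError):
            Recipe.build("R", "neg", [("A", -5.0)])
        with pytest.raises(FCTError):
            Recipe.build("R", "w", [("A", 5.0)], cooked_weight_g=0.0)


class TestRecipeRegistry:
    def test_register_and_duplicate(self):
        reg = RecipeRegistry()
        r = Recipe.build("R1", "d", [("A", 10.0)])
        register_recipe(r, reg)
        assert len(reg) == 1
        with pytest.raises(FCTError, match="already registered"):
            register_recipe(r, reg)

    def test_save_reload_round_trip(self, tmp_path):
        reg = RecipeRegistry(
            [
                Recipe.build(
                    "R1", "pilau", [("T001", 250.0), ("T002", 80.0)],
                    cooked_weight_g=300.0, method_notes="simmer 20 min",
                    source_doc="field notebook 3",
                ),
                Recipe.build("R2", "uji", [("T001", 50.0)]),
            ]
        )
        path = tmp_path / "recipes.yaml"
        reg.save(path)
        back = RecipeRegistry.load(path)
        assert {r.recipe_id: r for r in back} == {r.recipe_id: r for r in reg}


class TestFctContext:
    def test_context_resolution_reaches_supplemental_recipe_ingredients(
        self, tiny_fct, secondary_fct
    ):
        supplemental = FCTable("supplemental")
        supplemental.add(
            FoodItem(
                "U500", "octopus, raw", "meat_fish",
                NutrientVector(energy_kcal=82, protein_g=15, animal_protein_g=15),
                1.0,
            )
        )
        ctx = FctContext(
            primary=tiny_fct,
            secondary=secondary_fct,
            supplemental=supplemental,
            assignments={"octopus pilau": "R9"},
            recipes=RecipeRegistry(
                [Recipe.build("R9", "octopus pilau", [("U500", 100.0)])]
            ),
        )
        r = ctx.resolve(UNKNOWN_CODE, "octopus pilau")
        assert r.source == "recipe"
        assert math.isclose(r.item.per100g.energy_kcal, 82.0)
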