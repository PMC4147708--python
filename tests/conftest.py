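import pytest

from nutriswitch import (Category, FoodDatabase, FoodRecord, FvnlComposition,
                         GeneratorConfig, NutrientPanel, generate_database)


def make_panel(**kwargs) -> NutrientPanel:
    """Panel with every required nutrient defaulted to zero."""
    base = dict(energy_kj=0.0, protein_g=0.0, total_fat_g=0.0,
                saturated_fat_g=0.0, carbohydrate_g=0.0, sugars_g=0.0,
                sodium_mg=0.0)
    base.update(kwargs)
    return NutrientPanel(**base)


def make_record(upc="9300000000001", category_id="bread", is_beverage=False,
                name="item", **kwargs) -> FoodRecord:
    panel = kwargs.pop("panel", None) or make_panel(**kwargs.pop("nutrients", {}))
    return FoodRecord(upc=upc, name=name, brand="b", category_id=category_id,
                      is_beverage=is_beverage, panel=panel, **kwargs)


@pytest.fixture
def categories() -> dict[str, Category]:
    cats = [
        Category("bread", "Bread", is_beverage=False, fiber_possible=True),
        Category("cereal", "Breakfast cereal", is_beverage=False, fiber_possible=True,
                 fvnl_possible=True, default_fvnl_pct=5.0),
        Category("cheese", "Cheese", is_beverage=False, fiber_possible=False,
                 npsc_category3_member=True, is_cheese=True),
        Category("oil", "Edible oil", is_beverage=False, fiber_possible=False,
                 npsc_category3_member=True),
        Category("eggs", "Eggs", is_beverage=False, fiber_possible=False),
        Category("softdrink", "Sugar-sweetened soft drink", is_beverage=True,
                 fiber_possible=False, switch_excluded=True,
                 standard_message="Sugar-free drinks and water are healthier choices"),
        Category("juice", "Fruit juice", is_beverage=True, fiber_possible=False,
                 fvnl_possible=True, default_fvnl_pct=95.0),
    ]
    return {c.category_id: c for c in cats}


@pytest.fixture
def small_db(categories) -> FoodDatabase:
    """Hand-built database exercising every scoring category and the
    switch-excluded path; some optional fields deliberately absent."""
    records = [
        make_record(upc="9300000000017", category_id="bread", name="white loaf",
                    nutrients=dict(energy_kj=1000, protein_g=9, total_fat_g=2.5,
                                   saturated_fat_g=0.5, carbohydrate_g=48,
                                   sugars_g=4, sodium_mg=450, fiber_g=2.8)),
        make_record(upc="9300000000024", category_id="bread", name="rye loaf",
                    nutrients=dict(energy_kj=950, protein_g=8, total_fat_g=1.8,
                                   saturated_fat_g=0.3, carbohydrate_g=45,
                                   sugars_g=3, sodium_mg=380)),  # fiber absent
        make_record(upc="9300000000031", category_id="cereal", name="wheat flakes",
                    nutrients=dict(energy_kj=1500, protein_g=10, total_fat_g=2,
                                   saturated_fat_g=0.4, carbohydrate_g=70,
                                   sugars_g=22, sodium_mg=400, fiber_g=9),
                    serving_size_g=40.0),
        make_record(upc="9300000000048", category_id="cheese", name="cheddar",
                    nutrients=dict(energy_kj=1700, protein_g=25, total_fat_g=33,
                                   saturated_fat_g=21, carbohydrate_g=1,
                                   sugars_g=0.5, sodium_mg=700, calcium_mg=720)),
        make_record(upc="9300000000055", category_id="cheese", name="cream cheese",
                    nutrients=dict(energy_kj=1400, protein_g=6, total_fat_g=33,
                                   saturated_fat_g=22, carbohydrate_g=4,
                                   sugars_g=3.5, sodium_mg=350)),  # calcium absent
        make_record(upc="9300000000062", category_id="oil", name="olive oil",
                    nutrients=dict(energy_kj=3400, protein_g=0, total_fat_g=92,
                                   saturated_fat_g=14, carbohydrate_g=0,
                                   sugars_g=0, sodium_mg=0)),
        make_record(upc="9300000000079", category_id="eggs", name="dozen eggs",
                    nutrients=dict(energy_kj=600, protein_g=13, total_fat_g=10,
                                   saturated_fat_g=3.2, carbohydrate_g=1,
                                   sugars_g=0.5, sodium_mg=140)),
        make_record(upc="9300000000086", category_id="softdrink", is_beverage=True,
                    name="cola",
                    nutrients=dict(energy_kj=180, protein_g=0, total_fat_g=0,
                                   saturated_fat_g=0, carbohydrate_g=11,
                                   sugars_g=10.6, sodium_mg=10)),
        make_record(upc="9300000000093", category_id="juice", is_beverage=True,
                    name="orange juice",
                    nutrients=dict(energy_kj=160, protein_g=0.6, total_fat_g=0.1,
                                   saturated_fat_g=0, carbohydrate_g=9,
                                   sugars_g=8.5, sodium_mg=4)),
    ]
    db = FoodDatabase(records={r.upc: r for r in records}, categories=categories)
    db.validate()
    return db


@pytest.fixture(scope="session")
def synth_db() -> FoodDatabase:
    """Medium synthetic database shared across tests (seeded, deterministic)."""
    return generate_database(GeneratorConfig(seed=42, n_categories=12,
                                             products_per_category=(8, 20)))
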