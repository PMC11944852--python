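import pytest

from adgat import (
    ADGDatabase,
    ADGFoodRecord,
    FFQItemDef,
    FoodGroupVector,
    load_default_items,
    load_reference_table,
)


def make_record(
    food_id="F1",
    description="Food, plain",
    groups=(1.0, 0.0, 0.0, 0.0, 0.0),
    discretionary=False,
    energy=500.0,
):
    return ADGFoodRecord(
        food_id=food_id,
        description=description,
        groups=FoodGroupVector(*groups),
        discretionary_flag=discretionary,
        energy_kj_per_100g=energy,
    )


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def default_items():
    return load_default_items()


@pytest.fixture
def butter_family_db():
    """Six-record database: an NFD butter summary, flavoured variants, a
    raw decoy and an unrelated record."""
    return ADGDatabase(
        [
            make_record("B01", "Butter, plain, not further defined",
                        (0, 0, 0, 0, 0), True, 3000.0),
            make_record("B02", "Butter, garlic", (0, 0, 0, 0, 0), True, 2900.0),
            make_record("B03", "Butter, herb flavoured", (0, 0, 0, 0, 0), True, 2950.0),
            make_record("B04", "Dairy blend, butter and vegetable oil",
                        (0, 0, 0, 0.1, 0), True, 2800.0),
            make_record("B05", "Butter, separable fat", (0, 0, 0, 0, 0), False, 3100.0),
            make_record("B06", "Apple, raw", (0, 0, 0.7, 0, 0), False, 250.0),
        ]
    )


@pytest.fixture
def butter_item():
    return FFQItemDef("Butter", ("butter",), "processed", is_specific=False)
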