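import io

import pytest

from nutrilabel.basket import load_archetypes
from nutrilabel.model import FoodRecord, NutrientPanel
from nutrilabel.nova import load_vocabulary


@pytest.fixture(scope="session")
def vocab():
    return load_vocabulary()


@pytest.fixture(scope="session")
def library():
    return load_archetypes()


HEADER = ("food_id,name,group,state,energy_kcal,sugars_g,saturated_fat_g,"
          "total_fat_g,sodium_mg,fibre_g,protein_g,fvnl_pct,added_sugar,"
          "added_sat_fat,added_sodium,markers,special_category")


def make_csv(rows):
    """Build an in-memory food-table CSV from raw row strings."""
    return io.StringIO("\n".join([HEADER, *rows]) + "\n")


@pytest.fixture
def simple_rows():
    return [
        "f1,porridge oats,cereals,solid,375,1,1.2,7,5,10,13,0,0,0,0,,none",
        "f2,cola,sugars_others,liquid,42,10.6,0,0,10,0,0,0,1,0,0,colouring;flavouring,beverage",
        "f3,gouda,dairy,solid,356,2.2,17.9,27.4,819,0,25,0,0,0,1,fermented;added_salt,cheese",
    ]


def make_record(group="cereals", state="solid", markers=(), special="none",
                added_sugar=False, added_sat_fat=False, added_sodium=False,
                **panel_kwargs):
    defaults = dict(energy_kcal=100, sugars_g=1.0, saturated_fat_g=0.5,
                    total_fat_g=1.0, sodium_mg=50, fibre_g=1.0, protein_g=2.0,
                    fvnl_pct=0.0)
    defaults.update(panel_kwargs)
    return FoodRecord(
        food_id="t1", name="test food", group=group, state=state,
        panel=NutrientPanel(**defaults), markers=frozenset(markers),
        special_category=special, added_sugar=added_sugar,
        added_sat_fat=added_sat_fat, added_sodium=added_sodium)
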