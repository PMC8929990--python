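import datetime as dt
import textwrap

import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from dietrecall.fct import FCTable, FctContext, FoodItem, load_fct
from dietrecall.ingest import DemographicRecord, MealEntry, PersonDayRecall
from dietrecall.nutrivec import NutrientVector
from dietrecall.portions import PortionDatabase, PortionEntry

DATE = dt.date(2019, 3, 12)


@pytest.fixture
def tiny_fct_file(tmp_path):
    """Three-row FCT fixture with hand-checkable values."""
    text = textwrap.dedent(
        """\
        code,name,food_group,edible_fraction,energy_kcal,protein_g,animal_protein_g,fat_g,carb_g,fiber,calcium_mg,iron_mg,zinc_mg,vitA_ug_RE,folate_ug
        T001,maize ugali,cereals,1.0,112.0,3.1,0.0,0.5,23.0,1.2,8.0,0.9,0.6,0.0,18.0
        T002,fish relish with oil,meat_fish,0.8,190.0,18.5,17.0,12.0,1.5,0.0,120.0,1.4,1.1,20.0,8.0
        T003,mango ripe,fruits,0.69,60.0,0.8,0.0,0.4,15.0,1.6,11.0,0.2,0.1,54.0,43.0
        """
    )
    path = tmp_path / "fct.csv"
    path.write_text(text)
    return path


@pytest.fixture
def tiny_fct(tiny_fct_file):
    return load_fct(tiny_fct_file, "primary")


@pytest.fixture
def secondary_fct():
    t = FCTable(source_label="secondary")
    t.add(
        FoodItem(
            code="K100",
            name="octopus stew",
            food_group="meat_fish",
            per100g=NutrientVector(energy_kcal=82.0, protein_g=15.0, animal_protein_g=15.0),
            edible_fraction=1.0,
        )
    )
    return t


@pytest.fixture
def tiny_portion_db():
    db = PortionDatabase()
    db.add(PortionEntry("cereals", "plate", "medium", 400.0, "group default"))
    db.add(PortionEntry("cereals", "bowl", "medium", 350.0, "group default"))
    db.add(PortionEntry("meat_fish", "bowl", "medium", 300.0, "group default"))
    db.add(PortionEntry("fruits", "plate", "medium", 240.0, "group default"))
    # food-specific override that differs from its group default
    db.add(PortionEntry("T001", "plate", "medium", 420.0, "weighed estimate"))
    db.add(PortionEntry("T003", "plate", "medium", 180.0, "slice estimate"))
    return db


def make_demog(pid="P001", bf=0, cohort="adult", age=41.0, unit="years", sex="female"):
    return DemographicRecord(
        participant_id=pid,
        recall_date=DATE,
        cohort=cohort,
        age_value=age,
        age_unit=unit,
        sex=sex,
        day_character="typical",
        supplement_use=False,
        declared_bf_frequency=bf,
    )


def make_entry(
    pid="P001",
    index=1,
    time=540,
    code="T001",
    desc="maize ugali",
    utensil="plate",
    size="medium",
    portion=1.0,
    location="home",
    bf=False,
):
    return MealEntry(
        participant_id=pid,
        recall_date=DATE,
        entry_index=index,
        clock_time=time,
        location=location,
        food_code="" if bf else code,
        description="breast milk" if bf else desc,
        ingredients=None,
        utensil="" if bf else utensil,
        utensil_size="" if bf else size,
        portion_count=None if bf else portion,
        is_breastmilk=bf,
    )


@pytest.fixture
def simple_recall(tiny_fct):
    """Three food meals at 09:00 / 13:30 / 20:30 with known grams."""
    demog = make_demog()
    entries = [
        make_entry(index=1, time=540, code="T001", portion=1.0),  # 420 g override
        make_entry(index=2, time=810, code="T002", desc="fish relish",
                   utensil="bowl", portion=0.5),  # 150 g via group default
        make_entry(index=3, time=1230, code="T003", desc="mango", portion=2.0),  # 360 g
    ]
    return PersonDayRecall(demographics=demog, entries=entries)


@pytest.fixture
def fct_context(tiny_fct, secondary_fct):
    return FctContext(primary=tiny_fct, secondary=secondary_fct)
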