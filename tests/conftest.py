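import pandas as pd
import pytest

from reciprostat.config import PopulationConfig
from reciprostat.effects import add_nectar_calories
from reciprostat.synth import generate_dataset


@pytest.fixture(scope="session")
def default_config() -> PopulationConfig:
    return PopulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_table(default_config) -> pd.DataFrame:
    """One default synthetic dataset (with derived nectar calories)."""
    return add_nectar_calories(generate_dataset(default_config))


def tidy_table(values_by_cell, trait="t", cluster=None):
    """Build a tidy trait table from ``{(area, morph): values}``.

    ``cluster`` assigns units to that many individuals round-robin
    (None = every unit its own individual).
    """
    rows = []
    for (area, morph), vals in values_by_cell.items():
        for j, v in enumerate(vals):
            k = j % cluster if cluster else j
            rows.append({"area": area, "morph": morph,
                         "individual_id": f"{area}-{morph}-i{k}",
                         "unit_id": f"{area}-{morph}-u{j}",
                         "trait": trait, "value": float(v)})
    return pd.DataFrame(rows)


CELLS = [("no_fire", "L"), ("no_fire", "S"), ("fire", "L"), ("fire", "S")]
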