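import importlib.resources
from pathlib import Path

import pytest

from dietopt import GeneratorConfig, generate_food_database, load_food_database


@pytest.fixture(scope="session")
def default_db():
    """The full 76-food synthetic database, seed 0."""
    return generate_food_database(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def micro_db():
    """The packaged 10-food micro fixture (synthetic, CSV pair)."""
    data_dir = Path(str(importlib.resources.files("dietopt") / "data"))
    return load_food_database(data_dir, format="csv_pair")
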