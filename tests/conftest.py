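import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dgrhunt.rt_search import load_toy_rt_references
from dgrhunt.synthetic_data import GeneratorConfig, plant_dgr


@pytest.fixture(scope="session")
def toy_refs():
    return load_toy_rt_references()


@pytest.fixture(scope="session")
def planted():
    """One mid-sized contig with a planted DGR plus its truth record."""
    return plant_dgr(GeneratorConfig(contig_length=20_000, seed=11))
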