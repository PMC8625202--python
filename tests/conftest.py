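import numpy as np
import pytest

from shearfold import compile_model
from shearfold.synthetic import make_hairpin_pdb, make_toy_sheet


@pytest.fixture(scope="session")
def hairpin_pdb() -> str:
    return make_hairpin_pdb(10)


@pytest.fixture(scope="session")
def toy_sheet():
    return make_toy_sheet(seed=0)


@pytest.fixture(scope="session")
def toy_sheet_ff(toy_sheet):
    return compile_model(toy_sheet.model)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
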