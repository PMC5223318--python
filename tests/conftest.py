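import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gcomp import ObservedData, OutcomeModelSpec, toy_fixture

settings.register_profile("deterministic", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def toy() -> ObservedData:
    """14-row fixture: cell means 3/4, 1/2, 1/4, 1/4; treated fraction 6/14."""
    return toy_fixture()


@pytest.fixture
def toy_spec(toy) -> OutcomeModelSpec:
    """Saturated spec for the toy fixture (A + C + A:C)."""
    return OutcomeModelSpec.saturated(toy.covariate_names)


@pytest.fixture
def null8() -> ObservedData:
    """One copy of every (A, C, Y) combination: every cell mean is 1/2."""
    rows = [(a, c, y) for a in (0, 1) for c in (0, 1) for y in (0, 1)]
    arr = np.array(rows)
    return ObservedData(
        treatment=arr[:, 0],
        outcome=arr[:, 2],
        covariates=pd.DataFrame({"C": arr[:, 1]}),
        unit_id=np.arange(8),
    )


@pytest.fixture
def toy_csv(tmp_path, toy):
    path = tmp_path / "toy.csv"
    toy.to_frame(treatment="A", outcome="Y").to_csv(path, index=False)
    return path
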