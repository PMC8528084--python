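import numpy as np
import pandas as pd
import pytest

from toxpimap import (
    ComponentDefinition,
    DataMatrix,
    Direction,
    SimSpec,
    SliceDefinition,
    ToxPiModel,
    generate_lattice,
    pvi_like_model,
    score,
)


@pytest.fixture
def tiny_model() -> ToxPiModel:
    """Three slices in two domains, mixed directions and within-slice weights."""
    return ToxPiModel(
        name="tiny",
        slices=(
            SliceDefinition(
                name="exposure", domain="env", weight=2.0, color="#cc0000",
                components=(
                    ComponentDefinition("pm25"),
                    ComponentDefinition("ozone", weight=3.0),
                ),
            ),
            SliceDefinition(
                name="susceptibility", domain="pop", weight=1.0, color="#0000cc",
                components=(ComponentDefinition("age65"),),
            ),
            SliceDefinition(
                name="protection", domain="pop", weight=1.0, color="#00cc00",
                components=(
                    ComponentDefinition("vaccination", Direction.LOWER_IS_WORSE),
                ),
            ),
        ),
    )


@pytest.fixture
def tiny_matrix(tiny_model) -> DataMatrix:
    values = pd.DataFrame(
        {
            "pm25": [10.0, 20.0, 30.0],
            "ozone": [1.0, 2.0, 3.0],
            "age65": [0.1, 0.3, 0.2],
            "vaccination": [0.9, 0.5, 0.1],
        },
        index=pd.Index(["a", "b", "c"], name="id"),
    )
    return DataMatrix(
        values=values,
        lat=pd.Series([35.0, 35.5, 36.0], index=values.index),
        lon=pd.Series([-80.0, -80.5, -81.0], index=values.index),
    )


@pytest.fixture
def tiny_results(tiny_matrix, tiny_model):
    return score(tiny_matrix, tiny_model)


@pytest.fixture(scope="session")
def lattice_results():
    """A scored 8x8 lattice cohort with groups and boundaries (seed 11)."""
    spec = SimSpec(n_cols=8, n_rows=8, seed=11)
    model = pvi_like_model()
    matrix, boundaries, groups = generate_lattice(spec, model)
    return score(matrix, model), boundaries, groups, spec


def random_matrix(rng: np.random.Generator, model: ToxPiModel, n: int) -> DataMatrix:
    """Randomized component matrix over the model's components."""
    cols = model.component_names
    values = pd.DataFrame(
        rng.normal(size=(n, len(cols))) * rng.uniform(0.5, 50),
        index=pd.Index([f"r{i}" for i in range(n)], name="id"),
        columns=cols,
    )
    return DataMatrix(
        values=values,
        lat=pd.Series(rng.uniform(-60, 60, n), index=values.index),
        lon=pd.Series(rng.uniform(-179, 179, n), index=values.index),
    )
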