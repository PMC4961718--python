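import numpy as np
import pandas as pd
import pytest

from licur import GeneratorConfig, PanelSchema, RawPanel, VariableDecl, generate


@pytest.fixture
def toy_schema() -> PanelSchema:
    return PanelSchema(
        variables=(
            VariableDecl("sprint", "lower"),
            VariableDecl("jump", "higher", attempts=("jump_1", "jump_2")),
        ),
        has_outcome=False,
    )


@pytest.fixture
def toy_panel(toy_schema) -> RawPanel:
    data = pd.DataFrame(
        {
            "person_id": ["A", "B", "C", "A", "B", "C"],
            "timepoint": [1, 1, 1, 2, 2, 2],
            "sprint": [6.5, 6.8, np.nan, 6.4, 6.7, 6.6],
            "jump_1": [28.0, 30.0, 26.0, 29.0, 31.0, 27.0],
            "jump_2": [27.5, 30.5, 25.0, 29.5, 30.0, 27.5],
        }
    )
    return RawPanel(data=data, schema=toy_schema)


@pytest.fixture
def factor_panel_clean():
    """Complete factor-mode panel, no outliers/missingness, planted k=4."""
    cfg = GeneratorConfig(seed=7, raw_mode=False, missing_rate=0.0, n_outliers=0)
    panel, truth = generate(cfg)
    return panel, truth
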