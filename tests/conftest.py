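"""Shared fixtures: tiny handcrafted inputs and one default simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cernet.core_io import ExpressionBundle, SampleSheet
from cernet.simulate import SimulationConfig, simulate_expression, simulate_genesets, simulate_sequences


@pytest.fixture
def tiny_sheet() -> SampleSheet:
    return SampleSheet(("I1", "I2", "C1", "C2"), ("induced", "induced", "control", "control"))


@pytest.fixture
def tiny_bundle(tiny_sheet) -> ExpressionBundle:
    """3 features per class, 2+2 samples, values chosen by hand."""
    samples = list(tiny_sheet.sample_ids)

    def mat(rows: dict[str, list[float]]) -> pd.DataFrame:
        return pd.DataFrame(rows, index=samples).T

    return ExpressionBundle(
        lncrna=mat({"L1": [9.0, 9.2, 6.9, 7.1], "L2": [7.0, 7.1, 7.0, 6.9], "L3": [5.0, 5.2, 8.0, 8.2]}),
        mirna=mat({"M1": [5.0, 5.1, 8.0, 8.1], "M2": [6.0, 6.1, 6.0, 6.1], "M3": [9.0, 9.1, 6.0, 6.1]}),
        mrna=mat({"G1": [9.1, 9.0, 7.0, 7.0], "G2": [6.5, 6.4, 6.5, 6.6], "G3": [5.1, 5.0, 8.1, 8.0]}),
        sheet=tiny_sheet,
    )


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def sim(default_config):
    """One full default simulation (expression + sequences + gene sets), seed 1."""
    bundle, truth = simulate_expression(default_config)
    mirnas, targets, truth = simulate_sequences(default_config, truth)
    collection = simulate_genesets(default_config, truth)
    return dict(config=default_config, bundle=bundle, truth=truth,
                mirnas=mirnas, targets=targets, collection=collection)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
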