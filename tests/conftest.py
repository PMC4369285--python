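import pandas as pd
import pytest

import solvcoef as sc


@pytest.fixture(scope="session")
def benzoic_acid() -> sc.SoluteDescriptors:
    return sc.SoluteDescriptors(0.730, 0.90, 0.59, 0.40, 0.9317, name="benzoic acid")


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return sc.load_table1()


@pytest.fixture(scope="session")
def table1_consistent(table1) -> pd.DataFrame:
    """Paired rows that obey the shared Delta = c*beta recalibration law."""
    return table1.loc[~sc.flag_inconsistent_pairs(table1)]


@pytest.fixture(scope="session")
def zero_rows() -> list[sc.SolventCoefficients]:
    return sc.table1_zero_intercept()


@pytest.fixture(scope="session")
def original_rows() -> list[sc.SolventCoefficients]:
    return sc.table1_original()


@pytest.fixture(scope="session")
def predicted_rows() -> list[sc.SolventCoefficients]:
    return sc.load_table3()


@pytest.fixture(scope="session")
def population() -> sc.SolutePopulation:
    """A mid-sized synthetic solute population shared across tests."""
    return sc.make_solute_population(sc.SynthesisConfig(n=300, seed=7))
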