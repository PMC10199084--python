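import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hittriage as ht
from hittriage import druglikeness, ligand_efficiency, tables_io

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return tables_io.load_fixture("table1")


@pytest.fixture(scope="session")
def table3():
    return tables_io.load_fixture("table3")


@pytest.fixture(scope="session")
def table4():
    return tables_io.load_fixture("table4")


@pytest.fixture(scope="session")
def table5():
    return tables_io.load_fixture("table5")


@pytest.fixture(scope="session")
def profiles(table3):
    """PhyschemProfile per compound label from the descriptor table."""
    return druglikeness.profiles_from_table(table3)


@pytest.fixture(scope="session")
def reference_reports(table1, table3, table4):
    """Efficiency reports per label, Ki taken from the published column."""
    reports = {}
    for label in table1.index:
        reports[label] = ligand_efficiency.evaluate_metrics(
            ligand_efficiency.EfficiencyInputs(
                binding_energy=float(table1.loc[label, "binding_energy_kcal_mol"]),
                heavy_atoms=int(table3.loc[label, "ha"]),
                logp=float(table3.loc[label, "logp"]),
                ki_override=float(table4.loc[label, "ki_uM"]) * 1e-6,
            )
        )
    return reports


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
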