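import pytest

from prandikit import (
    CohortTable,
    ControlReading,
    Diet,
    FeedingRecord,
    Sex,
    SimulationConfig,
    noiseless_config,
    simulate_study,
)


@pytest.fixture
def tiny_cohort() -> CohortTable:
    """Two females, three days each, one chamber, hand-checkable numbers."""
    records = []
    for fid, descents, eggs in [("f1", (3.0, 4.0, 2.0), (10, 12, 8)), ("f2", (5.0, 2.0, 1.0), (20, 4, 2))]:
        for day, (d, e) in enumerate(zip(descents, eggs), start=1):
            records.append(
                FeedingRecord(
                    fly_id=fid, sex=Sex.F, diet=Diet.SUGAR_LIQUID, hpc_id="H1",
                    age_day=day, raw_descent=d, eggs=e, alive=True,
                )
            )
    controls = [ControlReading(hpc_id="H1", age_day=d, evaporation=1.0) for d in (1, 2, 3)]
    return CohortTable(records=records, controls=controls)


@pytest.fixture(scope="session")
def default_study():
    """One seeded run of the full four-cohort study at default conditions."""
    return simulate_study(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free study: deterministic intake and exact surface-mean eggs."""
    return simulate_study(noiseless_config(seed=7))
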