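import pytest

from lungclaims.codes import load_default_table
from lungclaims.synth import ScenarioConfig, edge_case_panel, generate_population


@pytest.fixture(scope="session")
def table():
    return load_default_table()


@pytest.fixture(scope="session")
def default_population():
    """A mid-size default-scenario population with ground truth."""
    cfg = ScenarioConfig(n_patients=400, seed=11)
    return generate_population(cfg)


@pytest.fixture(scope="session")
def panel():
    return edge_case_panel()


@pytest.fixture(scope="session")
def panel_by_id(panel):
    records, truths = panel
    return {p.patient_id: p for p in records}, {t.patient_id: t for t in truths}


def clean_scenario(**overrides) -> ScenarioConfig:
    """Scenario without exclusion contamination: every incident patient
    is included, treated, and classifiable by construction."""
    base = dict(
        n_patients=300,
        seed=1,
        lc_fraction=1.0,
        treated_fraction=1.0,
        second_line_fraction=0.0,
        off_label_rate=0.0,
        type_specific_only=True,
        group_mixture={
            "Immunotherapy": 0.0,
            "Inhibitors": 0.0,
            "Chemotherapy": 1.0,
            "Radiotherapy": 0.0,
            "Study": 0.0,
        },
        exclusion_rates={
            "other_primary": 0.0,
            "short_pre_observation": 0.0,
            "short_post_observation": 0.0,
        },
    )
    base.update(overrides)
    return ScenarioConfig(**base)
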