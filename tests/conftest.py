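import pytest

from adrec import knowledgebase as kbmod
from adrec import synthetic_cohort as sc


@pytest.fixture(scope="session")
def small_cohort():
    """2000-patient single-drug cohort with three planted coefficients."""
    ids = sc.event_ids(50)
    beta = {ids[0]: 1.0, ids[1]: -1.0, ids[2]: 0.9}
    config = sc.CohortConfig(
        n_patients=2000,
        drugs=["sertraline"],
        n_events=50,
        true_models={"sertraline": sc.TrueModel(-0.3, beta)},
        seed=42,
    )
    events, dispensings, truth = sc.generate_cohort(config)
    return config, events, dispensings, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    config, events, _, truth = small_cohort
    X = sc.feature_table(events, truth["patient_id"].tolist(), config.event_ids)
    return kbmod.FeatureMatrix(X, truth["response"].to_numpy())


def make_toy_kb(*, zero_coefficients=False):
    """Three-drug toy knowledgebase over a five-event schema.

    Event e4 carries weight +2 for drug B only, so flipping it can overturn
    an A-first recommendation; e2 feeds the single imputation model for e3.
    """
    schema = kbmod.EventSchema(
        {"DX_e0": "DX", "RX_e1": "RX", "PX_e2": "PX", "ADR_e3": "ADR", "DX_e4": "DX"}
    )
    scale = 0.0 if zero_coefficients else 1.0
    models = {
        "amitriptyline": kbmod.DrugModel(
            "amitriptyline", -0.4,
            {"DX_e0": 1.0 * scale, "RX_e1": -0.5 * scale},
        ),
        "bupropion": kbmod.DrugModel(
            "bupropion", -0.9,
            {"DX_e0": 0.5 * scale, "DX_e4": 2.0 * scale},
        ),
        "citalopram": kbmod.DrugModel(
            "citalopram", -2.5, {"ADR_e3": 0.8 * scale},
        ),
    }
    imputation = [
        kbmod.ImputationModel("ADR_e3", -1.0, {"PX_e2": 0.5 * scale}),
    ]
    return kbmod.Knowledgebase(
        schema=schema, models=models, imputation_models=imputation
    )


@pytest.fixture
def toy_kb():
    return make_toy_kb()
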