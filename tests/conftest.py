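import pandas as pd
import pytest

from cytoprofile import (
    EffectModel,
    ExperimentDesign,
    NoiseModel,
    ScreenModel,
    WellProfiles,
    aggregate_compounds,
    aggregate_wells,
)
from cytoprofile.synthetic import DEFAULT_NOISE


@pytest.fixture(scope="session")
def tiny_design():
    """4 plates x 24 wells: 40 compounds in duplicate + 4 mock wells/plate."""
    return ExperimentDesign(
        n_plates=4,
        wells_per_plate=24,
        n_compounds=40,
        n_replicates=2,
        mock_wells_per_plate=4,
        n_features=15,
        cells_per_well_range=(10, 20),
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_design):
    """Tiny screen with two planted mechanism groups of three compounds."""
    return ScreenModel(
        tiny_design,
        EffectModel(
            n_mechanism_groups=2,
            compounds_per_group=3,
            affected_feature_fraction=0.3,
            effect_magnitude=2.0,
        ),
        DEFAULT_NOISE,
    )


def profile_screen(model):
    """Generate + aggregate one synthetic screen into well/compound profiles."""
    frames = []
    platemaps = model.platemaps()
    for pm in platemaps:
        frames.append(aggregate_wells(model.cell_table(pm), pm, model.mock_label).data)
    wells = WellProfiles(pd.concat(frames, ignore_index=True), mock_label=model.mock_label)
    return platemaps, wells, aggregate_compounds(wells)


@pytest.fixture(scope="session")
def tiny_screen(tiny_model):
    platemaps, wells, compounds = profile_screen(tiny_model)
    return {
        "model": tiny_model,
        "platemaps": platemaps,
        "wells": wells,
        "compounds": compounds,
    }


@pytest.fixture(scope="session")
def noiseless_model():
    """Deterministic limit: every noise scale zero, no planted effects."""
    design = ExperimentDesign(
        n_plates=2,
        wells_per_plate=12,
        n_compounds=8,
        n_replicates=2,
        mock_wells_per_plate=4,
        n_features=6,
        cells_per_well_range=(5, 5),
        seed=5,
    )
    return ScreenModel(
        design, EffectModel(), NoiseModel(plate_shift_sd=0, well_position_sd=0, cell_noise_sd=0)
    )
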