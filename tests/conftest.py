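import numpy as np
import pytest

from tastechip.recording import (
    Recording,
    StimulusLabel,
    TASTANT_UNITS,
    Tastant,
)
from tastechip.simulate import CellType, build_default_model


def acetic_label(conc: float) -> StimulusLabel:
    return StimulusLabel(
        Tastant.SOUR_ACETIC, conc, TASTANT_UNITS[Tastant.SOUR_ACETIC]
    )


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


@pytest.fixture(scope="session")
def sour_top_profile(default_model):
    """typeIII profile for the strongest acetic-acid condition."""
    return default_model.resolve(CellType.TYPE_III_SOUR, acetic_label(25.0))


@pytest.fixture()
def small_recording():
    rng = np.random.default_rng(7)
    return Recording(
        samples=rng.normal(0, 5, size=(3, 400)),
        fs=1000.0,
        channel_ids=("E1", "E2", "E3"),
        stimulus=acetic_label(6.25),
        chip_id="chipA",
    )
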