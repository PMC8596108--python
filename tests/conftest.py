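import numpy as np
import pytest

from pdopharm import (
    DoseResponseCurve,
    DrugPanelEntry,
    default_panel,
    dilution_series,
    simulate_screen,
)
from pdopharm.dose_response import four_pl


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_panel():
    return [
        DrugPanelEntry("drugA", "microtubule", approved_for_breast=True),
        DrugPanelEntry("drugB", "platinum"),
        DrugPanelEntry("drugC", "proteasome"),
    ]


@pytest.fixture(scope="session")
def small_screen(small_panel):
    """A 6-line screen on three drugs, 10% CV, with its truth."""
    return simulate_screen(small_panel, n_pdos=6, noise_cv=0.10, seed=11)


def make_curve(top=100.0, bottom=0.0, hill=1.0, ec50=0.5e-6,
               concs=None, n_rep=3, pdo="PDO001", drug="drugA"):
    """Noiseless 4PL viability curve on the default dose grid."""
    if concs is None:
        concs = dilution_series(20e-6, 3.0, 7)
    viab = four_pl(concs, top, bottom, hill, ec50)
    return DoseResponseCurve(pdo, drug, concs,
                             np.tile(viab[:, None], (1, n_rep)))
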