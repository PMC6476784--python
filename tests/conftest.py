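import math

import numpy as np
import pytest

from coelomic import SimConfig, generate_study
from coelomic.chemistry import MMHG_PER_KPA, GasTension
from coelomic.io import records_to_frame, tonometry_to_frame
from coelomic.tonometry import TonometrySeries, TonometryStep


@pytest.fixture(scope="session")
def default_study():
    """One full default-size synthetic study (frames), fixed seed."""
    records, series = generate_study(SimConfig(), seed=7)
    return records_to_frame(records), tonometry_to_frame(series)


@pytest.fixture(scope="session")
def small_quiet_config():
    """A small, deathless configuration used by pipeline/CLI tests."""
    return SimConfig(n_per_cell=5, mortality_p=0.0)


def make_consistent_series(
    individual_id="u1",
    temperature=15.0,
    pk=6.3,
    alpha=0.050,
    tensions_kpa=(0.1, 0.3, 0.5, 0.8),
    hco3=None,
):
    """Build a noise-free tonometry series exactly consistent with one pK'.

    For each tension, pick a bicarbonate value, then set
    pH = pK' + log10(hco3 / (alpha*p)) and TCO2 = hco3 + alpha*p, so every
    step satisfies the Henderson-Hasselbalch equilibrium at the given pK'.
    """
    if hco3 is None:
        hco3 = np.linspace(2.0, 5.0, len(tensions_kpa))
    steps = []
    for t_kpa, h in zip(tensions_kpa, hco3):
        aco2 = alpha * t_kpa * MMHG_PER_KPA
        steps.append(
            TonometryStep(
                set_tension=GasTension(t_kpa, "kPa"),
                measured_ph=pk + math.log10(h / aco2),
                measured_tco2=h + aco2,
            )
        )
    return TonometrySeries(individual_id, temperature, steps)
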