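import numpy as np
import pytest

from methylrap.crystallites import make_crystallites
from methylrap.redor import (
    RedorGrid,
    SequenceParams,
    _delta_phase_factors,
)
from methylrap.synthetic import SyntheticStructureSpec, make_structure


@pytest.fixture(scope="session")
def fit_schedule():
    """Dephasing times 2 tau_r (n+1), n = 0,4,...,44 at 50 kHz MAS."""
    tau_r = 1.0 / 50e3
    n = np.arange(0, 48, 4)
    return 2.0 * tau_r * (n + 1)


@pytest.fixture(scope="session")
def fit_grid(fit_schedule):
    """Coarse delta-pulse simulation grid (|delta| 0..16 kHz step 100, eta step 0.1)."""
    params = SequenceParams(mas_rate=50e3, zeta=4e-6, n_max=0, delta_pulse=True)
    # 987 x 16 gamma angles: powder-converged (few 1e-3) out to the longest
    # dephasing time of the schedule even at |delta| = 16 kHz
    cryst = make_crystallites("zcw", 987, 16)
    PhiA, PhiB = _delta_phase_factors(params, cryst, fit_schedule)
    aniso = np.arange(0.0, 16000.0 + 50.0, 100.0)
    eta = np.arange(0.0, 1.05, 0.1)
    curves = np.empty((aniso.size, eta.size, fit_schedule.size))
    w = cryst.weights
    for j, e in enumerate(eta):
        Phi = PhiA + e * PhiB
        for t in range(fit_schedule.size):
            curves[:, j, t] = 1.0 - np.cos(
                2.0 * np.pi * aniso[:, None] * Phi[t][None, :]
            ) @ w
    return RedorGrid(aniso, eta, fit_schedule, curves, params,
                     {"crystallites": "zcw 987x16"})


@pytest.fixture(scope="session")
def core_structure():
    """Clustered-core globule with a bundled Leu/Val core."""
    return make_structure(
        SyntheticStructureSpec(12, "VLAVLTAVLGIM", "clustered_core", seed=3)
    )
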