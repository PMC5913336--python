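import numpy as np
import pytest

from hipfa import NbCalibration
from hipfa.simulate import PlateSpec, WellSpec, simulate_nb_series, simulate_plate


NB_TRUE = NbCalibration(baseline_fa=0.18, amplitude=0.12, kd_nb=1700.0, nb_total=5.0)


@pytest.fixture(scope="session")
def nb_true() -> NbCalibration:
    return NB_TRUE


@pytest.fixture(scope="session")
def nb_series_noiseless():
    return simulate_nb_series(NB_TRUE, noise_fa_sd=0.0)


def make_plate(kd2_values, seed=0, noise=0.0, n_calibration=3, **overrides):
    wells = [
        WellSpec(well=f"T{i + 1:02d}", true_kd2_nM=float(k))
        for i, k in enumerate(kd2_values)
    ]
    wells += [WellSpec(well=f"C{i + 1:02d}", role="calibration") for i in range(n_calibration)]
    return PlateSpec(wells=tuple(wells), seed=seed, noise_rel_sd=noise, **overrides)


@pytest.fixture(scope="session")
def noiseless_plate():
    """Single noiseless titration well (K_D2 = 10 nM) with calibration wells."""
    return simulate_plate(make_plate([10.0], seed=42))
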