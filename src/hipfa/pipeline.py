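"""End-to-end plate analysis: intensities -> calibrated K_D fits per well."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .binding import FitOptions, FitResult, analyze_well
from .fa_core import InstrumentConfig, anisotropy_table, trajectories_from_table
from .gradient import (
    ConsensusField,
    NbCalibration,
    calibrate_wells,
    fit_nb_calibration,
)

__all__ = ["PlateAnalysis", "analyze_plate"]


@dataclass(frozen=True)
class PlateAnalysis:
    """Everything the plate-level analysis produced."""

    nb_calibration: NbCalibration
    field: ConsensusField
    results: dict[str, FitResult]


def analyze_plate(
    intensities: pd.DataFrame,
    roles: Mapping[str, str],
    nb_series: Sequence[tuple[float, float]],
    kd1_nM: float,
    t0_s: float,
    instrument: InstrumentConfig = InstrumentConfig(),
    fit_options: FitOptions = FitOptions(),
    nb_total_nM: float = 5.0,
    floor_nM: float = 100.0,
) -> PlateAnalysis:
    """Run the full chain on a mean-intensity table.

    ``roles`` maps well id -> 'titration' | 'calibration'; ``nb_series`` is
    the conventional NB titration used to fit the concentration sensor;
    ``kd1_nM`` the separately determined reference affinity; ``t0_s`` the
    fixed gradient time offset.  Returns per-titration-well fit results
    along with the calibration objects.
    """
    fa = anisotropy_table(intensities, instrument)
    cal_wells = [w for w, r in roles.items() if r == "calibration"]
    tit_wells = [w for w, r in roles.items() if r == "titration"]
    if not cal_wells:
        raise ValueError("missing calibration: no calibration wells on the plate")

    nb_cal = fit_nb_calibration(nb_series, nb_total=nb_total_nM)
    field = calibrate_wells(
        fa[fa["well"].isin(cal_wells)], nb_cal, t0=t0_s, floor_nM=floor_nM
    )
    trajectories = trajectories_from_table(fa[fa["well"].isin(tit_wells)])
    results = {
        well: analyze_well(points, field, kd1_nM, fit_options)
        for well, points in trajectories.items()
    }
    return PlateAnalysis(nb_calibration=nb_cal, field=field, results=results)
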