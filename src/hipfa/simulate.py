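"""Forward model of the controlled-delivery anisotropy experiment.

Generates synthetic plates that exercise the full analysis chain: the
competitor gradient follows the one-dimensional erf diffusion profile, the
bound labeled fraction comes from the numerically exact two-ligand
mass-action equilibrium (independent of the closed form used for fitting),
anisotropy mixes linearly between free and bound, and polarized intensities
are synthesized with multiplicative Gaussian camera noise.  Calibration
wells emit the Nile-Blue sensor readout instead of the competition signal.

Defaults reproduce the reference experiment: 25 cycles at 7.5 min
intervals, 12 planes at 145 µm steps with the lowest plane 1400 µm above
the coverslip, z-stacks acquired bottom to top, wells staggered uniformly
across the cycle interval, G-factor 1.15, labeled DNA 1 nM, NB sensor with
K_D 1.7 µM at 5 nM.  Every dataset is bit-reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .binding import DILUTION_SERIES_NM, TitrationCurve, equilibrium_oracle
from .fa_core import INTENSITY_COLUMNS, InstrumentConfig, anisotropy_table
from .gradient import NbCalibration, nb_forward_fa
from .kinetics import DissociationTrace, exponential_decay

__all__ = [
    "WellSpec",
    "PlateSpec",
    "SyntheticDataset",
    "simulate_plate",
    "simulate_nb_series",
    "simulate_dilution_series",
    "simulate_dissociation_trace",
    "default_plate",
    "draq5_sensor",
    "plate_spec_from_dict",
]


@dataclass(frozen=True)
class WellSpec:
    """One well: a titration well with a true competitor K_D, or a calibration well.

    For calibration wells the sensor response is baseline + amplitude *
    (fraction of dye bound); ``brightness`` scales the synthesized intensity
    and ``noise_scale`` the relative intensity noise (a dimmer dye is
    noisier, e.g. DRAQ5 at ~10x dimmer).
    """

    well: str
    role: str = "titration"  # titration | calibration
    sequence: str = ""
    true_kd2_nM: Optional[float] = None
    c0_nM: float = 4000.0
    sensor_kd_nM: float = 1700.0
    sensor_baseline_fa: float = 0.18
    sensor_amplitude_fa: float = 0.12
    sensor_total_nM: float = 5.0
    brightness: float = 1.0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("titration", "calibration"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "titration" and not (self.true_kd2_nM and self.true_kd2_nM > 0):
            raise ValueError(f"titration well {self.well} needs true_kd2_nM > 0")
        if self.c0_nM <= 0:
            raise ValueError("c0 must be > 0")


@dataclass(frozen=True)
class PlateSpec:
    """Plate layout plus the shared physics, optics and timing parameters."""

    wells: tuple[WellSpec, ...]
    kd1_nM: float = 2.0
    rt_nominal_nM: float = 40.0
    active_fraction: float = 1.0
    lst_nM: float = 1.0
    diffusion_um2_s: float = 100.0
    t0_s: float = 300.0
    cycles: int = 25
    cycle_interval_s: float = 450.0
    planes: int = 12
    z_step_um: float = 145.0
    lowest_plane_um: float = 1400.0
    gel_height_um: float = 3000.0
    fa_bound: float = 0.25
    fa_free: float = 0.05
    noise_rel_sd: float = 0.001
    g_factor: float = 1.15
    frame_time_s: float = 0.3
    intensity_counts: float = 10000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.wells:
            raise ValueError("plate needs at least one well")
        if not (0 < self.active_fraction <= 1):
            raise ValueError("active_fraction must be in (0, 1]")
        if self.rt_nominal_nM < self.lst_nM:
            raise ValueError("TF must be in molar excess over labeled reference DNA")
        for v in (self.kd1_nM, self.diffusion_um2_s, self.lst_nM):
            if v <= 0:
                raise ValueError("rates and concentrations must be > 0")
        top = self.lowest_plane_um + (self.planes - 1) * self.z_step_um
        if top >= self.gel_height_um:
            raise ValueError("focal stack extends above the gel surface")
        if self.t0_s <= 0:
            raise ValueError("acquisition schedule requires t0 > 0")

    @property
    def rt_active_nM(self) -> float:
        return self.rt_nominal_nM * self.active_fraction

    def plane_depth_um(self, z_index: int) -> float:
        """Depth of focal plane ``z_index`` below the gel top (µm); plane 0 is lowest."""
        return self.gel_height_um - (self.lowest_plane_um + z_index * self.z_step_um)

    def plane_width(self, z_index: int) -> float:
        """Composite erf width z / sqrt(4 D) for the plane, sqrt-seconds."""
        return self.plane_depth_um(z_index) / math.sqrt(4.0 * self.diffusion_um2_s)

    def instrument_config(self) -> InstrumentConfig:
        return InstrumentConfig(
            g_factor=self.g_factor,
            z_step_um=self.z_step_um,
            lowest_plane_um=self.lowest_plane_um,
            planes_per_stack=self.planes,
            cycle_interval_s=self.cycle_interval_s,
        )

    def nb_calibration(self, well: WellSpec) -> NbCalibration:
        return NbCalibration(
            baseline_fa=well.sensor_baseline_fa,
            amplitude=well.sensor_amplitude_fa,
            kd_nb=well.sensor_kd_nM,
            nb_total=well.sensor_total_nM,
        )


@dataclass(frozen=True)
class SyntheticDataset:
    """Simulated intensity table plus the complete generating truth."""

    intensities: pd.DataFrame
    truth: dict
    spec: PlateSpec

    def anisotropy(self) -> pd.DataFrame:
        """Push the synthetic intensities through the standard FA computation."""
        return anisotropy_table(self.intensities, self.spec.instrument_config())

    def roles(self) -> dict[str, str]:
        return {w.well: w.role for w in self.spec.wells}


def _intensities_from_fa(
    fa: float, total: float, g: float, rel_sd: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Split a target FA into a polarized intensity pair, then add camera noise."""
    i_perp = total * (1.0 - fa) / (2.0 + g)
    i_par = total - 2.0 * i_perp
    if rel_sd > 0:
        i_par *= 1.0 + rel_sd * rng.standard_normal()
        i_perp *= 1.0 + rel_sd * rng.standard_normal()
    return max(i_par, 0.0), max(i_perp, 0.0)


def gradient_concentration(spec: PlateSpec, z_index: int, t: float, c0: float) -> float:
    """True competitor concentration at (plane, time) for top concentration c0."""
    from scipy.special import erfc

    if t + spec.t0_s <= 0:
        raise ValueError("t + t0 must be > 0")
    return c0 * float(erfc(spec.plane_width(z_index) / math.sqrt(t + spec.t0_s)))


def _well_fa(spec: PlateSpec, well: WellSpec, c: float) -> float:
    if well.role == "calibration":
        return float(
            nb_forward_fa(
                c,
                well.sensor_baseline_fa,
                well.sensor_amplitude_fa,
                well.sensor_kd_nM,
                well.sensor_total_nM,
            )
        )
    eq = equilibrium_oracle(
        kd1=spec.kd1_nM,
        kd2=float(well.true_kd2_nM),
        rt=spec.rt_active_nM,
        lst=spec.lst_nM,
        lt=c,
    )
    fsb = eq["bound_labeled"] / spec.lst_nM
    amplitude = spec.fa_bound - spec.fa_free
    return spec.fa_free + amplitude * fsb


def simulate_plate(spec: PlateSpec) -> SyntheticDataset:
    """Generate the full plate: one intensity row per (well, cycle, plane).

    Within a cycle the wells are visited in listed order, staggered uniformly
    across the cycle interval; each z-stack is acquired bottom to top at the
    frame time.  Identical spec (including seed) regenerates the dataset
    bit-exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n_wells = len(spec.wells)
    rows = []
    for cycle in range(spec.cycles):
        for w_idx, well in enumerate(spec.wells):
            t_well = cycle * spec.cycle_interval_s + (
                w_idx / n_wells
            ) * spec.cycle_interval_s
            for z in range(spec.planes):
                t = t_well + z * spec.frame_time_s
                c = gradient_concentration(spec, z, t, well.c0_nM)
                fa = _well_fa(spec, well, c)
                total = spec.intensity_counts * well.brightness
                i_par, i_perp = _intensities_from_fa(
                    fa,
                    total,
                    spec.g_factor,
                    spec.noise_rel_sd * well.noise_scale,
                    rng,
                )
                rows.append((well.well, cycle, z, t, i_par, i_perp))
    intensities = pd.DataFrame(rows, columns=INTENSITY_COLUMNS)
    truth = {
        "kd1_nM": spec.kd1_nM,
        "rt_active_nM": spec.rt_active_nM,
        "rt_nominal_nM": spec.rt_nominal_nM,
        "active_fraction": spec.active_fraction,
        "lst_nM": spec.lst_nM,
        "amplitude": spec.fa_bound - spec.fa_free,
        "offset": spec.fa_free,
        "t0_s": spec.t0_s,
        "seed": spec.seed,
        "wells": {
            w.well: {
                "role": w.role,
                "sequence": w.sequence,
                "true_kd2_nM": w.true_kd2_nM,
                "c0_nM": w.c0_nM,
                "plane_widths": [spec.plane_width(z) for z in range(spec.planes)],
            }
            for w in spec.wells
        },
    }
    return SyntheticDataset(intensities=intensities, truth=truth, spec=spec)


def simulate_nb_series(
    calib: NbCalibration,
    concentrations_nM: Sequence[float] = (
        0, 25, 50, 100, 250, 500, 1000, 1700, 3000, 6000, 10000, 16000,
    ),
    n_replicates: int = 3,
    noise_fa_sd: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Conventional NB titration standard curve (c, FA_NB) used to fit the sensor.

    The default design is a 12-point ladder bracketing the NB K_D, measured in
    triplicate: the sensor calibration is done once per dye/oligomer batch and
    its error propagates into every concentration on the plate, so it is worth
    a dense design.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        for c in concentrations_nM:
            fa = float(
                nb_forward_fa(
                    c, calib.baseline_fa, calib.amplitude, calib.kd_nb, calib.nb_total
                )
            )
            if noise_fa_sd > 0:
                fa += noise_fa_sd * rng.standard_normal()
            out.append((float(c), fa))
    return out


def simulate_dilution_series(
    kd2_true_nM: float,
    series_nM: Sequence[float] = DILUTION_SERIES_NM,
    kd1_nM: float = 1.0,
    rt_nM: float = 20.0,
    lst_nM: float = 1.0,
    fa_bound: float = 0.25,
    fa_free: float = 0.05,
    noise_rel_sd: float = 0.0,
    g_factor: float = 1.15,
    intensity_counts: float = 10000.0,
    seed: int = 0,
) -> tuple[TitrationCurve, dict]:
    """Conventional competitive titration at the printed 12-point design.

    Each concentration gives one equilibrium FA from the mass-action oracle;
    intensities are synthesized and perturbed exactly as in the plate
    simulator, then converted back to FA.
    """
    from .fa_core import compute_fa

    rng = np.random.default_rng(seed)
    amplitude = fa_bound - fa_free
    points = []
    for lt in series_nM:
        eq = equilibrium_oracle(kd1=kd1_nM, kd2=kd2_true_nM, rt=rt_nM, lst=lst_nM, lt=float(lt))
        fa = fa_free + amplitude * eq["bound_labeled"] / lst_nM
        i_par, i_perp = _intensities_from_fa(
            fa, intensity_counts, g_factor, noise_rel_sd, rng
        )
        points.append((float(lt), compute_fa(i_par, i_perp, g_factor)))
    curve = TitrationCurve(points=tuple(points), well="dilution", mode="dilution-series")
    truth = {
        "kd2_nM": kd2_true_nM,
        "kd1_nM": kd1_nM,
        "rt_nM": rt_nM,
        "lst_nM": lst_nM,
        "amplitude": amplitude,
        "offset": fa_free,
        "seed": seed,
    }
    return curve, truth


def simulate_dissociation_trace(
    a: float,
    b: float,
    tau_off_s: float,
    t_add_s: float = 10.0,
    dt_s: float = 0.3,
    duration_s: float = 40.0,
    noise_fa_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DissociationTrace, dict]:
    """FA time trace: plateau a+b before t_add, first-order decay to a after."""
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_s, dt_s)
    fa = np.where(
        times < t_add_s,
        a + b,
        exponential_decay(times, a, b, tau_off_s, t_add_s),
    )
    if noise_fa_sd > 0:
        fa = fa + noise_fa_sd * rng.standard_normal(times.size)
    trace = DissociationTrace(times=times, fa=fa, t_add=t_add_s)
    truth = {"a": a, "b": b, "tau_off_s": tau_off_s, "t_add_s": t_add_s, "seed": seed}
    return trace, truth


def draq5_sensor(well: str = "cal_draq5", c0_nM: float = 4000.0) -> WellSpec:
    """Calibration well using the high-affinity DRAQ5 dye: K_D ~10 nM, 10x dimmer.

    Serves as the cross-check scenario for the low-concentration
    extrapolation of the NB gradient fits.
    """
    return WellSpec(
        well=well,
        role="calibration",
        c0_nM=c0_nM,
        sensor_kd_nM=10.0,
        brightness=0.1,
        noise_scale=10.0,
    )


def default_plate(
    kd2_values_nM: Sequence[float],
    n_calibration: int = 5,
    seed: int = 0,
    noise_rel_sd: float = 0.001,
    **overrides,
) -> PlateSpec:
    """Standard plate: one titration well per K_D plus NB calibration wells."""
    wells = [
        WellSpec(well=f"T{i + 1:02d}", role="titration", true_kd2_nM=float(kd2))
        for i, kd2 in enumerate(kd2_values_nM)
    ]
    wells += [
        WellSpec(well=f"C{i + 1:02d}", role="calibration")
        for i in range(n_calibration)
    ]
    return PlateSpec(wells=tuple(wells), seed=seed, noise_rel_sd=noise_rel_sd, **overrides)


def plate_spec_from_dict(cfg: dict) -> PlateSpec:
    """Build a PlateSpec from a parsed structured config (e.g. YAML)."""
    wells = tuple(WellSpec(**w) for w in cfg.pop("wells"))
    return PlateSpec(wells=wells, **cfg)
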