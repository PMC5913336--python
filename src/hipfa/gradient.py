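"""Competitor-concentration field c(z, t) from Nile-Blue calibration wells.

Calibration wells contain the weakly DNA-intercalating dye Nile Blue (NB),
whose anisotropy rises as competitor DNA diffuses in: NB acts as an in-gel
concentration sensor.  The analysis has two layers:

1. an NB binding isotherm (single site, with depletion of the 5 nM dye)
   mapping DNA concentration to FA_NB, fitted once on a conventional
   titration series and then inverted to read concentrations off the
   calibration wells;
2. a one-dimensional diffusion profile per focal plane,

       c(z, t) = c0 * (1 + erf(-z / sqrt(4 D (t + t0))))

   fitted to the inverted concentrations with the composite width
   w = z / sqrt(4 D) and c0 free and t0 held fixed.  The fitted profile
   extrapolates below the direct-measurement floor (~100 nM, where the weak
   NB affinity makes direct inversion unreliable) and smooths above it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lmfit import Model
from scipy.optimize import brentq
from scipy.special import erfc

__all__ = [
    "NbCalibration",
    "GradientFit",
    "ConsensusField",
    "InversionResult",
    "CannotCalibrateError",
    "InsufficientSpanError",
    "nb_forward_fa",
    "fit_nb_calibration",
    "invert_nb_calibration",
    "erf_concentration",
    "fit_erf_profile",
    "concentration_field",
    "aggregate_calibration_wells",
    "calibrate_wells",
    "read_calibration_series",
    "read_gradient_fits",
    "write_gradient_fits",
]

log = logging.getLogger(__name__)

#: below this concentration (nM) direct NB inversion is unreliable and the
#: fitted erf profile is used instead
DIRECT_MEASUREMENT_FLOOR_NM = 100.0


class CannotCalibrateError(RuntimeError):
    """No usable concentration observations for a focal plane."""


class InsufficientSpanError(ValueError):
    """Calibration series does not span the binding transition."""


@dataclass(frozen=True)
class NbCalibration:
    """Fitted NB-sensor response: FA_NB = baseline + amplitude * fraction bound.

    ``kd_nb`` is the NB-DNA dissociation constant (nM; ~1700 for Nile Blue)
    and ``nb_total`` the embedded dye concentration (nM).
    """

    baseline_fa: float
    amplitude: float
    kd_nb: float
    nb_total: float
    rms: float = 0.0

    def __post_init__(self) -> None:
        if self.kd_nb <= 0:
            raise ValueError("kd_nb must be > 0")
        if self.amplitude == 0:
            raise ValueError("amplitude must be nonzero")
        if self.nb_total <= 0:
            raise ValueError("nb_total must be > 0")


@dataclass(frozen=True)
class GradientFit:
    """Per-plane erf diffusion profile: c(t) = c0 * erfc(width / sqrt(t + t0)).

    ``width`` is the composite z / sqrt(4 D) in sqrt-seconds; absolute depth
    and diffusion coefficient are never separated.
    """

    c0: float
    width: float
    t0: float
    z_index: int = 0
    rms: float = 0.0
    ill_conditioned: bool = False

    def __post_init__(self) -> None:
        if self.c0 <= 0:
            raise ValueError("c0 must be > 0")
        if self.width < 0:
            raise ValueError("width must be >= 0")


@dataclass(frozen=True)
class InversionResult:
    """Concentration read off the NB sensor, with validity flags."""

    c_nM: float
    clamped: bool = False
    extrapolation_required: bool = False


def _nb_fraction_bound(c_nM, kd_nb: float, nb_total: float):
    """Fraction of NB bound to DNA at total DNA concentration c (depletion exact).

    Single-site equilibrium with receptor = NB: the bound complex is the
    smaller root of the binding quadratic, numerically stabilized.
    """
    c = np.asarray(c_nM, dtype=float)
    s = nb_total + c + kd_nb
    # smaller quadratic root via the product form (avoids cancellation)
    disc = np.sqrt(np.maximum(s * s - 4.0 * nb_total * c, 0.0))
    bound = 2.0 * nb_total * c / (s + disc)
    out = bound / nb_total
    return float(out) if out.ndim == 0 else out


def nb_forward_fa(c_nM, baseline_fa, amplitude, kd_nb, nb_total):
    """Model FA_NB at DNA concentration c (nM); linear in fraction bound."""
    return baseline_fa + amplitude * _nb_fraction_bound(c_nM, kd_nb, nb_total)


def fit_nb_calibration(
    series: Sequence[tuple[float, float]], nb_total: float
) -> NbCalibration:
    """Fit (baseline, amplitude, kd_nb) to a conventional NB titration series.

    ``series`` holds (DNA concentration nM, FA_NB) pairs; at least five
    distinct concentrations spanning the transition are required.  A clearly
    non-monotone series fits poorly and is reported via a warning with the
    residual.
    """
    c = np.array([p[0] for p in series], dtype=float)
    fa = np.array([p[1] for p in series], dtype=float)
    if len(np.unique(c)) < 5 or c.max() <= c.min():
        raise InsufficientSpanError(
            "need >= 5 distinct DNA concentrations spanning the transition"
        )

    model = Model(
        nb_forward_fa,
        independent_vars=["c_nM", "nb_total"],
        param_names=["baseline_fa", "amplitude", "kd_nb"],
    )
    span = fa.max() - fa.min()
    params = model.make_params(
        baseline_fa=float(fa[np.argmin(c)]),
        amplitude=float(span if span > 0 else 1e-3),
        kd_nb=float(np.median(c[c > 0])) if (c > 0).any() else 1000.0,
    )
    params["kd_nb"].set(min=1e-6)
    result = model.fit(fa, params, c_nM=c, nb_total=nb_total)
    rms = float(np.sqrt(np.mean(result.residual**2)))
    if span > 0 and rms > 0.2 * span:
        log.warning(
            "NB calibration fits poorly (rms %.3g vs span %.3g); series may be non-monotone",
            rms,
            span,
        )
    return NbCalibration(
        baseline_fa=float(result.params["baseline_fa"].value),
        amplitude=float(result.params["amplitude"].value),
        kd_nb=float(result.params["kd_nb"].value),
        nb_total=float(nb_total),
        rms=rms,
    )


def invert_nb_calibration(
    fa_nb: float,
    calib: NbCalibration,
    floor_nM: float = DIRECT_MEASUREMENT_FLOOR_NM,
    rel_tol: float = 1e-10,
) -> InversionResult:
    """Concentration whose forward isotherm FA equals ``fa_nb``.

    The depletion isotherm is strictly monotone in c, so the inverse is
    unique; it is found by bracketed root-finding.  FA values outside the
    span of the calibration curve are clamped to the nearest end and flagged;
    concentrations below ``floor_nM`` are flagged ``extrapolation_required``.
    """
    # fraction bound implied by the anisotropy
    fb = (fa_nb - calib.baseline_fa) / calib.amplitude
    if fb <= 0.0:
        return InversionResult(0.0, clamped=fb < -rel_tol, extrapolation_required=True)
    if fb >= 1.0:
        return InversionResult(math.inf, clamped=True)

    def g(c: float) -> float:
        return _nb_fraction_bound(c, calib.kd_nb, calib.nb_total) - fb

    hi = calib.kd_nb + calib.nb_total
    while g(hi) < 0:
        hi *= 4.0
        if hi > 1e15:  # pragma: no cover - unreachable for fb < 1
            raise RuntimeError("failed to bracket NB inversion")
    c = brentq(g, 0.0, hi, xtol=1e-12, rtol=1e-14)
    return InversionResult(float(c), extrapolation_required=c < floor_nM)


def erf_concentration(t, c0: float, width: float, t0: float):
    """Eq.-of-motion of the gradient: c(t) = c0 * erfc(width / sqrt(t + t0))."""
    t = np.asarray(t, dtype=float)
    if np.any(t + t0 <= 0):
        raise ValueError("t + t0 must be > 0")
    out = c0 * erfc(width / np.sqrt(t + t0))
    return float(out) if out.ndim == 0 else out


def fit_erf_profile(
    observations: Sequence[tuple[float, float]],
    t0: float,
    z_index: int = 0,
    floor_nM: float = DIRECT_MEASUREMENT_FLOOR_NM,
) -> GradientFit:
    """Fit c0 and the composite width to (t, c) observations at one plane.

    Only observations at/above the direct-measurement floor enter the fit
    (below it the NB readout is unreliable); t0 is held fixed.  At least four
    such time points are required.  A fitted curve whose relative span over
    the observed times is negligible cannot separate c0 from width and is
    flagged ``ill_conditioned``.
    """
    t = np.array([p[0] for p in observations], dtype=float)
    c = np.array([p[1] for p in observations], dtype=float)
    keep = c >= floor_nM
    if keep.sum() < 4:
        raise CannotCalibrateError(
            f"plane {z_index}: only {int(keep.sum())} observations at/above "
            f"{floor_nM:g} nM; cannot calibrate"
        )
    t, c = t[keep], c[keep]

    model = Model(
        erf_concentration, independent_vars=["t", "t0"], param_names=["c0", "width"]
    )
    params = model.make_params(c0=float(c.max()), width=max(float(np.sqrt(t.min() + t0)), 1.0))
    params["c0"].set(min=1e-9)
    params["width"].set(min=0.0)
    result = model.fit(c, params, t=t, t0=t0)
    c0 = float(result.params["c0"].value)
    width = float(result.params["width"].value)
    rms = float(np.sqrt(np.mean(result.residual**2)))

    fitted = erf_concentration(t, c0, width, t0)
    mean_level = float(np.mean(fitted))
    span = float(fitted.max() - fitted.min())
    ill = mean_level > 0 and span / mean_level < 1e-3
    if ill:
        log.warning(
            "plane %d: flat concentration profile; c0/width degenerate", z_index
        )
    return GradientFit(
        c0=c0, width=width, t0=float(t0), z_index=z_index, rms=rms, ill_conditioned=ill
    )


def concentration_field(fit: GradientFit, t):
    """Evaluate the fitted gradient at time(s) t (seconds) -> concentration nM."""
    return erf_concentration(t, fit.c0, fit.width, fit.t0)


@dataclass
class ConsensusField:
    """Mean concentration field across calibration wells, with per-plane CV."""

    fits: Mapping[str, Mapping[int, GradientFit]]
    cv_threshold: float = 0.30

    def __post_init__(self) -> None:
        if not self.fits:
            raise ValueError("need at least one calibration well")
        planes: set[int] = set()
        for per_plane in self.fits.values():
            planes |= set(per_plane)
        self.planes: tuple[int, ...] = tuple(sorted(planes))

    def _plane_values(self, z_index: int, t) -> np.ndarray:
        vals = [
            concentration_field(per_plane[z_index], t)
            for per_plane in self.fits.values()
            if z_index in per_plane
        ]
        if not vals:
            raise KeyError(f"no calibration fit for plane {z_index}")
        return np.asarray(vals, dtype=float)

    def concentration(self, z_index: int, t):
        """Mean across calibration wells of the fitted c(z, t)."""
        vals = self._plane_values(z_index, t)
        out = vals.mean(axis=0)
        return float(out) if np.ndim(out) == 0 else out

    def cv(self, z_index: int, t):
        """Coefficient of variation across wells at (z, t); NaN for one well."""
        vals = self._plane_values(z_index, t)
        if vals.shape[0] < 2:
            out = np.full(np.shape(np.asarray(t, dtype=float)), np.nan)
            return float(out) if out.ndim == 0 else out
        mean = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=1)
        out = np.where(mean > 0, sd / mean, np.nan)
        return float(out) if np.ndim(out) == 0 else out


def aggregate_calibration_wells(
    fits: Mapping[str, Mapping[int, GradientFit]],
    cv_threshold: float = 0.30,
    check_times: Sequence[float] = (),
) -> ConsensusField:
    """Build the consensus field; warn when between-well CV exceeds threshold."""
    field_ = ConsensusField(fits=dict(fits), cv_threshold=cv_threshold)
    for z in field_.planes:
        for t in check_times:
            cv = field_.cv(z, t)
            if np.isfinite(cv) and cv > cv_threshold:
                log.warning(
                    "calibration CV %.2f at plane %d, t=%.0f s exceeds %.2f",
                    cv,
                    z,
                    t,
                    cv_threshold,
                )
    return field_


def calibrate_wells(
    anisotropy: pd.DataFrame,
    calib: NbCalibration,
    t0: float,
    floor_nM: float = DIRECT_MEASUREMENT_FLOOR_NM,
    cv_threshold: float = 0.30,
) -> ConsensusField:
    """Full calibration path: FA_NB table for calibration wells -> consensus field.

    ``anisotropy`` is an fa_core anisotropy table restricted to calibration
    wells.  Per well and plane, each FA_NB is inverted through the isotherm
    and the erf profile is fitted to the resulting (t, c) points.
    """
    fits: dict[str, dict[int, GradientFit]] = {}
    for (well, z), grp in anisotropy.groupby(["well", "z_index"]):
        obs = [
            (float(row.t_seconds), invert_nb_calibration(float(row.fa), calib, floor_nM).c_nM)
            for row in grp.itertuples(index=False)
        ]
        obs = [(t, c) for t, c in obs if np.isfinite(c)]
        try:
            fit = fit_erf_profile(obs, t0=t0, z_index=int(z), floor_nM=floor_nM)
        except CannotCalibrateError as exc:
            log.warning("well %s: %s", well, exc)
            continue
        fits.setdefault(str(well), {})[int(z)] = fit
    if not fits:
        raise CannotCalibrateError("no plane of any calibration well could be fitted")
    times = sorted(anisotropy["t_seconds"].unique())
    check = times[:: max(len(times) // 5, 1)]
    return aggregate_calibration_wells(fits, cv_threshold=cv_threshold, check_times=check)


# ---------------------------------------------------------------------------
# I/O

def read_calibration_series(path) -> list[tuple[float, float]]:
    """Read an NB titration series TSV with columns c_nM, fa."""
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["c_nM"].astype(float), df["fa"].astype(float)))


def read_gradient_fits(path, cv_threshold: float = 0.30) -> ConsensusField:
    """Rebuild a consensus field from a gradient-fits TSV (see write_gradient_fits)."""
    df = pd.read_csv(path, sep="\t")
    fits: dict[str, dict[int, GradientFit]] = {}
    for row in df.itertuples(index=False):
        fits.setdefault(str(row.well), {})[int(row.z_index)] = GradientFit(
            c0=float(row.c0_nM),
            width=float(row.width),
            t0=float(row.t0_s),
            z_index=int(row.z_index),
            rms=float(row.rms),
        )
    return ConsensusField(fits=fits, cv_threshold=cv_threshold)


def write_gradient_fits(field_: ConsensusField, path) -> None:
    """Write per-well per-plane gradient fits as TSV."""
    rows = []
    for well, per_plane in field_.fits.items():
        for z, fit in sorted(per_plane.items()):
            rows.append(
                {
                    "well": well,
                    "z_index": z,
                    "c0_nM": fit.c0,
                    "width": fit.width,
                    "t0_s": fit.t0,
                    "rms": fit.rms,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
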