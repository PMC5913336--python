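"""Competitive-binding model and K_D fitting engine.

A labeled reference DNA (L_S, concentration L_ST) and an unlabeled
competitor (L, concentration L_T) compete for the same TF (R, total active
concentration R_T).  The coupled two-ligand mass-action equilibrium has an
exact closed-form solution (Roehrl et al.): with

    d = K_D1 + K_D2 + L_ST + L_T - R_T
    e = (L_T - R_T) K_D1 + (L_ST - R_T) K_D2 + K_D1 K_D2
    f = -K_D1 K_D2 R_T
    theta = arccos((-2 d^3 + 9 d e - 27 f) / (2 sqrt((d^2 - 3 e)^3)))

the free-receptor concentration is R = (2 sqrt(d^2 - 3e) cos(theta/3) - d)/3
and the fraction of labeled DNA bound is FSB = R / (K_D1 + R).  Measured
anisotropy is linear in that fraction, FA = C * FSB + B.

Fitting a titration curve FA(L_T) with K_D1 known yields four parameters:
the competitor affinity K_D2, the active protein concentration R_T, and the
normalization pair (C, B).  K_D2 and R_T are optimized in log10 space with a
multi-start grid over K_D2, since affinities span six decades (10 pM-10 µM).

An independent numerical oracle (bracketed root-finding on free receptor)
verifies the closed form and generates synthetic equilibria.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .fa_core import AnisotropyPoint
from .gradient import ConsensusField

__all__ = [
    "CompetitionParams",
    "TitrationCurve",
    "FitResult",
    "FitOptions",
    "NonPhysicalParamsError",
    "competitive_fa",
    "free_receptor_closed_form",
    "equilibrium_oracle",
    "fit_titration",
    "fit_reference_kd",
    "analyze_well",
    "aggregate_replicates",
    "read_curve",
    "write_results",
    "DILUTION_SERIES_NM",
    "LOW_KD_FLOOR_NM",
]

log = logging.getLogger(__name__)

#: 12-point competitor design used for very strong binders (K_D < 0.5 nM)
DILUTION_SERIES_NM: tuple[float, ...] = (
    0.0, 1.25, 3.5, 9.0, 19.0, 45.0, 90.0, 190.0, 425.0, 900.0, 1900.0, 4000.0,
)

#: below this fitted K_D the gradient mode is unreliable and a conventional
#: dilution series is recommended
LOW_KD_FLOOR_NM = 0.5

_ARCCOS_CLIP_TOL = 1e-9


class NonPhysicalParamsError(ValueError):
    """The cubic discriminant is negative beyond numerical tolerance."""


@dataclass(frozen=True)
class CompetitionParams:
    """Full parameter set of the competition model (concentrations in nM)."""

    kd1: float
    kd2: float
    rt: float
    lst: float
    amplitude: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.kd1 <= 0 or self.kd2 <= 0:
            raise ValueError("dissociation constants must be > 0")
        if self.rt < 0 or self.lst < 0:
            raise ValueError("concentrations must be >= 0")
        for v in (self.kd1, self.kd2, self.rt, self.lst, self.amplitude, self.offset):
            if not np.isfinite(v):
                raise ValueError("parameters must be finite")


@dataclass(frozen=True)
class TitrationCurve:
    """(L_T, FA) pairs for one well; mode 'gradient' or 'dilution-series'."""

    points: tuple[tuple[float, float], ...]
    well: str = ""
    mode: str = "gradient"

    def __post_init__(self) -> None:
        pts = tuple((float(l), float(f)) for l, f in self.points)
        if any(l < 0 for l, _ in pts):
            raise ValueError("competitor concentrations must be >= 0")
        object.__setattr__(self, "points", pts)

    @property
    def lt(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def fa(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FitResult:
    """Estimated competition parameters with diagnostics."""

    kd2: Optional[float]
    rt: Optional[float]
    amplitude: Optional[float]
    offset: Optional[float]
    stderr: Mapping[str, float] = field(default_factory=dict)
    rms: float = math.nan
    converged: bool = False
    n_points: int = 0
    flags: frozenset[str] = frozenset()
    well: str = ""

    def with_flags(self, *extra: str) -> "FitResult":
        return replace(self, flags=self.flags | frozenset(extra))


@dataclass(frozen=True)
class FitOptions:
    """Fit-engine knobs; defaults suit the six-decade affinity range."""

    kd2_bounds_nM: tuple[float, float] = (1e-3, 1e6)
    rt_bounds_nM: tuple[float, float] = (1e-2, 1e4)
    multistart_kd2_nM: tuple[float, ...] = tuple(float(10.0**k) for k in range(-2, 5))
    nominal_rt_nM: float = 40.0
    lst_nM: float = 1.0
    noise_floor_fa: float = 0.01
    low_kd_floor_nM: float = LOW_KD_FLOOR_NM
    min_points: int = 6
    weights: Optional[Sequence[float]] = None


def free_receptor_closed_form(lt, p: CompetitionParams):
    """Free-receptor concentration R from the cubic closed form (nM).

    Accepts scalar or array L_T.  Raises :class:`NonPhysicalParamsError` if
    d^2 - 3e < 0 beyond floating-point tolerance; arccos arguments outside
    [-1, 1] by more than 1e-9 are likewise rejected, smaller excursions are
    clipped and logged.
    """
    ld = np.longdouble
    lt = np.asarray(lt, dtype=ld)
    kd1, kd2, rt, lst = ld(p.kd1), ld(p.kd2), ld(p.rt), ld(p.lst)
    d = kd1 + kd2 + lst + lt - rt
    e = (lt - rt) * kd1 + (lst - rt) * kd2 + kd1 * kd2
    f = -kd1 * kd2 * rt
    disc = d * d - 3.0 * e
    scale = np.maximum(d * d, 1.0)
    if np.any(disc < -1e-12 * scale):
        raise NonPhysicalParamsError("d^2 - 3e < 0: non-physical parameter set")
    disc = np.maximum(disc, 0.0)
    sqrt_disc = np.sqrt(disc)
    denom = 2.0 * sqrt_disc**3
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = np.where(
            denom > 0,
            (-2.0 * d**3 + 9.0 * d * e - 27.0 * f) / np.where(denom > 0, denom, 1.0),
            1.0,
        )
    excursion = float(np.max(np.abs(arg))) - 1.0
    if excursion > _ARCCOS_CLIP_TOL:
        raise NonPhysicalParamsError(
            f"arccos argument off by {excursion:.3g}: non-physical parameter set"
        )
    if excursion > 0:
        log.debug("clipping arccos argument excursion %.3g", excursion)
    theta = np.arccos(np.clip(arg, -1.0, 1.0))
    r = (2.0 * sqrt_disc * np.cos(theta / 3.0) - d) / 3.0
    r = np.maximum(r, 0.0)
    # The trig evaluation of the cubic root loses precision when the arccos
    # argument sits near +-1 (free receptor tiny relative to d); a few Newton
    # steps on the cubic R^3 + d R^2 + e R + f itself restore it.
    for _ in range(3):
        poly = f + r * (e + r * (d + r))
        dpoly = e + r * (2.0 * d + 3.0 * r)
        step = np.where(dpoly != 0, poly / np.where(dpoly != 0, dpoly, 1.0), 0.0)
        r = np.maximum(r - step, 0.0)
    r = r.astype(float)
    return float(r) if r.ndim == 0 else r


def competitive_fa(lt, p: CompetitionParams):
    """Model anisotropy FA = C * FSB + B at competitor concentration(s) L_T."""
    r = free_receptor_closed_form(lt, p)
    fsb = np.asarray(r) / (p.kd1 + np.asarray(r))
    out = p.amplitude * fsb + p.offset
    return float(out) if np.ndim(out) == 0 else out


def equilibrium_oracle(
    kd1: float, kd2: float, rt: float, lst: float, lt: float
) -> dict[str, float]:
    """Numerically exact two-ligand equilibrium by root-finding on free receptor.

    Independent of the closed form: solves the receptor conservation law

        R + R*L_ST/(K_D1 + R) + R*L_T/(K_D2 + R) = R_T

    for R in [0, R_T] and returns all species concentrations (nM).
    """
    if kd1 <= 0 or kd2 <= 0:
        raise ValueError("dissociation constants must be > 0")
    if min(rt, lst, lt) < 0:
        raise ValueError("concentrations must be >= 0")

    def balance(r: float) -> float:
        return r * (1.0 + lst / (kd1 + r) + lt / (kd2 + r)) - rt

    if rt == 0:
        r = 0.0
    else:
        r = brentq(balance, 0.0, rt, xtol=1e-300, rtol=8.9e-16, maxiter=300)
    bound_labeled = r * lst / (kd1 + r)
    bound_competitor = r * lt / (kd2 + r)
    return {
        "free_receptor": r,
        "bound_labeled": bound_labeled,
        "bound_competitor": bound_competitor,
        "free_labeled": lst - bound_labeled,
        "free_competitor": lt - bound_competitor,
    }


# ---------------------------------------------------------------------------
# fitting


def _pack_model(lt: np.ndarray, kd1: float, lst: float, shared_kd: bool):
    """Residual-model factory; x = [log10 kd2, log10 rt, C, B]."""

    def model_fa(x: np.ndarray) -> np.ndarray:
        kd2 = 10.0 ** x[0]
        rt = 10.0 ** x[1]
        p = CompetitionParams(
            kd1=kd2 if shared_kd else kd1, kd2=kd2, rt=rt, lst=lst,
            amplitude=x[2], offset=x[3],
        )
        return competitive_fa(lt, p)

    return model_fa


def _fit_curve(
    curve: TitrationCurve,
    kd1: Optional[float],
    cfg: FitOptions,
    shared_kd: bool,
) -> FitResult:
    lt = curve.lt
    fa = curve.fa
    n = len(curve)
    if n < cfg.min_points:
        raise ValueError(f"need >= {cfg.min_points} points to fit, got {n}")
    span = float(fa.max() - fa.min())
    if span < cfg.noise_floor_fa:
        return FitResult(
            kd2=None, rt=None, amplitude=None, offset=None,
            converged=False, n_points=n, well=curve.well,
            flags=frozenset({"no-binding-detected"}),
        )

    weights = (
        np.sqrt(np.asarray(cfg.weights, dtype=float))
        if cfg.weights is not None
        else None
    )
    model_fa = _pack_model(lt, kd1 if kd1 is not None else 1.0, cfg.lst_nM, shared_kd)

    def residual(x: np.ndarray) -> np.ndarray:
        res = model_fa(x) - fa
        return res if weights is None else res * weights

    lo = [math.log10(cfg.kd2_bounds_nM[0]), math.log10(cfg.rt_bounds_nM[0]), -5.0, -5.0]
    hi = [math.log10(cfg.kd2_bounds_nM[1]), math.log10(cfg.rt_bounds_nM[1]), 5.0, 5.0]

    b0 = float(fa.min())
    c0 = span
    rt0 = float(np.clip(cfg.nominal_rt_nM, *cfg.rt_bounds_nM))
    # competitor concentration nearest the half-span crossing seeds kd2
    half = b0 + 0.5 * span
    pos_lt = lt[lt > 0]
    kd2_half = float(pos_lt[np.argmin(np.abs(fa[lt > 0] - half))]) if pos_lt.size else 10.0
    starts = [kd2_half, *cfg.multistart_kd2_nM]

    best = None
    for kd2_start in starts:
        kd2_start = float(np.clip(kd2_start, *cfg.kd2_bounds_nM))
        x0 = np.clip(
            [math.log10(kd2_start), math.log10(rt0), c0, b0],
            lo, hi,
        )
        try:
            sol = least_squares(
                residual, x0, bounds=(lo, hi), method="trf",
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except NonPhysicalParamsError:  # pragma: no cover - bounded params are physical
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        return FitResult(
            kd2=None, rt=None, amplitude=None, offset=None,
            converged=False, n_points=n, well=curve.well,
            flags=frozenset({"unconverged"}),
        )

    x = best.x
    kd2 = 10.0 ** x[0]
    rt = 10.0 ** x[1]
    rms = float(np.sqrt(np.mean((model_fa(x) - fa) ** 2)))
    stderr = _standard_errors(best, n, kd2, rt)
    flags = set()
    if not (cfg.kd2_bounds_nM[0] * 1.01 < kd2 < cfg.kd2_bounds_nM[1] / 1.01):
        flags.add("kd2-at-bound")
    return FitResult(
        kd2=float(kd2), rt=float(rt), amplitude=float(x[2]), offset=float(x[3]),
        stderr=stderr, rms=rms, converged=bool(best.success), n_points=n,
        flags=frozenset(flags), well=curve.well,
    )


def _standard_errors(sol, n: int, kd2: float, rt: float) -> dict[str, float]:
    """Local-curvature standard errors; log-space errors mapped to linear scale."""
    p = sol.x.size
    dof = max(n - p, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    ln10 = math.log(10.0)
    return {
        "kd2": float(kd2 * ln10 * se[0]),
        "rt": float(rt * ln10 * se[1]),
        "amplitude": float(se[2]),
        "offset": float(se[3]),
    }


def fit_titration(curve: TitrationCurve, kd1: float, cfg: FitOptions = FitOptions()) -> FitResult:
    """Four-parameter fit (K_D2, R_T, C, B) of a titration curve, K_D1 known."""
    if kd1 <= 0:
        raise ValueError("kd1 must be > 0")
    return _fit_curve(curve, kd1, cfg, shared_kd=False)


def fit_reference_kd(curve: TitrationCurve, cfg: FitOptions = FitOptions()) -> FitResult:
    """Self-competition fit with K_D2 constrained equal to K_D1.

    Used to establish the reference affinity: the competitor is the same
    (unlabeled) sequence as the labeled reference.  The returned
    ``FitResult.kd2`` holds the shared K_D estimate.  If the fitted active
    protein does not exceed the labeled-DNA concentration, the stated assay
    assumption (TF in molar excess over reference DNA) is violated and the
    result is flagged.
    """
    res = _fit_curve(curve, None, cfg, shared_kd=True)
    if res.converged and res.rt is not None and res.rt < cfg.lst_nM:
        res = res.with_flags("rt-below-lst")
        log.warning(
            "fitted active protein %.3g nM below labeled DNA %.3g nM",
            res.rt,
            cfg.lst_nM,
        )
    return res


def analyze_well(
    points: Sequence[AnisotropyPoint],
    field_: ConsensusField,
    kd1: float,
    cfg: FitOptions = FitOptions(),
) -> FitResult:
    """Join FA(z, t) with the calibrated c(z, t) field and fit the well.

    Every anisotropy point is paired with the consensus competitor
    concentration at its (plane, time); all planes are merged into a single
    titration curve.  Fitted K_D2 below the low-K_D floor (default 0.5 nM)
    is flagged ``use-dilution-series``: the gradient mode cannot resolve it.
    """
    if field_ is None:
        raise ValueError("missing calibration: consensus gradient field required")
    pts = []
    for p in points:
        lt = field_.concentration(p.z_index, p.t_seconds)
        pts.append((float(lt), p.fa))
    curve = TitrationCurve(points=tuple(pts), well=points[0].well if points else "", mode="gradient")
    result = fit_titration(curve, kd1, cfg)
    if result.converged and result.kd2 is not None and result.kd2 < cfg.low_kd_floor_nM:
        result = result.with_flags("use-dilution-series")
    return result


def aggregate_replicates(kd2_values: Sequence[float]) -> dict[str, float]:
    """Replicate summary: geometric-mean K_D and linear-scale CV."""
    vals = np.asarray(kd2_values, dtype=float)
    if vals.size == 0 or (vals <= 0).any():
        raise ValueError("replicate K_Ds must be positive and non-empty")
    gmean = float(np.exp(np.mean(np.log(vals))))
    cv = float(vals.std(ddof=1) / vals.mean()) if vals.size > 1 else math.nan
    return {"kd2_geomean_nM": gmean, "cv": cv, "n": int(vals.size)}


# ---------------------------------------------------------------------------
# I/O

def read_curve(path, well: str = "", mode: str = "gradient") -> TitrationCurve:
    """Read a titration-curve TSV with columns lt_nM, fa."""
    df = pd.read_csv(path, sep="\t")
    return TitrationCurve(
        points=tuple(zip(df["lt_nM"].astype(float), df["fa"].astype(float))),
        well=well,
        mode=mode,
    )


def write_results(results: Iterable[FitResult], path, sequences: Optional[Mapping[str, str]] = None) -> None:
    """Write fit results as TSV (well, sequence, kd2_nM, rt_nM, C, B, rms, converged, flags)."""
    rows = []
    for r in results:
        rows.append(
            {
                "well": r.well,
                "sequence": (sequences or {}).get(r.well, ""),
                "kd2_nM": r.kd2,
                "rt_nM": r.rt,
                "C": r.amplitude,
                "B": r.offset,
                "rms": r.rms,
                "converged": r.converged,
                "flags": ";".join(sorted(r.flags)),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
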