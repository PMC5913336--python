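"""Dissociation kinetics: exponential FA decay -> k_off, k_on.

After a large excess of unlabeled competitor is added at time t_add, the
labeled complex decays with first-order kinetics,

    FA(t) = A + B * exp(-(t - t_add) / tau_off),

so tau_off is read off a single trace; k_off = 1 / tau_off and, with the
equilibrium constant from the titration assay, k_on = k_off / K_D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from lmfit import Model

__all__ = [
    "DissociationTrace",
    "KineticsResult",
    "exponential_decay",
    "fit_dissociation",
    "rate_constants",
    "detect_addition_time",
    "read_trace",
]

NM_TO_M = 1e-9  # exact


@dataclass(frozen=True)
class DissociationTrace:
    """FA time trace with the competitor-addition time t_add (seconds)."""

    times: np.ndarray
    fa: np.ndarray
    t_add: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        f = np.asarray(self.fa, dtype=float)
        if t.shape != f.shape:
            raise ValueError("times and fa differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (t[0] <= self.t_add <= t[-1]):
            raise ValueError("t_add must lie within the observed range")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fa", f)


@dataclass(frozen=True)
class KineticsResult:
    """Fitted decay (A, B, tau_off) and derived rate constants."""

    a: float
    b: float
    tau_off_s: float
    k_off_per_s: Optional[float] = None
    k_on_per_M_s: Optional[float] = None
    rms: float = math.nan
    no_decay: bool = False


def exponential_decay(t, a, b, tau_off, t_add):
    """Model FA(t) = A + B exp(-(t - t_add)/tau_off) for t >= t_add."""
    return a + b * np.exp(-(np.asarray(t, dtype=float) - t_add) / tau_off)


def fit_dissociation(trace: DissociationTrace) -> KineticsResult:
    """Least-squares fit of the first-order decay on points with t >= t_add.

    Points before t_add only sanity-check the pre-addition plateau.  An
    amplitude indistinguishable from zero (|B| < 2 x its standard error)
    sets the ``no_decay`` flag: dissociation was faster than the sampling,
    or absent.
    """
    after = trace.times >= trace.t_add
    t = trace.times[after]
    fa = trace.fa[after]
    if t.size < 8:
        raise ValueError(f"need >= 8 points after t_add, got {t.size}")

    model = Model(
        exponential_decay, independent_vars=["t", "t_add"], param_names=["a", "b", "tau_off"]
    )
    a0 = float(fa[-1])
    b0 = float(fa[0] - fa[-1])
    tau0 = max(float(t[-1] - t[0]) / 5.0, 1e-6)
    params = model.make_params(a=a0, b=b0, tau_off=tau0)
    params["tau_off"].set(min=1e-9)
    result = model.fit(fa, params, t=t, t_add=trace.t_add)
    b = result.params["b"]
    no_decay = b.stderr is not None and abs(b.value) < 2.0 * b.stderr
    return KineticsResult(
        a=float(result.params["a"].value),
        b=float(b.value),
        tau_off_s=float(result.params["tau_off"].value),
        rms=float(np.sqrt(np.mean(result.residual**2))),
        no_decay=bool(no_decay),
    )


def rate_constants(result: KineticsResult, kd_nM: float) -> KineticsResult:
    """Attach k_off = 1/tau_off (s^-1) and k_on = k_off / K_D (M^-1 s^-1)."""
    if kd_nM <= 0:
        raise ValueError("kd must be > 0")
    if not result.tau_off_s > 0:
        raise ValueError("tau_off must be fitted and > 0")
    k_off = 1.0 / result.tau_off_s
    k_on = k_off / (kd_nM * NM_TO_M)
    return replace(result, k_off_per_s=k_off, k_on_per_M_s=k_on)


def detect_addition_time(times, fa, window: int = 5) -> float:
    """Changepoint helper (off by default): time of steepest smoothed FA drop."""
    t = np.asarray(times, dtype=float)
    f = np.asarray(fa, dtype=float)
    kernel = np.ones(window) / window
    smooth = np.convolve(f, kernel, mode="same")
    i = int(np.argmin(np.diff(smooth)))
    return float(t[i])


def read_trace(path, t_add: float) -> DissociationTrace:
    """Read a trace TSV with columns t_seconds, fa."""
    df = pd.read_csv(path, sep="\t")
    return DissociationTrace(
        times=df["t_seconds"].to_numpy(float),
        fa=df["fa"].to_numpy(float),
        t_add=t_add,
    )
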