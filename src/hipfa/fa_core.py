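"""Raw polarized intensities -> fluorescence anisotropy trajectories.

The microscope records, for every well, measurement cycle and z-focal plane,
a pair of images: the parallel (I_par) and perpendicular (I_perp) polarized
components of the emission.  Anisotropy is

    FA = (I_par - G * I_perp) / (I_par + 2 * I_perp)

where the G-factor corrects the instrument's bias toward the perpendicular
channel (default 1.15 for the reference setup).  This module extracts
region-of-interest means from image frames, applies the formula, and
assembles per-well FA(z, t) trajectories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Rect",
    "RoiLayout",
    "InstrumentConfig",
    "PolarizedFrame",
    "AnisotropyPoint",
    "UndefinedAnisotropyError",
    "extract_roi_means",
    "compute_fa",
    "build_trajectories",
    "read_intensity_table",
    "anisotropy_table",
    "write_anisotropy_table",
    "trajectories_from_table",
]

log = logging.getLogger(__name__)

#: columns of the canonical mean-intensity table
INTENSITY_COLUMNS = ["well", "cycle", "z_index", "t_seconds", "i_par", "i_perp"]
#: columns of the anisotropy output table
ANISOTROPY_COLUMNS = ["well", "z_index", "t_seconds", "fa", "i_total"]


class UndefinedAnisotropyError(ValueError):
    """Raised when I_par + 2*I_perp <= 0 so FA is undefined."""


@dataclass(frozen=True)
class Rect:
    """Pixel rectangle, 0-based, half-open: rows [top, bottom), cols [left, right)."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (self.bottom > self.top and self.right > self.left):
            raise ValueError(f"degenerate rectangle {self}")

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.bottom <= other.top
            or other.bottom <= self.top
            or self.right <= other.left
            or other.right <= self.left
        )


@dataclass(frozen=True)
class RoiLayout:
    """The two regions of interest on the camera chip (beam-splitter halves)."""

    parallel: Rect
    perpendicular: Rect

    def __post_init__(self) -> None:
        if self.parallel.overlaps(self.perpendicular):
            raise ValueError("parallel and perpendicular ROIs overlap")


@dataclass(frozen=True)
class InstrumentConfig:
    """Optical and stage geometry of the acquisition.

    Parameters
    ----------
    g_factor:
        Polarization-channel correction G; dimensionless, > 0.
    z_step_um:
        Piezo step between consecutive focal planes, µm.
    lowest_plane_um:
        Height of the lowest focal plane above the coverslip, µm.
    planes_per_stack:
        Number of z-planes per stack.
    cycle_interval_s:
        Time between the starts of consecutive measurement cycles, seconds.
    saturation_ceiling:
        Camera counts at/above which a frame is flagged as saturated.
    """

    g_factor: float = 1.15
    z_step_um: float = 145.0
    lowest_plane_um: float = 1400.0
    planes_per_stack: int = 12
    cycle_interval_s: float = 450.0
    saturation_ceiling: float = 65535.0

    def __post_init__(self) -> None:
        if self.g_factor <= 0:
            raise ValueError("g_factor must be > 0")
        if self.z_step_um <= 0:
            raise ValueError("z_step_um must be > 0")
        if self.planes_per_stack < 1:
            raise ValueError("planes_per_stack must be >= 1")


@dataclass(frozen=True)
class PolarizedFrame:
    """One dual-channel exposure: both polarization images for (well, cycle, z)."""

    well: str
    cycle: int
    z_index: int
    t_seconds: float
    parallel: np.ndarray
    perpendicular: np.ndarray

    def __post_init__(self) -> None:
        par = np.asarray(self.parallel, dtype=float)
        perp = np.asarray(self.perpendicular, dtype=float)
        if par.shape != perp.shape:
            raise ValueError("parallel and perpendicular images differ in shape")
        if (par < 0).any() or (perp < 0).any():
            raise ValueError("negative camera counts")
        object.__setattr__(self, "parallel", par)
        object.__setattr__(self, "perpendicular", perp)


@dataclass(frozen=True)
class AnisotropyPoint:
    """One FA observation at (well, z, t)."""

    well: str
    z_index: int
    t_seconds: float
    fa: float
    i_total: float
    suspect: bool = field(default=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.fa):
            raise ValueError("non-finite anisotropy")
        if self.i_total < 0:
            raise ValueError("negative total intensity")


def _check_rect(rect: Rect, shape: tuple[int, int], name: str) -> None:
    rows, cols = shape
    if rect.top < 0 or rect.left < 0 or rect.bottom > rows or rect.right > cols:
        raise IndexError(
            f"{name} region {rect} outside frame bounds {rows}x{cols}"
        )


def extract_roi_means(frame: PolarizedFrame, layout: RoiLayout) -> tuple[float, float]:
    """Mean pixel intensity of each polarization ROI, (parallel, perpendicular).

    Each channel's mean is taken on its own image over its own region, which
    matches a setup where the beam splitter maps the two components to two
    regions of the chip.
    """
    _check_rect(layout.parallel, frame.parallel.shape, "parallel")
    _check_rect(layout.perpendicular, frame.perpendicular.shape, "perpendicular")
    p = layout.parallel
    q = layout.perpendicular
    i_par = float(frame.parallel[p.top : p.bottom, p.left : p.right].mean())
    i_perp = float(frame.perpendicular[q.top : q.bottom, q.left : q.right].mean())
    return i_par, i_perp


def compute_fa(i_parallel: float, i_perpendicular: float, g: float = 1.15) -> float:
    """Fluorescence anisotropy from the two polarized intensities.

    FA = (I_par - g*I_perp) / (I_par + 2*I_perp).  Raises
    :class:`UndefinedAnisotropyError` when the total intensity is not positive.
    Accepts scalars or arrays (broadcast).
    """
    i_parallel = np.asarray(i_parallel, dtype=float)
    i_perpendicular = np.asarray(i_perpendicular, dtype=float)
    denom = i_parallel + 2.0 * i_perpendicular
    if np.any(denom <= 0):
        raise UndefinedAnisotropyError("I_par + 2*I_perp must be > 0")
    out = (i_parallel - g * i_perpendicular) / denom
    if out.ndim == 0:
        return float(out)
    return out


def build_trajectories(
    frames: Iterable[PolarizedFrame],
    layout: RoiLayout,
    cfg: InstrumentConfig,
) -> dict[str, list[AnisotropyPoint]]:
    """Assemble FA(z, t) trajectories per well from dual-channel frames.

    One :class:`AnisotropyPoint` per frame, ordered by (t, z) within each well.
    Duplicate (well, cycle, z) triples are an error; missing planes are only
    logged.  Frames containing saturated pixels are flagged ``suspect`` but
    kept, as are FA values outside [-0.5, 1.0].
    """
    seen: set[tuple[str, int, int]] = set()
    wells: dict[str, list[AnisotropyPoint]] = {}
    counts: dict[str, set[int]] = {}
    for frame in frames:
        key = (frame.well, frame.cycle, frame.z_index)
        if key in seen:
            raise ValueError(f"duplicate frame for (well, cycle, z) = {key}")
        seen.add(key)
        i_par, i_perp = extract_roi_means(frame, layout)
        fa = compute_fa(i_par, i_perp, cfg.g_factor)
        saturated = (
            frame.parallel.max(initial=0.0) >= cfg.saturation_ceiling
            or frame.perpendicular.max(initial=0.0) >= cfg.saturation_ceiling
        )
        suspect = saturated or not (-0.5 <= fa <= 1.0)
        wells.setdefault(frame.well, []).append(
            AnisotropyPoint(
                well=frame.well,
                z_index=frame.z_index,
                t_seconds=frame.t_seconds,
                fa=fa,
                i_total=i_par + 2.0 * i_perp,
                suspect=suspect,
            )
        )
        counts.setdefault(frame.well, set()).add(frame.z_index)
    for well, zs in counts.items():
        missing = set(range(cfg.planes_per_stack)) - zs
        if missing:
            log.warning("well %s: no frames for planes %s", well, sorted(missing))
    for points in wells.values():
        points.sort(key=lambda p: (p.t_seconds, p.z_index))
    return wells


def frames_from_tiff(path, well: str, page_index: Sequence[dict]) -> list[PolarizedFrame]:
    """Load dual-ROI frames from a multi-page TIFF with a sidecar page index.

    ``page_index`` holds one entry per pair of consecutive pages
    ``{"cycle": int, "z_index": int, "t_seconds": float}``; page 2k is the
    parallel image of entry k and page 2k+1 the perpendicular one.  This is a
    convenience wrapper: the canonical input path is the mean-intensity table.
    """
    import tifffile

    pages = tifffile.imread(path)
    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None, ...]
    if pages.shape[0] != 2 * len(page_index):
        raise ValueError(
            f"TIFF has {pages.shape[0]} pages but index describes {len(page_index)} frame pairs"
        )
    frames = []
    for k, entry in enumerate(page_index):
        frames.append(
            PolarizedFrame(
                well=well,
                cycle=int(entry["cycle"]),
                z_index=int(entry["z_index"]),
                t_seconds=float(entry["t_seconds"]),
                parallel=pages[2 * k],
                perpendicular=pages[2 * k + 1],
            )
        )
    return frames


# ---------------------------------------------------------------------------
# table I/O — the canonical path: precomputed mean intensities per (well,z,t)

def read_intensity_table(path) -> pd.DataFrame:
    """Read a mean-intensity TSV (well, cycle, z_index, t_seconds, i_par, i_perp)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(INTENSITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns {sorted(missing)}")
    return df


def anisotropy_table(intensities: pd.DataFrame, cfg: InstrumentConfig) -> pd.DataFrame:
    """Convert a mean-intensity table to an anisotropy table.

    Output columns: well, z_index, t_seconds, fa, i_total; rows sorted by
    (well, t_seconds, z_index).
    """
    df = intensities.copy()
    df["fa"] = compute_fa(
        df["i_par"].to_numpy(), df["i_perp"].to_numpy(), cfg.g_factor
    )
    df["i_total"] = df["i_par"] + 2.0 * df["i_perp"]
    out = df[ANISOTROPY_COLUMNS].sort_values(["well", "t_seconds", "z_index"])
    return out.reset_index(drop=True)


def write_anisotropy_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def trajectories_from_table(df: pd.DataFrame) -> dict[str, list[AnisotropyPoint]]:
    """Group an anisotropy table into per-well AnisotropyPoint lists."""
    wells: dict[str, list[AnisotropyPoint]] = {}
    for row in df.itertuples(index=False):
        wells.setdefault(str(row.well), []).append(
            AnisotropyPoint(
                well=str(row.well),
                z_index=int(row.z_index),
                t_seconds=float(row.t_seconds),
                fa=float(row.fa),
                i_total=float(row.i_total),
            )
        )
    for points in wells.values():
        points.sort(key=lambda p: (p.t_seconds, p.z_index))
    return wells
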