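"""PWM evaluation by occupancy prediction against peak intervals.

A PWM is scanned over genomic sequence (both strands, log2-odds vs
background); sites above a score threshold are converted to strengths
2^score, weighted by per-base chromatin accessibility (closed chromatin
suppresses predicted binding), placed as impulses and smoothed with a
discretized gamma kernel that mimics the fragment-length distribution of a
ChIP experiment.  The resulting per-base occupancy profile is compared with
measured peak intervals by a per-base precision-recall sweep.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from sklearn.metrics import precision_recall_curve

from .specificity import BASES, Pwm

__all__ = [
    "GammaKernel",
    "OccupancyProfile",
    "PrCurve",
    "scan_pwm",
    "predict_profile",
    "precision_recall",
    "evaluate_regions",
    "read_fasta",
    "read_bed",
    "read_bedgraph",
    "region_values_from_bedgraph",
    "mask_from_intervals",
    "write_bedgraph",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GammaKernel:
    """Symmetric smoothing kernel k(d) ~ Gamma_pdf(|d|; shape, scale), d in bp."""

    shape: float = 2.0
    scale_bp: float = 100.0
    truncation_bp: int = 1000

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale_bp <= 0:
            raise ValueError("shape and scale must be > 0")

    def discretize(self) -> np.ndarray:
        """Kernel weights on [-truncation, truncation], normalized to sum 1."""
        d = np.arange(-self.truncation_bp, self.truncation_bp + 1)
        w = gamma_dist.pdf(np.abs(d), a=self.shape, scale=self.scale_bp)
        total = w.sum()
        if total <= 0:
            raise ValueError("degenerate kernel")
        return w / total


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-base predicted occupancy over [start, end) of one sequence."""

    sequence_id: str
    start: int
    end: int
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.end - self.start,):
            raise ValueError("profile length must match the interval")
        if not np.all(np.isfinite(v)) or (v < 0).any():
            raise ValueError("profile values must be finite and >= 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PrCurve:
    """Precision/recall per threshold and trapezoidal area under the curve."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    auc: float


def _encode(sequence: str) -> np.ndarray:
    """Map ACGT to 0..3; anything else to -1 (scored as background)."""
    seq = sequence.upper()
    out = np.full(len(seq), -1, dtype=int)
    for i, b in enumerate(BASES):
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _logodds(pwm: Pwm) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(pwm.matrix / pwm.background)


def _revcomp_matrix(lo: np.ndarray) -> np.ndarray:
    # reverse positions and swap A<->T, C<->G columns
    return lo[::-1, ::-1]


def scan_pwm(pwm: Pwm, sequence: str) -> np.ndarray:
    """Log2-odds site score at each window offset; max over the two strands.

    Windows run over offsets 0 .. len(sequence) - len(pwm); non-ACGT bases
    contribute 0 (background) at their position.
    """
    w = len(pwm)
    if len(sequence) < w:
        raise ValueError("sequence shorter than the PWM")
    enc = _encode(sequence)
    lo_fwd = _logodds(pwm)
    lo_rev = _revcomp_matrix(lo_fwd)
    n = len(sequence) - w + 1
    scores = np.zeros((2, n))
    for strand, lo in enumerate((lo_fwd, lo_rev)):
        for j in range(w):
            col = enc[j : j + n]
            valid = col >= 0
            scores[strand, valid] += lo[j, col[valid]]
    return scores.max(axis=0)


def predict_profile(
    scores: np.ndarray,
    accessibility: np.ndarray,
    kernel: GammaKernel = GammaKernel(),
    score_threshold: float = 0.0,
    sequence_id: str = "",
    start: int = 0,
) -> OccupancyProfile:
    """Per-base occupancy from site scores and accessibility weights.

    Sites with score >= threshold get strength 2^score multiplied by the
    accessibility (in [0, 1]) at the site center, are placed as impulses and
    convolved with the normalized gamma kernel.  ``accessibility`` has one
    value per base of the scanned sequence; the PWM width is recovered from
    the length difference to the score vector.
    """
    scores = np.asarray(scores, dtype=float)
    accessibility = np.asarray(accessibility, dtype=float)
    length = accessibility.size
    if length < scores.size:
        raise ValueError(
            f"accessibility length {length} shorter than score vector {scores.size}"
        )
    width = length - scores.size + 1
    centers = np.arange(scores.size) + width // 2
    impulses = np.zeros(length)
    above = scores >= score_threshold
    impulses[centers[above]] = 2.0 ** scores[above] * accessibility[centers[above]]
    weights = kernel.discretize()
    # full convolution sliced to the region, so kernels wider than the region work
    half = weights.size // 2
    profile = np.convolve(impulses, weights, mode="full")[half : half + length]
    return OccupancyProfile(
        sequence_id=sequence_id, start=start, end=start + length, values=profile
    )


def precision_recall(profile_values: np.ndarray, truth: np.ndarray) -> PrCurve:
    """Per-base precision-recall sweep of an occupancy profile against truth.

    ``truth`` is a boolean per-base labeling (peak bases True).  Precision
    and recall are evaluated at every distinct profile value used as a
    threshold (predicted positive: value >= threshold); the area under the
    curve is the trapezoid over recall.
    """
    values = np.asarray(profile_values, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if values.shape != truth.shape:
        raise ValueError("profile and truth labeling differ in length")
    if not truth.any():
        raise ValueError("empty truth: recall undefined")
    precision, recall, thresholds = precision_recall_curve(truth.astype(int), values)
    # sklearn appends the (recall=0, precision=1) endpoint; keep it for the sweep
    order = np.argsort(recall)
    auc = float(np.trapezoid(precision[order], recall[order]))
    return PrCurve(
        thresholds=thresholds, precision=precision, recall=recall, auc=auc
    )


def evaluate_regions(
    pwm: Pwm,
    regions: Sequence[tuple[str, str, np.ndarray, np.ndarray]],
    kernel: GammaKernel = GammaKernel(),
    score_threshold: float = 0.0,
) -> PrCurve:
    """Scan, predict and score several regions jointly.

    ``regions`` holds (sequence_id, sequence, accessibility, truth_mask)
    tuples; profiles are concatenated before the precision-recall sweep so
    that a single threshold applies across all regions.
    """
    profiles = []
    truths = []
    for seq_id, seq, acc, truth in regions:
        scores = scan_pwm(pwm, seq)
        prof = predict_profile(
            scores, acc, kernel=kernel, score_threshold=score_threshold, sequence_id=seq_id
        )
        profiles.append(prof.values)
        truths.append(np.asarray(truth, dtype=bool))
    return precision_recall(np.concatenate(profiles), np.concatenate(truths))


# ---------------------------------------------------------------------------
# format helpers (FASTA via Biopython; bedGraph/BED as plain tables)

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_bed(path) -> pd.DataFrame:
    """Read a BED3 file into columns chrom, start, end (0-based half-open)."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2], names=["chrom", "start", "end"],
    )
    return df


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph file into columns chrom, start, end, value."""
    return pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "value"],
    )


def region_values_from_bedgraph(
    df: pd.DataFrame, chrom: str, start: int, end: int, default: float = 0.0
) -> np.ndarray:
    """Per-base values over [start, end) from a bedGraph table.

    ``df`` has columns chrom, start, end, value; uncovered bases take
    ``default``.
    """
    out = np.full(end - start, default, dtype=float)
    sel = df[(df["chrom"] == chrom) & (df["end"] > start) & (df["start"] < end)]
    for row in sel.itertuples(index=False):
        lo = max(int(row.start), start) - start
        hi = min(int(row.end), end) - start
        out[lo:hi] = float(row.value)
    return out


def mask_from_intervals(df: pd.DataFrame, chrom: str, start: int, end: int) -> np.ndarray:
    """Boolean per-base mask over [start, end) from BED intervals."""
    mask = np.zeros(end - start, dtype=bool)
    sel = df[(df["chrom"] == chrom) & (df["end"] > start) & (df["start"] < end)]
    for row in sel.itertuples(index=False):
        lo = max(int(row.start), start) - start
        hi = min(int(row.end), end) - start
        mask[lo:hi] = True
    return mask


def write_bedgraph(profile: OccupancyProfile, path, chrom: Optional[str] = None) -> None:
    chrom = chrom or profile.sequence_id
    with open(path, "w") as fh:
        for i, v in enumerate(profile.values):
            pos = profile.start + i
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{v:.6g}\n")
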