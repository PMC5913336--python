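"""Binding-specificity models: K_D tables -> PWMs and information content.

Measuring the K_D of a consensus site and of each of its 3N single-base
variants determines, under the positional-independence assumption, a full
position weight matrix without any motif alignment: the probability of base
b at a position is proportional to 1 / K_D(b),

    p_b = (1 / K_Db) / sum_b' (1 / K_Db').

Specificity is summarized by the information content (total KL divergence
from background, in bits),

    IC = sum_pos sum_b PWM_pos(b) * log2(PWM_pos(b) / P_B(b)).

Two pseudo-count conventions are supported: the count-based one for matrices
built from a handful of aligned sites (+0.25 per count, one unspecific
site), and an uncertainty-style one for affinity-derived matrices (+0.01
per probability entry, renormalized).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "KdTable",
    "Pwm",
    "IncompleteTableError",
    "enumerate_point_mutants",
    "pwm_from_kds",
    "information_content",
    "per_position_information",
    "apply_pseudocounts",
    "read_kd_table",
    "write_kd_table",
    "write_meme",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "KD_CEILING_NM",
]

BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: affinities above this ceiling (10 µM) are not reliably measurable and are
#: entered at the ceiling with a flag
KD_CEILING_NM = 10_000.0


class IncompleteTableError(ValueError):
    """A (position, base) variant required for PWM construction is missing."""


def _validate_sequence(seq: str) -> str:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set(BASES)
    if bad:
        raise ValueError(f"non-ACGT characters {sorted(bad)} in sequence {seq!r}")
    return seq


@dataclass(frozen=True)
class KdTable:
    """Consensus sequence plus K_D (nM) for it and every single-base variant.

    ``variants`` maps (0-based position, substituted base) -> K_D; optional
    per-entry CVs in ``cv``.  K_Ds above :data:`KD_CEILING_NM` are clamped to
    the ceiling and recorded in ``ceiling_flagged``.
    """

    consensus: str
    consensus_kd: float
    variants: Mapping[tuple[int, str], float]
    cv: Mapping[tuple[int, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_sequence(self.consensus)
        if self.consensus_kd <= 0:
            raise ValueError("consensus K_D must be > 0")
        clamped = {}
        flagged = []
        for (pos, base), kd in self.variants.items():
            if not (0 <= pos < len(self.consensus)):
                raise ValueError(f"variant position {pos} outside consensus")
            if base not in BASES:
                raise ValueError(f"invalid base {base!r}")
            if base == self.consensus[pos]:
                raise ValueError(f"variant at {pos} equals the consensus base {base}")
            if kd <= 0:
                raise ValueError("variant K_Ds must be > 0")
            if kd > KD_CEILING_NM:
                flagged.append((pos, base))
                kd = KD_CEILING_NM
            clamped[(pos, base)] = float(kd)
        object.__setattr__(self, "variants", clamped)
        object.__setattr__(self, "ceiling_flagged", tuple(flagged))

    def kd_at(self, pos: int, base: str) -> float:
        if base == self.consensus[pos]:
            return self.consensus_kd
        try:
            return self.variants[(pos, base)]
        except KeyError:
            raise IncompleteTableError(
                f"missing variant (position {pos}, base {base})"
            ) from None


@dataclass(frozen=True)
class Pwm:
    """Positions x {A, C, G, T} probability matrix with background."""

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "pwm"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must be positions x 4")
        if (m < 0).any():
            raise ValueError("probabilities must be >= 0")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each position must sum to 1")
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background must be 4 probabilities summing to 1")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "background", bg)

    def __len__(self) -> int:
        return self.matrix.shape[0]


def enumerate_point_mutants(consensus: str) -> list[tuple[int, str, str]]:
    """All 3N single-base variants of a consensus, position-major, base-alphabetical.

    Returns (position, substituted base, variant sequence) triples; every
    variant is at Hamming distance 1 from the consensus.
    """
    _validate_sequence(consensus)
    out = []
    for pos, ref in enumerate(consensus):
        for base in BASES:
            if base == ref:
                continue
            variant = consensus[:pos] + base + consensus[pos + 1 :]
            out.append((pos, base, variant))
    return out


def pwm_from_kds(table: KdTable, name: Optional[str] = None) -> Pwm:
    """PWM whose column probabilities are proportional to 1/K_D (affinity weights).

    The consensus base at each position uses the consensus K_D.  The
    construction is scale-free: multiplying every K_D by a constant leaves
    the PWM unchanged, so specificity decouples from absolute affinity.  If
    any variant binds more strongly than the consensus the matrix is still
    built and a ``consensus_not_maximal`` warning is attached (an incorrect
    starting consensus calls for another mutational iteration).
    """
    n = len(table.consensus)
    m = np.empty((n, 4))
    for pos in range(n):
        inv = np.array([1.0 / table.kd_at(pos, b) for b in BASES])
        m[pos] = inv / inv.sum()
    pwm = Pwm(matrix=m, name=name or f"kd_pwm_{table.consensus}")
    if any(kd < table.consensus_kd for kd in table.variants.values()):
        import logging

        logging.getLogger(__name__).warning(
            "consensus-not-maximal: a variant binds more strongly than %s",
            table.consensus,
        )
    return pwm


def per_position_information(pwm: Pwm) -> np.ndarray:
    """Per-column KL divergence from background, bits; 0*log(0) treated as 0."""
    m = pwm.matrix
    bg = pwm.background
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(m > 0, m * np.log2(m / bg), 0.0)
    return terms.sum(axis=1)


def information_content(pwm: Pwm) -> float:
    """Total information content of the PWM in bits."""
    return float(per_position_information(pwm).sum())


def apply_pseudocounts(matrix, mode: str, background=None, name: str = "pwm") -> Pwm:
    """Regularize a motif so no base has zero probability.

    mode='count-based': ``matrix`` holds per-position base counts; 0.25 is
    added to every cell (one additional unspecific site) before
    column-normalizing.  mode='hipfa': ``matrix`` holds probabilities; 0.01
    is added to every cell and columns are renormalized.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] != 4:
        raise ValueError("matrix must be positions x 4")
    if (m < 0).any():
        raise ValueError("entries must be >= 0")
    if mode == "count-based":
        m = m + 0.25
    elif mode == "hipfa":
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("hipfa mode expects a probability matrix")
        m = m + 0.01
    else:
        raise ValueError(f"unknown pseudo-count mode {mode!r}")
    m = m / m.sum(axis=1, keepdims=True)
    kwargs = {} if background is None else {"background": np.asarray(background, float)}
    return Pwm(matrix=m, name=name, **kwargs)


# ---------------------------------------------------------------------------
# I/O

def read_kd_table(path) -> KdTable:
    """Read a K_D table TSV (role, position, base, sequence, kd_nM[, cv]).

    The consensus row has role='consensus'; variant rows role='variant' with
    0-based position and substituted base.
    """
    df = pd.read_csv(path, sep="\t")
    cons_rows = df[df["role"] == "consensus"]
    if len(cons_rows) != 1:
        raise ValueError("K_D table must contain exactly one consensus row")
    cons = cons_rows.iloc[0]
    variants = {}
    cvs = {}
    for row in df[df["role"] == "variant"].itertuples(index=False):
        key = (int(row.position), str(row.base))
        variants[key] = float(row.kd_nM)
        if hasattr(row, "cv") and pd.notna(row.cv):
            cvs[key] = float(row.cv)
    return KdTable(
        consensus=str(cons["sequence"]),
        consensus_kd=float(cons["kd_nM"]),
        variants=variants,
        cv=cvs,
    )


def write_kd_table(table: KdTable, path) -> None:
    rows = [
        {
            "role": "consensus",
            "position": "",
            "base": "",
            "sequence": table.consensus,
            "kd_nM": table.consensus_kd,
            "cv": table.cv.get(("consensus", ""), ""),
        }
    ]
    for (pos, base), kd in sorted(table.variants.items()):
        seq = table.consensus[:pos] + base + table.consensus[pos + 1 :]
        rows.append(
            {
                "role": "variant",
                "position": pos,
                "base": base,
                "sequence": seq,
                "kd_nM": kd,
                "cv": table.cv.get((pos, base), ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_meme(pwm: Pwm, path) -> None:
    """Write the PWM in MEME minimal motif format."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: + -",
        "",
        "Background letter frequencies",
        " ".join(f"{b} {p:.6f}" for b, p in zip(BASES, pwm.background)),
        "",
        f"MOTIF {pwm.name}",
        f"letter-probability matrix: alength= 4 w= {len(pwm)} nsites= 20 E= 0",
    ]
    for row in pwm.matrix:
        lines.append(" ".join(f"{p:10.6f}" for p in row))
    lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


def write_matrix_tsv(pwm: Pwm, path) -> None:
    df = pd.DataFrame(pwm.matrix, columns=list(BASES))
    df.insert(0, "position", np.arange(len(pwm)))
    df.to_csv(path, sep="\t", index=False)


def read_matrix_tsv(path, name: str = "pwm", background=None) -> Pwm:
    df = pd.read_csv(path, sep="\t")
    m = df[list(BASES)].to_numpy(float)
    kwargs = {} if background is None else {"background": np.asarray(background, float)}
    return Pwm(matrix=m, name=name, **kwargs)
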