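"""Vibrational band scaling, assignment, model scoring and differencing.

Computed harmonic frequencies overestimate observed fundamentals; a
multiplicative scale factor corrects the bulk of the error.  This module
scales frequency lists, matches computed band lists against experimental
ones, scores each method/basis combination by its mean absolute deviation
(MAD) over matched bands, and compares two experimental spectra to find
new, lost and shifted bands (e.g. a carboxyl band appearing on composite
formation).

Matching is *monotone*: both band lists are kept in wavenumber order and
paired one-to-one without crossings, because vibrational band order is
physically meaningful.  The optimal non-crossing pairing is found by
dynamic programming (Needleman–Wunsch style) with the skip penalty set to
the matching tolerance, and any surviving pair whose residual still
exceeds the tolerance is dissolved into the unmatched lists.

A band is either a single wavenumber (``lo == hi``) or an interval; the
residual between two bands is zero when their intervals overlap, else the
distance between the nearest endpoints.  Interval pairs participate in
matching but are excluded from MAD/RMSD by default, since endpoint
distance is not a like-for-like residual.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Band",
    "BandList",
    "AssignmentResult",
    "ModelScore",
    "BandDiff",
    "apply_scale",
    "band_residual",
    "assign_bands",
    "model_error",
    "rank_models",
    "estimate_scale",
    "diff_bands",
    "bands_to_frame",
    "bands_from_frame",
]


@dataclass(frozen=True)
class Band:
    """One spectroscopic band: a wavenumber or an interval, in cm⁻¹.

    ``present=False`` marks a placeholder row (a mode absent from one
    spectrum, tabulated as "-" to keep assignment rows aligned); absent
    bands never participate in matching.
    """

    lo: float
    hi: Optional[float] = None
    assignment: str = ""
    present: bool = True

    def __post_init__(self):
        if self.hi is None:
            object.__setattr__(self, "hi", self.lo)
        if not (0 < self.lo <= self.hi):
            raise ValueError(
                f"band requires 0 < lo <= hi, got lo={self.lo}, hi={self.hi}"
            )

    @property
    def is_interval(self) -> bool:
        return self.hi > self.lo

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def __str__(self) -> str:
        w = f"{self.lo:g}" if not self.is_interval else f"{self.lo:g}~{self.hi:g}"
        return f"{w} {self.assignment}".strip()


@dataclass(frozen=True)
class BandList:
    """An ordered set of bands from one source (experiment or a model tag)."""

    bands: tuple[Band, ...]
    source: str = ""

    def __post_init__(self):
        object.__setattr__(
            self, "bands", tuple(sorted(self.bands, key=lambda b: (b.lo, b.hi)))
        )

    def __iter__(self):
        return iter(self.bands)

    def __len__(self):
        return len(self.bands)

    @property
    def present_bands(self) -> list[Band]:
        return [b for b in self.bands if b.present]


@dataclass(frozen=True)
class AssignmentResult:
    """Outcome of matching a model band list against an experimental one."""

    pairs: tuple[tuple[Band, Band, float], ...]  # (model, exp, residual)
    unmatched_model: tuple[Band, ...]
    unmatched_exp: tuple[Band, ...]
    model_source: str = ""
    exp_source: str = ""


@dataclass(frozen=True)
class ModelScore:
    """Error summary of one method/basis combination against experiment."""

    model: str
    mad: float  # mean absolute deviation, cm⁻¹
    rmsd: float  # root-mean-square deviation, cm⁻¹
    n_matched: int


@dataclass(frozen=True)
class BandDiff:
    """Differences between two experimental band lists."""

    new: tuple[Band, ...]  # present in b, unmatched in a
    lost: tuple[Band, ...]  # present in a, unmatched in b
    shifted: tuple[tuple[Band, Band, float], ...]  # (a, b, signed shift b−a)


def apply_scale(
    freqs: Sequence[float], factor: float
) -> list[float]:
    """Multiply harmonic frequencies (cm⁻¹) by a positive scale factor.

    Imaginary modes (negative wavenumbers) are excluded with a warning —
    scaling them is meaningless and downstream band matching assumes real
    fundamentals.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    freqs = list(freqs)
    real = [f for f in freqs if f >= 0]
    if len(real) != len(freqs):
        warnings.warn(
            f"excluded {len(freqs) - len(real)} imaginary mode(s) from scaling",
            stacklevel=2,
        )
    return [f * factor for f in real]


def band_residual(a: Band, b: Band) -> float:
    """Distance between two bands: 0 if their intervals overlap, else the
    gap between the nearest endpoints."""
    return max(a.lo - b.hi, b.lo - a.hi, 0.0)


_LARGE_GAP = 1e9  # effective "match everything possible" skip penalty


def _monotone_match(
    a: list[Band], b: list[Band], tol: float
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Min-cost non-crossing alignment of two sorted band lists.

    Skipping a band costs ``tol`` (so a pair forms whenever its residual
    beats leaving both sides unmatched); pairs whose residual exceeds
    ``tol`` are dissolved afterwards.  ``tol=inf`` forces a maximum
    matching with no dissolution.
    """
    gap_cost = tol if math.isfinite(tol) else _LARGE_GAP
    n, m = len(a), len(b)
    D = np.empty((n + 1, m + 1))
    D[0, :] = np.arange(m + 1) * gap_cost
    D[:, 0] = np.arange(n + 1) * gap_cost
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + band_residual(a[i - 1], b[j - 1]),
                D[i - 1, j] + gap_cost,
                D[i, j - 1] + gap_cost,
            )
    # traceback, preferring a match on ties for a deterministic result
    pairs: list[tuple[int, int, float]] = []
    i, j = n, m
    while i > 0 and j > 0:
        r = band_residual(a[i - 1], b[j - 1])
        if abs(D[i, j] - (D[i - 1, j - 1] + r)) < 1e-9:
            pairs.append((i - 1, j - 1, r))
            i, j = i - 1, j - 1
        elif abs(D[i, j] - (D[i - 1, j] + gap_cost)) < 1e-9:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    if math.isfinite(tol):
        kept = [(i, j, r) for i, j, r in pairs if r <= tol]
    else:
        kept = pairs
    used_a = {i for i, _, _ in kept}
    used_b = {j for _, j, _ in kept}
    return (
        kept,
        [i for i in range(n) if i not in used_a],
        [j for j in range(m) if j not in used_b],
    )


def assign_bands(
    model: BandList, exp: BandList, tol: float = 100.0
) -> AssignmentResult:
    """Match a computed band list to an experimental one.

    ``tol`` (cm⁻¹) bounds the residual a retained pair may have; the
    default 100 cm⁻¹ suits scaled-harmonic vs experimental comparisons.
    Absent (``present=False``) bands are ignored on both sides.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    a, b = model.present_bands, exp.present_bands
    kept, un_a, un_b = _monotone_match(a, b, tol)
    return AssignmentResult(
        pairs=tuple((a[i], b[j], r) for i, j, r in kept),
        unmatched_model=tuple(a[i] for i in un_a),
        unmatched_exp=tuple(b[j] for j in un_b),
        model_source=model.source,
        exp_source=exp.source,
    )


def model_error(
    ar: AssignmentResult, include_intervals: bool = False
) -> ModelScore:
    """MAD and RMSD of a model over its matched bands.

    By default only single-valued pairs enter the statistics; interval
    pairs can be opted in, in which case their overlap/endpoint residual
    is used.
    """
    res = [
        r
        for mb, eb, r in ar.pairs
        if include_intervals or (not mb.is_interval and not eb.is_interval)
    ]
    if not res:
        raise ValueError("no matched band pairs to score")
    arr = np.asarray(res)
    return ModelScore(
        model=ar.model_source,
        mad=float(np.mean(np.abs(arr))),
        rmsd=float(np.sqrt(np.mean(arr**2))),
        n_matched=len(res),
    )


def rank_models(scores: Sequence[ModelScore]) -> list[ModelScore]:
    """Order models best-first: ascending MAD, ties by RMSD then tag."""
    if not scores:
        raise ValueError("rank_models requires at least one score")
    return sorted(scores, key=lambda s: (s.mad, s.rmsd, s.model))


def estimate_scale(
    calc: Sequence[float], exp: Sequence[float]
) -> float:
    """Least-squares scale factor (slope through the origin) of exp vs calc.

    The estimator is Σ(calc·exp)/Σ(calc²) over paired lists of equal
    length ≥ 2; scaling ``calc`` by c scales the estimate by 1/c.
    """
    c = np.asarray(calc, dtype=float)
    e = np.asarray(exp, dtype=float)
    if c.shape != e.shape:
        raise ValueError(f"length mismatch: {c.size} calc vs {e.size} exp")
    if c.size < 2:
        raise ValueError("at least two paired frequencies required")
    denom = float(c @ c)
    if denom == 0:
        raise ValueError("all calculated frequencies are zero")
    return float(c @ e) / denom


def diff_bands(a: BandList, b: BandList, tol: float = 50.0) -> BandDiff:
    """Compare two experimental band lists (e.g. pristine vs composite).

    Bands of ``b`` unmatched within ``tol`` are *new*, bands of ``a``
    unmatched are *lost*, and every matched pair reports its signed shift
    b − a (band centers for intervals).  The default 50 cm⁻¹ is tight
    enough to isolate a genuinely new band from an ordinary red/blue
    shift of a neighbouring one.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    la, lb = a.present_bands, b.present_bands
    kept, un_a, un_b = _monotone_match(la, lb, tol)
    shifted = tuple(
        (la[i], lb[j], lb[j].center - la[i].center) for i, j, _ in kept
    )
    return BandDiff(
        new=tuple(lb[j] for j in un_b),
        lost=tuple(la[i] for i in un_a),
        shifted=shifted,
    )


# -- CSV interchange --------------------------------------------------------


def bands_to_frame(bl: BandList) -> pd.DataFrame:
    """Band list as a DataFrame with columns lo, hi, assignment, present."""
    return pd.DataFrame(
        {
            "lo": [b.lo for b in bl.bands],
            "hi": [b.hi for b in bl.bands],
            "assignment": [b.assignment for b in bl.bands],
            "present": [b.present for b in bl.bands],
        }
    )


def bands_from_frame(df: pd.DataFrame, source: str = "") -> BandList:
    """Inverse of :func:`bands_to_frame`; hi and present are optional."""
    bands = []
    for _, row in df.iterrows():
        hi = row.get("hi")
        bands.append(
            Band(
                lo=float(row["lo"]),
                hi=None if pd.isna(hi) else float(hi),
                assignment=str(row.get("assignment", "") or ""),
                present=bool(row.get("present", True)),
            )
        )
    return BandList(bands=tuple(bands), source=source)
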