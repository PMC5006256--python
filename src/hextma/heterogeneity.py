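"""Spatial-entropy heterogeneity scoring of the tiled labeling-index field.

Intratumoral heterogeneity of marker expression is summarized per case by
Haralick entropy of a gray-level co-occurrence matrix built over the
hexagonal tiling: local LI values of informative tiles are quantized into
``levels`` equal-width bins on [0, 1], every unordered pair of adjacent
informative tiles (6-neighborhood on the hex lattice) contributes
symmetrically, and entropy is −Σ p·log p (natural log) over the normalized
matrix.  A cohort is then dichotomized at the median entropy into
homogeneous (≤ median) and heterogeneous (> median) halves.

The quantization (8 bins), neighborhood (adjacent hexagons) and log base
are package choices exposed as parameters; entropy values are internally
consistent but not numerically comparable across different settings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .hexgrid import NEIGHBOR_OFFSETS, STATUS_INFORMATIVE, TilingResult

__all__ = [
    "CooccurrenceMatrix",
    "HeterogeneityProfile",
    "NoTextureSupportError",
    "HOMOGENEOUS",
    "HETEROGENEOUS",
    "cooccurrence",
    "haralick_entropy",
    "entropy_profile",
    "dichotomize",
]

HOMOGENEOUS = "homogeneous"
HETEROGENEOUS = "heterogeneous"
UNASSIGNED = "unassigned"


class NoTextureSupportError(ValueError):
    """Raised when a tiling has no adjacent pair of informative tiles."""


@dataclass(frozen=True)
class CooccurrenceMatrix:
    """Symmetric, normalized co-occurrence matrix over LI bins."""

    levels: int
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (self.levels, self.levels):
            raise ValueError("matrix shape must be (levels, levels)")
        if (m < 0).any():
            raise ValueError("co-occurrence weights must be nonnegative")
        object.__setattr__(self, "matrix", m)


@dataclass
class HeterogeneityProfile:
    case_id: str
    entropy: float
    het_class: str = UNASSIGNED


def quantize_li(li: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width bin index on [0, 1]; LI = 1 folds into the top bin."""
    b = np.floor(np.asarray(li, dtype=float) * levels).astype(np.int64)
    return np.clip(b, 0, levels - 1)


def cooccurrence(tiling: TilingResult, levels: int = 8) -> CooccurrenceMatrix:
    """Co-occurrence matrix of quantized local LI over adjacent informative tiles.

    Each unordered pair of informative tiles at hex-lattice distance 1
    contributes one count to cell (bᵢ, bⱼ) and one to (bⱼ, bᵢ); the matrix
    is normalized to sum 1.

    Raises
    ------
    NoTextureSupportError
        If no two informative tiles are adjacent.
    """
    if levels < 2:
        raise ValueError("levels must be ≥ 2")
    info = tiling.tiles[tiling.tiles["status"] == STATUS_INFORMATIVE]
    bins = quantize_li(info["local_li"].to_numpy(), levels)
    index = {(int(q), int(r)): b for q, r, b in zip(info["q"], info["r"], bins)}

    m = np.zeros((levels, levels), dtype=float)
    # half of the 6-neighborhood so each unordered pair is visited once
    for dq, dr in NEIGHBOR_OFFSETS[:3]:
        for (q, r), bi in index.items():
            bj = index.get((q + dq, r + dr))
            if bj is not None:
                m[bi, bj] += 1.0
                m[bj, bi] += 1.0
    total = m.sum()
    if total == 0:
        raise NoTextureSupportError(
            f"case {tiling.case_id}: no adjacent informative tiles (no texture support)"
        )
    return CooccurrenceMatrix(levels=levels, matrix=m / total)


def haralick_entropy(m: CooccurrenceMatrix) -> float:
    """Haralick entropy −Σ p·ln p of a normalized co-occurrence matrix.

    Zero cells contribute nothing; the result lies in [0, ln(levels²)].
    """
    p = m.matrix
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"co-occurrence matrix is not normalized (sum = {total})")
    nz = p[p > 0]
    return float(max(0.0, -(nz * np.log(nz)).sum()))


def entropy_profile(tiling: TilingResult, levels: int = 8) -> HeterogeneityProfile:
    """Entropy score for one case (class left unassigned)."""
    return HeterogeneityProfile(
        case_id=tiling.case_id,
        entropy=haralick_entropy(cooccurrence(tiling, levels=levels)),
    )


def dichotomize(
    profiles: Sequence[HeterogeneityProfile],
) -> list[HeterogeneityProfile]:
    """Split a cohort at the median entropy.

    Cases with entropy ≤ median are labeled homogeneous, the rest
    heterogeneous; ties at the median therefore fall on the homogeneous
    side, so the two halves differ in size by at most the number of ties.
    """
    if len(profiles) < 2:
        raise ValueError("dichotomization needs at least 2 cases")
    ent = np.array([p.entropy for p in profiles], dtype=float)
    if not np.isfinite(ent).all():
        raise ValueError("all entropies must be finite")
    med = float(np.median(ent))
    return [
        replace_class(p, HOMOGENEOUS if p.entropy <= med else HETEROGENEOUS)
        for p in profiles
    ]


def replace_class(p: HeterogeneityProfile, het_class: str) -> HeterogeneityProfile:
    return HeterogeneityProfile(case_id=p.case_id, entropy=p.entropy, het_class=het_class)


def profiles_frame(profiles: Iterable[HeterogeneityProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"case_id": p.case_id, "entropy": p.entropy, "het_class": p.het_class}
         for p in profiles]
    )
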