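"""Synthetic tumor generator: DIA-like nuclei point data with known truth.

No public dataset of per-nucleus DIA exports exists for the Ki67 sampling
problem, so this module fabricates cases with controlled ground truth:
nucleus positions follow a homogeneous planar Poisson process at a chosen
density over a rectangular (or polygonal) region, and each nucleus is
positive with probability given by a spatial field

* ``constant`` — p(x, y) = target LI everywhere (a homogeneous tumor; the
  positive count in any window is exactly binomial, giving closed-form
  error oracles);
* ``patchy``   — p(x, y) = target LI + amplitude · f(x, y), where f is a
  smooth zero-mean mixture of seeded random cosine waves with wavelength ≈
  ``patch_scale``, scaled to unit variance and clipped to [−1, 1] (a
  heterogeneous tumor with patches at a controllable spatial scale).

Defaults emulate a desk-scale invasive tumor region: 8 × 8 mm, 1,500
nuclei/mm² (≈ 660 nuclei per default hexagon, comfortably above the
100-nucleus informativeness filter), patch scale 1.5 mm (about two hexagon
pitches, so heterogeneity is visible at the tile scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .hexgrid import TumorCase

__all__ = [
    "SyntheticSpec",
    "generate_case",
    "generate_cohort",
    "binomial_ce_oracle",
]

DEFAULT_REGION_MM = (8.0, 8.0)
DEFAULT_DENSITY = 1500.0  # nuclei per mm²
DEFAULT_PATCH_SCALE_MM = 1.5
#: patchy amplitude as a fraction of the largest admissible value
DEFAULT_AMPLITUDE_FACTOR = 0.8
_N_WAVES = 6


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative parameters for one simulated tumor.

    ``region`` is either a (width_mm, height_mm) rectangle or a shapely
    polygon in mm.  ``amplitude`` must stay below min(target_li,
    1 − target_li) so positivity probabilities remain inside (0, 1) after
    the clipped field is applied.
    """

    case_id: str
    target_li: float
    region: tuple[float, float] | BaseGeometry = DEFAULT_REGION_MM
    density: float = DEFAULT_DENSITY
    field: str = "constant"
    patch_scale: float = DEFAULT_PATCH_SCALE_MM
    amplitude: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be nonempty")
        if not 0.0 < self.target_li < 1.0:
            raise ValueError("target_li must lie in (0, 1)")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.field not in ("constant", "patchy"):
            raise ValueError(f"unknown field type {self.field!r}")
        if self.field == "patchy":
            if self.patch_scale <= 0:
                raise ValueError("patch_scale must be positive")
            limit = min(self.target_li, 1.0 - self.target_li)
            if not 0.0 <= self.amplitude < limit:
                raise ValueError(
                    f"amplitude must lie in [0, {limit:.3f}) for target_li "
                    f"{self.target_li}"
                )

    @property
    def geometry(self) -> BaseGeometry:
        if isinstance(self.region, BaseGeometry):
            return self.region
        w, h = self.region
        return shapely.box(0.0, 0.0, float(w), float(h))

    @property
    def area_mm2(self) -> float:
        return float(self.geometry.area)


class _CosineField:
    """Smooth zero-mean random field: unit-variance sum of cosine waves.

    f(x, y) = (Σₖ cos(kₖ·x + φₖ)) / sqrt(K/2) with |kₖ| = 2π/λ and random
    directions and phases; each cosine has variance 1/2, so the sum scaled
    by sqrt(K/2) has variance 1.  Values are clipped to [−1, 1] when
    evaluated, which makes strong fields saturate into plateau-like patches.
    """

    def __init__(self, wavelength_mm: float, rng: np.random.Generator,
                 n_waves: int = _N_WAVES) -> None:
        k = 2.0 * math.pi / wavelength_mm
        theta = rng.uniform(0.0, 2.0 * math.pi, n_waves)
        self.kx = k * np.cos(theta)
        self.ky = k * np.sin(theta)
        self.phase = rng.uniform(0.0, 2.0 * math.pi, n_waves)
        self.scale = 1.0 / math.sqrt(n_waves / 2.0)

    def __call__(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        arg = (
            np.multiply.outer(x_mm, self.kx)
            + np.multiply.outer(y_mm, self.ky)
            + self.phase
        )
        return np.clip(np.cos(arg).sum(axis=-1) * self.scale, -1.0, 1.0)


def generate_case(spec: SyntheticSpec) -> TumorCase:
    """Realize one synthetic case (coordinates in µm).

    Nucleus count ~ Poisson(density × area); positions uniform over the
    region (rejection sampling from the bounding box for polygons); labels
    Bernoulli with the spec's probability field.  Deterministic given
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    n = int(rng.poisson(spec.density * spec.area_mm2))
    x_mm, y_mm = _uniform_points(geom, n, rng)

    if spec.field == "patchy" and spec.amplitude > 0:
        f = _CosineField(spec.patch_scale, rng)
        p = spec.target_li + spec.amplitude * f(x_mm, y_mm)
    else:
        # amplitude-0 patchy degenerates exactly to constant: no field draws
        # are consumed, so the same seed yields identical labels
        p = np.full(n, spec.target_li)
    if n and (p.min() <= 0.0 or p.max() >= 1.0):
        raise AssertionError("positivity probabilities escaped (0, 1)")
    positive = rng.random(n) < p

    nuclei = pd.DataFrame(
        {"x": x_mm * 1000.0, "y": y_mm * 1000.0, "positive": positive}
    )
    roi = shapely.transform(geom, lambda c: c * 1000.0)
    return TumorCase(case_id=spec.case_id, nuclei=nuclei, roi=roi)


def _uniform_points(
    geom: BaseGeometry, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    minx, miny, maxx, maxy = geom.bounds
    if math.isclose(geom.area, (maxx - minx) * (maxy - miny), rel_tol=1e-9):
        x = rng.uniform(minx, maxx, n)
        y = rng.uniform(miny, maxy, n)
        return x, y
    xs, ys = [], []
    need = n
    while need > 0:
        m = max(int(need / max(geom.area / ((maxx - minx) * (maxy - miny)), 1e-6)), need)
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        inside = shapely.covers(geom, shapely.points(cx, cy))
        xs.append(cx[inside][:need])
        ys.append(cy[inside][:need])
        need -= len(xs[-1])
    return np.concatenate(xs), np.concatenate(ys)


def generate_cohort(
    n_cases: int,
    fraction_heterogeneous: float = 0.5,
    li_range: tuple[float, float] = (0.05, 0.60),
    seed: Optional[int] = None,
    region: tuple[float, float] | BaseGeometry = DEFAULT_REGION_MM,
    density: float = DEFAULT_DENSITY,
    patch_scale: float = DEFAULT_PATCH_SCALE_MM,
    amplitude_factor: float = DEFAULT_AMPLITUDE_FACTOR,
    case_prefix: str = "SYN",
) -> tuple[list[TumorCase], pd.DataFrame]:
    """Generate a cohort with recorded ground-truth heterogeneity labels.

    ``round(fraction_heterogeneous × n_cases)`` cases get a patchy field
    (amplitude = ``amplitude_factor`` × the largest admissible amplitude for
    their LI), the rest a constant field; per-case target LI is uniform over
    ``li_range``.  Returns the cases and a manifest DataFrame with columns
    ``case_id``, ``target_li``, ``field``, ``amplitude``, ``seed``.
    """
    if n_cases < 2:
        raise ValueError("a cohort needs at least 2 cases")
    if not 0.0 <= fraction_heterogeneous <= 1.0:
        raise ValueError("fraction_heterogeneous must lie in [0, 1]")
    lo, hi = li_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("li_range must satisfy 0 < lo < hi < 1")
    ss = np.random.SeedSequence(seed)
    master = np.random.default_rng(ss)
    n_het = int(round(fraction_heterogeneous * n_cases))
    kinds = np.array(["patchy"] * n_het + ["constant"] * (n_cases - n_het))
    master.shuffle(kinds)
    lis = master.uniform(lo, hi, n_cases)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_cases)]

    cases, rows = [], []
    width = len(str(n_cases))
    for i, (kind, li, cseed) in enumerate(zip(kinds, lis, child_seeds), start=1):
        amp = amplitude_factor * min(li, 1.0 - li) if kind == "patchy" else 0.0
        spec = SyntheticSpec(
            case_id=f"{case_prefix}{i:0{width}d}",
            target_li=float(li),
            region=region,
            density=density,
            field=str(kind),
            patch_scale=patch_scale,
            amplitude=float(amp),
            seed=cseed,
        )
        cases.append(generate_case(spec))
        rows.append(
            {
                "case_id": spec.case_id,
                "target_li": spec.target_li,
                "field": spec.field,
                "amplitude": spec.amplitude,
                "seed": spec.seed,
            }
        )
    return cases, pd.DataFrame(rows)


def binomial_ce_oracle(p: float, n: int) -> float:
    """Exact CE of an unbiased proportion estimate from n Bernoulli(p) nuclei.

    CE = sd/mean = sqrt(p(1−p)/n)/p = sqrt((1−p)/(n·p)); for small p this is
    the 1/sqrt(count-of-positives) counting rule.  Serves as the
    closed-form oracle for CE_Nuclei on constant-field cases.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1)")
    if n < 1:
        raise ValueError("n must be ≥ 1")
    return math.sqrt((1.0 - p) / (n * p))
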