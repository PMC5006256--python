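"""Monte-Carlo virtual-TMA subsampling and coefficient-of-error analysis.

For each case, subsets of ``hexn`` informative hexagons are drawn uniformly
without replacement (all hexagons are returned to the pool before the next
subset).  Each subset yields an LI estimate by one of three estimators:

* ``sum``  — pooled counts, Σpos / (Σpos + Σneg) over the subset's tiles;
* ``mean`` — unweighted mean of the tiles' local LIs;
* ``median`` — median of the tiles' local LIs (midpoint convention).

From the sampling distribution of the estimates the coefficient of error is

    CE = sqrt((mu − T)² + sigma²) / T,

with ``T`` the whole-region reference LI, ``mu``/``sigma`` the mean and
standard deviation of the estimates.  CE indexed by the number of cores is
``CE_Area``; pooling all subsets across core counts and binning them by the
number of nuclei they contain (250-nuclei half-open bins [0,250), [250,500),
…) gives ``CE_Nuclei`` as a function of cell count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .hexgrid import TilingResult

__all__ = [
    "ESTIMATORS",
    "SamplingConfig",
    "coefficient_of_error",
    "estimate_li",
    "draw_subset_estimates",
    "run_error_analysis",
    "ce_by_nuclei",
    "single_subsample",
    "cohort_mean_ce",
]

ESTIMATORS = ("sum", "mean", "median")

#: chunk size (random numbers) for memory-bounded subset drawing
_CHUNK_BUDGET = 4_000_000


@dataclass(frozen=True)
class SamplingConfig:
    """Parameters of the resampling experiment.

    Defaults follow the reference protocol: core counts 1–15, 50,000
    subsets per core count, all three estimators, 250-nuclei bins.  Tests
    and desk-scale runs reduce ``iterations`` (≥ 2,000 keeps Monte-Carlo
    error small relative to the quantities compared).
    """

    hexn_values: tuple[int, ...] = tuple(range(1, 16))
    iterations: int = 50_000
    estimators: tuple[str, ...] = ESTIMATORS
    nuclei_bin_width: int = 250
    seed: Optional[int] = None
    include_insufficient: bool = False

    def __post_init__(self) -> None:
        hv = tuple(int(h) for h in self.hexn_values)
        if not hv or any(h <= 0 for h in hv) or any(
            b <= a for a, b in zip(hv, hv[1:])
        ):
            raise ValueError("hexn_values must be positive and strictly increasing")
        object.__setattr__(self, "hexn_values", hv)
        if self.iterations < 1:
            raise ValueError("iterations must be ≥ 1")
        if self.nuclei_bin_width < 1:
            raise ValueError("nuclei_bin_width must be ≥ 1")
        bad = set(self.estimators) - set(ESTIMATORS)
        if bad:
            raise ValueError(f"unknown estimators: {sorted(bad)}")


def coefficient_of_error(mu: float, sigma: float, T: float) -> float:
    """CE = sqrt((mu − T)² + sigma²) / T; undefined (error) for T = 0."""
    if T <= 0:
        raise ValueError("CE is undefined for reference LI T ≤ 0")
    return float(np.sqrt((mu - T) ** 2 + sigma**2) / T)


def estimate_li(
    n_pos: np.ndarray, n_neg: np.ndarray, estimator: str
) -> float:
    """LI estimate from one subset of tiles.

    ``sum`` pools raw counts; ``mean``/``median`` aggregate the per-tile
    local LIs unweighted — the source of the small-subset bias in
    heterogeneous tissue, since tiles with few nuclei count as much as
    dense ones.
    """
    n_pos = np.asarray(n_pos, dtype=float)
    n_neg = np.asarray(n_neg, dtype=float)
    if n_pos.size == 0:
        raise ValueError("empty subset")
    tot = n_pos + n_neg
    if estimator == "sum":
        denom = tot.sum()
        if denom <= 0:
            raise ValueError("sum estimator needs at least one nucleus")
        return float(n_pos.sum() / denom)
    local = n_pos / tot
    if estimator == "mean":
        return float(local.mean())
    if estimator == "median":
        return float(np.median(local))
    raise ValueError(f"unknown estimator {estimator!r}")


def _pool_arrays(tiling: TilingResult, include_insufficient: bool):
    if include_insufficient:
        pool = tiling.tiles[tiling.tiles["status"] != "missing"]
    else:
        pool = tiling.informative
    n_pos = pool["n_pos"].to_numpy(np.int64)
    n_neg = pool["n_neg"].to_numpy(np.int64)
    return n_pos, n_neg


def draw_subset_estimates(
    tiling: TilingResult,
    cfg: SamplingConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw all Monte-Carlo subsets for one case.

    Returns a long DataFrame with columns ``hexn``, ``estimator``,
    ``li_hat``, ``total_nuclei`` — one row per subset × estimator.  Core
    counts exceeding the informative pool are skipped with a warning.
    Fully reproducible from ``cfg.seed`` (or an explicit ``rng``).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_pos, n_neg = _pool_arrays(tiling, cfg.include_insufficient)
    pool = len(n_pos)
    n_tot = n_pos + n_neg
    local = n_pos / np.maximum(n_tot, 1)

    frames = []
    for hexn in cfg.hexn_values:
        if hexn > pool:
            warnings.warn(
                f"case {tiling.case_id}: hexn={hexn} exceeds informative pool "
                f"({pool}); skipped",
                stacklevel=2,
            )
            continue
        li = {est: np.empty(cfg.iterations) for est in cfg.estimators}
        totals = np.empty(cfg.iterations, dtype=np.int64)
        chunk = max(1, _CHUNK_BUDGET // pool)
        done = 0
        while done < cfg.iterations:
            m = min(chunk, cfg.iterations - done)
            idx = _draw_without_replacement(rng, pool, hexn, m)
            sel_pos = n_pos[idx]
            sel_tot = n_tot[idx]
            totals[done : done + m] = sel_tot.sum(axis=1)
            if "sum" in cfg.estimators:
                li["sum"][done : done + m] = sel_pos.sum(axis=1) / sel_tot.sum(axis=1)
            if "mean" in cfg.estimators:
                li["mean"][done : done + m] = local[idx].mean(axis=1)
            if "median" in cfg.estimators:
                li["median"][done : done + m] = np.median(local[idx], axis=1)
            done += m
        for est in cfg.estimators:
            frames.append(
                pd.DataFrame(
                    {
                        "hexn": hexn,
                        "estimator": est,
                        "li_hat": li[est],
                        "total_nuclei": totals,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(columns=["hexn", "estimator", "li_hat", "total_nuclei"])
    return pd.concat(frames, ignore_index=True)


def _draw_without_replacement(
    rng: np.random.Generator, pool: int, k: int, n_subsets: int
) -> np.ndarray:
    """(n_subsets, k) index array; each row a uniform k-subset of range(pool)."""
    if k == pool:
        return np.tile(np.arange(pool), (n_subsets, 1))
    u = rng.random((n_subsets, pool))
    return np.argpartition(u, k - 1, axis=1)[:, :k]


def _exact_std(v: pd.Series) -> float:
    # degenerate distributions must give exactly 0 (exhaustive-subset case)
    arr = v.to_numpy()
    if np.ptp(arr) == 0:
        return 0.0
    return float(np.std(arr))


def _summarize(df: pd.DataFrame, T: float, key: str) -> pd.DataFrame:
    g = df.groupby([key, "estimator"], sort=True)["li_hat"]
    out = g.agg(mu="mean", sigma=_exact_std, n_subsets="size")
    out = out.reset_index()
    out["T"] = T
    out["ce"] = np.sqrt((out["mu"] - T) ** 2 + out["sigma"] ** 2) / T
    return out


def run_error_analysis(
    tiling: TilingResult,
    cfg: SamplingConfig,
    rng: Optional[np.random.Generator] = None,
    estimates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-(hexn, estimator) error summary for one case (``CE_Area``).

    Columns: ``hexn``, ``estimator``, ``mu``, ``sigma``, ``T``, ``ce``,
    ``n_subsets``, ``case_id``.  ``sigma`` is the population (ddof = 0)
    standard deviation of the subset estimates, matching the exhaustive
    enumeration limit.
    """
    if not tiling.eligible:
        raise ValueError(f"case {tiling.case_id} is not eligible (too few informative tiles)")
    if tiling.T <= 0:
        raise ValueError(f"case {tiling.case_id}: reference LI T = 0, CE undefined")
    if estimates is None:
        estimates = draw_subset_estimates(tiling, cfg, rng=rng)
    out = _summarize(estimates, tiling.T, "hexn")
    out.insert(0, "case_id", tiling.case_id)
    return out


def ce_by_nuclei(
    estimates: pd.DataFrame,
    T: float,
    bin_width: int = 250,
    case_id: Optional[str] = None,
) -> pd.DataFrame:
    """``CE_Nuclei``: error summary binned by nuclei counted per subset.

    ``estimates`` are the pooled subsets across all core counts for one
    case.  Bin k is the half-open interval [k·w, (k+1)·w), labeled by its
    lower edge (``bin_low``); bins with fewer than 2 subsets are flagged
    ``unstable`` (sigma is degenerate there).
    """
    if T <= 0:
        raise ValueError("CE is undefined for reference LI T ≤ 0")
    df = estimates.copy()
    df["nuclei_bin"] = (df["total_nuclei"] // bin_width).astype(np.int64)
    out = _summarize(df, T, "nuclei_bin")
    out["bin_low"] = out["nuclei_bin"] * bin_width
    out["bin_high"] = out["bin_low"] + bin_width
    out["unstable"] = out["n_subsets"] < 2
    if case_id is not None:
        out.insert(0, "case_id", case_id)
    return out


def single_subsample(
    tilings: Sequence[TilingResult],
    hexn: int,
    estimator: str = "sum",
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """One random draw per case — the 'physical TMA, punched once' scenario.

    Returns a regression-ready table of (case_id, li_hat, T).  Cases that
    are ineligible or whose pool is smaller than ``hexn`` are excluded and
    reported via warning.
    """
    rng = np.random.default_rng(seed)
    rows, excluded = [], []
    for t in tilings:
        n_pos, n_neg = _pool_arrays(t, include_insufficient=False)
        if not t.eligible or len(n_pos) < hexn:
            excluded.append(t.case_id)
            continue
        idx = rng.choice(len(n_pos), size=hexn, replace=False)
        rows.append(
            {
                "case_id": t.case_id,
                "li_hat": estimate_li(n_pos[idx], n_neg[idx], estimator),
                "T": t.T,
            }
        )
    if excluded:
        warnings.warn(f"excluded ineligible/undersized cases: {excluded}", stacklevel=2)
    return pd.DataFrame(rows, columns=["case_id", "li_hat", "T"])


def cohort_mean_ce(
    summaries: pd.DataFrame,
    het_class: Optional[Mapping[str, str]] = None,
    key: str = "hexn",
) -> pd.DataFrame:
    """Mean CE curves over cases, per heterogeneity group.

    ``summaries`` concatenates per-case error summaries (must contain
    ``case_id``, ``estimator``, ``ce`` and the ``key`` column).  The mean is
    unweighted over cases.  Groups: ``all`` always; plus each label in
    ``het_class`` (case_id → class).  Empty groups are omitted with a
    warning.
    """
    frames = []

    def _mean(df: pd.DataFrame, group: str) -> pd.DataFrame:
        m = (
            df.groupby([key, "estimator"], sort=True)
            .agg(mean_ce=("ce", "mean"), n_cases=("case_id", "nunique"))
            .reset_index()
        )
        m.insert(0, "group", group)
        return m

    frames.append(_mean(summaries, "all"))
    if het_class is not None:
        labels = sorted(set(het_class.values()))
        for lab in labels:
            ids = {c for c, v in het_class.items() if v == lab}
            sub = summaries[summaries["case_id"].isin(ids)]
            if sub.empty:
                warnings.warn(f"heterogeneity group {lab!r} is empty; omitted",
                              stacklevel=2)
                continue
            frames.append(_mean(sub, lab))
    return pd.concat(frames, ignore_index=True)
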