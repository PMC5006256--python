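"""End-to-end run: synth/ingest → tile → entropy → simulate → fit → report.

A :class:`RunConfig` drives the whole experiment from one global seed.  The
seed spawns independent per-stage substreams (synthesis, grid placement,
resampling, single subsampling), so adding or re-running a stage never
perturbs the draws of another, and a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hexgrid import HexGridSpec, TilingResult, TumorCase, build_tiling
from .heterogeneity import dichotomize, entropy_profile, profiles_frame
from .io import config_hash, read_nuclei, read_roi, write_csv, write_nuclei, write_tiles
from .fits import cohort_regression, fit_power_law, required_sampling
from .sampler import (
    SamplingConfig,
    ce_by_nuclei,
    cohort_mean_ce,
    draw_subset_estimates,
    run_error_analysis,
    single_subsample,
)
from .synthetic import generate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("hextma")

#: exit-style status codes for a pipeline run
STATUS_OK = "ok"
STATUS_NO_ELIGIBLE_CASES = "no_eligible_cases"


@dataclass
class RunConfig:
    """Everything needed to reproduce a full experiment."""

    out_dir: str = "hextma_run"
    seed: int = 0

    # input: either a nuclei CSV ...
    nuclei_path: Optional[str] = None
    roi_path: Optional[str] = None
    units: str = "um"
    pixel_size: float = 0.5

    # ... or a synthetic cohort
    synth_n_cases: Optional[int] = None
    synth_fraction_heterogeneous: float = 0.5
    synth_li_range: tuple[float, float] = (0.05, 0.60)
    synth_region_mm: tuple[float, float] = (8.0, 8.0)
    synth_density: float = 1500.0

    # grid
    circumradius_um: float = 412.5
    orientation: str = "flat_top"
    min_nuclei: int = 100
    min_informative_tiles: int = 30

    # entropy
    entropy_levels: int = 8

    # sampling
    hexn_values: tuple[int, ...] = tuple(range(1, 16))
    iterations: int = 50_000
    estimators: tuple[str, ...] = ("sum", "mean", "median")
    nuclei_bin_width: int = 250

    # reporting
    target_ce: float = 0.10
    regression_hexn: Optional[Sequence[int]] = None  # default: all hexn_values

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("synth_li_range", "synth_region_mm", "hexn_values", "estimators"):
            val = getattr(cfg, name)
            if isinstance(val, list):
                setattr(cfg, name, tuple(val))
        return cfg

    def params(self) -> dict:
        return asdict(self)


@dataclass
class PipelineResult:
    status: str
    out_dir: Path
    files: dict[str, Path] = field(default_factory=dict)
    n_cases: int = 0
    n_eligible: int = 0


def _load_cases(cfg: RunConfig, rng_synth: np.random.Generator) -> tuple[list[TumorCase], Optional[pd.DataFrame]]:
    if cfg.synth_n_cases is not None:
        seed = int(rng_synth.integers(2**31))
        cases, manifest = generate_cohort(
            cfg.synth_n_cases,
            fraction_heterogeneous=cfg.synth_fraction_heterogeneous,
            li_range=cfg.synth_li_range,
            region=cfg.synth_region_mm,
            density=cfg.synth_density,
            seed=seed,
        )
        return cases, manifest
    if cfg.nuclei_path is None:
        raise ValueError("config must set either nuclei_path or synth_n_cases")
    roi = read_roi(cfg.roi_path) if cfg.roi_path else None
    cases = read_nuclei(cfg.nuclei_path, units=cfg.units,
                        pixel_size=cfg.pixel_size, roi=roi)
    return cases, None


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full virtual-TMA experiment and write the report bundle.

    Stages: (1) load or synthesize cases; (2) hexagonal tiling with
    randomized grid placement; (3) entropy scoring and median
    dichotomization of eligible cases; (4) Monte-Carlo error analysis
    (CE_Area per core count, CE_Nuclei per nuclei bin) and mean-CE curves
    per heterogeneity group; (5) single-subsample cohort regressions and
    power-law fits of CE against LI; (6) sampling requirements at the
    target CE.  Every CSV carries the seed and config hash in its header.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash the experiment, not its destination
    chash = config_hash({k: v for k, v in cfg.params().items() if k != "out_dir"})
    meta = {"hextma_version": __version__, "seed": cfg.seed, "config": chash}
    res = PipelineResult(status=STATUS_OK, out_dir=out)

    ss = np.random.SeedSequence(cfg.seed)
    s_synth, s_grid, s_sample, s_single = ss.spawn(4)
    rng_synth = np.random.default_rng(s_synth)
    rng_grid = np.random.default_rng(s_grid)

    log.info("stage synth/ingest")
    try:
        cases, manifest = _load_cases(cfg, rng_synth)
    except Exception as exc:
        raise RuntimeError(f"[ingest] {exc}") from exc
    res.n_cases = len(cases)
    res.files["nuclei"] = write_nuclei(cases, out / "nuclei.csv", meta)
    if manifest is not None:
        res.files["synth_manifest"] = write_csv(manifest, out / "synth_manifest.csv", meta)

    log.info("stage tiling (%d cases)", len(cases))
    tilings: list[TilingResult] = []
    case_rows = []
    for case in cases:
        grid = HexGridSpec(
            circumradius=cfg.circumradius_um,
            orientation=cfg.orientation,
            seed=int(rng_grid.integers(2**31)),
        )
        try:
            t = build_tiling(case, grid, min_nuclei=cfg.min_nuclei,
                             min_informative_tiles=cfg.min_informative_tiles)
        except Exception as exc:
            raise RuntimeError(f"[tiling] case {case.case_id}: {exc}") from exc
        tilings.append(t)
        case_rows.append(
            {
                "case_id": t.case_id,
                "n_nuclei": int(t.tiles["n_pos"].sum() + t.tiles["n_neg"].sum()),
                "T": t.T,
                "n_tiles": len(t.tiles),
                "n_informative": t.n_informative,
                "eligible": t.eligible,
                "grid_seed": t.grid.seed,
            }
        )
    cases_df = pd.DataFrame(case_rows)
    res.files["cases"] = write_csv(cases_df, out / "cases.csv", meta)
    res.files["tiles"] = write_tiles(tilings, out / "tiles.csv", meta)

    eligible = [t for t in tilings if t.eligible]
    res.n_eligible = len(eligible)
    if len(eligible) < 2:
        log.warning("only %d eligible case(s); stopping after eligibility report",
                    len(eligible))
        res.status = STATUS_NO_ELIGIBLE_CASES
        _write_manifest(cfg, res, meta, chash)
        return res

    log.info("stage entropy (%d eligible cases)", len(eligible))
    try:
        profiles = dichotomize(
            [entropy_profile(t, levels=cfg.entropy_levels) for t in eligible]
        )
    except Exception as exc:
        raise RuntimeError(f"[entropy] {exc}") from exc
    ent_df = profiles_frame(profiles)
    ent_df["levels"] = cfg.entropy_levels
    res.files["entropy"] = write_csv(ent_df, out / "entropy.csv", meta)
    het_class = dict(zip(ent_df["case_id"], ent_df["het_class"]))

    log.info("stage simulate (%d iterations × HexN %s)", cfg.iterations,
             list(cfg.hexn_values))
    scfg = SamplingConfig(
        hexn_values=tuple(cfg.hexn_values),
        iterations=cfg.iterations,
        estimators=tuple(cfg.estimators),
        nuclei_bin_width=cfg.nuclei_bin_width,
    )
    rng_sample = np.random.default_rng(s_sample)
    area_frames, nuclei_frames = [], []
    try:
        for t in eligible:
            est = draw_subset_estimates(t, scfg, rng=rng_sample)
            area_frames.append(run_error_analysis(t, scfg, estimates=est))
            nuclei_frames.append(
                ce_by_nuclei(est, t.T, bin_width=cfg.nuclei_bin_width,
                             case_id=t.case_id)
            )
    except Exception as exc:
        raise RuntimeError(f"[simulate] {exc}") from exc
    err_area = pd.concat(area_frames, ignore_index=True)
    err_nuclei = pd.concat(nuclei_frames, ignore_index=True)
    res.files["error_by_hexn"] = write_csv(err_area, out / "error_by_hexn.csv", meta)
    res.files["error_by_nuclei"] = write_csv(err_nuclei, out / "error_by_nuclei.csv", meta)

    mean_area = cohort_mean_ce(err_area, het_class, key="hexn")
    mean_nuclei = cohort_mean_ce(
        err_nuclei[~err_nuclei["unstable"]], het_class, key="bin_low"
    )
    res.files["mean_ce_area"] = write_csv(mean_area, out / "mean_ce_area.csv", meta)
    res.files["mean_ce_nuclei"] = write_csv(mean_nuclei, out / "mean_ce_nuclei.csv", meta)

    log.info("stage fit")
    try:
        reg_df = _regressions(eligible, cfg, het_class, s_single)
        power_area = _power_fits(err_area, cases_df, het_class, key="hexn",
                                 scope="per_hexn")
        power_nuclei = _power_fits(
            err_nuclei[~err_nuclei["unstable"]], cases_df, het_class,
            key="bin_low", scope="per_nuclei_bin",
        )
        req = _requirements(mean_area, mean_nuclei, cfg.target_ce)
    except Exception as exc:
        raise RuntimeError(f"[fit] {exc}") from exc
    res.files["regression"] = write_csv(reg_df, out / "regression.csv", meta)
    res.files["powerlaw_area"] = write_csv(power_area, out / "powerlaw_area.csv", meta)
    res.files["powerlaw_nuclei"] = write_csv(power_nuclei, out / "powerlaw_nuclei.csv", meta)
    res.files["sampling_requirements"] = write_csv(req, out / "sampling_requirements.csv", meta)

    _write_manifest(cfg, res, meta, chash)
    return res


def _regressions(eligible, cfg: RunConfig, het_class, seed_seq) -> pd.DataFrame:
    """Single-subsample OLS per (estimator × hexn × heterogeneity class)."""
    rng = np.random.default_rng(seed_seq)
    hexn_list = list(cfg.regression_hexn or cfg.hexn_values)
    rows = []
    for hexn in hexn_list:
        for est in cfg.estimators:
            pairs = single_subsample(
                eligible, hexn, estimator=est, seed=int(rng.integers(2**31))
            )
            if pairs.empty:
                continue
            pairs["het_class"] = pairs["case_id"].map(het_class)
            groups = {"all": pairs}
            for lab, sub in pairs.groupby("het_class"):
                groups[str(lab)] = sub
            for lab, sub in groups.items():
                if len(sub) < 3 or np.ptp(sub["T"].to_numpy()) == 0:
                    continue
                r = cohort_regression(sub, estimator=est, hexn=hexn, het_class=lab)
                rows.append(
                    {
                        "hexn": hexn, "estimator": est, "het_class": lab,
                        "r2": r.r2, "slope": r.slope, "intercept": r.intercept,
                        "p_value": r.p_value, "n_cases": r.n_cases,
                    }
                )
    return pd.DataFrame(rows)


def _power_fits(err: pd.DataFrame, cases_df: pd.DataFrame, het_class,
                key: str, scope: str) -> pd.DataFrame:
    """CE = a·x⁻ᵇ per (key × estimator × class), x = per-case LI in percent."""
    df = err.merge(cases_df[["case_id"]], on="case_id")
    df["li_percent"] = df["T"] * 100.0
    df["het_class"] = df["case_id"].map(het_class)
    rows = []
    for (k, est), sub in df.groupby([key, "estimator"]):
        groups = {"all": sub}
        for lab, s in sub.groupby("het_class"):
            groups[str(lab)] = s
        for lab, s in groups.items():
            pts = s[(s["li_percent"] > 0) & (s["ce"] > 0)]
            if len(pts) < 3:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f = fit_power_law(pts["li_percent"].to_numpy(),
                                  pts["ce"].to_numpy(),
                                  scope=scope, key=int(k), het_class=lab)
            rows.append(
                {
                    "scope": scope, "key": int(k), "estimator": est,
                    "het_class": lab, "a": f.a, "b": f.b,
                    "n_points": f.n_points, "n_dropped": f.n_dropped,
                }
            )
    return pd.DataFrame(rows)


def _requirements(mean_area, mean_nuclei, target_ce: float) -> pd.DataFrame:
    rows = []
    for scope, df, key in (("cores", mean_area, "hexn"),
                           ("nuclei", mean_nuclei, "bin_low")):
        for (group, est), sub in df.groupby(["group", "estimator"]):
            curve = dict(zip(sub[key], sub["mean_ce"]))
            if scope == "nuclei":  # label bins by midpoint for the curve
                w = np.diff(sorted(curve))  # bin width from the grid
                half = (w.min() / 2.0) if len(w) else 0.0
                curve = {k + half: v for k, v in curve.items()}
            r = required_sampling(curve, target_ce)
            rows.append(
                {
                    "scope": scope, "group": group, "estimator": est,
                    "target_ce": target_ce, "reached": r.reached,
                    "required": r.key, "min_ce": r.min_ce,
                }
            )
    return pd.DataFrame(rows)


def _write_manifest(cfg: RunConfig, res: PipelineResult, meta, chash) -> None:
    manifest = {
        "hextma_version": __version__,
        "status": res.status,
        "seed": cfg.seed,
        "config_hash": chash,
        "parameters": cfg.params(),
        "n_cases": res.n_cases,
        "n_eligible": res.n_eligible,
        "files": {k: str(v) for k, v in res.files.items()},
    }
    path = res.out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    res.files["manifest"] = path
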