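import numpy as np
import pandas as pd
import pytest

from hextma.hexgrid import HexGridSpec, TilingResult


def make_tiling(rows, case_id="TOY", min_nuclei=100, min_informative_tiles=30,
                grid=None):
    """Build a TilingResult directly from (q, r, n_pos, n_neg) rows.

    Lets sampler/heterogeneity tests pin exact tile populations without
    going through point assignment.
    """
    grid = grid or HexGridSpec(origin_offset=(0.0, 0.0))
    df = pd.DataFrame(rows, columns=["q", "r", "n_pos", "n_neg"])
    cx, cy = grid.centers(df["q"].to_numpy(), df["r"].to_numpy())
    df["center_x_um"], df["center_y_um"] = cx, cy
    tot = df["n_pos"] + df["n_neg"]
    df["local_li"] = np.where(tot > 0, df["n_pos"] / tot.replace(0, 1), np.nan)
    status = np.full(len(df), "informative", dtype=object)
    status[(tot > 0) & (tot < min_nuclei)] = "insufficient"
    status[tot == 0] = "missing"
    df["status"] = status
    total = int(tot.sum())
    T = int(df["n_pos"].sum()) / total if total else 0.0
    n_info = int((df["status"] == "informative").sum())
    return TilingResult(
        case_id=case_id, grid=grid,
        tiles=df[["q", "r", "center_x_um", "center_y_um",
                  "n_pos", "n_neg", "local_li", "status"]],
        T=T, eligible=n_info >= min_informative_tiles,
        min_nuclei=min_nuclei, min_informative_tiles=min_informative_tiles,
    )


@pytest.fixture(scope="session")
def constant_tiling():
    """One constant-field synthetic case (LI 0.3, 5×5 mm), tiled."""
    from hextma import HexGridSpec, SyntheticSpec, build_tiling, generate_case

    spec = SyntheticSpec(case_id="CONST", target_li=0.30, region=(5.0, 5.0), seed=101)
    case = generate_case(spec)
    return build_tiling(case, HexGridSpec(seed=17))


@pytest.fixture(scope="session")
def mixed_cohort_tilings():
    """30-case half-patchy cohort on a 5×5 mm region, tiled (seeded)."""
    from hextma import HexGridSpec, build_tiling, generate_cohort

    cases, manifest = generate_cohort(30, region=(5.0, 5.0), seed=303)
    rng = np.random.default_rng(9)
    tilings = [
        build_tiling(c, HexGridSpec(seed=int(rng.integers(2**31)))) for c in cases
    ]
    return tilings, manifest
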