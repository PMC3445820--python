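"""Aggregation of grid results into summary tables plus file output.

The aggregations reproduce the layouts of the published summary tables:
true Prob(X<Y) per distribution pair, per-cell rejection rates, mean
rejection rates by sample size, and the probability that the WMW p-value
is smaller than the Welch p-value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .distpair import FAMILIES, make_pair, prob_x_less_y
from .simulate import (
    GridTable,
    N_GRID,
    SD_RATIO_GRID,
    SKEWNESS_GRID,
    ScenarioResult,
    ScenarioSpec,
)

__all__ = [
    "AggregateRow",
    "mean_rejection_by_n",
    "mean_prop_wmw_smaller_by_n",
    "prob_table",
    "grid_to_frame",
    "write_results",
    "read_results",
]

_CSV_COLUMNS = [
    "family",
    "skewness",
    "sd_ratio",
    "n_per_group",
    "alpha",
    "replications",
    "seed",
    "reject_rate_t",
    "reject_rate_wmw",
    "prop_wmw_smaller",
    "mc_se_t",
    "mc_se_wmw",
    "mc_se_prop",
]


@dataclass(frozen=True)
class AggregateRow:
    """One summary-table row: a label plus a percentage for each sample size."""

    label: str
    values_by_n: dict[int, float]


def _cells_for(grid: GridTable, family: str, n: int) -> list[ScenarioResult]:
    """All (skewness x sd_ratio) cells of one family at one sample size."""
    cells, missing = [], []
    for sk in SKEWNESS_GRID:
        for r in SD_RATIO_GRID:
            key = (family, sk, r, n)
            if key in grid.results:
                cells.append(grid.results[key])
            else:
                missing.append(key)
    if missing:
        raise ValueError(f"grid is missing {len(missing)} cells: {missing[:5]}...")
    return cells


def mean_rejection_by_n(
    grid: GridTable, family: str, test: str, n_values: Sequence[int] = N_GRID
) -> AggregateRow:
    """Unweighted mean rejection rate (%) over the 32 skewness x ratio cells.

    ``test`` is ``"welch_t"`` or ``"wmw"``.
    """
    if test not in ("welch_t", "wmw"):
        raise ValueError(f"unknown test {test!r}")
    attr = "reject_rate_t" if test == "welch_t" else "reject_rate_wmw"
    values = {
        n: 100.0 * sum(getattr(c, attr) for c in _cells_for(grid, family, n)) / 32.0
        for n in n_values
    }
    return AggregateRow(label=f"{family}/{test}", values_by_n=values)


def mean_prop_wmw_smaller_by_n(
    grid: GridTable, family: str, n_values: Sequence[int] = N_GRID
) -> AggregateRow:
    """Mean probability (%) that the WMW p-value is below the Welch p-value."""
    values = {
        n: 100.0 * sum(c.prop_wmw_smaller for c in _cells_for(grid, family, n)) / 32.0
        for n in n_values
    }
    return AggregateRow(label=family, values_by_n=values)


def prob_table(
    families: Sequence[str] = FAMILIES,
    skewness_values: Sequence[float] = SKEWNESS_GRID,
    sd_ratios: Sequence[float] = SD_RATIO_GRID,
) -> pd.DataFrame:
    """True Prob(X<Y) for every (family, skewness, sd_ratio) combination.

    Full-precision values; round to 2 decimals for display.
    """
    rows = [
        {
            "family": fam,
            "skewness": sk,
            "sd_ratio": r,
            "prob_x_less_y": prob_x_less_y(make_pair(fam, sk, r)),
        }
        for fam in families
        for sk in skewness_values
        for r in sd_ratios
    ]
    return pd.DataFrame(rows)


def grid_to_frame(grid: GridTable) -> pd.DataFrame:
    """Flatten a GridTable to one row per scenario cell (full precision)."""
    rows = []
    for res in grid:
        row = asdict(res.spec)
        row.update(
            reject_rate_t=res.reject_rate_t,
            reject_rate_wmw=res.reject_rate_wmw,
            prop_wmw_smaller=res.prop_wmw_smaller,
            mc_se_t=res.mc_se_t,
            mc_se_wmw=res.mc_se_wmw,
            mc_se_prop=res.mc_se_prop,
        )
        rows.append(row)
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    return frame.sort_values(["family", "skewness", "sd_ratio", "n_per_group"]).reset_index(
        drop=True
    )


def write_results(grid: GridTable, path, fmt: str = "csv") -> Path:
    """Write a GridTable to CSV or JSON; values round-trip losslessly.

    CSV: one header row then one row per cell (columns documented in the
    README). JSON: a list of objects each carrying the full ScenarioSpec
    including its seed.
    """
    path = Path(path)
    frame = grid_to_frame(grid)
    try:
        if fmt == "csv":
            frame.to_csv(path, index=False, float_format="%.17g")
        elif fmt == "json":
            path.write_text(json.dumps(frame.to_dict(orient="records"), indent=1))
        else:
            raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    except OSError as exc:
        raise OSError(f"failed to write results to {path}: {exc}") from exc
    return path


def read_results(path, fmt: str = "csv") -> GridTable:
    """Read back a GridTable written by :func:`write_results`."""
    path = Path(path)
    if fmt == "csv":
        # round_trip parsing: the default fast parser can be off by 1 ulp
        frame = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "json":
        frame = pd.DataFrame(json.loads(path.read_text()), columns=_CSV_COLUMNS)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
    table = GridTable()
    for row in frame.to_dict(orient="records"):
        spec = ScenarioSpec(
            family=row["family"],
            skewness=float(row["skewness"]),
            sd_ratio=float(row["sd_ratio"]),
            n_per_group=int(row["n_per_group"]),
            alpha=float(row["alpha"]),
            replications=int(row["replications"]),
            seed=int(row["seed"]),
        )
        table.add(
            ScenarioResult(
                spec=spec,
                reject_rate_t=float(row["reject_rate_t"]),
                reject_rate_wmw=float(row["reject_rate_wmw"]),
                prop_wmw_smaller=float(row["prop_wmw_smaller"]),
                mc_se_t=float(row["mc_se_t"]),
                mc_se_wmw=float(row["mc_se_wmw"]),
                mc_se_prop=float(row["mc_se_prop"]),
            )
        )
    return table
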