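"""Surface-roughness (Ra) statistics from AFM line profiles.

Ra, the arithmetic mean deviation of a roughness profile, is the mean
absolute deviation of sampled heights from the profile mean:

    Ra = (1/n) * sum_i |z_i - mean(z)|

One cell contributes several short line scans (typically three or four
500-nm lines); the cell's Ra is the unweighted mean of its line Ra values.
Strains are compared on per-cell Ra with a two-sided two-sample t-test
using pooled standard deviations.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoughnessLine",
    "CellRoughness",
    "GroupComparison",
    "compute_ra",
    "cell_ra",
    "cells_from_lines",
    "compare_groups",
    "read_roughness_tsv",
    "cells_to_frame",
    "comparison_to_frame",
]


@dataclass(frozen=True)
class RoughnessLine:
    """Ordered height samples (nm) along one scan line of one cell."""

    cell_id: str
    heights: tuple[float, ...]
    line_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        if len(self.heights) < 2:
            raise ValueError(
                f"line {self.line_id!r} of cell {self.cell_id!r}: need >= 2 samples"
            )


@dataclass(frozen=True)
class CellRoughness:
    cell_id: str
    line_ra: tuple[float, ...]
    ra: float
    group: str = ""


@dataclass(frozen=True)
class GroupComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t_statistic: float
    df: int
    p_value: float


def compute_ra(heights: Sequence[float], detrend: bool = False) -> float:
    """Arithmetic mean deviation of a height profile, in the profile's units.

    With ``detrend=True`` a least-squares line is removed first (for tilted
    scans); the default reference is the profile mean.
    """
    z = np.asarray(heights, dtype=float)
    if z.size < 2:
        raise ValueError("need >= 2 height samples")
    if detrend:
        x = np.arange(z.size)
        slope, intercept = np.polyfit(x, z, 1)
        z = z - (slope * x + intercept)
    return float(np.abs(z - z.mean()).mean())


def cell_ra(lines: Sequence[RoughnessLine], detrend: bool = False) -> CellRoughness:
    """Per-cell Ra: unweighted mean of the per-line Ra values."""
    if not lines:
        raise ValueError("no lines for cell")
    cell_ids = {ln.cell_id for ln in lines}
    if len(cell_ids) != 1:
        raise ValueError(f"lines from multiple cells: {sorted(cell_ids)}")
    ras = tuple(compute_ra(ln.heights, detrend) for ln in lines)
    return CellRoughness(
        cell_id=lines[0].cell_id,
        line_ra=ras,
        ra=float(np.mean(ras)),
        group=lines[0].group,
    )


def cells_from_lines(
    lines: Iterable[RoughnessLine], detrend: bool = False
) -> list[CellRoughness]:
    by_cell: dict[str, list[RoughnessLine]] = defaultdict(list)
    for ln in lines:
        by_cell[ln.cell_id].append(ln)
    return [cell_ra(v, detrend) for _, v in sorted(by_cell.items())]


def compare_groups(
    a: Sequence[CellRoughness],
    b: Sequence[CellRoughness],
    label_a: str = "group_a",
    label_b: str = "group_b",
) -> GroupComparison:
    """Two-sided pooled-SD t-test on per-cell Ra values.

    Degenerate input (zero variance in both groups with equal means)
    returns t = 0, p = 1 by convention.
    """
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 cells")
    xa = np.array([c.ra for c in a])
    xb = np.array([c.ra for c in b])
    df = xa.size + xb.size - 2
    if xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean():
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_ind(xa, xb, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=xa.size,
        n_b=xb.size,
        mean_a=float(xa.mean()),
        sd_a=float(xa.std(ddof=1)),
        mean_b=float(xb.mean()),
        sd_b=float(xb.std(ddof=1)),
        t_statistic=t_stat,
        df=df,
        p_value=p,
    )


def read_roughness_tsv(path: str | Path) -> list[RoughnessLine]:
    """Read line profiles from TSV (cell_id, line_id, sample_index, height_nm).

    An optional ``group`` column labels strains; samples are ordered by
    ``sample_index`` within each line.
    """
    table = pd.read_csv(str(path), sep="\t")
    required = {"cell_id", "line_id", "sample_index", "height_nm"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    has_group = "group" in table.columns
    lines: list[RoughnessLine] = []
    for (cell, line), sub in table.groupby(["cell_id", "line_id"], sort=True):
        sub = sub.sort_values("sample_index")
        group = str(sub["group"].iloc[0]) if has_group else ""
        lines.append(
            RoughnessLine(
                cell_id=str(cell),
                line_id=str(line),
                heights=tuple(float(h) for h in sub["height_nm"]),
                group=group,
            )
        )
    return lines


def cells_to_frame(cells: Sequence[CellRoughness]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "group": [c.group for c in cells],
            "n_lines": [len(c.line_ra) for c in cells],
            "ra_nm": [c.ra for c in cells],
        }
    )


def comparison_to_frame(cmp: GroupComparison) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group_a": cmp.label_a,
                "group_b": cmp.label_b,
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
                "mean_ra_a": cmp.mean_a,
                "sd_ra_a": cmp.sd_a,
                "mean_ra_b": cmp.mean_b,
                "sd_ra_b": cmp.sd_b,
                "t_statistic": cmp.t_statistic,
                "df": cmp.df,
                "p_value": cmp.p_value,
            }
        ]
    )
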