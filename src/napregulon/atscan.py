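"""Windowed AT-content scan of a genome and AT-rich region flagging.

Nucleoid-associated proteins of the H-NS/Lsr2 family preferentially bind
compositionally atypical (AT-rich) DNA inside an otherwise GC-rich
chromosome.  The landscape of that bias is summarized by tiling each contig
with fixed-width windows (default 500 bp, 500-bp step) and recording the AT
fraction of each.  N bases are excluded from the denominator so that masked
regions do not bias the statistic; a window that is all N has no defined AT
fraction and is excluded from summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Genome

__all__ = [
    "ATWindow",
    "compute_at_windows",
    "at_rich_threshold",
    "at_rich_regions",
    "windows_to_frame",
    "write_windows_tsv",
    "write_bedgraph",
]


@dataclass(frozen=True)
class ATWindow:
    """AT fraction of one genomic window (0-based half-open coordinates).

    ``at_fraction`` is NaN when the window contains only N bases.
    """

    contig: str
    start: int
    end: int
    at_fraction: float
    n_count: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.at_fraction)


def _base_masks(seq: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    is_n = arr == ord("N")
    return is_at, is_n


def compute_at_windows(
    genome: Genome, window: int = 500, step: int = 500
) -> list[ATWindow]:
    """Tile each contig from offset 0 and compute per-window AT fractions.

    A trailing fragment shorter than ``window`` is dropped, so every window
    has equal width and the per-window statistic is comparable genome-wide.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    out: list[ATWindow] = []
    for contig, seq in genome.contigs.items():
        if len(seq) < window:
            continue
        is_at, is_n = _base_masks(seq)
        cum_at = np.concatenate([[0], np.cumsum(is_at)])
        cum_n = np.concatenate([[0], np.cumsum(is_n)])
        starts = np.arange(0, len(seq) - window + 1, step)
        at = cum_at[starts + window] - cum_at[starts]
        nn = cum_n[starts + window] - cum_n[starts]
        denom = window - nn
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(denom > 0, at / np.maximum(denom, 1), np.nan)
        for s, f, n in zip(starts, frac, nn):
            out.append(
                ATWindow(
                    contig=contig,
                    start=int(s),
                    end=int(s) + window,
                    at_fraction=float(f),
                    n_count=int(n),
                )
            )
    return out


def at_rich_threshold(windows: Sequence[ATWindow], n_sd: float = 2.0) -> float:
    """Default AT-rich cutoff: mean window AT plus ``n_sd`` standard deviations.

    The cutoff is a documented default of this pipeline, not a literature
    constant; it adapts to the genome's baseline composition.
    """
    vals = np.array([w.at_fraction for w in windows if w.defined])
    if vals.size == 0:
        raise ValueError("no windows with a defined AT fraction")
    return float(vals.mean() + n_sd * vals.std(ddof=0))


def at_rich_regions(
    windows: Sequence[ATWindow], threshold: float
) -> list[tuple[str, int, int]]:
    """Merge maximal runs of consecutive windows with AT fraction >= threshold.

    Returns ``(contig, start, end)`` intervals; overlapping qualifying
    windows (step < window) merge into one region.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    regions: list[tuple[str, int, int]] = []
    run: list[ATWindow] | None = None
    prev: ATWindow | None = None
    for w in windows:
        qualifies = w.defined and w.at_fraction >= threshold
        contiguous = (
            run is not None
            and prev is not None
            and w.contig == prev.contig
            and w.start <= prev.end  # adjacent or overlapping tiles
        )
        if qualifies:
            if run is not None and contiguous:
                run.append(w)
            else:
                if run:
                    regions.append((run[0].contig, run[0].start, run[-1].end))
                run = [w]
            prev = w
        else:
            if run:
                regions.append((run[0].contig, run[0].start, run[-1].end))
            run = None
            prev = w
    if run:
        regions.append((run[0].contig, run[0].start, run[-1].end))
    return regions


def windows_to_frame(windows: Sequence[ATWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "contig": [w.contig for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "at_fraction": [w.at_fraction for w in windows],
            "n_count": [w.n_count for w in windows],
        }
    )


def write_windows_tsv(windows: Sequence[ATWindow], path: str | Path) -> None:
    windows_to_frame(windows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_bedgraph(windows: Sequence[ATWindow], path: str | Path) -> None:
    """Write defined windows as a bedGraph track (AT fraction as the value)."""
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="AT_fraction"\n')
        for w in windows:
            if w.defined:
                fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{w.at_fraction:.6g}\n")
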