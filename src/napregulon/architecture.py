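"""Binding-site architecture relative to gene models, and spacing statistics.

Each ChIP binding site is reduced to a single reference point (its interval
midpoint by default) and classified against the annotation:

* ``intragenic`` — the point lies inside a gene body;
* ``intergenic_tandem`` — the flanking genes share a strand;
* ``intergenic_convergent`` — flanks point toward the site (``+ . -``);
* ``intergenic_divergent`` — flanks point away from the site (``- . +``);
* ``terminal`` — only one flank exists (contig end).

Nearest-neighbor spacing between sites, summarized by quartiles, bounds how
many genes a bridging nucleoid-associated protein could loop together: an
interquartile spacing range divided by the average gene length gives a
min–max bridged-gene estimate.
"""

from __future__ import annotations

import bisect
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import Gene, Peak
from ._stats import round_half_away

__all__ = [
    "CATEGORIES",
    "PeakContext",
    "SpacingSummary",
    "GeneIndex",
    "classify_peak",
    "classify_peaks",
    "architecture_fractions",
    "nearest_peak_distances",
    "quartiles",
    "bridged_gene_range",
    "spacing_summary",
    "contexts_to_frame",
]

CATEGORIES = (
    "intragenic",
    "intergenic_tandem",
    "intergenic_convergent",
    "intergenic_divergent",
    "terminal",
)

AVG_GENE_LENGTH_BP = 946  # average M. smegmatis gene length (mycobrowser)


class ClassificationError(ValueError):
    """A peak could not be classified (e.g. its contig has no annotation)."""


@dataclass(frozen=True)
class PeakContext:
    """Architecture call for one peak.

    ``containing_gene_id`` is set for intragenic peaks; ``left_gene_id`` /
    ``right_gene_id`` are the flanks for intergenic and terminal peaks.
    """

    peak_id: str
    category: str
    left_gene_id: str | None = None
    right_gene_id: str | None = None
    containing_gene_id: str | None = None


@dataclass(frozen=True)
class SpacingSummary:
    """Pooled nearest-neighbor distances and the bridged-gene estimate."""

    distances: tuple[int, ...]
    q1: float
    median: float
    q3: float
    min_genes: int
    max_genes: int


class GeneIndex:
    """Per-contig lookup structures for containment and flank queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        by_contig: dict[str, list[Gene]] = defaultdict(list)
        self.by_id: dict[str, Gene] = {}
        for g in genes:
            self.trees[g.contig].addi(g.start, g.end, g)
            by_contig[g.contig].append(g)
            self.by_id[g.gene_id] = g
        # flank lookups: genes sorted by end (left flank) and by start (right)
        self._by_end: dict[str, tuple[list[int], list[Gene]]] = {}
        self._by_start: dict[str, tuple[list[int], list[Gene]]] = {}
        for contig, gl in by_contig.items():
            ge = sorted(gl, key=lambda g: (g.end, g.start))
            gs = sorted(gl, key=lambda g: (g.start, g.end))
            self._by_end[contig] = ([g.end for g in ge], ge)
            self._by_start[contig] = ([g.start for g in gs], gs)

    def containing(self, contig: str, pos: int) -> Gene | None:
        hits = [iv.data for iv in self.trees[contig].at(pos)]
        if not hits:
            return None
        return min(hits, key=lambda g: (g.start, g.end, g.gene_id))

    def left_of(self, contig: str, pos: int) -> Gene | None:
        """Gene with the greatest end <= pos."""
        ends, genes = self._by_end[contig]
        i = bisect.bisect_right(ends, pos)
        return genes[i - 1] if i > 0 else None

    def right_of(self, contig: str, pos: int) -> Gene | None:
        """Gene with the smallest start > pos."""
        starts, genes = self._by_start[contig]
        i = bisect.bisect_right(starts, pos)
        return genes[i] if i < len(genes) else None


def _reference_point(peak: Peak, position: str) -> int:
    if position == "midpoint":
        return peak.midpoint
    if position == "start":
        return peak.start
    if position == "end":
        return peak.end - 1
    raise ValueError(f"unknown position {position!r}")


def classify_peak(
    peak: Peak,
    annotation: Sequence[Gene] | GeneIndex,
    position: str = "midpoint",
    containment: str = "point",
) -> PeakContext:
    """Classify one peak against the annotation.

    ``containment='point'`` calls a peak intragenic when its reference point
    lies inside a gene; ``'overlap'`` calls it intragenic when the peak
    interval overlaps any gene by >= 1 bp.  Ties (overlapping genes) go to
    the containing gene with the smallest start.
    """
    index = annotation if isinstance(annotation, GeneIndex) else GeneIndex(annotation)
    if peak.contig not in index.trees or not index.trees[peak.contig]:
        raise ClassificationError(
            f"peak {peak.peak_id!r}: no annotated genes on contig {peak.contig!r}"
        )
    point = _reference_point(peak, position)

    if containment == "point":
        inside = index.containing(peak.contig, point)
    elif containment == "overlap":
        hits = [iv.data for iv in index.trees[peak.contig].overlap(peak.start, peak.end)]
        inside = min(hits, key=lambda g: (g.start, g.end, g.gene_id)) if hits else None
    else:
        raise ValueError(f"unknown containment mode {containment!r}")

    if inside is not None:
        return PeakContext(
            peak_id=peak.peak_id, category="intragenic",
            containing_gene_id=inside.gene_id,
        )

    left = index.left_of(peak.contig, point)
    right = index.right_of(peak.contig, point)
    if left is None or right is None:
        flank = left or right
        assert flank is not None  # contig has >= 1 gene and point is outside all
        return PeakContext(
            peak_id=peak.peak_id,
            category="terminal",
            left_gene_id=left.gene_id if left else None,
            right_gene_id=right.gene_id if right else None,
        )
    pair = (left.strand, right.strand)
    if pair in (("+", "+"), ("-", "-")):
        category = "intergenic_tandem"
    elif pair == ("+", "-"):
        category = "intergenic_convergent"
    else:
        category = "intergenic_divergent"
    return PeakContext(
        peak_id=peak.peak_id,
        category=category,
        left_gene_id=left.gene_id,
        right_gene_id=right.gene_id,
    )


def classify_peaks(
    peaks: Iterable[Peak],
    annotation: Sequence[Gene] | GeneIndex,
    position: str = "midpoint",
    containment: str = "point",
) -> list[PeakContext]:
    index = annotation if isinstance(annotation, GeneIndex) else GeneIndex(annotation)
    return [classify_peak(p, index, position, containment) for p in peaks]


def architecture_fractions(contexts: Sequence[PeakContext]) -> pd.DataFrame:
    """Tabulate category counts and integer percentages (all categories listed)."""
    if not contexts:
        raise ValueError("no peak contexts to summarize")
    counts = Counter(c.category for c in contexts)
    total = len(contexts)
    rows = [
        {
            "category": cat,
            "count": counts.get(cat, 0),
            "percent": round_half_away(100.0 * counts.get(cat, 0) / total),
        }
        for cat in CATEGORIES
    ]
    return pd.DataFrame(rows)


def nearest_peak_distances(
    peaks: Sequence[Peak],
    position: str = "midpoint",
    circular: bool = False,
    contig_lengths: dict[str, int] | None = None,
) -> list[int]:
    """Each peak's distance to its nearest neighbor on the same contig, pooled.

    Distances are point-to-point (midpoint by default).  Contigs with a
    single peak contribute nothing; if no contig has two peaks, an error is
    raised.  With ``circular=True`` (requires ``contig_lengths``) the first
    and last peaks on a contig are also neighbors across the origin.
    """
    if circular and contig_lengths is None:
        raise ValueError("circular mode requires contig_lengths")
    by_contig: dict[str, list[int]] = defaultdict(list)
    for p in peaks:
        by_contig[p.contig].append(_reference_point(p, position))
    distances: list[int] = []
    for contig, points in by_contig.items():
        if len(points) < 2:
            continue
        points.sort()
        wrap = contig_lengths[contig] - points[-1] + points[0] if circular else None
        for i, m in enumerate(points):
            candidates = []
            if i > 0:
                candidates.append(m - points[i - 1])
            if i < len(points) - 1:
                candidates.append(points[i + 1] - m)
            if wrap is not None and (i == 0 or i == len(points) - 1):
                candidates.append(wrap)
            distances.append(min(candidates))
    if not distances:
        raise ValueError("need at least two peaks on some contig")
    return distances


def quartiles(values: Sequence[float], method: str = "hinges") -> tuple[float, float, float]:
    """Quartiles of a sample.

    ``method='hinges'`` (default) uses Tukey hinges: the median splits the
    sorted data into halves that, for odd n, both include the median; Q1/Q3
    are the medians of those halves.  This matches the verbal definition
    "the middle number between the smallest number and the median".
    ``method='linear'`` uses linear interpolation between order statistics
    (numpy's default quantile estimator).
    """
    if len(values) == 0:
        raise ValueError("quartiles of an empty collection")
    data = np.sort(np.asarray(values, dtype=float))
    n = data.size
    med = float(np.median(data))
    if method == "hinges":
        half = n // 2
        lower = data[: half + (n % 2)]  # include median for odd n
        upper = data[half:]
        return float(np.median(lower)), med, float(np.median(upper))
    if method == "linear":
        q1, q3 = np.quantile(data, [0.25, 0.75])
        return float(q1), med, float(q3)
    raise ValueError(f"unknown quartile method {method!r}")


def bridged_gene_range(
    q1: float, q3: float, avg_gene_len: float = AVG_GENE_LENGTH_BP
) -> tuple[int, int]:
    """Bound how many average-length genes fit in the interquartile spacing.

    ``min_genes = floor(q1/avg_gene_len)``, ``max_genes = floor(q3/avg_gene_len)``.
    """
    if q1 <= 0 or q3 <= 0 or avg_gene_len <= 0:
        raise ValueError("q1, q3 and avg_gene_len must be positive")
    if q1 > q3:
        raise ValueError(f"q1 must be <= q3, got {q1} > {q3}")
    return int(q1 // avg_gene_len), int(q3 // avg_gene_len)


def spacing_summary(
    peaks: Sequence[Peak],
    position: str = "midpoint",
    method: str = "hinges",
    avg_gene_len: float = AVG_GENE_LENGTH_BP,
) -> SpacingSummary:
    """Nearest-neighbor spacing quartiles plus the bridged-gene estimate."""
    distances = nearest_peak_distances(peaks, position)
    q1, med, q3 = quartiles(distances, method)
    if q1 > 0:
        min_genes, max_genes = bridged_gene_range(q1, q3, avg_gene_len)
    else:
        min_genes = max_genes = 0
    return SpacingSummary(
        distances=tuple(distances),
        q1=q1,
        median=med,
        q3=q3,
        min_genes=min_genes,
        max_genes=max_genes,
    )


def contexts_to_frame(contexts: Sequence[PeakContext]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [c.peak_id for c in contexts],
            "category": [c.category for c in contexts],
            "containing_gene_id": [c.containing_gene_id or "" for c in contexts],
            "left_gene_id": [c.left_gene_id or "" for c in contexts],
            "right_gene_id": [c.right_gene_id or "" for c in contexts],
        }
    )
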