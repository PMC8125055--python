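"""Regulon calling from differential expression and direct-target assignment.

The regulon of a nucleoid-associated protein (NAP) is defined from a
deletion-mutant vs wild-type comparison: genes whose |log2 fold change|
strictly exceeds a threshold (default log2(3) = 1.585, i.e. at least a
3-fold change) and whose adjusted p-value passes a configurable cutoff.

Directionality is encoded from the NAP's perspective: a gene that goes UP
in the deletion mutant is *repressed_by_nap*, one that goes DOWN is
*activated_by_nap*.  The same facts are rendered both ways in summaries
(the fraction activated by the NAP equals the fraction with decreased
transcription in the mutant) because both phrasings occur in reports.

A regulated gene is a *direct* target when a ChIP binding site overlaps its
putative promoter region — the strand-aware window covering the given
number of bp (default 150) upstream of the start codon — by at least 1 bp;
otherwise it is *indirect*.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._stats import percentage
from .io import DERecord, Gene, Peak

__all__ = [
    "REPRESSED",
    "ACTIVATED",
    "RegulonEntry",
    "Regulon",
    "RegulonComparison",
    "call_regulon",
    "lfc_threshold_for_fold",
    "promoter_window",
    "assign_direct_targets",
    "regulon_summary",
    "compare_regulons",
    "regulon_to_frame",
]

REPRESSED = "repressed_by_nap"  # higher expression in the deletion mutant
ACTIVATED = "activated_by_nap"  # lower expression in the deletion mutant

DEFAULT_LFC_THRESHOLD = 1.585  # log2(3): at least a 3-fold change
DEFAULT_UPSTREAM_BP = 150


@dataclass(frozen=True)
class RegulonEntry:
    gene_id: str
    log2fc: float
    direction: str
    mode: str | None = None  # 'direct' / 'indirect'; None before assignment
    supporting_peaks: tuple[str, ...] = ()


@dataclass(frozen=True)
class Regulon:
    condition: str
    entries: tuple[RegulonEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.gene_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate gene ids in regulon {self.condition!r}")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.gene_ids

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(e.gene_id for e in self.entries)

    def direct_entries(self) -> list[RegulonEntry]:
        return [e for e in self.entries if e.mode == "direct"]


@dataclass(frozen=True)
class RegulonComparison:
    shared: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]

    @property
    def n_shared(self) -> int:
        return len(self.shared)

    @property
    def n_unique_a(self) -> int:
        return len(self.unique_a)

    @property
    def n_unique_b(self) -> int:
        return len(self.unique_b)


def lfc_threshold_for_fold(fold: float) -> float:
    """log2 of a fold change, rounded to 3 decimals for reporting (3 -> 1.585)."""
    if fold <= 0:
        raise ValueError(f"fold must be positive, got {fold}")
    return round(math.log2(fold), 3)


def call_regulon(
    de_records: Iterable[DERecord],
    condition: str,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    p_threshold: float | None = 0.05,
) -> Regulon:
    """Select regulated genes for one condition.

    Membership requires |log2fc| strictly greater than ``lfc_threshold``
    and, unless ``p_threshold`` is None, adj_p <= ``p_threshold``.  The
    threshold is strict because the fold-change rule is "greater than".
    """
    relevant = [r for r in de_records if r.condition == condition]
    if not relevant:
        raise ValueError(f"no DE records for condition {condition!r}")
    entries = []
    for r in relevant:
        if abs(r.log2fc) <= lfc_threshold:
            continue
        if p_threshold is not None and r.adj_p > p_threshold:
            continue
        direction = REPRESSED if r.log2fc > 0 else ACTIVATED
        entries.append(RegulonEntry(gene_id=r.gene_id, log2fc=r.log2fc, direction=direction))
    entries.sort(key=lambda e: e.gene_id)
    return Regulon(condition=condition, entries=tuple(entries))


def promoter_window(
    gene: Gene,
    upstream: int = DEFAULT_UPSTREAM_BP,
    contig_length: int | None = None,
) -> tuple[int, int]:
    """Strand-aware upstream window adjacent to the start codon, half-open.

    For a '+' gene the window is ``[start-upstream, start)``; for a '-'
    gene the start codon sits at the high-coordinate end, so the window is
    ``[end, end+upstream)``.  The window is clipped to the contig and may
    be empty for a gene at the contig edge.
    """
    if upstream < 1:
        raise ValueError(f"upstream must be >= 1, got {upstream}")
    if gene.strand == "+":
        return max(0, gene.start - upstream), gene.start
    end = gene.end + upstream
    if contig_length is not None:
        end = min(end, contig_length)
    return gene.end, end


def assign_direct_targets(
    regulon: Regulon,
    peaks: Sequence[Peak],
    annotation: Sequence[Gene] | Mapping[str, Gene],
    upstream: int = DEFAULT_UPSTREAM_BP,
    contig_lengths: Mapping[str, int] | None = None,
) -> Regulon:
    """Fill each entry's mode from promoter-window/peak overlap.

    A gene is direct iff >= 1 peak interval overlaps its promoter window by
    >= 1 bp; all such peak ids are recorded.  Membership never changes.
    """
    genes = (
        dict(annotation)
        if isinstance(annotation, Mapping)
        else {g.gene_id: g for g in annotation}
    )
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in peaks:
        trees[p.contig].addi(p.start, p.end, p.peak_id)
    new_entries = []
    for entry in regulon.entries:
        gene = genes.get(entry.gene_id)
        if gene is None:
            raise KeyError(f"regulon gene {entry.gene_id!r} missing from annotation")
        clen = contig_lengths.get(gene.contig) if contig_lengths else None
        wstart, wend = promoter_window(gene, upstream, clen)
        if wstart < wend:
            hits = sorted(iv.data for iv in trees[gene.contig].overlap(wstart, wend))
        else:
            hits = []
        new_entries.append(
            replace(
                entry,
                mode="direct" if hits else "indirect",
                supporting_peaks=tuple(hits),
            )
        )
    return Regulon(condition=regulon.condition, entries=tuple(new_entries))


def regulon_summary(regulon: Regulon) -> dict[str, int]:
    """Counts and integer percentages describing one regulon.

    Percentages round half away from zero.  ``pct_activated`` and
    ``pct_with_decreased_transcription_in_mutant`` are the same quantity
    phrased from the NAP's and the mutant's perspective respectively.
    """
    n = len(regulon)
    n_rep = sum(1 for e in regulon.entries if e.direction == REPRESSED)
    n_act = n - n_rep
    direct = regulon.direct_entries()
    n_direct = len(direct)
    n_direct_rep = sum(1 for e in direct if e.direction == REPRESSED)
    return {
        "n_total": n,
        "n_repressed": n_rep,
        "n_activated": n_act,
        "pct_activated": percentage(n_act, n),
        "pct_with_decreased_transcription_in_mutant": percentage(n_act, n),
        "n_direct": n_direct,
        "n_direct_repressed": n_direct_rep,
        "n_direct_activated": n_direct - n_direct_rep,
    }


def compare_regulons(a: Regulon, b: Regulon) -> RegulonComparison:
    """Exact set comparison of two regulons on gene ids."""
    ids_a, ids_b = a.gene_ids, b.gene_ids
    return RegulonComparison(
        shared=frozenset(ids_a & ids_b),
        unique_a=frozenset(ids_a - ids_b),
        unique_b=frozenset(ids_b - ids_a),
    )


def regulon_to_frame(regulon: Regulon) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in regulon.entries],
            "condition": regulon.condition,
            "log2fc": [e.log2fc for e in regulon.entries],
            "direction": [e.direction for e in regulon.entries],
            "mode": [e.mode or "" for e in regulon.entries],
            "supporting_peaks": [";".join(e.supporting_peaks) for e in regulon.entries],
        }
    )
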