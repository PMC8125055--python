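"""Promoter AT-composition statistics.

AT-binding nucleoid proteins are expected to leave a compositional
footprint in the promoters of the genes they regulate.  This module
extracts fixed-length, strand-corrected upstream sequences ("promoters"),
samples a random-promoter background, and compares the two sets' AT
content with a two-sample test plus per-position AT profiles.

Sequences are strand-corrected so that the last position of every promoter
is the base adjacent to the start codon, which makes positional profiles
comparable between strands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .io import Gene, Genome
from .regulon import DEFAULT_UPSTREAM_BP, promoter_window

__all__ = [
    "PromoterSet",
    "ATComparison",
    "at_fraction",
    "extract_promoters",
    "sample_random_promoters",
    "compare_at",
    "comparison_to_frame",
    "profiles_to_frame",
]


def at_fraction(seq: str) -> float:
    """Fraction of A+T among non-N bases of a sequence (NaN if all N)."""
    n = seq.count("N")
    denom = len(seq) - n
    if denom == 0:
        return float("nan")
    return (seq.count("A") + seq.count("T")) / denom


@dataclass(frozen=True)
class PromoterSet:
    """Equal-length, strand-corrected upstream sequences for a set of genes."""

    label: str
    gene_ids: tuple[str, ...]
    sequences: tuple[str, ...]
    upstream: int

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.sequences):
            raise ValueError("gene_ids and sequences must align")
        if any(len(s) != self.upstream for s in self.sequences):
            raise ValueError(f"all sequences must have length {self.upstream}")

    def __len__(self) -> int:
        return len(self.sequences)

    def at_fractions(self) -> np.ndarray:
        return np.array([at_fraction(s) for s in self.sequences])

    def positional_profile(self) -> np.ndarray:
        """Per-position AT frequency across members (position 0 = -upstream)."""
        mat = np.array([list(s) for s in self.sequences])
        return ((mat == "A") | (mat == "T")).mean(axis=0)


@dataclass(frozen=True)
class ATComparison:
    """Result of comparing AT content between two promoter sets."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    mean_at_a: float
    mean_at_b: float
    difference: float  # mean_at_a - mean_at_b
    statistic: float
    p_value: float
    test: str
    positional_profile_a: tuple[float, ...]
    positional_profile_b: tuple[float, ...]


def extract_promoters(
    genes: Iterable[Gene],
    genome: Genome,
    upstream: int = DEFAULT_UPSTREAM_BP,
    label: str = "promoters",
) -> PromoterSet:
    """Strand-aware upstream sequences; genes clipped by a contig edge are dropped.

    '-'-strand promoters are reverse-complemented so position ``upstream-1``
    is always adjacent to the start codon.
    """
    ids: list[str] = []
    seqs: list[str] = []
    dropped: list[str] = []
    for gene in genes:
        if gene.contig not in genome:
            raise KeyError(f"gene {gene.gene_id!r}: contig {gene.contig!r} not in genome")
        wstart, wend = promoter_window(gene, upstream, genome.length(gene.contig))
        if wend - wstart < upstream:
            dropped.append(gene.gene_id)
            continue
        seq = genome.fetch(gene.contig, wstart, wend)
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        ids.append(gene.gene_id)
        seqs.append(seq)
    if dropped:
        warnings.warn(
            f"{len(dropped)} promoter window(s) clipped by a contig edge and "
            f"dropped: {dropped[:5]}{'...' if len(dropped) > 5 else ''}"
        )
    if not ids:
        raise ValueError("all promoter windows were clipped; nothing to extract")
    return PromoterSet(label=label, gene_ids=tuple(ids), sequences=tuple(seqs), upstream=upstream)


def sample_random_promoters(
    annotation: Sequence[Gene],
    genome: Genome,
    n: int = 50,
    seed: int | np.random.Generator | None = None,
    exclude: Iterable[str] = (),
    upstream: int = DEFAULT_UPSTREAM_BP,
    label: str = "random",
) -> PromoterSet:
    """Uniform sample (without replacement) of n gene promoters.

    Genes in ``exclude`` (typically the regulated set, to keep the null
    uncontaminated) and genes whose window would be clipped by a contig
    edge are ineligible.
    """
    excluded = set(exclude)
    eligible = []
    for g in annotation:
        if g.gene_id in excluded:
            continue
        wstart, wend = promoter_window(g, upstream, genome.length(g.contig))
        if wend - wstart == upstream:
            eligible.append(g)
    if len(eligible) < n:
        raise ValueError(
            f"only {len(eligible)} eligible genes after exclusion; need {n}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    chosen = [eligible[i] for i in sorted(idx)]
    return extract_promoters(chosen, genome, upstream, label=label)


def compare_at(
    a: PromoterSet,
    b: PromoterSet,
    test: str = "welch_t",
    n_permutations: int = 10_000,
    seed: int | None = 0,
) -> ATComparison:
    """Two-sided comparison of per-promoter AT fractions between two sets.

    ``welch_t`` (default) and ``pooled_t`` are t-tests on the per-promoter
    fractions; ``permutation`` shuffles set labels (seeded) and uses the
    add-one estimate p = (1 + #as-extreme) / (1 + n_permutations).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both promoter sets must be nonempty")
    if a.upstream != b.upstream:
        raise ValueError(
            f"sequence length mismatch: {a.upstream} vs {b.upstream}"
        )
    fa, fb = a.at_fractions(), b.at_fractions()
    diff = float(fa.mean() - fb.mean())
    if test in ("welch_t", "pooled_t"):
        res = stats.ttest_ind(fa, fb, equal_var=(test == "pooled_t"))
        statistic, p_value = float(res.statistic), float(res.pvalue)
        if np.isnan(statistic):  # identical constant groups
            statistic, p_value = 0.0, 1.0
    elif test == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([fa, fb])
        n_a = len(fa)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            d = perm[:n_a].mean() - perm[n_a:].mean()
            if abs(d) >= abs(diff) - 1e-15:
                count += 1
        statistic = diff
        p_value = (1 + count) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ATComparison(
        label_a=a.label,
        label_b=b.label,
        n_a=len(a),
        n_b=len(b),
        mean_at_a=float(fa.mean()),
        mean_at_b=float(fb.mean()),
        difference=diff,
        statistic=statistic,
        p_value=p_value,
        test=test,
        positional_profile_a=tuple(a.positional_profile()),
        positional_profile_b=tuple(b.positional_profile()),
    )


def comparison_to_frame(cmp: ATComparison) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label_a": cmp.label_a,
                "label_b": cmp.label_b,
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
                "mean_at_a": cmp.mean_at_a,
                "mean_at_b": cmp.mean_at_b,
                "difference": cmp.difference,
                "statistic": cmp.statistic,
                "p_value": cmp.p_value,
                "test": cmp.test,
            }
        ]
    )


def profiles_to_frame(cmp: ATComparison) -> pd.DataFrame:
    """Positional AT profiles indexed -L..-1 relative to the start codon."""
    L = len(cmp.positional_profile_a)
    return pd.DataFrame(
        {
            "position": np.arange(-L, 0),
            f"at_freq_{cmp.label_a}": cmp.positional_profile_a,
            f"at_freq_{cmp.label_b}": cmp.positional_profile_b,
        }
    )
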