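"""Desk-scale synthetic data with the statistical structure the pipeline assumes.

The generators emulate a GC-rich bacterial chromosome (baseline ~67% GC,
as in mycobacteria) carrying planted AT-rich islands, a dense annotation
of non-overlapping genes in mixed orientations (average length 946 bp),
ChIP binding sites planted in promoter windows of the regulated genes plus
AT-biased background sites, differential-expression tables with planted
direct/indirect targets over a small-|log2fc| noise floor, and Gaussian
AFM roughness profiles with group-specific Ra parameters.

Every generator is a pure function of its parameters and seed.  A single
master seed fans out to fixed per-component child seeds, so regenerating
one file never shifts the others.  A machine-readable truth object records
everything needed to score each pipeline stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import DERecord, Gene, Genome, Peak
from .regulon import DEFAULT_UPSTREAM_BP, promoter_window
from .roughness import RoughnessLine

__all__ = [
    "SyntheticTruth",
    "child_seed",
    "generate_genome",
    "generate_annotation",
    "generate_peaks_and_de",
    "generate_roughness",
    "generate_dataset",
]

# fixed fan-out indices: regenerating one component never shifts the others
_COMPONENT = {"genome": 0, "annotation": 1, "peaks_de": 2, "roughness": 3}

# study-condition defaults: one 200-kb contig, 200 genes of mean length 946 bp,
# 30 direct + 10 indirect planted targets, 150 background peaks, Ra groups at
# the wild-type/deletion parameter values 4.68 +/- 1.25 and 3.33 +/- 1.81 nm
DEFAULT_CONTIG_LEN = 200_000
DEFAULT_N_GENES = 200
DEFAULT_MEAN_GENE_LEN = 946
DEFAULT_N_DIRECT = 30
DEFAULT_N_INDIRECT = 10
DEFAULT_N_BACKGROUND = 150
DEFAULT_ROUGHNESS_GROUPS = {
    "wild_type": (4.68, 1.25),
    "nap_deletion": (3.33, 1.81),
}


def child_seed(master_seed: int, component: str) -> int:
    """Deterministic per-component seed derived from the master seed."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(_COMPONENT[component],))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class SyntheticTruth:
    """Ground truth sufficient to score every pipeline stage."""

    master_seed: int | None = None
    islands: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    island_at: float = 0.0
    baseline_gc: float = 0.0
    genes: list[dict] = field(default_factory=list)
    peak_classes: dict[str, str] = field(default_factory=dict)
    peak_target_gene: dict[str, str] = field(default_factory=dict)
    direct_targets: dict[str, float] = field(default_factory=dict)
    indirect_targets: dict[str, float] = field(default_factory=dict)
    noise_lfc_sd: float = 0.0
    condition: str = ""
    roughness_groups: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["islands"] = {
            c: [tuple(iv) for iv in ivs] for c, ivs in data["islands"].items()
        }
        data["roughness_groups"] = {
            g: tuple(v) for g, v in data["roughness_groups"].items()
        }
        return cls(**data)


# ---------------------------------------------------------------------------
# genome


def _draw_bases(rng: np.random.Generator, n: int, at: float) -> np.ndarray:
    probs = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def generate_genome(
    n_contigs: int = 1,
    contig_len: int = DEFAULT_CONTIG_LEN,
    baseline_gc: float = 0.67,
    n_islands: int = 8,
    island_len: int = 3_000,
    island_at: float = 0.65,
    seed: int | None = 0,
) -> tuple[Genome, SyntheticTruth]:
    """I.i.d. bases at the baseline composition with planted AT-rich islands.

    Islands are non-overlapping intervals of elevated AT content; their
    coordinates are recorded in the truth object.
    """
    baseline_at = 1.0 - baseline_gc
    if n_islands > 0 and island_at <= baseline_at:
        raise ValueError(
            f"island AT ({island_at}) must exceed baseline AT ({baseline_at:.2f})"
        )
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    islands: dict[str, list[tuple[int, int]]] = {}
    for c in range(n_contigs):
        name = f"contig_{c + 1}"
        arr = _draw_bases(rng, contig_len, baseline_at)
        placed: list[tuple[int, int]] = []
        for _ in range(n_islands):
            for _attempt in range(1_000):
                start = int(rng.integers(0, contig_len - island_len + 1))
                iv = (start, start + island_len)
                if all(iv[1] <= s or iv[0] >= e for s, e in placed):
                    placed.append(iv)
                    break
            else:
                raise ValueError(
                    f"could not place {n_islands} non-overlapping islands of "
                    f"{island_len} bp in a {contig_len}-bp contig"
                )
        placed.sort()
        for s, e in placed:
            arr[s:e] = _draw_bases(rng, e - s, island_at)
        contigs[name] = arr.tobytes().decode("ascii")
        islands[name] = placed
    genome = Genome(contigs)
    truth = SyntheticTruth(
        islands=islands, island_at=island_at, baseline_gc=baseline_gc
    )
    return genome, truth


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(
    genome: Genome,
    n_genes: int = DEFAULT_N_GENES,
    mean_gene_len: int = DEFAULT_MEAN_GENE_LEN,
    gene_len_sd: float = 250.0,
    min_gene_len: int = 200,
    strand_plus_prob: float = 0.5,
    seed: int | None = 1,
) -> list[Gene]:
    """Pack non-overlapping genes with positive intergenic gaps on each contig.

    Genes are distributed across contigs proportionally to length; lengths
    are Gaussian around ``mean_gene_len`` (clipped at ``min_gene_len``) and
    strands are Bernoulli(``strand_plus_prob``).
    """
    rng = np.random.default_rng(seed)
    lengths_by_contig = genome.lengths()
    total_len = sum(lengths_by_contig.values())
    genes: list[Gene] = []
    counter = 0
    allocated = 0
    items = list(lengths_by_contig.items())
    for k, (contig, clen) in enumerate(items):
        n_here = (
            n_genes - allocated
            if k == len(items) - 1
            else int(round(n_genes * clen / total_len))
        )
        allocated += n_here
        if n_here == 0:
            continue
        gl = np.maximum(
            min_gene_len,
            np.round(rng.normal(mean_gene_len, gene_len_sd, size=n_here)),
        ).astype(int)
        spare = clen - int(gl.sum()) - (n_here + 1)  # every gap >= 1 bp
        if spare < 0:
            raise ValueError(
                f"cannot pack {n_here} genes (total {int(gl.sum())} bp) with "
                f"positive gaps into {clen}-bp contig {contig!r}"
            )
        extra = rng.multinomial(spare, np.full(n_here + 1, 1.0 / (n_here + 1)))
        gaps = 1 + extra
        pos = 0
        for i in range(n_here):
            pos += int(gaps[i])
            counter += 1
            strand = "+" if rng.random() < strand_plus_prob else "-"
            genes.append(
                Gene(
                    contig=contig,
                    start=pos,
                    end=pos + int(gl[i]),
                    gene_id=f"gene_{counter:04d}",
                    strand=strand,
                )
            )
            pos += int(gl[i])
    return genes


# ---------------------------------------------------------------------------
# peaks + DE


def _window_overlaps(iv: tuple[int, int], windows: Sequence[tuple[int, int]]) -> bool:
    return any(iv[0] < e and s < iv[1] for s, e in windows)


def generate_peaks_and_de(
    genome: Genome,
    genes: Sequence[Gene],
    islands: dict[str, list[tuple[int, int]]] | None = None,
    n_direct: int = DEFAULT_N_DIRECT,
    n_indirect: int = DEFAULT_N_INDIRECT,
    n_background_peaks: int = DEFAULT_N_BACKGROUND,
    repressed_fraction: float = 0.9,
    lfc_direct_range: tuple[float, float] = (2.2, 5.0),
    lfc_noise_sd: float = 0.3,
    upstream: int = DEFAULT_UPSTREAM_BP,
    island_bias: float = 0.7,
    intergenic_bias: float = 0.8,
    condition: str = "aerobic",
    seed: int | None = 2,
) -> tuple[list[Peak], list[DERecord], SyntheticTruth]:
    """Plant direct-target peaks and an AT-biased background, plus DE records.

    * Each direct target receives one peak wholly inside its promoter
      window; regulated genes are chosen so their windows are pairwise
      disjoint, keeping planted modes unambiguous.
    * Background peaks are preferentially intergenic (midpoint inside an
      intergenic gap with probability ``intergenic_bias``) and biased
      toward gaps inside AT-rich islands (probability ``island_bias``
      among intergenic draws); they never touch the promoter window of
      any regulated gene.
    * Regulated genes get |log2fc| in ``lfc_direct_range`` (sign: repressed
      with probability ``repressed_fraction``); every other gene gets a
      small Gaussian log2fc truncated well below the regulon threshold.
    """
    n_regulated = n_direct + n_indirect
    if n_regulated > len(genes):
        raise ValueError(
            f"n_direct + n_indirect = {n_regulated} exceeds {len(genes)} genes"
        )
    rng = np.random.default_rng(seed)
    clens = genome.lengths()

    min_peak_w, max_peak_w = 30, 120
    # choose regulated genes with usable, pairwise-disjoint promoter windows
    order = rng.permutation(len(genes))
    chosen: list[Gene] = []
    chosen_windows: dict[str, list[tuple[int, int]]] = {c: [] for c in clens}
    for idx in order:
        g = genes[idx]
        w = promoter_window(g, upstream, clens[g.contig])
        if w[1] - w[0] < min_peak_w:
            continue
        if _window_overlaps(w, chosen_windows[g.contig]):
            continue
        chosen.append(g)
        chosen_windows[g.contig].append(w)
        if len(chosen) == n_regulated:
            break
    if len(chosen) < n_regulated:
        raise ValueError(
            f"only {len(chosen)} genes with disjoint promoter windows; "
            f"need {n_regulated}"
        )
    direct_genes = chosen[:n_direct]
    indirect_genes = chosen[n_direct:]
    protected = {
        c: [promoter_window(g, upstream, clens[g.contig]) for g in chosen if g.contig == c]
        for c in clens
    }

    raw_peaks: list[tuple[str, int, int, str, str]] = []  # contig,start,end,class,target
    for g in direct_genes:
        ws, we = promoter_window(g, upstream, clens[g.contig])
        width = int(rng.integers(min_peak_w, min(max_peak_w, we - ws) + 1))
        start = int(rng.integers(ws, we - width + 1))
        raw_peaks.append((g.contig, start, start + width, "promoter_planted", g.gene_id))

    contig_names = list(clens)
    contig_p = np.array([clens[c] for c in contig_names], dtype=float)
    contig_p /= contig_p.sum()
    # intergenic gaps, flagged when they overlap an AT-rich island
    gaps: list[tuple[str, int, int]] = []
    for c in contig_names:
        bounds = [(g.start, g.end) for g in sorted(genes) if g.contig == c]
        edges = [0] + [x for se in bounds for x in se] + [clens[c]]
        for gs, ge in zip(edges[::2], edges[1::2]):
            if ge - gs >= 2:
                gaps.append((c, gs, ge))
    c_islands = islands or {}
    island_gaps = [
        (c, gs, ge)
        for c, gs, ge in gaps
        if any(gs < e and s < ge for s, e in c_islands.get(c, []))
    ]
    for _ in range(n_background_peaks):
        for _attempt in range(1_000):
            width = int(rng.integers(100, 301))
            use_gap = bool(gaps) and rng.random() < intergenic_bias
            if use_gap:
                use_island = bool(island_gaps) and rng.random() < island_bias
                pool = island_gaps if use_island else gaps
                c, gs, ge = pool[int(rng.integers(len(pool)))]
                mid = int(rng.integers(gs, ge))
                cls = "background_island" if use_island else "background_intergenic"
            else:
                c = contig_names[int(rng.choice(len(contig_names), p=contig_p))]
                mid = int(rng.integers(0, clens[c]))
                cls = "background_uniform"
            start = max(0, mid - width // 2)
            end = min(clens[c], start + width)
            if end - start < 2:
                continue
            iv = (start, end)
            if _window_overlaps(iv, protected[c]):
                continue
            raw_peaks.append((c, iv[0], iv[1], cls, ""))
            break
        else:
            raise ValueError("could not place background peaks under constraints")

    raw_peaks.sort(key=lambda t: (t[0], t[1], t[2]))
    peaks: list[Peak] = []
    peak_classes: dict[str, str] = {}
    peak_target: dict[str, str] = {}
    for i, (c, s, e, cls, target) in enumerate(raw_peaks, start=1):
        pid = f"peak_{i:04d}"
        peaks.append(Peak(contig=c, start=s, end=e, peak_id=pid))
        peak_classes[pid] = cls
        if target:
            peak_target[pid] = target

    # DE records: planted signal for regulated genes, noise floor elsewhere
    regulated_ids = {g.gene_id for g in chosen}
    direct_lfc: dict[str, float] = {}
    indirect_lfc: dict[str, float] = {}
    records: list[DERecord] = []
    for g in genes:
        if g.gene_id in regulated_ids:
            mag = float(rng.uniform(*lfc_direct_range))
            sign = 1.0 if rng.random() < repressed_fraction else -1.0
            lfc = sign * mag
            adj_p = float(10.0 ** rng.uniform(-8, -3))
            if g.gene_id in {x.gene_id for x in direct_genes}:
                direct_lfc[g.gene_id] = lfc
            else:
                indirect_lfc[g.gene_id] = lfc
        else:
            lfc = float(np.clip(rng.normal(0.0, lfc_noise_sd), -1.2, 1.2))
            adj_p = float(rng.uniform(0.0, 1.0))
        records.append(
            DERecord(gene_id=g.gene_id, log2fc=lfc, adj_p=adj_p, condition=condition)
        )

    truth = SyntheticTruth(
        peak_classes=peak_classes,
        peak_target_gene=peak_target,
        direct_targets=direct_lfc,
        indirect_targets=indirect_lfc,
        noise_lfc_sd=lfc_noise_sd,
        condition=condition,
    )
    return peaks, records, truth


# ---------------------------------------------------------------------------
# roughness


def generate_roughness(
    n_cells_per_group: int = 50,
    groups: dict[str, tuple[float, float]] | None = None,
    lines_per_cell: tuple[int, ...] = (3, 4),
    samples_per_line: int = 256,
    seed: int | None = 3,
) -> tuple[list[RoughnessLine], SyntheticTruth]:
    """Gaussian height profiles whose expected line Ra matches per-cell targets.

    Each cell draws a target Ra from its group's (mean, SD); line heights
    are zero-mean Gaussian with sigma = target_Ra / sqrt(2/pi), the sigma
    for which Gaussian noise has expected mean absolute deviation equal to
    the target.
    """
    groups = dict(DEFAULT_ROUGHNESS_GROUPS) if groups is None else groups
    for name, (mean, sd) in groups.items():
        if sd <= 0:
            raise ValueError(f"group {name!r}: SD must be positive")
    rng = np.random.default_rng(seed)
    lines: list[RoughnessLine] = []
    for group, (mean, sd) in groups.items():
        for c in range(1, n_cells_per_group + 1):
            cell_id = f"{group}_cell_{c:03d}"
            target_ra = max(0.05, float(rng.normal(mean, sd)))
            sigma = target_ra / math.sqrt(2.0 / math.pi)
            n_lines = int(rng.choice(lines_per_cell))
            for li in range(1, n_lines + 1):
                heights = rng.normal(0.0, sigma, size=samples_per_line)
                lines.append(
                    RoughnessLine(
                        cell_id=cell_id,
                        line_id=f"line_{li}",
                        heights=tuple(float(h) for h in heights),
                        group=group,
                    )
                )
    truth = SyntheticTruth(roughness_groups={g: tuple(v) for g, v in groups.items()})
    return lines, truth


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(
    outdir: str | Path,
    master_seed: int = 0,
    **overrides,
) -> SyntheticTruth:
    """Generate and write the full synthetic dataset plus its truth file.

    Writes ``genome.fasta``, ``genes.gff3``, ``peaks.bed``,
    ``de_<condition>.tsv``, ``roughness.tsv`` and ``truth.json`` under
    ``outdir``.  ``overrides`` are forwarded to the individual generators
    by parameter name.
    """
    from . import io as nio
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def _kw(func, extra=()):
        import inspect

        names = set(inspect.signature(func).parameters) - {"seed"} - set(extra)
        return {k: v for k, v in overrides.items() if k in names}

    genome, gtruth = generate_genome(
        seed=child_seed(master_seed, "genome"), **_kw(generate_genome)
    )
    genes = generate_annotation(
        genome, seed=child_seed(master_seed, "annotation"),
        **_kw(generate_annotation, extra=("genome",)),
    )
    peaks, de_records, ptruth = generate_peaks_and_de(
        genome, genes, islands=gtruth.islands,
        seed=child_seed(master_seed, "peaks_de"),
        **_kw(generate_peaks_and_de, extra=("genome", "genes", "islands")),
    )
    lines, rtruth = generate_roughness(
        seed=child_seed(master_seed, "roughness"), **_kw(generate_roughness)
    )

    nio.write_fasta(genome, outdir / "genome.fasta")
    nio.write_gff3(genes, outdir / "genes.gff3")
    nio.write_bed(peaks, outdir / "peaks.bed")
    nio.write_de_table(de_records, outdir / f"de_{ptruth.condition}.tsv")
    rows = []
    for ln in lines:
        for i, h in enumerate(ln.heights):
            rows.append((ln.group, ln.cell_id, ln.line_id, i, h))
    pd.DataFrame(
        rows, columns=["group", "cell_id", "line_id", "sample_index", "height_nm"]
    ).to_csv(outdir / "roughness.tsv", sep="\t", index=False, float_format="%.5f")

    truth = SyntheticTruth(
        master_seed=master_seed,
        islands=gtruth.islands,
        island_at=gtruth.island_at,
        baseline_gc=gtruth.baseline_gc,
        genes=[
            {"gene_id": g.gene_id, "contig": g.contig, "start": g.start,
             "end": g.end, "strand": g.strand}
            for g in genes
        ],
        peak_classes=ptruth.peak_classes,
        peak_target_gene=ptruth.peak_target_gene,
        direct_targets=ptruth.direct_targets,
        indirect_targets=ptruth.indirect_targets,
        noise_lfc_sd=ptruth.noise_lfc_sd,
        condition=ptruth.condition,
        roughness_groups=rtruth.roughness_groups,
    )
    truth.to_json(outdir / "truth.json")
    return truth
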