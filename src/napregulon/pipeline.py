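"""Run configuration, replicate-peak intersection, and the full pipeline.

``run_pipeline`` chains every analysis stage on one set of inputs —
AT-content scan, binding-site architecture and spacing, regulon calling
with direct-target assignment, promoter-composition test, and (optionally)
surface roughness and a second-condition regulon comparison — and writes
all summary tables plus a ``manifest.txt`` (key: value) recording the
effective parameters and seeds, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml
from intervaltree import IntervalTree

from . import __version__, atscan, architecture, promoters, regulon as reg, roughness as rough
from .io import (
    Peak,
    read_bed,
    read_de_table,
    read_fasta,
    read_gff3,
    write_bed,
)

__all__ = ["RunConfig", "PipelineError", "intersect_replicate_peaks", "run_pipeline"]

logger = logging.getLogger("napregulon")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """All inputs and tunables for one pipeline run.

    Defaults mirror the analysis constants used throughout the package:
    500-bp AT windows with a 500-bp step, 150-bp promoter windows, a
    |log2FC| > 1.585 (3-fold) regulon rule with adj_p <= 0.05, Tukey-hinge
    quartiles, Welch's t for promoter composition, and n = 50 random
    background promoters.
    """

    genome: str = ""
    annotation: str = ""
    peaks: str = ""
    de_table: str = ""
    condition: str = "aerobic"
    de_table_b: str = ""  # optional second condition for regulon comparison
    condition_b: str = ""
    roughness: str = ""  # optional AFM profile TSV with a 'group' column
    outdir: str = "results"
    window: int = 500
    step: int = 500
    at_rich_sd: float = 2.0
    upstream: int = 150
    lfc_threshold: float = reg.DEFAULT_LFC_THRESHOLD
    p_threshold: float | None = 0.05
    quartile_method: str = "hinges"
    avg_gene_len: float = architecture.AVG_GENE_LENGTH_BP
    peak_position: str = "midpoint"
    containment: str = "point"
    at_test: str = "welch_t"
    n_random_promoters: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def intersect_replicate_peaks(
    a: Sequence[Peak], b: Sequence[Peak], min_overlap: int = 1
) -> list[Peak]:
    """Peaks of ``a`` that overlap some peak of ``b`` by >= ``min_overlap`` bp.

    The reported interval is the overlap region with the best-overlapping
    ``b`` peak (ties: leftmost), keeping ``a``'s ids — the usual way two
    ChIP replicates are reconciled into a reproducible site list.
    """
    if min_overlap < 1:
        raise ValueError(f"min_overlap must be >= 1, got {min_overlap}")
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for p in b:
        trees[p.contig].addi(p.start, p.end, p)
    out: list[Peak] = []
    for p in a:
        best: tuple[int, int, int] | None = None  # (-overlap, start, end)
        for iv in trees[p.contig].overlap(p.start, p.end):
            s, e = max(p.start, iv.begin), min(p.end, iv.end)
            if e - s >= min_overlap:
                cand = (-(e - s), s, e)
                if best is None or cand < best:
                    best = cand
        if best is not None:
            out.append(
                Peak(contig=p.contig, start=best[1], end=best[2],
                     peak_id=p.peak_id, score=p.score)
            )
    return out


def _stage(name: str):
    def deco(func):
        def wrapper(*args, **kwargs):
            try:
                return func(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run every configured stage and write all outputs under ``config.outdir``.

    Returns the report tables keyed by name; deterministic given the
    config (including its seed).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, pd.DataFrame] = {}
    manifest: dict[str, object] = {
        "napregulon_version": __version__,
        **{f"param_{k}": v for k, v in dataclasses.asdict(config).items()},
    }

    logger.info("reading inputs")
    genome = _stage("read_genome")(read_fasta)(config.genome)
    genes = _stage("read_annotation")(read_gff3)(config.annotation)
    peaks = _stage("read_peaks")(read_bed)(config.peaks)
    de_records = _stage("read_de_table")(read_de_table)(config.de_table, config.condition)

    logger.info("AT-content scan (%d-bp windows, %d-bp step)", config.window, config.step)
    windows = _stage("at_scan")(atscan.compute_at_windows)(
        genome, config.window, config.step
    )
    atscan.write_windows_tsv(windows, outdir / "at_windows.tsv")
    atscan.write_bedgraph(windows, outdir / "at_windows.bedgraph")
    threshold = atscan.at_rich_threshold(windows, config.at_rich_sd)
    regions = atscan.at_rich_regions(windows, threshold)
    pd.DataFrame(regions, columns=["contig", "start", "end"]).to_csv(
        outdir / "at_rich_regions.tsv", sep="\t", index=False
    )
    manifest["at_rich_threshold"] = round(threshold, 6)

    logger.info("binding-site architecture (%d peaks)", len(peaks))
    contexts = _stage("classify_peaks")(architecture.classify_peaks)(
        peaks, genes, config.peak_position, config.containment
    )
    architecture.contexts_to_frame(contexts).to_csv(
        outdir / "peak_contexts.tsv", sep="\t", index=False
    )
    fractions = architecture.architecture_fractions(contexts)
    fractions.to_csv(outdir / "architecture_summary.tsv", sep="\t", index=False)
    report["architecture"] = fractions

    spacing = _stage("spacing")(architecture.spacing_summary)(
        peaks, config.peak_position, config.quartile_method, config.avg_gene_len
    )
    pd.DataFrame({"distance_bp": spacing.distances}).to_csv(
        outdir / "nearest_peak_distances.tsv", sep="\t", index=False
    )
    spacing_frame = pd.DataFrame(
        [
            {
                "q1_bp": spacing.q1,
                "median_bp": spacing.median,
                "q3_bp": spacing.q3,
                "min_bridged_genes": spacing.min_genes,
                "max_bridged_genes": spacing.max_genes,
            }
        ]
    )
    spacing_frame.to_csv(outdir / "spacing_summary.tsv", sep="\t", index=False)
    report["spacing"] = spacing_frame

    logger.info("regulon calling (condition %r)", config.condition)
    regulon = _stage("call_regulon")(reg.call_regulon)(
        de_records, config.condition, config.lfc_threshold, config.p_threshold
    )
    regulon = _stage("assign_direct_targets")(reg.assign_direct_targets)(
        regulon, peaks, genes, config.upstream, genome.lengths()
    )
    reg.regulon_to_frame(regulon).to_csv(outdir / "regulon.tsv", sep="\t", index=False)
    summary = pd.DataFrame([reg.regulon_summary(regulon)])
    summary.to_csv(outdir / "regulon_summary.tsv", sep="\t", index=False)
    report["regulon_summary"] = summary

    if config.de_table_b:
        cond_b = config.condition_b or "condition_b"
        de_b = _stage("read_de_table_b")(read_de_table)(config.de_table_b, cond_b)
        regulon_b = _stage("call_regulon_b")(reg.call_regulon)(
            de_b, cond_b, config.lfc_threshold, config.p_threshold
        )
        cmp_ab = reg.compare_regulons(regulon, regulon_b)
        cmp_frame = pd.DataFrame(
            [
                {
                    "condition_a": regulon.condition,
                    "condition_b": regulon_b.condition,
                    "n_a": len(regulon),
                    "n_b": len(regulon_b),
                    "n_shared": cmp_ab.n_shared,
                    "n_unique_a": cmp_ab.n_unique_a,
                    "n_unique_b": cmp_ab.n_unique_b,
                    "shared_genes": ";".join(sorted(cmp_ab.shared)),
                }
            ]
        )
        cmp_frame.to_csv(outdir / "regulon_comparison.tsv", sep="\t", index=False)
        report["regulon_comparison"] = cmp_frame

    logger.info("promoter AT composition")
    gene_index = {g.gene_id: g for g in genes}
    regulated_genes = [gene_index[e.gene_id] for e in regulon.entries]
    if regulated_genes:
        promo = _stage("extract_promoters")(promoters.extract_promoters)(
            regulated_genes, genome, config.upstream, label="regulated"
        )
        background = _stage("sample_random_promoters")(promoters.sample_random_promoters)(
            genes, genome, config.n_random_promoters, config.seed,
            exclude=regulon.gene_ids, upstream=config.upstream,
        )
        comparison = _stage("compare_at")(promoters.compare_at)(
            promo, background, config.at_test, seed=config.seed
        )
        promoters.comparison_to_frame(comparison).to_csv(
            outdir / "promoter_at_comparison.tsv", sep="\t", index=False
        )
        promoters.profiles_to_frame(comparison).to_csv(
            outdir / "promoter_at_profiles.tsv", sep="\t", index=False,
            float_format="%.6g",
        )
        report["promoter_at"] = promoters.comparison_to_frame(comparison)

    if config.roughness:
        logger.info("surface roughness")
        lines = _stage("read_roughness")(rough.read_roughness_tsv)(config.roughness)
        cells = rough.cells_from_lines(lines)
        rough.cells_to_frame(cells).to_csv(
            outdir / "roughness_cells.tsv", sep="\t", index=False, float_format="%.6g"
        )
        groups = sorted({c.group for c in cells})
        if len(groups) == 2:
            ga = [c for c in cells if c.group == groups[0]]
            gb = [c for c in cells if c.group == groups[1]]
            gcmp = _stage("compare_groups")(rough.compare_groups)(
                ga, gb, groups[0], groups[1]
            )
            gframe = rough.comparison_to_frame(gcmp)
            gframe.to_csv(
                outdir / "roughness_comparison.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            report["roughness_comparison"] = gframe

    with open(outdir / "manifest.txt", "w") as fh:
        for key in sorted(manifest):
            fh.write(f"{key}: {manifest[key]}\n")
    logger.info("done; outputs in %s", outdir)
    return report
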