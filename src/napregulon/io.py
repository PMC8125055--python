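"""Readers and writers for the standard formats the pipeline touches.

All coordinates are normalized to a single internal convention — 0-based,
half-open intervals — regardless of the on-disk format:

* FASTA sequences are uppercased on read; only ``A C G T N`` are accepted.
* GFF3 is 1-based inclusive on disk and converted on read (``start-1, end``)
  and reconverted on write.
* BED is already 0-based half-open and passes through unchanged.
* Differential-expression tables are plain TSV with a header
  (``gene_id``, ``log2fc``, ``adj_p``); a column-mapping option adapts
  real-world exports whose columns are named differently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "Genome",
    "Gene",
    "Peak",
    "DERecord",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "read_de_table",
    "write_de_table",
]

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violates its format contract (raised with file/record context)."""


@dataclass
class Genome:
    """An ordered collection of named contig sequences (uppercase A/C/G/T/N)."""

    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise FormatError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise FormatError(
                    f"contig {name!r} contains invalid characters: {sorted(bad)}"
                )

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Slice ``[start, end)`` of a contig (0-based half-open)."""
        return self.contigs[contig][start:end]


@dataclass(frozen=True, order=True)
class Gene:
    """A strand-aware gene interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    gene_id: str
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: need 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, order=True)
class Peak:
    """A ChIP binding-site interval, 0-based half-open, with a defined midpoint."""

    contig: str
    start: int
    end: int
    peak_id: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"peak {self.peak_id!r}: start must be < end, "
                f"got [{self.start}, {self.end})"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression result (mutant vs wild type).

    ``log2fc`` is signed so that positive means higher expression in the
    deletion mutant; ``adj_p`` is the multiple-testing-adjusted p-value.
    """

    gene_id: str
    log2fc: float
    adj_p: float
    condition: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(
                f"gene {self.gene_id!r}: adj_p must be in [0, 1], got {self.adj_p}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences uppercased)."""
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise FormatError(f"{path}: duplicate contig id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: contig {record.id!r} has an empty sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: contig {record.id!r} contains invalid characters: "
                f"{sorted(bad)}"
            )
        contigs[record.id] = seq
    if not contigs:
        raise FormatError(f"{path}: no FASTA records found")
    return Genome(contigs)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.contigs.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str | Path, feature_type: str = "gene") -> list[Gene]:
    """Read ``gene`` features from a GFF3 file, converting to 0-based half-open.

    Features of other types are ignored; an annotation without any gene
    feature triggers a warning and returns an empty list.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
        id_spec="ID",
    )
    genes: list[Gene] = []
    seen: set[str] = set()
    for feat in db.features_of_type(feature_type, order_by="start"):
        gene_id = feat.attributes.get("ID", [None])[0]
        if gene_id is None:
            raise FormatError(f"{path}: feature at {feat.seqid}:{feat.start} lacks ID")
        if gene_id in seen:
            raise FormatError(f"{path}: duplicate gene id {gene_id!r}")
        if feat.end < feat.start:
            raise FormatError(f"{path}: gene {gene_id!r} has end < start")
        if feat.strand not in ("+", "-"):
            raise FormatError(
                f"{path}: gene {gene_id!r} has unknown strand {feat.strand!r}"
            )
        seen.add(gene_id)
        genes.append(
            Gene(
                contig=feat.seqid,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                gene_id=gene_id,
                strand=feat.strand,
            )
        )
    if not genes:
        warnings.warn(f"{path}: no {feature_type!r} features found; empty annotation")
    return genes


def write_gff3(genes: Iterable[Gene], path: str | Path, source: str = "napregulon") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes):
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# BED


def read_bed(path: str | Path) -> list[Peak]:
    """Read a BED3+ file into peaks; ids are auto-assigned if column 4 is absent."""
    try:
        table = pd.read_csv(
            str(path), sep="\t", header=None, comment="#", dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty BED file")
        return []
    if table.shape[1] < 3:
        raise FormatError(f"{path}: BED requires at least 3 columns")
    peaks: list[Peak] = []
    for i, row in enumerate(table.itertuples(index=False), start=1):
        try:
            start, end = int(row[1]), int(row[2])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: non-integer coordinates") from exc
        if start >= end:
            raise FormatError(f"{path}, line {i}: start >= end ({start} >= {end})")
        name = row[3] if len(row) > 3 and pd.notna(row[3]) else f"peak_{i:04d}"
        score = None
        if len(row) > 4 and pd.notna(row[4]) and str(row[4]) != ".":
            score = float(row[4])
        peaks.append(Peak(contig=str(row[0]), start=start, end=end,
                          peak_id=str(name), score=score))
    return peaks


def write_bed(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in sorted(peaks):
            score = "." if p.score is None else f"{p.score:g}"
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\n")


# ---------------------------------------------------------------------------
# Differential-expression tables


def read_de_table(
    path: str | Path,
    condition: str,
    columns: Mapping[str, str] | None = None,
) -> list[DERecord]:
    """Read a TSV of per-gene DE results and label records with ``condition``.

    ``columns`` optionally maps the required names (``gene_id``, ``log2fc``,
    ``adj_p``) onto the file's actual header, adapting other tools' exports.
    """
    table = pd.read_csv(str(path), sep="\t", float_precision="round_trip")
    mapping = {"gene_id": "gene_id", "log2fc": "log2fc", "adj_p": "adj_p"}
    if columns:
        mapping.update(columns)
    missing = [col for col in mapping.values() if col not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    records: list[DERecord] = []
    for i, row in enumerate(table.itertuples(index=False), start=2):
        data = dict(zip(table.columns, row))
        try:
            log2fc = float(data[mapping["log2fc"]])
            adj_p = float(data[mapping["adj_p"]])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}, line {i}: non-numeric log2fc/adj_p") from exc
        records.append(
            DERecord(
                gene_id=str(data[mapping["gene_id"]]),
                log2fc=log2fc,
                adj_p=adj_p,
                condition=condition,
            )
        )
    ids = [r.gene_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate gene ids in DE table")
    return records


def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "adj_p": [r.adj_p for r in records],
        }
    )
    # %.17g guarantees float round-trip through the text format
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
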