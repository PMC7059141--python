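"""Readers and writers for the external file formats the screen consumes.

All in-memory coordinates are 0-based, half-open intervals; conversions to
and from 1-based inclusive conventions (GTF) happen only at the I/O
boundary.  Chromosome names are taken verbatim from the input files — no
"chr" prefix normalization is attempted; use an explicit alias table if two
inputs disagree on naming.

Writers emit LF line endings, tab separators and ``#``-prefixed header
lines.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Interval",
    "GeneModel",
    "GenomeSequence",
    "Assembly",
    "Peak",
    "read_fasta",
    "write_fasta",
    "read_peaks",
    "write_peaks_bed",
    "write_peaks_narrowpeak",
    "read_gtf_genes",
    "write_gtf_genes",
    "read_chrom_sizes",
    "write_chrom_sizes",
]

_VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval, 0-based half-open, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "Interval") -> int:
        """Number of shared base pairs with *other* (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "Interval") -> int | None:
        """Base pairs separating two intervals; 0 when they overlap or touch.

        Returns ``None`` when the intervals lie on different chromosomes
        (no finite genomic distance exists).
        """
        if self.chrom != other.chrom:
            return None
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class GeneModel:
    """A gene as an interval plus its identifier and display name."""

    gene_id: str
    gene_name: str
    interval: Interval

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class GenomeSequence:
    """One chromosome: uppercase sequence plus a soft-mask flag per base."""

    chrom_name: str
    sequence: str
    mask: np.ndarray | None = None  # True where the input base was lowercase

    def __post_init__(self) -> None:
        if self.mask is not None and len(self.mask) != len(self.sequence):
            raise ValueError("mask length must equal sequence length")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Assembly:
    """An ordered collection of chromosomes with a derived length table."""

    sequences: dict[str, GenomeSequence] = field(default_factory=dict)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {name: seq.length for name, seq in self.sequences.items()}

    def __getitem__(self, name: str) -> GenomeSequence:
        return self.sequences[name]

    def __iter__(self):
        return iter(self.sequences.values())

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class Peak:
    """A ChIP enrichment interval with the optional BED/narrowPeak columns."""

    interval: Interval
    name: str = "."
    score: float | None = None
    signal_value: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    summit_offset: int | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    def sort_key(self):
        return (self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Assembly:
    """Read a (multi-record) FASTA into an :class:`Assembly`.

    Sequences are uppercased; soft-masked (lowercase) bases are recorded in
    a per-base boolean mask so downstream code can decide their handling.
    Duplicate record names and empty files are errors.
    """
    assembly = Assembly()
    for record in SeqIO.parse(str(path), "fasta"):
        raw = str(record.seq)
        name = record.id
        if name in assembly.sequences:
            raise ValueError(f"duplicate FASTA record name {name!r} in {path}")
        arr = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        mask = (arr >= ord("a")) & (arr <= ord("z"))
        assembly.sequences[name] = GenomeSequence(
            chrom_name=name,
            sequence=raw.upper(),
            mask=mask if mask.any() else np.zeros(len(raw), dtype=bool),
        )
    if not assembly.sequences:
        raise ValueError(f"no FASTA records found in {path}")
    return assembly


def write_fasta(assembly: Assembly, path, line_width: int = 60) -> None:
    """Write an assembly back to FASTA, restoring soft-mask as lowercase."""
    records = []
    for seq in assembly:
        s = seq.sequence
        if seq.mask is not None and seq.mask.any():
            chars = np.frombuffer(s.encode("ascii"), dtype=np.uint8).copy()
            chars[seq.mask] += ord("a") - ord("A")
            s = chars.tobytes().decode("ascii")
        records.append(SeqRecord(Seq(s), id=seq.chrom_name, description=""))
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED / narrowPeak


def _parse_strand(token: str) -> str:
    return token if token in _VALID_STRANDS else "."


def read_peaks(path, format: str = "bed", chrom_sizes: dict[str, int] | None = None):
    """Read a BED3+ or ENCODE narrowPeak file into a :class:`PeakSet`.

    Output is sorted by (chrom, start, end) regardless of input order.
    Duplicate rows are kept (deduplication is a separate, explicit step).
    ``start >= end`` raises with the offending line number; unknown
    chromosomes are only an error when a length table is supplied.
    """
    from .peak_differential import PeakSet  # local import: avoids a cycle

    if format not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown peak format {format!r} (use 'bed' or 'narrowPeak')")
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected at least 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            start, end = int(start_s), int(end_s)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            if chrom_sizes is not None:
                if chrom not in chrom_sizes:
                    raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                if end > chrom_sizes[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: interval end {end} exceeds "
                        f"{chrom} length {chrom_sizes[chrom]}"
                    )
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else None
            strand = _parse_strand(fields[5]) if len(fields) > 5 else "."
            kwargs = {}
            if format == "narrowPeak":
                if len(fields) < 10:
                    raise ValueError(
                        f"{path}:{lineno}: narrowPeak requires 10 columns, "
                        f"got {len(fields)}"
                    )
                kwargs = dict(
                    signal_value=float(fields[6]),
                    p_value=float(fields[7]),
                    q_value=float(fields[8]),
                    summit_offset=int(fields[9]),
                )
            peaks.append(
                Peak(
                    interval=Interval(chrom, start, end, strand),
                    name=name,
                    score=score,
                    **kwargs,
                )
            )
    peaks.sort(key=Peak.sort_key)
    return PeakSet(condition_label="", peaks=peaks)


def _fmt_score(score: float | None) -> str:
    if score is None:
        return "0"
    if float(score).is_integer():
        return str(int(score))
    return f"{score:g}"


def write_peaks_bed(peaks, path, header: list[str] | None = None) -> None:
    """Write peaks as BED6 (one row per peak, sorted input order preserved)."""
    with open(path, "w", newline="\n") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\n")
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t"
                f"{_fmt_score(p.score)}\t{p.interval.strand}\n"
            )


def write_peaks_narrowpeak(peaks, path) -> None:
    """Write peaks as 10-column ENCODE narrowPeak."""

    def opt(v, default):
        return default if v is None else f"{v:g}"

    with open(path, "w", newline="\n") as fh:
        for p in peaks:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        _fmt_score(p.score),
                        p.interval.strand,
                        opt(p.signal_value, "0"),
                        opt(p.p_value, "-1"),
                        opt(p.q_value, "-1"),
                        str(p.summit_offset if p.summit_offset is not None else -1),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GTF genes


def read_gtf_genes(path) -> list[GeneModel]:
    """Extract gene features from a GTF as :class:`GeneModel` records.

    Only rows whose feature type is ``gene`` are consumed; coordinates are
    converted from GTF's 1-based inclusive convention to the internal
    0-based half-open one (start-1, end).  A gene row without a ``gene_id``
    attribute is an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        if "gene_id" not in feat.attributes or not feat.attributes["gene_id"]:
            raise ValueError(
                f"gene feature at {feat.seqid}:{feat.start}-{feat.end} "
                "lacks a gene_id attribute"
            )
        gene_id = feat.attributes["gene_id"][0]
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in {path}")
        seen.add(gene_id)
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        strand = feat.strand if feat.strand in _VALID_STRANDS else "."
        genes.append(
            GeneModel(
                gene_id=gene_id,
                gene_name=gene_name,
                interval=Interval(feat.seqid, feat.start - 1, feat.end, strand),
            )
        )
    return genes


def write_gtf_genes(genes: list[GeneModel], path, source: str = "subteloscreen") -> None:
    """Write gene models as GTF gene features (1-based inclusive)."""
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}";'
            strand = g.interval.strand if g.interval.strand != "." else "+"
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# chromosome sizes


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column <chrom>TAB<length> table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>length'")
            if parts[0] in sizes:
                raise ValueError(f"{path}:{lineno}: duplicate chromosome {parts[0]!r}")
            sizes[parts[0]] = int(parts[1])
    if not sizes:
        raise ValueError(f"no chromosome sizes found in {path}")
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")
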