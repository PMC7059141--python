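"""Gene-to-feature association within a distance window, and telomere distance.

Two geometric primitives of the screen live here:

* :func:`associate_features` — a gene is associated with a feature (peak or
  ITS) when the gap between the gene body and the feature is at most the
  window (inclusive; 100 kb by default).  Overlap counts as distance 0.
* :func:`distance_to_telomere` — a gene's distance to the closest
  chromosome end of the assembly, the quantity used to call a gene
  subtelomeric.

Distances are measured between whole intervals (gene body to feature
interval), the least-assuming reading; a TSS anchor is available as an
explicit option.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .io_formats import GeneModel, Interval, Peak

__all__ = [
    "GeneAssociation",
    "TelomereDistance",
    "associate_features",
    "distance_to_telomere",
]

FEATURE_KINDS = ("peak_lost", "peak_gained", "peak", "its")


@dataclass(frozen=True)
class GeneAssociation:
    """One (gene, feature) pair within the window."""

    gene_id: str
    feature_interval: Interval
    feature_kind: str
    distance: int  # bp gap; 0 iff the gene and feature overlap or touch


@dataclass(frozen=True)
class TelomereDistance:
    """A gene's distance to the nearest chromosome end."""

    gene_id: str
    chrom: str
    distance_bp: int
    nearer_end: str  # "low_coordinate" (p-arm side on standard assemblies) or "high_coordinate"


def _anchor_interval(gene: GeneModel, anchor: str) -> Interval:
    if anchor == "body":
        return gene.interval
    if anchor == "tss":
        # TSS = 5' end of the gene on its strand; a 1-bp interval
        pos = gene.end - 1 if gene.interval.strand == "-" else gene.start
        return Interval(gene.chrom, pos, pos + 1, gene.interval.strand)
    raise ValueError(f"unknown anchor {anchor!r} (use 'body' or 'tss')")


def associate_features(
    genes: list[GeneModel],
    features: list[Peak] | list[Interval],
    window: int = 100_000,
    kind: str = "peak",
    anchor: str = "body",
) -> list[GeneAssociation]:
    """All (gene, feature) pairs whose gap is <= ``window`` bp.

    The window comparison is inclusive: a feature exactly ``window`` bp
    away is associated, one at ``window + 1`` is not.  One record is
    produced per qualifying pair; the unique gene ids form the derived
    gene set.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    intervals = [f.interval if isinstance(f, Peak) else f for f in features]
    trees: dict[str, IntervalTree] = {}
    # data = feature index, so duplicated feature intervals stay distinct
    for i, iv in enumerate(intervals):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, i)
    out: list[GeneAssociation] = []
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        g = _anchor_interval(gene, anchor)
        # query expanded by window+1 so boundary gaps (== window) are kept;
        # the exact gap filter below is authoritative
        lo = g.start - window - 1
        hi = g.end + window + 1
        hits = sorted(tree.overlap(lo, hi), key=lambda iv: (iv.begin, iv.end, iv.data))
        for hit in hits:
            gap = max(0, max(hit.begin, g.start) - min(hit.end, g.end))
            if gap <= window:
                out.append(
                    GeneAssociation(
                        gene_id=gene.gene_id,
                        feature_interval=intervals[hit.data],
                        feature_kind=kind,
                        distance=gap,
                    )
                )
    return out


def associated_gene_ids(associations: list[GeneAssociation]) -> set[str]:
    """The derived gene set of an association list."""
    return {a.gene_id for a in associations}


def distance_to_telomere(gene: GeneModel, chrom_length: int) -> TelomereDistance:
    """Distance from a gene to the closest end of its chromosome sequence.

    ``min(gene.start, chrom_length - gene.end)``; ties report the
    low-coordinate end.  On standard human/mouse assemblies the
    low-coordinate end is the p-arm telomere; for scaffolds or acrocentric
    chromosomes the caller must interpret the end labels with care.
    """
    if gene.end > chrom_length:
        raise ValueError(
            f"gene {gene.gene_id} end {gene.end} exceeds chromosome "
            f"length {chrom_length}"
        )
    d_low = gene.start
    d_high = chrom_length - gene.end
    if d_low <= d_high:
        return TelomereDistance(gene.gene_id, gene.chrom, d_low, "low_coordinate")
    return TelomereDistance(gene.gene_id, gene.chrom, d_high, "high_coordinate")


def write_associations_tsv(associations: list[GeneAssociation], path, header: list[str] | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write("# gene_id\tfeature_chrom\tfeature_start\tfeature_end\tfeature_kind\tdistance_bp\n")
        for a in associations:
            iv = a.feature_interval
            fh.write(
                f"{a.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{a.feature_kind}\t{a.distance}\n"
            )


def write_telomere_distances_tsv(distances: list[TelomereDistance], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("# gene_id\tchrom\tdistance_bp\tnearer_end\n")
        for d in distances:
            fh.write(f"{d.gene_id}\t{d.chrom}\t{d.distance_bp}\t{d.nearer_end}\n")
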