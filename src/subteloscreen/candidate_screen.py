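"""The end-to-end candidate screen: lost/gained peak genes x ITS genes.

Three gene sets are derived with the same association window (default
100 kb): genes near peaks lost on factor depletion, genes near peaks
gained on overexpression, and genes near at least one interstitial
telomeric sequence.  The *modulated* set is, by default, the union of the
lost and gained gene sets (either-direction modulation); intersection mode
is available.  The final candidate list is the intersection of the
modulated set with the ITS gene set, i.e. genes whose binding responds to
the factor's level and that carry telomere-like repeats nearby.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .gene_association import GeneAssociation, associate_features, associated_gene_ids
from .io_formats import GeneModel
from .its_scanner import INTERSTITIAL, RepeatArray, arrays_to_peaks
from .peak_differential import PeakSet

__all__ = ["CandidateReport", "run_screen", "venn_counts", "write_report"]

VENN_REGIONS = (
    "lost_only",
    "gained_only",
    "its_only",
    "lost_gained_only",
    "lost_its_only",
    "gained_its_only",
    "triple",
)


@dataclass
class CandidateReport:
    """Output of the screen: the constituent gene sets and the candidates."""

    lost_genes: set[str]
    gained_genes: set[str]
    its_genes: set[str]
    modulated_genes: set[str]
    final_candidates: set[str]
    params: dict = field(default_factory=dict)
    # supporting evidence: gene_id -> association records
    evidence: dict[str, list[GeneAssociation]] = field(default_factory=dict)
    gene_names: dict[str, str] = field(default_factory=dict)


def run_screen(
    lost: PeakSet,
    gained: PeakSet,
    its_arrays: list[RepeatArray],
    genes: list[GeneModel],
    window: int = 100_000,
    modulated_mode: str = "union",
    anchor: str = "body",
) -> CandidateReport:
    """Run the full association screen.

    ``its_arrays`` must already be classified and contain only interstitial
    arrays — passing a terminal tract is an error, because terminal
    telomeres would trivially mark every subtelomeric gene.
    """
    if modulated_mode not in ("union", "intersection"):
        raise ValueError(f"unknown modulated_mode {modulated_mode!r}")
    for a in its_arrays:
        if a.array_class != INTERSTITIAL:
            raise ValueError(
                f"array at {a.chrom}:{a.start}-{a.end} has class "
                f"{a.array_class!r}; classify arrays and pass interstitial only"
            )

    assoc_lost = associate_features(genes, list(lost), window, kind="peak_lost", anchor=anchor)
    assoc_gained = associate_features(genes, list(gained), window, kind="peak_gained", anchor=anchor)
    assoc_its = associate_features(
        genes, arrays_to_peaks(its_arrays), window, kind="its", anchor=anchor
    )

    lost_genes = associated_gene_ids(assoc_lost)
    gained_genes = associated_gene_ids(assoc_gained)
    its_genes = associated_gene_ids(assoc_its)
    if modulated_mode == "union":
        modulated = lost_genes | gained_genes
    else:
        modulated = lost_genes & gained_genes
    final = modulated & its_genes

    evidence: dict[str, list[GeneAssociation]] = {}
    for assoc in (assoc_lost, assoc_gained, assoc_its):
        for rec in assoc:
            if rec.gene_id in final:
                evidence.setdefault(rec.gene_id, []).append(rec)

    return CandidateReport(
        lost_genes=lost_genes,
        gained_genes=gained_genes,
        its_genes=its_genes,
        modulated_genes=modulated,
        final_candidates=final,
        params={
            "window": window,
            "modulated_mode": modulated_mode,
            "anchor": anchor,
            "lost_condition": lost.condition_label,
            "gained_condition": gained.condition_label,
            "n_lost_peaks": len(lost),
            "n_gained_peaks": len(gained),
            "n_its_arrays": len(its_arrays),
        },
        evidence=evidence,
        gene_names={g.gene_id: g.gene_name for g in genes},
    )


def venn_counts(report: CandidateReport) -> tuple[int, int, int, int, int, int, int]:
    """Counts of the seven regions of the lost/gained/ITS gene-set Venn.

    Order: (lost-only, gained-only, its-only, lost∩gained-only,
    lost∩its-only, gained∩its-only, triple).  The counts partition
    ``lost ∪ gained ∪ its``.
    """
    l, g, i = report.lost_genes, report.gained_genes, report.its_genes
    return (
        len(l - g - i),
        len(g - l - i),
        len(i - l - g),
        len((l & g) - i),
        len((l & i) - g),
        len((g & i) - l),
        len(l & g & i),
    )


def write_report(report: CandidateReport, path, json_path=None) -> None:
    """Write the candidate table as TSV with a JSON parameter sidecar.

    One TSV row per final candidate with its supporting features and
    distances; the sidecar records parameters and all region counts so a
    run is interpretable without the inputs.
    """
    path = str(path)
    if json_path is None:
        json_path = path + ".json"
    counts = venn_counts(report)
    with open(path, "w", newline="\n") as fh:
        for key, value in sorted(report.params.items()):
            fh.write(f"# {key}={value}\n")
        fh.write(
            "# gene_id\tgene_name\tn_lost_peaks\tn_gained_peaks\tn_its\t"
            "min_peak_distance_bp\tmin_its_distance_bp\tsupport\n"
        )
        for gene_id in sorted(report.final_candidates):
            recs = report.evidence.get(gene_id, [])
            peaks = [r for r in recs if r.feature_kind.startswith("peak")]
            its = [r for r in recs if r.feature_kind == "its"]
            support = ";".join(
                f"{r.feature_kind}:{r.feature_interval.chrom}:"
                f"{r.feature_interval.start}-{r.feature_interval.end}@{r.distance}"
                for r in recs
            )
            fh.write(
                "\t".join(
                    [
                        gene_id,
                        report.gene_names.get(gene_id, gene_id),
                        str(len([r for r in peaks if r.feature_kind == "peak_lost"])),
                        str(len([r for r in peaks if r.feature_kind == "peak_gained"])),
                        str(len(its)),
                        str(min((r.distance for r in peaks), default=-1)),
                        str(min((r.distance for r in its), default=-1)),
                        support,
                    ]
                )
                + "\n"
            )
    sidecar = {
        "params": report.params,
        "counts": {
            "lost_genes": len(report.lost_genes),
            "gained_genes": len(report.gained_genes),
            "its_genes": len(report.its_genes),
            "modulated_genes": len(report.modulated_genes),
            "final_candidates": len(report.final_candidates),
            "venn": dict(zip(VENN_REGIONS, counts)),
        },
        "final_candidates": sorted(report.final_candidates),
        "lost_genes": sorted(report.lost_genes),
        "gained_genes": sorted(report.gained_genes),
        "its_genes": sorted(report.its_genes),
    }
    with open(json_path, "w", newline="\n") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report_json(json_path) -> dict:
    with open(json_path) as fh:
        return json.load(fh)
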