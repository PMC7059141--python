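"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the statistical structure of the study design the
screen was built for, with no downloads:

* a multi-chromosome genome of i.i.d. background bases at a configurable
  GC content, with terminal telomeric tracts at both chromosome ends
  (G-strand running 5'->3' toward each end, as at real telomeres) and
  planted interstitial telomeric arrays of chosen unit counts;
* gene annotations with genes placed at controlled distances from
  chromosome ends (including a subtelomeric gene planted exactly 200 kb
  from a low-coordinate end, mirroring the human SIRT3 position);
* per-condition ChIP peak files with a controlled shared / A-only /
  B-only composition;
* replicate qPCR Ct tables with stated fold effects and Gaussian noise on
  the Ct (log-quantity) scale.

Everything is a pure function of (parameters, seed).  A master seed fans
out to fixed per-artifact child seeds so any one artifact can be
regenerated independently.

Background sequence is i.i.d. — no repeat families beyond the planted
ones — which keeps the scanner's ground truth exact.  Flanking guard
bases prevent chance background extension of a planted array.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    Assembly,
    GeneModel,
    GenomeSequence,
    Interval,
    Peak,
    write_chrom_sizes,
    write_fasta,
    write_gtf_genes,
    write_peaks_narrowpeak,
)
from .its_scanner import INTERSTITIAL, TERMINAL, RepeatArray, revcomp, write_arrays_bed
from .peak_differential import PeakSet
from .qpcr_quant import CT_COLUMNS, write_ct_table

__all__ = [
    "make_genome",
    "make_annotation",
    "make_peaks",
    "make_ct_table",
    "make_screen_fixture",
    "CT_PRESETS",
    "TruthBundle",
]

MOTIF = "TTAGGG"

# fixed child-seed offsets: regenerate any artifact independently
_GENOME, _ANNOTATION, _PEAKS, _CT, _FIXTURE = 1, 2, 3, 4, 5


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(offset)])


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


def _guard_base(excluded: set[str]) -> str:
    for base in "ACGT":
        if base not in excluded:
            return base
    raise AssertionError("unreachable: four bases, at most two exclusions")


# ---------------------------------------------------------------------------
# genome


def _plant_array(
    chars: np.ndarray,
    chrom: str,
    start: int,
    units: int,
    strand: str,
    mismatched_units: int = 0,
    array_class: str = INTERSTITIAL,
    rng: np.random.Generator | None = None,
) -> RepeatArray:
    """Write one repeat array into the chromosome byte buffer.

    ``mismatched_units`` units (never the first, which anchors the frame)
    get one substituted base each.  Guard bases on both flanks stop chance
    extension by background sequence.
    """
    unit = MOTIF if strand == "+" else revcomp(MOTIF)
    seq = unit * units
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mismatched_units = min(mismatched_units, units - 1)
    matched = 6 * units
    if mismatched_units:
        if rng is None:
            raise ValueError("rng required to plant mismatched units")
        which = rng.choice(np.arange(1, units), size=mismatched_units, replace=False)
        for u in which:
            pos_in_unit = int(rng.integers(1, 5))  # keep unit boundaries intact
            pos = int(u) * 6 + pos_in_unit
            old = chr(arr[pos])
            arr[pos] = ord(_guard_base({old}))
            matched -= 1
    end = start + len(arr)
    chars[start:end] = arr
    if start > 0:
        chars[start - 1] = ord(_guard_base({unit[-1], revcomp(MOTIF)[-1], MOTIF[-1]}))
    if end < len(chars):
        chars[end] = ord(_guard_base({unit[0], revcomp(MOTIF)[0], MOTIF[0]}))
    return RepeatArray(
        interval=Interval(chrom, start, end, strand),
        strand=strand,
        unit_count=units,
        matched_bases=matched,
        purity=matched / len(arr),
        array_class=array_class,
    )


def make_genome(
    n_chrom: int = 2,
    chrom_length: int = 100_000,
    gc: float = 0.5,
    terminal_tract_units: int = 50,
    its_spec: list[tuple] | None = None,
    seed: int = 0,
    fasta_path=None,
    truth_bed_path=None,
) -> tuple[Assembly, list[RepeatArray]]:
    """Generate a genome with terminal tracts and planted ITSs.

    ``its_spec`` is applied to every chromosome; each entry is
    ``(position_fraction, units, mismatched_units)`` with an optional
    fourth element, the strand (default '+').  Overlapping plant requests
    are an error.  Returns the assembly and the planted-array truth
    (terminal tracts included, classified).
    """
    if its_spec is None:
        its_spec = [(0.35, 6, 0), (0.7, 10, 0)]
    rng = _rng(seed, _GENOME)
    assembly = Assembly()
    truth: list[RepeatArray] = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        chars = _random_bases(rng, chrom_length, gc)
        plants: list[tuple[int, int, int, str, str]] = []  # start, units, mm, strand, class
        if terminal_tract_units > 0:
            tract = terminal_tract_units * 6
            if 2 * tract >= chrom_length:
                raise ValueError("terminal tracts longer than the chromosome")
            # G-strand 5'->3' toward each end: CCCTAA at the low end
            # (G-run on the minus strand), TTAGGG at the high end
            plants.append((0, terminal_tract_units, 0, "-", TERMINAL))
            plants.append((chrom_length - tract, terminal_tract_units, 0, "+", TERMINAL))
        for entry in its_spec:
            frac, units, mm = entry[0], entry[1], entry[2]
            strand = entry[3] if len(entry) > 3 else "+"
            start = int(round(frac * chrom_length))
            plants.append((start, units, mm, strand, INTERSTITIAL))
        plants.sort()
        prev_end = -2  # one guard base of clearance between plants
        for start, units, mm, strand, array_class in plants:
            end = start + units * 6
            if start <= prev_end + 1 or end > chrom_length:
                raise ValueError(
                    f"planted arrays overlap or exceed bounds on {chrom} "
                    f"(request at {start}-{end})"
                )
            truth.append(
                _plant_array(chars, chrom, start, units, strand, mm, array_class, rng)
            )
            prev_end = end
        assembly.sequences[chrom] = GenomeSequence(
            chrom_name=chrom,
            sequence=chars.tobytes().decode("ascii"),
            mask=np.zeros(chrom_length, dtype=bool),
        )
    if fasta_path is not None:
        write_fasta(assembly, fasta_path)
    if truth_bed_path is not None:
        write_arrays_bed(truth, truth_bed_path)
    return assembly, truth


# ---------------------------------------------------------------------------
# annotation


def make_annotation(
    chrom_sizes: dict[str, int],
    genes_per_chrom: int = 25,
    length_range: tuple[int, int] = (1_000, 5_000),
    placements: list[dict] | None = None,
    seed: int = 0,
    allow_overlap: bool = False,
    gtf_path=None,
) -> list[GeneModel]:
    """Random gene annotation plus genes at requested distances from ends.

    Each placement is a dict with keys ``gene_id``, ``chrom``,
    ``distance`` (bp from the chosen end to the nearest gene edge),
    ``end`` ("low" or "high") and optional ``length`` and ``gene_name``.
    A low-end placement at distance d puts the gene start exactly at d, so
    the telomere distance of that gene is d by construction.
    """
    rng = _rng(seed, _ANNOTATION)
    genes: list[GeneModel] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}

    def overlaps(chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in occupied[chrom])

    for p in placements or []:
        chrom = p["chrom"]
        length = int(p.get("length", 2_000))
        size = chrom_sizes[chrom]
        if p.get("end", "low") == "low":
            start = int(p["distance"])
        else:
            start = size - int(p["distance"]) - length
        end = start + length
        if start < 0 or end > size:
            raise ValueError(f"placement {p['gene_id']} outside {chrom}")
        genes.append(
            GeneModel(
                gene_id=p["gene_id"],
                gene_name=p.get("gene_name", p["gene_id"]),
                interval=Interval(chrom, start, end, "+"),
            )
        )
        occupied[chrom].append((start, end))

    idx = 1
    for chrom, size in chrom_sizes.items():
        placed = 0
        attempts = 0
        while placed < genes_per_chrom:
            attempts += 1
            if attempts > 100 * genes_per_chrom:
                raise ValueError(f"cannot place {genes_per_chrom} genes on {chrom}")
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            start = int(rng.integers(0, max(1, size - length)))
            end = start + length
            if not allow_overlap and overlaps(chrom, start, end):
                continue
            genes.append(
                GeneModel(
                    gene_id=f"SYNG{idx:04d}",
                    gene_name=f"SYNG{idx:04d}",
                    interval=Interval(chrom, start, end, "+" if rng.random() < 0.5 else "-"),
                )
            )
            occupied[chrom].append((start, end))
            idx += 1
            placed += 1
    if gtf_path is not None:
        write_gtf_genes(genes, gtf_path)
    return genes


# ---------------------------------------------------------------------------
# peaks


def make_peaks(
    chrom_sizes: dict[str, int],
    n_shared: int = 20,
    n_only_a: int = 15,
    n_only_b: int = 10,
    width_range: tuple[int, int] = (200, 400),
    min_separation: int = 100_001,
    seed: int = 0,
    labels: tuple[str, str] = ("shScramble", "TRF2"),
    path_a=None,
    path_b=None,
) -> tuple[PeakSet, PeakSet, dict[str, list[Interval]]]:
    """Two condition peak sets with a planted shared/A-only/B-only mix.

    Shared peaks overlap across conditions by at least 1 bp;
    condition-specific peaks sit at least ``min_separation`` bp from every
    peak of the other condition, so any sane overlap rule classifies them
    identically.
    """
    rng = _rng(seed, _PEAKS)
    max_w = width_range[1]
    slot = min_separation + 2 * max_w
    slots: list[tuple[str, int]] = []
    for chrom, size in chrom_sizes.items():
        for pos in range(max_w, size - slot, slot):
            slots.append((chrom, pos))
    total = n_shared + n_only_a + n_only_b
    if total > len(slots):
        raise ValueError(
            f"need {total} peak slots but the genome only provides {len(slots)}; "
            "use longer chromosomes or fewer peaks"
        )
    chosen = rng.choice(len(slots), size=total, replace=False)
    kinds = ["shared"] * n_shared + ["only_a"] * n_only_a + ["only_b"] * n_only_b

    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    truth: dict[str, list[Interval]] = {"shared": [], "only_a": [], "only_b": []}

    def mk(chrom, start, width, name):
        return Peak(
            interval=Interval(chrom, start, start + width),
            name=name,
            score=float(rng.integers(100, 1000)),
            signal_value=float(np.round(rng.uniform(2, 50), 3)),
            p_value=float(np.round(rng.uniform(3, 12), 3)),
            q_value=float(np.round(rng.uniform(2, 10), 3)),
            summit_offset=width // 2,
        )

    for i, (slot_idx, kind) in enumerate(zip(chosen, kinds)):
        chrom, pos = slots[int(slot_idx)]
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        if kind == "shared":
            shift = int(rng.integers(0, max(1, width - 1)))  # overlap >= 1 bp
            pa = mk(chrom, pos, width, f"shared_{i}")
            pb = mk(chrom, pos + shift, width, f"shared_{i}")
            peaks_a.append(pa)
            peaks_b.append(pb)
            truth["shared"].append(pa.interval)
        elif kind == "only_a":
            pa = mk(chrom, pos, width, f"a_only_{i}")
            peaks_a.append(pa)
            truth["only_a"].append(pa.interval)
        else:
            pb = mk(chrom, pos, width, f"b_only_{i}")
            peaks_b.append(pb)
            truth["only_b"].append(pb.interval)

    set_a = PeakSet(condition_label=labels[0], peaks=peaks_a)
    set_b = PeakSet(condition_label=labels[1], peaks=peaks_b)
    if path_a is not None:
        write_peaks_narrowpeak(set_a, path_a)
    if path_b is not None:
        write_peaks_narrowpeak(set_b, path_b)
    return set_a, set_b, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables

HKG_HUMAN = ("HPRT", "PPIA", "GAPDH")
HKG_MOUSE = ("Hprt", "Ppib", "Gapdh")

# Each preset: groups (reference first), targets with planted fold
# (treatment vs reference quantity ratio), housekeeping/reference targets
# (fold pinned to 1).  "mtdna_shTERF2" plants the eightfold mitochondrial
# DNA increase seen on TERF2 knockdown; "sirt3_down" plants a halved SIRT3
# with the other sirtuins flat.
CT_PRESETS: dict[str, dict] = {
    "null": {
        "groups": ("control", "treatment"),
        "targets": {"TARGET": 1.0},
        "hkg": HKG_HUMAN,
    },
    "mtdna_shTERF2": {
        "groups": ("shScramble", "shTERF2"),
        "targets": {"MT_ND1": 8.0},
        "hkg": ("B2M",),  # single-copy nuclear amplicon
        "mito_amplicon": "MT_ND1",
        "nuclear_amplicon": "B2M",
    },
    "sirt3_down": {
        "groups": ("shScramble", "shTERF2"),
        "targets": {
            "SIRT3": 0.5,
            "SIRT1": 1.0,
            "SIRT2": 1.0,
            "SIRT4": 1.0,
            "SIRT5": 1.0,
            "SIRT6": 1.0,
            "SIRT7": 1.0,
        },
        "hkg": HKG_HUMAN,
    },
}


def make_ct_table(
    preset: str = "null",
    n_per_group: int = 6,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    replicates: int = 2,
    tsv_path=None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Replicate Ct table for a named preset, plus the planted folds.

    Ct = target baseline + group effect + Normal(0, ct_noise_sd) per
    technical replicate, where the group effect is -log2(planted fold) in
    the treatment group (a doubled quantity appears one cycle earlier).
    Housekeeping targets are unaffected by group.
    """
    if preset not in CT_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(CT_PRESETS)}"
        )
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    spec = CT_PRESETS[preset]
    rng = _rng(seed, _CT)
    ref_group, treat_group = spec["groups"]
    all_targets = list(spec["targets"]) + list(spec["hkg"])
    baselines = {t: float(np.round(rng.uniform(18, 28), 2)) for t in all_targets}
    rows = []
    for group in (ref_group, treat_group):
        for s in range(1, n_per_group + 1):
            sample_id = f"{group}_{s}"
            for target in all_targets:
                fold = spec["targets"].get(target, 1.0)
                effect = -np.log2(fold) if group == treat_group else 0.0
                for rep in range(1, replicates + 1):
                    noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                    rows.append(
                        (sample_id, group, target, rep, baselines[target] + effect + noise)
                    )
    table = pd.DataFrame(rows, columns=CT_COLUMNS)
    if tsv_path is not None:
        write_ct_table(table, tsv_path)
    return table, dict(spec["targets"])


# ---------------------------------------------------------------------------
# full screen fixture


@dataclass
class TruthBundle:
    """Everything the pipeline consumes, with the generator's ground truth."""

    seed: int
    window: int
    assembly: Assembly
    genes: list[GeneModel]
    peaks_a: PeakSet  # control condition (shScramble): shared + lost
    peaks_b: PeakSet  # overexpression condition (TRF2): shared + gained
    peak_labels: dict[str, list[Interval]]
    its_truth: list[RepeatArray]  # all planted arrays, classified
    candidate_truth: set[str]
    decoy_gene_ids: set[str]
    lost_gene_truth: set[str] = field(default_factory=set)
    gained_gene_truth: set[str] = field(default_factory=set)
    its_gene_truth: set[str] = field(default_factory=set)
    ct_table: pd.DataFrame | None = None
    ct_planted_folds: dict[str, float] = field(default_factory=dict)
    paths: dict[str, str] = field(default_factory=dict)


def make_screen_fixture(
    seed: int = 0,
    out_dir=None,
    n_chrom: int = 8,
    chrom_length: int = 3_000_000,
    window: int = 100_000,
    gc: float = 0.45,
    terminal_tract_units: int = 50,
    n_candidates: int = 40,
    ct_noise_sd: float = 0.2,
) -> TruthBundle:
    """Compose a full screen fixture with planted candidates and decoys.

    The genome is tiled into isolated blocks 250 kb apart (well beyond the
    association window), each holding one scenario: a candidate gene near
    both a modulated peak and an ITS, plus a decoy gene at exactly
    window + 1 bp from those features; genes near only a lost peak, only a
    gained peak, only an ITS, or only a peak shared between conditions;
    and blocks of filler genes near nothing.  Terminal tracts act as decoy
    arrays that classification must exclude.  By default 40 of the 400
    genes satisfy the screen.
    """
    rng = _rng(seed, _FIXTURE)
    spacing = 250_000
    if spacing <= window + 110_000:
        raise ValueError("block spacing must exceed the window comfortably")
    centers = list(range(spacing, chrom_length - spacing + 1, spacing))
    blocks = [(f"chr{c + 1}", center) for c in range(n_chrom) for center in centers]

    n_pl = n_pg = 8
    n_i = 16
    n_s = 8
    n_e = 8
    types = (
        ["C"] * n_candidates
        + ["PL"] * n_pl
        + ["PG"] * n_pg
        + ["I"] * n_i
        + ["S"] * n_s
        + ["E"] * n_e
    )
    if len(types) > len(blocks):
        raise ValueError(
            f"{len(types)} blocks requested but only {len(blocks)} available; "
            "increase n_chrom or chrom_length"
        )
    order = rng.permutation(len(blocks))[: len(types)]
    assignment = {blocks[int(b)]: t for b, t in zip(order, types)}

    # ----- plan features and genes per block
    its_plan: dict[str, list[tuple]] = {f"chr{c + 1}": [] for c in range(n_chrom)}
    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    peak_labels: dict[str, list[Interval]] = {"shared": [], "only_a": [], "only_b": []}
    genes: list[GeneModel] = []
    candidate_truth: set[str] = set()
    decoys: set[str] = set()
    lost_truth: set[str] = set()
    gained_truth: set[str] = set()
    its_gene_truth: set[str] = set()

    gene_counter = 0

    def new_gene(chrom: str, start: int, length: int = 2_000) -> GeneModel:
        nonlocal gene_counter
        gene_counter += 1
        gid = f"GENE{gene_counter:04d}"
        return GeneModel(gid, gid, Interval(chrom, start, start + length, "+"))

    def mk_peak(chrom: str, start: int, width: int, name: str) -> Peak:
        return Peak(
            interval=Interval(chrom, start, start + width),
            name=name,
            score=float(rng.integers(100, 1000)),
            signal_value=float(np.round(rng.uniform(2, 50), 3)),
            p_value=float(np.round(rng.uniform(3, 12), 3)),
            q_value=float(np.round(rng.uniform(2, 10), 3)),
            summit_offset=width // 2,
        )

    lost_turn = True  # alternate candidate blocks between lost and gained
    block_idx = 0
    e_blocks_seen = 0
    for (chrom, center), btype in sorted(assignment.items()):
        block_idx += 1
        width = 300
        if btype in ("C", "PL", "PG", "S"):
            name = f"{btype.lower()}_{block_idx}"
            if btype == "S":
                shift = 80
                pa = mk_peak(chrom, center, width, name)
                pb = mk_peak(chrom, center + shift, width, name)
                peaks_a.append(pa)
                peaks_b.append(pb)
                peak_labels["shared"].append(pa.interval)
            else:
                is_lost = btype == "PL" or (btype == "C" and lost_turn)
                if btype == "C":
                    lost_turn = not lost_turn
                peak = mk_peak(chrom, center, width, name)
                if is_lost:
                    peaks_a.append(peak)
                    peak_labels["only_a"].append(peak.interval)
                else:
                    peaks_b.append(peak)
                    peak_labels["only_b"].append(peak.interval)
        if btype in ("C", "I"):
            units = 4 + (block_idx * 3) % 17
            its_start = center + 2_000 if btype == "C" else center
            strand = "+" if block_idx % 2 else "-"
            its_plan[chrom].append((its_start, units, strand))
        # genes
        if btype == "E":
            e_blocks_seen += 1
            n_fill = 34 if e_blocks_seen == 1 else 35
            for j in range(n_fill):
                genes.append(new_gene(chrom, center - 52_500 + j * 3_000))
        else:
            gene = new_gene(chrom, center + 5_000)
            genes.append(gene)
            if btype == "C":
                candidate_truth.add(gene.gene_id)
                its_gene_truth.add(gene.gene_id)
                (lost_truth if not lost_turn else gained_truth).add(gene.gene_id)
                # NB lost_turn was already toggled; "not lost_turn" recovers
                # the branch taken for this block's peak
                decoy = new_gene(chrom, center - window - 2_001)
                genes.append(decoy)
                decoys.add(decoy.gene_id)
            elif btype == "PL":
                lost_truth.add(gene.gene_id)
            elif btype == "PG":
                gained_truth.add(gene.gene_id)
            elif btype == "I":
                its_gene_truth.add(gene.gene_id)

    # near-telomere control: within the window of a terminal tract only;
    # must never appear in the ITS gene set
    genes.append(new_gene("chr1", 15_000))

    # ----- build the genome with the planned arrays
    genome_rng = _rng(seed, _GENOME)
    assembly = Assembly()
    its_truth: list[RepeatArray] = []
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        chars = _random_bases(genome_rng, chrom_length, gc)
        tract = terminal_tract_units * 6
        its_truth.append(
            _plant_array(chars, chrom, 0, terminal_tract_units, "-", 0, TERMINAL)
        )
        for start, units, strand in sorted(its_plan[chrom]):
            its_truth.append(
                _plant_array(chars, chrom, start, units, strand, 0, INTERSTITIAL)
            )
        its_truth.append(
            _plant_array(
                chars, chrom, chrom_length - tract, terminal_tract_units, "+", 0, TERMINAL
            )
        )
        assembly.sequences[chrom] = GenomeSequence(
            chrom_name=chrom,
            sequence=chars.tobytes().decode("ascii"),
            mask=np.zeros(chrom_length, dtype=bool),
        )

    set_a = PeakSet(condition_label="shScramble", peaks=peaks_a)
    set_b = PeakSet(condition_label="TRF2", peaks=peaks_b)

    ct_table, planted_folds = make_ct_table(
        "mtdna_shTERF2", n_per_group=6, ct_noise_sd=ct_noise_sd, seed=seed
    )

    bundle = TruthBundle(
        seed=seed,
        window=window,
        assembly=assembly,
        genes=genes,
        peaks_a=set_a,
        peaks_b=set_b,
        peak_labels=peak_labels,
        its_truth=its_truth,
        candidate_truth=candidate_truth,
        decoy_gene_ids=decoys,
        lost_gene_truth=lost_truth,
        gained_gene_truth=gained_truth,
        its_gene_truth=its_gene_truth,
        ct_table=ct_table,
        ct_planted_folds=planted_folds,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": str(out / "genome.fa"),
            "chrom_sizes": str(out / "genome.chrom.sizes"),
            "gtf": str(out / "genes.gtf"),
            "peaks_a": str(out / "shScramble.narrowPeak"),
            "peaks_b": str(out / "trf2oe.narrowPeak"),
            "its_truth": str(out / "its_truth.bed"),
            "ct_table": str(out / "ct_mtdna.tsv"),
            "truth": str(out / "truth.json"),
        }
        write_fasta(assembly, paths["fasta"])
        write_chrom_sizes(assembly.chrom_sizes, paths["chrom_sizes"])
        write_gtf_genes(genes, paths["gtf"])
        write_peaks_narrowpeak(set_a, paths["peaks_a"])
        write_peaks_narrowpeak(set_b, paths["peaks_b"])
        write_arrays_bed(its_truth, paths["its_truth"])
        write_ct_table(ct_table, paths["ct_table"])
        with open(paths["truth"], "w", newline="\n") as fh:
            json.dump(
                {
                    "seed": seed,
                    "window": window,
                    "candidate_truth": sorted(candidate_truth),
                    "decoy_gene_ids": sorted(decoys),
                    "lost_gene_truth": sorted(lost_truth),
                    "gained_gene_truth": sorted(gained_truth),
                    "its_gene_truth": sorted(its_gene_truth),
                    "ct_planted_folds": planted_folds,
                },
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")
        bundle.paths = paths
    return bundle
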