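"""Condition-specific ("gained"/"lost") peak calls between two conditions.

The comparison is presence/absence of whole called peaks: a peak of
condition A is *shared* iff it overlaps at least one peak of condition B
by at least ``min_overlap`` bp, otherwise it is *only in A*.  Peaks are
never split, so the downstream Venn logic operates on whole input peaks.
With A the control knockdown condition and B the overexpression condition,
A-only peaks are *lost* binding sites and B-only peaks are *gained* ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io_formats import Interval, Peak

__all__ = [
    "PeakSet",
    "DifferentialResult",
    "merge_peaks",
    "compare_conditions",
    "label_modulated",
]


@dataclass
class PeakSet:
    """A labelled, sorted collection of peaks from one condition."""

    condition_label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=Peak.sort_key)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self) -> list[Interval]:
        return [p.interval for p in self.peaks]

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out


@dataclass
class DifferentialResult:
    """Partition of two peak sets into condition-specific and shared peaks.

    ``only_in_A`` and ``shared_A`` partition A; likewise for B.
    """

    only_in_A: PeakSet
    only_in_B: PeakSet
    shared_A: PeakSet
    shared_B: PeakSet
    min_overlap: int = 1


def merge_peaks(peak_set: PeakSet, max_gap: int = 0) -> PeakSet:
    """Union peaks whose gap is at most ``max_gap`` bp.

    Half-open touching intervals ([0,100) and [100,200)) have gap 0 and
    merge at the default.  Scores of merged peaks combine by max.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[Peak] = []
    for chrom, peaks in sorted(peak_set.by_chrom().items()):
        cur_start, cur_end = peaks[0].start, peaks[0].end
        cur_score = peaks[0].score
        cur_names = [peaks[0].name]
        for p in peaks[1:]:
            if p.start - cur_end <= max_gap:
                cur_end = max(cur_end, p.end)
                if p.score is not None:
                    cur_score = p.score if cur_score is None else max(cur_score, p.score)
                cur_names.append(p.name)
            else:
                merged.append(
                    Peak(Interval(chrom, cur_start, cur_end), name=cur_names[0], score=cur_score)
                )
                cur_start, cur_end, cur_score, cur_names = p.start, p.end, p.score, [p.name]
        merged.append(
            Peak(Interval(chrom, cur_start, cur_end), name=cur_names[0], score=cur_score)
        )
    return PeakSet(condition_label=peak_set.condition_label, peaks=merged)


def _overlap_trees(peak_set: PeakSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, peaks in peak_set.by_chrom().items():
        trees[chrom] = IntervalTree.from_tuples((p.start, p.end) for p in peaks)
    return trees


def compare_conditions(a: PeakSet, b: PeakSet, min_overlap: int = 1) -> DifferentialResult:
    """Classify every peak of each condition as shared or condition-specific.

    A peak is shared iff some peak of the other condition overlaps it by at
    least ``min_overlap`` bp.  The classification is per input peak; peaks
    are not split or merged by the comparison.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    def split(source: PeakSet, other_trees: dict[str, IntervalTree]):
        only, shared = [], []
        for p in source:
            tree = other_trees.get(p.chrom)
            hit = False
            if tree is not None:
                for iv in tree.overlap(p.start, p.end):
                    if min(p.end, iv.end) - max(p.start, iv.begin) >= min_overlap:
                        hit = True
                        break
            (shared if hit else only).append(p)
        return only, shared

    trees_a, trees_b = _overlap_trees(a), _overlap_trees(b)
    only_a, shared_a = split(a, trees_b)
    only_b, shared_b = split(b, trees_a)
    return DifferentialResult(
        only_in_A=PeakSet(a.condition_label, only_a),
        only_in_B=PeakSet(b.condition_label, only_b),
        shared_A=PeakSet(a.condition_label, shared_a),
        shared_B=PeakSet(b.condition_label, shared_b),
        min_overlap=min_overlap,
    )


def label_modulated(
    diff: DifferentialResult, orientation: str = "A_is_control"
) -> tuple[PeakSet, PeakSet]:
    """Map the differential partition to (lost, gained) peak sets.

    With ``A_is_control`` (control/knockdown as A, factor overexpression as
    B): binding *lost* on factor depletion = peaks only in A; binding
    *gained* = peaks only in B.  ``B_is_control`` swaps the roles.
    """
    if orientation == "A_is_control":
        lost, gained = diff.only_in_A, diff.only_in_B
    elif orientation == "B_is_control":
        lost, gained = diff.only_in_B, diff.only_in_A
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    lost = PeakSet(condition_label=f"lost({lost.condition_label})", peaks=lost.peaks)
    gained = PeakSet(condition_label=f"gained({gained.condition_label})", peaks=gained.peaks)
    return lost, gained
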