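"""Independent brute-force oracles the implementation is checked against.

Everything here is written for clarity over speed and deliberately avoids
the package's data structures and algorithms: naive string scanning,
O(n^2) interval closures, all-pairs distance checks, dict-and-loop qPCR
arithmetic.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def enumerate_repeat_arrays(
    seq: str,
    motif: str = "TTAGGG",
    min_units: int = 3,
    max_spacer: int = 0,
    max_mismatches: int = 0,
):
    """Naive enumeration of maximal repeat runs on both strands.

    Returns a sorted list of (start, end, strand, unit_count,
    matched_bases) tuples.  Chaining is greedy-leftmost: from each
    unconsumed match, repeatedly take the leftmost next match that starts
    at or after the current end and within max_spacer of it.
    """
    k = len(motif)
    out = []
    for strand, m in (("+", motif), ("-", rc(motif))):
        matches: list[tuple[int, int]] = []
        if max_mismatches == 0:
            p = seq.find(m)
            while p != -1:
                matches.append((p, 0))
                p = seq.find(m, p + 1)
        else:
            for p in range(len(seq) - k + 1):
                mm = sum(1 for a, b in zip(seq[p : p + k], m) if a != b)
                if mm <= max_mismatches:
                    matches.append((p, mm))
        i = 0
        while i < len(matches):
            p0, mm0 = matches[i]
            end = p0 + k
            chain = [(p0, mm0)]
            while True:
                nxt = None
                for q, qm in matches:  # naive: rescan from the start
                    if end <= q <= end + max_spacer:
                        nxt = (q, qm)
                        break
                if nxt is None:
                    break
                chain.append(nxt)
                end = nxt[0] + k
            if len(chain) >= min_units and any(c[1] == 0 for c in chain):
                out.append(
                    (p0, end, strand, len(chain), sum(k - c[1] for c in chain))
                )
            while i < len(matches) and matches[i][0] < end:
                i += 1
    return sorted(out)


def merge_closure(intervals, max_gap: int):
    """Repeated pairwise union of intervals with gap <= max_gap, to fixpoint.

    intervals: list of (chrom, start, end).  Returns a sorted list.
    """
    items = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                a, b = items[i], items[j]
                if a[0] != b[0]:
                    continue
                gap = max(a[1], b[1]) - min(a[2], b[2])
                if gap <= max_gap:
                    a[1], a[2] = min(a[1], b[1]), max(a[2], b[2])
                    del items[j]
                    changed = True
                    break
            if changed:
                break
    return sorted(tuple(x) for x in items)


def all_pairs_associations(genes, features, window: int):
    """All (gene_id, feature index) pairs with interval gap <= window.

    genes: list of (gene_id, chrom, start, end); features: list of
    (chrom, start, end).  Returns a sorted list of (gene_id, feature_index,
    gap).
    """
    out = []
    for gid, gchrom, gstart, gend in genes:
        for fi, (fchrom, fstart, fend) in enumerate(features):
            if gchrom != fchrom:
                continue
            gap = max(0, max(gstart, fstart) - min(gend, fend))
            if gap <= window:
                out.append((gid, fi, gap))
    return sorted(out)


def spreadsheet_fold_change(rows, target, hkgs, reference_group):
    """Dict-and-loop ddCt recomputation from raw (sample, group, target,
    ct) rows, the way one would in a spreadsheet.

    Returns {group: fold_change}.
    """
    cts: dict[tuple[str, str], list[float]] = {}
    sample_group: dict[str, str] = {}
    for sample, group, tgt, ct in rows:
        cts.setdefault((sample, tgt), []).append(ct)
        sample_group[sample] = group
    mean = {k: sum(v) / len(v) for k, v in cts.items()}
    dct = {}
    for sample in sample_group:
        hk = sum(mean[(sample, h)] for h in hkgs) / len(hkgs)
        dct[sample] = mean[(sample, target)] - hk
    group_dct: dict[str, list[float]] = {}
    for sample, group in sample_group.items():
        group_dct.setdefault(group, []).append(dct[sample])
    gmean = {g: sum(v) / len(v) for g, v in group_dct.items()}
    ref = gmean[reference_group]
    return {g: 2.0 ** -(m - ref) for g, m in gmean.items()}


def brute_force_screen(genes, lost_features, gained_features, its_features,
                       window: int, modulated_mode: str = "union"):
    """Re-evaluate the screen definition by all-pairs distance checks.

    genes: list of (gene_id, chrom, start, end); feature lists of
    (chrom, start, end).  Returns (lost_genes, gained_genes, its_genes,
    final_candidates) as sets of gene ids.
    """
    def gene_set(features):
        return {g for g, _, _ in
                ((gid, fi, gap) for gid, fi, gap in
                 all_pairs_associations(genes, features, window))}

    lost = gene_set(lost_features)
    gained = gene_set(gained_features)
    its = gene_set(its_features)
    modulated = lost | gained if modulated_mode == "union" else lost & gained
    return lost, gained, its, modulated & its
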