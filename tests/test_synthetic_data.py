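import json

import numpy as np
import pytest

from oracles import brute_force_screen

from subteloscreen import synthetic_data as sd
from subteloscreen.its_scanner import (
    INTERSTITIAL,
    TERMINAL,
    ScanConfig,
    classify_arrays,
    scan_arrays,
)
from subteloscreen.peak_differential import compare_conditions


def arrays_as_tuples(arrays):
    return sorted((a.chrom, a.start, a.end, a.strand, a.unit_count, a.array_class)
                  for a in arrays)


class TestMakeGenome:
    def test_scanner_finds_exactly_the_planted_arrays(self):
        asm, truth = sd.make_genome(n_chrom=2, chrom_length=100_000, seed=7)
        found = []
        for seq in asm:
            found.extend(scan_arrays(seq))
        found = classify_arrays(found, asm.chrom_sizes)
        assert arrays_as_tuples(found) == arrays_as_tuples(truth)
        # 2 ITSs and 2 terminal tracts per chromosome
        assert sum(a.array_class == TERMINAL for a in found) == 4
        assert sum(a.array_class == INTERSTITIAL for a in found) == 4

    def test_no_terminal_tracts_leaves_only_interstitial(self):
        asm, truth = sd.make_genome(n_chrom=1, chrom_length=50_000,
                                    terminal_tract_units=0, seed=3)
        found = classify_arrays(
            [a for seq in asm for a in scan_arrays(seq)], asm.chrom_sizes)
        assert found and all(a.array_class == INTERSTITIAL for a in found)

    def test_same_seed_is_byte_identical(self, tmp_path):
        p1, p2 = tmp_path / "a.fa", tmp_path / "b.fa"
        sd.make_genome(n_chrom=2, chrom_length=20_000, seed=5, fasta_path=p1)
        sd.make_genome(n_chrom=2, chrom_length=20_000, seed=5, fasta_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_overlapping_plants_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sd.make_genome(n_chrom=1, chrom_length=10_000,
                           its_spec=[(0.5, 10, 0), (0.502, 10, 0)], seed=1)

    def test_degenerate_plants_found_in_mismatch_mode(self):
        asm, truth = sd.make_genome(
            n_chrom=1, chrom_length=30_000, terminal_tract_units=0,
            its_spec=[(0.4, 8, 2)], seed=13)
        seq = asm["chr1"]
        found = scan_arrays(seq, ScanConfig(max_mismatches_per_unit=1))
        assert len(found) == 1
        a, t = found[0], truth[0]
        assert (a.start, a.end, a.unit_count, a.matched_bases) == \
               (t.start, t.end, t.unit_count, t.matched_bases)
        assert a.purity == pytest.approx(46 / 48)


class TestMakeAnnotation:
    def test_requested_distance_is_exact_by_construction(self):
        from subteloscreen.gene_association import distance_to_telomere

        sizes = {"chr1": 1_000_000}
        genes = sd.make_annotation(
            sizes, genes_per_chrom=10, seed=1,
            placements=[{"gene_id": "SIRT3_LIKE", "chrom": "chr1",
                         "distance": 200_000, "end": "low", "length": 21_000}])
        target = next(g for g in genes if g.gene_id == "SIRT3_LIKE")
        d = distance_to_telomere(target, sizes["chr1"])
        assert (d.distance_bp, d.nearer_end) == (200_000, "low_coordinate")

    def test_high_end_placement(self):
        from subteloscreen.gene_association import distance_to_telomere

        sizes = {"chr1": 10_000_000}
        genes = sd.make_annotation(
            sizes, genes_per_chrom=0, seed=1,
            placements=[{"gene_id": "G", "chrom": "chr1", "distance": 4_000_000,
                         "end": "high"}])
        d = distance_to_telomere(genes[0], sizes["chr1"])
        assert (d.distance_bp, d.nearer_end) == (4_000_000, "high_coordinate")

    def test_genes_do_not_overlap_when_forbidden(self):
        sizes = {"chr1": 300_000}
        genes = sd.make_annotation(sizes, genes_per_chrom=40, seed=2)
        ivs = sorted((g.start, g.end) for g in genes)
        assert all(ivs[i][1] <= ivs[i + 1][0] for i in range(len(ivs) - 1))


class TestMakePeaks:
    def test_composition_recovered_by_comparison(self):
        sizes = {f"chr{i}": 20_000_000 for i in range(1, 4)}
        a, b, truth = sd.make_peaks(sizes, 20, 15, 10, seed=4)
        diff = compare_conditions(a, b)
        assert (len(diff.only_in_A), len(diff.only_in_B),
                len(diff.shared_A), len(diff.shared_B)) == (15, 10, 20, 20)

    def test_zero_counts_give_empty_sets(self):
        sizes = {"chr1": 5_000_000}
        a, b, truth = sd.make_peaks(sizes, 0, 0, 0, seed=4)
        assert len(a) == len(b) == 0
        assert truth == {"shared": [], "only_a": [], "only_b": []}

    def test_determinism_under_seed(self, tmp_path):
        sizes = {"chr1": 20_000_000}
        pa1, pa2 = tmp_path / "a1", tmp_path / "a2"
        sd.make_peaks(sizes, 5, 5, 5, seed=8, path_a=pa1, path_b=tmp_path / "b1")
        sd.make_peaks(sizes, 5, 5, 5, seed=8, path_a=pa2, path_b=tmp_path / "b2")
        assert pa1.read_bytes() == pa2.read_bytes()

    def test_too_many_peaks_for_genome_rejected(self):
        with pytest.raises(ValueError, match="slots"):
            sd.make_peaks({"chr1": 500_000}, 50, 50, 50, seed=1)


class TestMakeCtTable:
    def test_unknown_preset_lists_available(self):
        with pytest.raises(ValueError, match="mtdna_shTERF2"):
            sd.make_ct_table("nope")

    def test_null_preset_without_noise_is_flat(self):
        table, folds = sd.make_ct_table("null", 4, 0.0, seed=6)
        assert folds == {"TARGET": 1.0}
        per_target = table.groupby("target")["ct"].nunique()
        assert (per_target == 1).all()  # no group effect, no noise

    def test_housekeeping_genes_unaffected_by_group(self):
        table, _ = sd.make_ct_table("sirt3_down", 4, 0.0, seed=6)
        hkg = table[table.target.isin(sd.HKG_HUMAN)]
        assert (hkg.groupby("target")["ct"].nunique() == 1).all()
        sirt3 = table[table.target == "SIRT3"].groupby("group")["ct"].mean()
        assert sirt3["shTERF2"] - sirt3["shScramble"] == pytest.approx(1.0)  # -log2(0.5)


class TestScreenFixture:
    def test_truth_is_self_consistent_under_brute_force(self, bundle):
        genes = [(g.gene_id, g.chrom, g.start, g.end) for g in bundle.genes]
        lost = [(iv.chrom, iv.start, iv.end) for iv in bundle.peak_labels["only_a"]]
        gained = [(iv.chrom, iv.start, iv.end) for iv in bundle.peak_labels["only_b"]]
        its = [(a.chrom, a.start, a.end) for a in bundle.its_truth
               if a.array_class == INTERSTITIAL]
        l, g, i, final = brute_force_screen(genes, lost, gained, its, bundle.window)
        assert final == bundle.candidate_truth
        assert l == bundle.lost_gene_truth
        assert g == bundle.gained_gene_truth
        assert i == bundle.its_gene_truth

    def test_default_composition(self, bundle):
        assert len(bundle.genes) == 400
        assert len(bundle.candidate_truth) == 40
        assert len(bundle.decoy_gene_ids) == 40
        assert bundle.ct_planted_folds == {"MT_ND1": 8.0}

    def test_regenerates_identically_under_seed(self, tmp_path, bundle):
        d1, d2 = tmp_path / "f1", tmp_path / "f2"
        sd.make_screen_fixture(seed=0, out_dir=d1)
        sd.make_screen_fixture(seed=0, out_dir=d2)
        for name in ("genome.fa", "genes.gtf", "shScramble.narrowPeak",
                     "trf2oe.narrowPeak", "its_truth.bed", "truth.json",
                     "ct_mtdna.tsv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
        truth = json.loads((d1 / "truth.json").read_text())
        assert set(truth["candidate_truth"]) == bundle.candidate_truth
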