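# subteloscreen

Telomere-binding factors such as TRF2 do not only sit at chromosome ends:
they also occupy interstitial telomeric sequences (ITSs) — tracts of
telomere-like TTAGGG repeats inside chromosome arms — where they can
regulate neighbouring genes, including subtelomeric genes hundreds of
kilobases from the nearest telomere (telomere position effect over long
distances). `subteloscreen` implements the computational screen used to
find such target genes, for anyone with per-condition ChIP-seq peak calls
and a genome annotation:

1. **ITS detection** — scan a genome (FASTA) for maximal tandem arrays of
   a 6-bp telomeric unit (default TTAGGG, both strands, optional spacers
   and per-unit mismatches) and classify each array as a *terminal* tract
   (within a margin of a chromosome end) or *interstitial*.
2. **Differential peaks** — compare whole called peaks between two
   conditions (e.g. factor knockdown vs overexpression): a peak is
   *shared* if it overlaps a peak of the other condition by ≥ `min_overlap`
   bp, otherwise condition-specific (*lost* in the control-only set,
   *gained* in the overexpression-only set).
3. **Gene association** — a gene is associated with a feature (peak or
   ITS) when the gap between the gene body and the feature is ≤ *w*
   (default *w* = 100 kb, inclusive).
4. **Candidate intersection** — with gene sets L (near lost peaks),
   G (near gained peaks) and I (near ≥ 1 ITS), the candidates are
   (L ∪ G) ∩ I (union mode; (L ∩ G) ∩ I available), reported with a
   seven-region Venn partition of L, G, I.
5. **Telomere distance** — d(gene) = min(start, L_chrom − end), the
   quantity that calls a gene subtelomeric.
6. **qPCR quantification** — comparative-Ct readouts used to validate
   candidates: ΔCt = Ct(target) − mean Ct(HKGs), ΔΔCt = ΔCt(group) −
   ΔCt(reference), fold = 2^(−ΔΔCt); and relative mtDNA content
   2^(−(Ct_mito − Ct_nuclear)) normalized to the control-group mean.

A synthetic-data generator (`subteloscreen.synthetic_data`) produces every
input with known ground truth — genomes with planted terminal tracts and
ITSs, annotations with genes at controlled telomere distances, peak files
with a planted shared/lost/gained mix, and replicate Ct tables with
planted folds — so the whole pipeline runs and is testable offline.

## Worked example

Generate the default planted-truth fixture and run the whole screen:

```sh
subteloscreen simulate fixture --seed 0 --out fix
cat > screen.cfg <<EOF
fasta: fix/genome.fa
peaks_a: fix/shScramble.narrowPeak
peaks_b: fix/trf2oe.narrowPeak
genes: fix/genes.gtf
condition_a: shScramble
condition_b: TRF2
EOF
subteloscreen run --config screen.cfg --out out
```

stderr shows the stage log; stdout prints the summary:

```
[subteloscreen] stage=scan elapsed=0.28s arrays=72
[subteloscreen] stage=diff elapsed=0.28s lost=28 gained=28 shared_a=8 shared_b=8
[subteloscreen] stage=screen elapsed=0.31s genes=400 candidates=40
{"arrays": 72, "interstitial": 56, "lost_peaks": 28, "gained_peaks": 28,
 "final_candidates": 40, "venn": [8, 8, 16, 0, 20, 20, 0]}
```

Reading: the scanner found all 72 planted arrays; 16 terminal tracts were
excluded, leaving 56 ITSs. The peak comparison recovered 28 lost and 28
gained peaks. Of 400 genes, 40 are candidates — near a modulated peak
*and* an ITS — matching the generator's planted truth exactly
(`out/report.tsv` lists each candidate with its supporting features and
distances; `out/report.json` holds the gene sets and Venn counts
lost-only=8, gained-only=8, its-only=16, lost∩its=20, gained∩its=20;
`out/manifest.json` records parameters and input hashes).

The qPCR side, on a generated noise-free table:

```sh
subteloscreen simulate ct --preset mtdna_shTERF2 --noise-sd 0 --out ct.tsv
subteloscreen mtdna --table ct.tsv --mito MT_ND1 --nuclear B2M \
    --control shScramble --out mt.tsv
cat mt.tsv
# group	relative_content	sem
shScramble	1	0
shTERF2	8	0
```

— the planted eightfold mitochondrial-DNA increase is recovered exactly
(2³ = 8, i.e. the mito amplicon appears three cycles earlier).

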