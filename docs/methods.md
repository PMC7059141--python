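# Methods

## Coordinate conventions

All in-memory coordinates are 0-based half-open; GTF's 1-based inclusive
convention is converted at the I/O boundary (start−1, end) and back on
writing. Chromosome names are taken verbatim; an explicit alias table
(`--chrom-alias`) maps dialects. Soft-masked bases are kept uppercase in
memory with a per-base mask flag, and N never matches a scan motif base.

## ITS scanning model

There is no community-standard definition of an interstitial telomeric
sequence, so the scanner makes its definition explicit and echoes it into
every output header. A *unit match* at position p is a 6-mer equal to the
motif on the scanned strand (default TTAGGG; the minus strand is scanned
as the reverse complement on forward coordinates), or within
`max_mismatches_per_unit` Hamming distance in degenerate mode. An *array*
is a maximal greedy-leftmost chain of non-overlapping unit matches with
inter-unit gaps ≤ `max_spacer` (default 0, strictly tandem). Defaults:

| parameter | default | why |
|---|---|---|
| motif | TTAGGG | canonical vertebrate telomeric unit |
| min_units | 3 (18 bp) | two tandem units are expected by chance ~180× in a 3-Gb genome per strand; three are expected ~0.01× |
| max_spacer | 0 bp | strictly tandem arrays; spacers admit degenerate satellite |
| max_mismatches_per_unit | 0 | variant repeats opt-in; a degenerate array must still contain ≥1 exact unit to anchor the reading frame and stop drift into G-rich runs |
| terminal_margin | 10 kb | arrays starting within this margin of either sequence end are terminal tracts, not ITSs (strict inequality on both sides) |

Determinism tie-break: when overlapping frames compete (possible only in
degenerate/spacer modes — TTAGGG has no period shorter than 6, so exact
tandem matches cannot overlap), the leftmost-starting maximal array wins
and its consumed matches cannot seed another array. Two consequences,
verified by counterexample and encoded in the property tests rather than
papered over: (i) mirroring a sequence mirrors the scan exactly only in
exact-tandem mode; (ii) raising the mismatch budget preserves every
exact-mode detection as overlap, but a neighbouring degenerate chain may
consume an exact array's first unit and shift its reported boundary by up
to one unit. Exact-tandem mode has neither ambiguity, and the scanner is
equivalence-tested against a brute-force enumeration oracle across modes.

Because detection parameters are a choice, the pipeline alternatively
accepts a precomputed ITS BED (plus a chromosome-size table for
terminal/interstitial classification) in place of a FASTA.

## Differential peaks

The comparison is presence/absence of whole called peaks, not quantitative
re-scoring: peak calling is upstream of this package. A peak of A is
shared iff some peak of B overlaps it by ≥ `min_overlap` bp (default 1 bp,
the weakest faithful reading of "found only in one condition"); peaks are
never split, so the downstream Venn logic operates on whole input peaks.
With A the control and B the overexpression condition, A-only peaks are
*lost* and B-only peaks *gained*. Condition labels are always supplied by
the caller — the tool never infers which file is the control.

## Gene association and the candidate screen

Association is gene-body-to-feature gap ≤ window, inclusive (a feature at
exactly 100,000 bp is associated; at 100,001 bp it is not). Gene body is
the least-assuming anchor; `anchor=tss` (stranded 5′ end, 1-bp interval)
is provided because peak-to-gene rules differ between tools. Genes are
identified by `gene_id`; `gene_name` is annotation only.

The screen derives L (genes near lost peaks), G (near gained peaks) and
I (near ≥1 interstitial array) with the same window, then intersects
modulated genes with I. `modulated_mode=union` (default) treats
either-direction modulation as relevant; `intersection` requires a gene
to sit near both a lost and a gained peak. Passing a terminal array into
the screen is an error, not a warning: a terminal tract would trivially
mark every subtelomeric gene as ITS-associated. Venn region counts are
reported in the fixed order (L-only, G-only, I-only, L∩G-only, L∩I-only,
G∩I-only, triple) and partition L ∪ G ∪ I.

Telomere distance is min(gene.start, chrom_length − gene.end) over the
assembly sequence, ties to the low-coordinate end. On standard human and
mouse assemblies the low-coordinate end is the p-arm telomere; for
scaffolds, unplaced contigs or acrocentric short arms the end labels need
caller interpretation, which is why the report carries the user-declared
assembly identifier rather than assuming a build.

## qPCR quantification

Comparative-Ct with amplification efficiency fixed at 2.0 (the method's
standard assumption; efficiency correction is out of scope). Technical
replicates are averaged (arithmetic mean of Ct) before any normalization.
The multi-housekeeping summary is the arithmetic mean of the three HKG
Cts — the geometric mean of the linear quantities, the standard
multi-reference normalization. ΔΔCt compares group-mean ΔCts to the
reference group, whose fold is therefore exactly 1. Because "average fold
change" is ambiguous (average of per-sample folds vs fold of average
ΔCt), both summaries are emitted; the SEM comes from per-sample folds.
Relative mtDNA content is per-sample 2^(−(Ct_mito − Ct_nuclear)), scaled
so the control-group mean is exactly 1; group means then read directly as
folds versus control.

## Synthetic data: what it emulates and what it does not

The generator is the package's stand-in for the study's deposited inputs.
Every artifact is a pure function of (parameters, seed); a master seed
fans out to fixed per-artifact child seeds.

* **Genome** — i.i.d. bases at configurable GC (default 0.45 for the
  screen fixture, roughly genomic); terminal TTAGGG/CCCTAA tracts with
  the G-strand running 5′→3′ toward each end, as at real telomeres;
  planted ITSs of chosen unit counts, optionally with one substitution in
  some units (the first unit stays exact). Guard bases at array flanks
  prevent chance background extension, keeping the planted coordinates an
  exact scanner oracle. Deliberately absent: repeat families, satellite,
  segmental duplications — so passing the recovery tests shows the
  interval logic is correct, not that ITS detection is robust to real
  repeat noise.
* **Annotation** — non-overlapping genes of 1–5 kb placed uniformly, plus
  genes planted at exact distances from chromosome ends (e.g. a
  SIRT3-like gene 200 kb from a low-coordinate end), so telomere-distance
  values are true by construction.
* **Peaks** — a planted shared/A-only/B-only composition; shared peaks
  overlap across conditions by ≥1 bp, condition-specific peaks sit
  ≥100,001 bp from every peak of the other condition, so any sane overlap
  rule classifies them identically.
* **Screen fixture** — 8 chromosomes × 3 Mb tiled into blocks 250 kb
  apart (isolation well beyond the 100-kb window). Blocks hold one
  scenario each: 40 candidate genes (near a modulated peak *and* an ITS),
  decoy genes at exactly window + 1 bp from those features, genes near
  only one feature class, genes near only a shared peak, filler genes
  near nothing, one gene within the window of a terminal tract only, and
  terminal tracts as decoy arrays — 400 genes in all, 40 of them true
  candidates. The stored truth is re-derived in the tests by an
  independent all-pairs evaluation of the screen definition.
* **Ct tables** — Ct = target baseline + group effect + N(0, sd) per
  technical replicate, sd default 0.2 cycles (typical technical scatter),
  with the group effect −log2(planted fold) and housekeeping targets
  unaffected by group. Presets: `mtdna_shTERF2` plants the eightfold
  mitochondrial-DNA increase on TERF2 knockdown (6 samples/group in
  technical duplicate); `sirt3_down` plants SIRT3 at fold 0.5 — the
  reported decrease is shown only graphically in the source data, so 0.5
  is this package's documented choice — with the other sirtuins and the
  HKGs flat; `null` plants fold 1.

### A note on stochastic fold recovery

With 6 samples/group, duplicate technical replicates and 0.2-cycle noise,
the per-sample mito−nuclear ΔCt has sd 0.2 cycles, giving the estimated
fold a relative sd of ≈8% (the arithmetic-mean and ΔΔCt estimators are
equally affected). A ±10% band is therefore ≈1.2σ and captures ≈79% of
experiments — not ≥95%, which would need sd ≈ 0.12 cycles or ≈16
samples/group. The acceptance suite keeps the stricter ≥95/100 bound as a
red marker of this design's intrinsic noise floor rather than silently
widening the band; the acceptance script reports the measured
per-experiment recovery rate alongside the fold averaged over replicate
simulated experiments, which is accurate to ≈1.6%.

## Problem sizes and numerical choices

Default fixture sizes (8 × 3 Mb genome, 400 genes, 72 arrays, 64 peaks)
were chosen so every planted scenario is represented several times while
a full pipeline run takes under a second. Scanner equivalence is
property-tested on hundreds of seeded sequences up to 50 kb. All
randomness flows through `numpy.random.default_rng` seeded explicitly;
sorting keys (coordinates, then strand; gene ids lexicographic) make
every output order deterministic. Degenerate inputs fail loudly: empty
FASTA, zero-length intervals, start ≥ end (with line number), missing
housekeeping genes (naming sample and gene), unknown chromosomes when a
length table is present, terminal arrays passed to the screen.

## Known limitations

* Presence/absence peak comparison cannot rank partially changed binding;
  quantitative differential binding from read counts is out of scope.
* The ITS definition is parametric by necessity; results should always be
  read together with the scan parameters recorded in the output headers.
* The 100-kb window and the union rule for modulation are defaults with
  explicit alternatives, not discoveries; report metadata records which
  was used.
* Group-comparison hypothesis testing on qPCR folds is deliberately not
  included — folds and dispersions are emitted for external testing.
* Whole-genome runs on real assemblies are bounded by the pure-Python
  chaining step; the vectorized match finding handles tens of megabases
  per second, which is adequate for per-chromosome batch runs.
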