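# Methods

This note documents the models, conventions and parameter choices behind
`paleomito`, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would otherwise have to reverse
engineer from the code.

## The circular reference

Human mtDNA is a 16,569 bp circle with community-standard 1-based inclusive
coordinates and an N placeholder at position 3107. `CircularReference`
models the circle directly: `wrap(length + k) == k`, and read mapping uses
an *elongated* form — the sequence followed by its first 500 bases — so
fragments spanning the origin align contiguously; placements starting in
the elongated tail are canonicalized back onto the circle by subtracting
the genome length. 500 bp comfortably exceeds any read length this package
handles.

The packaged reference is **synthetic**: a random sequence drawn with
rCRS-like base composition (A 30.9%, C 31.3%, G 13.1%, T 24.7%) and the N
placeholder at 3107. It exists so that no download is ever required and so
tests are self-contained; a user-supplied single-record FASTA (e.g. the
real rCRS) is accepted transparently. The packaged locus map is likewise a
simplified gene order (D-loop wrapping the origin, two rRNAs, tRNA
clusters, 13 protein-coding loci) whose intervals tile the circle exactly
once — sufficient for locus classification and per-locus variant-density
summaries, not an annotation resource.

## The read simulator

The generator emulates a gargammel-style simulation of an ancient
single-end library. Its defaults are the benchmark's study conditions:

| parameter | default | meaning |
|---|---|---|
| `endogenous_coverage` | 100 | fold coverage of the endogenous genome (fragment basis) |
| `fragment_length` | 110 bp | fixed fragment size; `min_fragment` 30 bp |
| `read_length` | 101 bp | single-end read, fragment truncated at the 3′ end |
| `contamination_rate` | 0–0.4 | fraction of *total* reads from the contaminant |
| `delta5_max`, `delta3_max` | 0.3 | C>T (5′) / G>A (3′) damage at terminal offset 0 |
| `decay` | 0.5 | geometric decay per base; `window` 12 bp |
| `error_rate` | 1e-3 | uniform substitution error, applied after damage |

Fragment starts are uniform on the circle, strands uniform; the fragment
count is `round(coverage · L / mean_fragment_length)`, so the contaminant
contributes `n_endo · cr / (1 − cr)` fragments and total depth is
`coverage / (1 − cr)`. Damage is applied in the molecule's own 5′→3′
orientation (double-stranded library semantics): the probability of C>T at
5′ offset *i* is `delta5_max · decay^i` for `i < window`, zero beyond, and
symmetrically G>A at the 3′ end; a measured per-position rate table may be
supplied instead of the geometric form. Only C (5′) and G (3′) ever mutate
under damage — G>T depurination transversions are not modelled, which the
test suite exploits as an invariant. Because the read covers only the
first 101 of 110 fragment bases, 3′ damage is mostly invisible in reads —
a realistic property of fixed-length libraries read shorter than the
insert.

Contaminant fragments are *undamaged* (a present-day human contaminant);
NumtS decoy reads derive from the same ancient extract and are damaged.
The contaminant haplotype defaults to the reference itself; heteroplasmy
designs mix a second endogenous haplotype B at a configured fraction, so
sites where the haplotypes differ carry expected AF `f · (1 − cr)`.

Two choices depart from physical realism and are deliberate:

- **Base qualities** are drawn uniformly from {30..34}. The admission
  contract for mapping requires mean base quality ≥ 30 (mirroring an
  upstream trimming step); jittering symmetrically around Q30 would reject
  half of all simulated reads on a coin flip, so the jitter is upward only.
  Reads therefore arrive "pre-trimmed", which is also why no adapters or
  paired-end chemistry are simulated.
- **N placeholders** in the reference are materialized as `A` in every
  simulated source sequence (a physical molecule has a concrete base where
  the reference carries a placeholder). Every simulation consequently
  produces an apparent N>A variant at 3107 with AF ≈ 1 — reproducing the
  known artifact at that site, which the evaluation blacklist removes.

What the generator does **not** emulate: GC or fragmentation-site bias,
platform-specific quality models, indel sequencing errors, UDG-treated
damage profiles, variable fragment-length distributions (supported via a
`length_sampler`, but the benchmark uses the fixed 110 bp design). Passing
tests on these simulations therefore demonstrates correctness of the
pipeline's logic under the stated design, not robustness to every artifact
of real ancient libraries.

## Mapping

The mapper is ungapped and substitution-only: 110 bp aDNA fragments rarely
need gaps, and gapped alignment is out of scope (indel *calls* from
externally supplied SAM/VCF are still handled downstream). Candidate
placements come from a pigeonhole k-mer index (k = 20, `max_mismatch` = 4):
a read split into five disjoint 20-mers must have one exact chunk at any
placement with ≤ 4 substitutions, so the search is provably equivalent to
an exhaustive minimum-mismatch scan within that radius (property-tested
against a brute-force oracle). Reads shorter than `k · (max_mismatch + 1)`
fall back to the exhaustive scan.

Mapping quality is a deliberate convention, not an estimate: 37 for a
unique best placement with < 2 mismatches, 25 for a unique best with ≥ 2,
0 for ties. Only MQ ≥ 30 reaches the caller, so **every base in the pileup
comes from a uniquely placed read with at most one mismatch**. Ambiguity
filtering additionally removes reads whose best placement is on a decoy
(potential NumtS) and, with `delta` > 0, reads whose second-best placement
is within `delta` mismatches of the best; the default `delta = 0` keeps
any unique best hit, and decreasing `delta` never removes more reads.

Duplicates collapse by exact coordinates (target, start, end, strand),
keeping the read with the highest summed base quality (ties: lowest read
index). With fixed-length fragments on a 16.6 kb circle at 100X this
removes a noticeable fraction of reads by birthday collision — the same
behaviour coordinate-based deduplication shows on real high-coverage mtDNA.

The damage profile is estimated on deduplicated *unfiltered* alignments
(before the MQ ≥ 30 selection): conditioning on < 2 mismatches would
censor damaged reads and bias terminal rates downward by ~20%. Rates are
computed in read orientation over reference-C (5′) and reference-G (3′)
sites; zero-denominator offsets are NaN, never 0. Rescaling then lowers
the quality of T-over-C (5′ window) and A-over-G (3′ window) bases to
`floor(−10·log10(d + 10^(−q/10)))` where `d` is the profile rate at that
offset — e.g. q = 30 at d = 0.3 becomes 5 — and never raises a quality.
Since the caller admits bases at quality ≥ 20, rescaling effectively
removes likely-damaged bases (d ≳ 0.009) from the pileup.

## Variant calling and filters

For every non-reference allele with AF ≥ the 5% emission floor the caller
emits a candidate with a log₁₀ likelihood ratio of "allele present at the
plug-in AF̂ = count/DP" against "sequencing errors only", using per-base
error `e = 10^(−q/10)` and `P(specific wrong base) = e/3`; the emission
threshold is lod ≥ 0. The plug-in AF̂ (rather than marginalizing over AF)
keeps the score a transparent two-hypothesis comparison; it is verified to
1e-9 against a direct likelihood evaluation in the tests.

Filter tags are cumulative and a call is PASS iff untagged:

- `low_af`: AF < 0.05 (relevant for ingested external calls);
- `position_bias`: median distance of variant bases from the nearer read
  end < 3;
- `strand_bias`: alt allele present on one strand only *and* two-sided
  Fisher exact test on (alt_fwd, alt_rev, ref_fwd, ref_rev) with
  p < 1e-3 — the single-strand guard keeps well-covered balanced sites
  from being tagged by depth alone;
- `contamination`: AF ≤ CR + 2·√(AF(1−AF)/DP) and AF < 0.5. The AF < 0.5
  guard means a majority allele is never discarded as contaminant — the
  consensus rule inserts AF ≥ 50% alleles regardless of CR;
- `weak_evidence`: lod < 0.

CR is an *input scalar* (in practice an external contamination estimate;
in simulations the true rate is known and can be supplied for correct-CR
experiments). Estimating CR is explicitly out of scope.

## Filter grid, consensus, heteroplasmy

A `FilterPattern` is one row of the benchmarked grid: CR mode
(none/mean/highest), minimum AD ∈ {—, 2, 3, 5, 10}, AF ∈ {5%, 50%},
minimum DP ∈ {—, 3, 4, 5, 10, 20}; an expert mode accepts arbitrary
values. AD and DP are independent thresholds (the conventional pairings
AD2↔DP4, AD3↔DP5, AD5↔DP10, AD10↔DP20 appear in `default_pattern_grid`,
which enumerates 28 distinct patterns). "AF ≥ 0.5" is inclusive; the only
possible SNP tie — two alleles at exactly 0.50 — sends both alleles to the
multiallelic rule, which reports the reference whenever more than one
alternative survives. The consensus writes N only at zero-depth sites and
reports `coverage_pct` separately, so fragmented samples remain
quantifiable; indels are substituted after SNPs in descending position
order to keep reference-based coordinates valid, and overlapping indels
are an error.

Heteroplasmy selection requires AD ≥ 10 *and* RD ≥ 10, where RD counts
reads supporting the reference allele specifically (not DP − AD). AF bins
are half-open on the left except the top bin: [5,10), [10,20), …, [80,90),
[90,100]; sites below 10% are "potential low heteroplasmies" and ≥ 90%
"quasi-homoplasmies". Indel calls are included in profiles and flagged via
a separate `n_indel` count. Ts/Tv returns an undefined sentinel (`None`)
when no transversion is present — division by zero is structurally
impossible.

## Evaluation

`classify_calls` classifies all 16,569 sites exactly once, so
TP + TN + FP + FN always equals the genome length (property-tested). An
allele mismatch at a shared position counts as one FP — counting it as
FP *and* FN would break the conservation identity — and the missed
reference allele is returned in a side report. Exclusion lists model
caller-specific suppression: test-set calls at the blacklist (3107) and
rare-reference-polymorphism positions (1189, 4769, 7028, 8860; the list is
user-extensible) are dropped before classification. Reference-set variants
at excluded positions are dropped from FN accounting under the
real-sample convention (`exclude_reference=True`, the default) but kept as
FN under the simulation-benchmark convention (`exclude_reference=False`),
where the excluded sites are injected truth variants the pipeline is known
never to report. Metric identities FDR = 1 − PPV and FNR = 1 − SN hold
exactly at full precision; rounding (two decimals; FPR/FOR in scientific
notation at 2 and 3 significant digits) happens only at display time.
Aggregate rows are column-wise means/medians over per-sample values, not
recomputed from pooled counts.

## Benchmark designs and problem sizes

Two designs drive the acceptance checks, both at their native scale (the
study design *is* desk scale):

- **Homoplasmic**: 36 SNPs at 100X, fragment 110 / read 101, damage
  0.3/0.5, 2% undamaged contamination, AD10/AF50 retention at CR 0.02.
  Four of the 36 SNPs are placed at the excluded rare-polymorphism
  positions. Expected outcome per seed: FP = 0 and TP = 32; 20 seeds per
  run (~1.5 s each).
- **Mixture**: haplotype B (36 SNPs) at 30% of 100X endogenous coverage
  mixed with the reference haplotype, 2% contamination; expected AF at
  differing sites 0.30 × 0.98 = 0.294. The mean AF over detected true
  sites is measured over 20 seeds.

The mixture design runs **damage off** by default. Under the strict
MQ convention above, a variant-carrying read starts with one mismatch, so
any damage event or error elsewhere in the read removes it from the
pileup, while reference-carrying reads need two extra events; with damage
on this asymmetry depresses the measured minor-allele fraction to ~0.23.
With damage off the remaining asymmetry comes only from sequencing errors
(~9.5% of variant reads vs ~0.5% of reference reads), giving measured AF
≈ 0.27–0.28 — the small residual deficit of the same mechanism. Variant
positions in synthetic haplotypes are drawn with ≥ 300 bp pairwise spacing
(no 110 bp fragment spans two variants, keeping the per-site read-loss
asymmetry independent across sites) and transition-biased alt alleles,
like real mtDNA variation.

## Known limitations

- Ungapped mapping: indel-carrying haplotypes cannot be simulated through
  the mapper (indel calls from external alignments are supported).
- The strand-bias and contamination rules are transparent approximations
  of a learned somatic-caller filter model; no filter-model training.
- The confusion framework attributes indel records to their anchor
  position; multi-nucleotide substitutions are not modelled.
- Consensus-based haplogroup assignment, functional annotation and
  contamination-rate *estimation* are out of scope by design.
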