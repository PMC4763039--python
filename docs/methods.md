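# Methods

## Scope and model

`msapkit` analyses methylation-sensitive amplified polymorphism (MSAP)
data. The observation unit is a presence bit per (locus, sample, enzyme
lane), where the two lanes are *Eco*RI/*Hpa*II and *Eco*RI/*Msp*I digests
of the same DNA. The package covers four analysis stages — band-type
scoring, comparative pattern classification, association testing,
bisulfite context calling — plus a forward simulator that generates data
with known truth for all of them. Gel-image band calling, fragment
cloning/annotation and transcriptome analysis are out of scope; bands
arrive already scored as bits.

## Band-type scoring

Each (locus, sample) cell is scored from its lane bits: (1,1) → type I
(unmethylated), (1,0) → II (hemi-methylated), (0,1) → III (fully
methylated internal cytosine), (0,0) → IV (hyper-methylated) *provided
the locus shows at least one band in some other sample*. A fragment that
never appears in any lane of any sample cannot be scored at all and is
excluded from every denominator; this is why missing cells are hard
errors rather than implicit absences — (0,0) is itself a datum.

Two caveats are inherent to the assay and deliberately not "corrected":

* a (0,0) pattern from restriction-site loss (genetic polymorphism) is
  indistinguishable from hyper-methylation; the scorer calls type IV;
* a hemi-methylated *internal* cytosine is cut by both enzymes and scores
  type I; MSAP cannot resolve it (see the simulator's `HM_int` state).

Percentages (total = II+III+IV, fully = III+IV, hemi = II, each over the
scored total) are carried at full precision; report rendering rounds
half-up to 1 decimal, matching how such tables are printed. Pooling over
samples sums the counts and recomputes percentages from the pooled counts
— percentages are never averaged.

## Comparative pattern classes

A control/treatment pair of lane patterns is one of 16 four-bit tuples
(bit order `(MspI, HpaII)` within each sample — fixed everywhere to
prevent silent transposition), labelled A–P and partitioned into
no-change (A–D, the diagonal), demethylation (E–J, bands gained in the
treatment) and methylation (K–P, bands lost). Swapping control and
treatment exchanges the demethylation and methylation classes pairwise
(E↔K, F↔L, G↔N, H↔M, I↔O, J↔P), which the tests assert as a bijection on
bits. The comparison universe is every locus with ≥1 band in either
member of the pair, plus fully absent pairs whose locus is observed in
some other sample (class D), mirroring the type-IV convention. Group
percentages use the comparison total as denominator.

## Association testing

Association between band-type (or event-group) classification and
condition uses the uncorrected Pearson χ² statistic; no continuity
correction is applied for any table size, since the reference statistics
the fixtures reproduce are uncorrected. All-zero rows/columns are dropped
with the degrees of freedom adjusted and the drop reported (simulated
small matrices can produce empty classes); a table left with fewer than
two informative rows or columns raises rather than returning a
meaningless statistic. The analytic tail probability comes from the χ²
survival function. As a validation oracle the package includes a
Monte-Carlo test that samples tables with both margins fixed (Patefield's
algorithm via `scipy.stats.random_table`), the correct conditional null
for a test of independence; the p-value uses the add-one convention
(1+k)/(1+N). Independent multinomial column sampling is intentionally not
used. No multiple-testing correction or exact test is provided.

## Bisulfite context calling

Contexts are assigned on the top strand only: a cytosine at *i* is CG if
base *i*+1 is G, CHG if *i*+1 ∈ {A,C,T} and *i*+2 is G, CHH if both
downstream bases are in {A,C,T}, and undetermined when the sequence ends
or an N intervenes. Calls compare a bisulfite clone to its unconverted
reference position-by-position (C→C methylated, C→T unmethylated,
anything else ambiguous). Clones are cloned PCR amplicons of a fixed
locus, so the comparison is gap-free over equal-length sequences and no
indel alignment is implemented. Undetermined contexts and ambiguous calls
are excluded from both numerator and denominator of the percentage, with
excluded counts reported; a zero countable denominator raises rather than
dividing silently. Positions are 0-based programmatically (1-based only
in flagged human-readable output). Conversion efficiency is never
estimated from data; it exists as a simulator parameter so its biasing
effect (residual unconverted Cs read as methylated) can be studied.

## Simulator

`simulate_msap` draws a methylation state per (locus, sample) from a
per-sample probability vector over {U, HM_ext, HM_int, FM_int, X},
converts it to lane bits through the isoschizomer sensitivity table
(U→11, HM_ext→10, HM_int→11, FM_int→01, X→00 as (hpa, msp)), then flips
each bit independently with probability `band_noise`. Defaults: the
probability of `HM_int` is 0 in example configurations because the assay
cannot see it — it exists to demonstrate the confound — and `band_noise`
defaults to 0 because no technical-replicate concordance is available to
calibrate an empirical error rate; the noise model (symmetric,
per-lane-independent flips) is the simplest one that exposes scorer
robustness. One integer seed governs everything; per-(locus, sample)
sub-streams are derived from CRC32 hashes of the identifiers, so adding
samples or loci leaves existing draws untouched.

`simulate_bisulfite` builds a random reference of configurable length
(default 300 nt, matching the ~100–300 bp amplicons such experiments
sequence) and GC content (default 0.45), draws a methylated flag per
(sample, classifiable cytosine) with its context's probability (defaults
CG 0.8, CHG 0.3, CHH 0.05 — the usual plant gene-body ordering), and
emits clones in which methylated Cs always read C while unmethylated Cs
convert to T with probability `conversion_efficiency` (default 1.0).
Clones of one sample share the sample's flags — they re-read one molecule
population — so clone-to-clone variation comes only from conversion
failures. The simulator does not model adaptor ligation, PCR selectivity,
fragment-length distributions, co-migration of distinct fragments, or
reverse-strand methylation; passing simulation-based tests therefore
validates the scoring/calling arithmetic, not gel-level artefacts of real
MSAP data.

## Packaged fixtures

Raw gel scorings for the apple chilling study the fixtures derive from
were never deposited, so `msapkit.datasets` ships count-level data: band
type counts per sample (stages DB/ST/GT/FS under high-/low-chill, e.g.
DBH = 444/33/50/83) and comparative class counts per low-vs-high
comparison. `sample_band_matrix` / `comparison_band_matrix` expand counts
into synthetic matrices with exactly those counts so the published
arithmetic is reproduced end-to-end through the matrix-level pipeline;
locus identifiers in those matrices are synthetic. Each expansion adds an
all-present `__anchor__` sample so that fully absent loci stay observable
(type IV / class D). Expansion is per sample (and per comparison) rather
than into one joint matrix: under the shared-universe scoring rule a
single matrix forces every sample to have the same scored total, whereas
the fixture totals differ per sample (610, 602, …) — consistent with
fragments having been scored per primer combination. For the same reason
each printed comparison's total equals the treatment sample's scored
total; the package reproduces the comparison table from its own printed
class counts and documents this rather than guessing an unstated pairing
universe.

Two tabulated p-values differ from full-precision recomputation by
printing artefacts: the dormant-bud tail is 0.3587 (tabulated 0.358) and
the green-tip tail 0.0373 (tabulated 0.03, a 2-decimal truncation). The
tests assert the recomputed values against the tabulated ones at the
tabulated precision.

## Problem sizes and numerical choices

Simulation-based tests use 10⁴ loci for the exact round-trip check,
10⁴ permutations for the Monte-Carlo/analytic agreement (tolerance
3·√(p(1−p)/N) plus discreteness slack), and 200 single-clone samples of a
400 nt locus for per-context probability recovery (tolerance 3 binomial
standard errors) — sizes at which the binomial tolerances are tight
enough to catch sign or off-by-one errors while the whole suite runs in
well under a minute. Percentage rounding is half-up (`decimal`), not
banker's, because that is how the reference tables round. Chi-square on
float-valued tables is rejected unless the values are integral.

## Known limitations

* MSAP resolution: `HM_int` invisibility and the type-IV ambiguity above.
* Top-strand-only bisulfite analysis; no CHG strand-symmetry checks.
* No differential-methylation statistics for bisulfite percentages (the
  upstream analyses report raw percentages only).
* The pipeline treats each matrix as complete; loci scored in one primer
  combination but absent from another must be shipped as separate
  matrices.
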