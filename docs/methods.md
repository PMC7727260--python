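# Methods

## The measurement model

C-to-U editing converts a genomically encoded cytidine to uridine in an
organellar transcript; in cDNA sequencing the edited molecules read T where
the reference has C. At an annotated site the editing efficiency is
estimated as the percentage of edited molecules among informative reads,

    efficiency = 100 · n_T / (n_T + n_C),

which is the maximum-likelihood estimate of the per-molecule editing
probability under binomial sampling of independent cDNA molecules. Bases
other than C or T at the site are sequencing errors with respect to this
dichotomy; they are tallied (`n_other`) but excluded from the denominator,
so an error rate ε only perturbs the estimate at order ε, not ε/efficiency.
Sites with fewer than `min_depth` informative reads (default 10) are
*undefined* rather than zero — a deliberate guard against tiny denominators;
set `min_depth=0` to reproduce unfiltered tables.

## Differential calling

The design compares two mutant libraries against two wild-type libraries.
For each site the four pairwise differences Δ = efficiency(mutant) −
efficiency(WT) are formed (mut1−wt1, mut1−wt2, mut2−wt1, mut2−wt2), in
percentage points. The call is

- **decreased** iff Δ ≤ −10 in all four comparisons,
- **increased** iff Δ ≥ +10 in all four,
- **low_coverage** if any library's efficiency is undefined,
- **unchanged** otherwise.

Boundaries are inclusive (≤/≥). Requiring overlap across all four
comparisons is a replication filter, not a significance test; no test is
applied, matching common practice for deep amplicon data where binomial
standard errors at depth ≥ 1000 are far below the 10 pp threshold.
Mixed-direction sites can satisfy neither all-≤ nor all-≥ and are therefore
unchanged — the natural completion of a rule stated only for the two
consistent directions.

Two further conventions were genuinely open and are fixed here as package
defaults: the *strong reduction* flag (mutant less than half the WT level)
compares each mutant library against the **mean** of the two WT libraries,
with a strict inequality so exactly-half is not flagged; and efficiencies
are written to one decimal place in output tables.

The caller is exposed as a model/results pair (`DifferentialEditing` /
`DifferentialEditingResults`) so that fitted tables, summaries and exports
live on one object; `from_efficiency_table` accepts published per-site
percentage tables when raw counts are unavailable.

## Alignment and pileup

Amplicon reads derive from the same small transcript set they are mapped
back to, so the aligner is gapless: candidate placements come from exact
k-mer seeding (k = 20) of both read orientations against the references,
and each candidate is scored by full mismatch count with a cap
(`max_mismatch` = 5 per 150 bp read). With `max_mismatch + 1` disjoint
seeds, pigeonhole guarantees every placement within the cap has an exact
seed, so the seeded search equals exhaustive scoring of every offset on
both strands — a property the test suite checks against a brute-force
oracle. Ties at distinct loci are *ambiguous* and excluded from pileups,
as are unmapped reads. Intron sequences that are quantification targets
(e.g. *nad4* intron 1) are separate reference entries with intron-local
coordinates. Coordinates are 1-based inclusive on the sense strand;
antisense reads are reverse-complemented before base counting, so pileup
counts are always sense-strand bases.

## Splicing and qPCR arithmetic

Relative expression uses the comparative-Ct convention with amplification
efficiency fixed at 2.0 per cycle (configurable): fold change = 2^−ΔΔCt,
replicate Ct values arithmetically averaged before differencing; replicate
SD is carried in `CtRecord` but does not gate any call. Within-sample
splicing efficiency is the relative abundance of the spliced-junction
amplicon over the intron-retaining amplicon, each normalised to a reference
gene (the reference cancels within a sample but its presence is required);
the reported statistic is the mutant/WT ratio of the two efficiencies, 1.0
meaning unaffected. No significance test is attached to the ratio.

Gene models encode exon/intron topology with each intron labelled cis or
trans. RT-PCR product logic: a primer pair anchored in exons amplifies the
mature transcript always, and the unspliced precursor only when every
spanned intron is cis — a trans intron means the precursor is not a single
contiguous molecule. The packaged *nad1* (trans, cis, trans, trans) and
*nad4* (cis ×3) models therefore predict precursor-silent behaviour for
*nad1* introns 1, 3 and 4 only. Segment lengths in these models are
synthetic placeholders of realistic magnitude; only topology and splice
mode enter any computation.

## Genetics

Segregation tests use the Pearson chi-square goodness-of-fit statistic with
1 df and **no Yates continuity correction**: for the 450:143 allelism
counts against 3:1 the uncorrected statistic (0.248) gives P = 0.6186 →
0.62, whereas the corrected version gives ≈ 0.65; the uncorrected form is
also the one whose null the package's own Monte-Carlo binomial check
reproduces (mid-p convention for the discrete atom at the observed
statistic, which carries probability ≈ 0.03). Point-mutation annotation
places position p in codon ⌈p/3⌉ and translates reference and mutated
codons with the standard genetic code (table 1, correct for plant
mitochondrial protein genes); premature stops report the truncated peptide
length ⌈p/3⌉ − 1.

## The simulator and what it does (not) show

`simulate_editing_reads` draws, per library and transcript, `n_fragments`
full-length cDNA molecules; each molecule is edited at each annotated site
by an independent Bernoulli draw with the configured per-library
probability (no linkage between sites — marginal efficiencies are the only
quantities the analysis consumes). A fragment of uniform length in
300–500 bp (clipped to the template) is cut at a uniform position, one
single-end read of 150 bp (truncated at fragment ends) is taken from a
uniformly chosen strand, and substitution errors are applied i.i.d. at rate
10⁻³, uniform over the three alternative bases. Qualities are constant Q30
and unused. Identical config + seed yields byte-identical FASTQ.

The planted study design used by the tests and the acceptance script scales
the experiment down to tractable size: 50 sites on ten synthetic 200 bp
transcripts (five sites each, placed in the window covered by reads from
either strand so per-site depth equals the fragment count), depth 1000 per
library, WT efficiency 50%, planted shifts of ±30 pp at 24 + 7 sites. At
depth 1000 the binomial standard error is ≈ 1.6 pp, so a ±30 pp shift sits
~12 standard errors past the 10 pp threshold and exact recovery of the
24/7/19 partition across seeds is the expected behaviour, not luck. What
passing these tests does **not** show: robustness to PCR duplication and
amplification bias, indel errors, splice-isoform contamination, linked
editing along single molecules, or real-library coverage heterogeneity —
none of which the generator emulates (and the first four are explicit
non-goals). Read length and layout of the original experiment are not
public; single-end 150 bp is a package default, not an inference.

The qPCR generator writes Ct = baseline − log2(abundance) + N(0, σ²) per
technical replicate with a reference amplicon per sample; the segregation
generator draws mutant counts Binomial(n, fraction). Both exist to
round-trip the downstream arithmetic.

## Numerical and degenerate-input choices

- Thresholds are compared with plain floating-point ≤/≥; efficiencies are
  percentages of integer counts, so 10.0 is exactly representable and the
  inclusive boundary is honoured.
- `editing_percentage` returns `None` (NaN in tables) below `min_depth`;
  a zero WT efficiency makes the strong-reduction flag undefined → False
  with a warning.
- Zero-read libraries produce all-low-coverage call tables, a logged
  warning and a normal exit, not an error.
- The aligner short-circuits mismatch counting at the cap and takes the
  lexicographically first locus for reporting ambiguous hits (the locus of
  an ambiguous read is never consumed downstream).
- Pipeline manifests re-validate read-count telescoping
  (reads in = mapped + ambiguous + unmapped) before being written.

## Problem sizes

The default test-suite and acceptance runs use the scaled design above
(40 000 reads per four-library run; ten independent seeds for the
partition-recovery check; 10⁵ draws for Monte-Carlo comparisons; depth
5000 for estimator-accuracy checks). These sizes were chosen so binomial
noise is negligible relative to every tested margin.
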