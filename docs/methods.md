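# Methods

## Problem and model

A SNP inside a miRNA gene is evaluated for two mechanisms. First, seed
rewiring: canonical animal miRNA targeting is dominated by Watson–Crick
pairing of mature positions 2–8 against the 3'UTR, so a substitution at
those positions replaces the site complement wholesale, while a substitution
at position 1 or 9+ leaves the 6/7/8mer site set provably unchanged (the
test suite asserts this neutrality on random sequences). Second, hairpin
stability: precursor processing depends on the hairpin fold, summarized here
by the minimum free energy (MFE) and the variant-induced change
ΔΔG = MFE(variant) − MFE(reference).

Every SNP is analyzed independently — one variant sequence per SNP, never
combined haplotypes, since phase is not available from site-only VCF
columns. A SNP overlapping two mature products (5p/3p overlap) yields one
record per mature. Multi-allelic VCF records are expanded per alternate
allele; indels are skipped with a logged count.

## Coordinates and strand

GFF3, VCF and the QTL TSV are 1-based inclusive; bedGraph is 0-based
half-open. Internally everything is converted at the I/O boundary and
offsets are reported 1-based within sense-orientation sequences. On the
minus strand the precursor offset is `end − pos + 1` and alleles are
complemented before T→U conversion. The VCF reference allele
(strand-adjusted) must equal the annotated precursor base; a mismatch is an
error by default (`--skip-mismatch` relaxes it to a logged skip), because
silent acceptance hides assembly-version mix-ups.

## Target engine

Site definitions, with S = rc(m2–m8) and S6 = rc(m2–m7): 8mer = S+A,
7mer-m8 = S not followed by A, 7mer-A1 = S6+A with the m8-opposite base not
pairing, 6mer = S6 with neither extension. Sites are maximal per offset (an
8mer is not additionally reported as its nested 7mers), windows containing N
never match, and overlapping sites at different offsets are all reported.
The default policy counts {8mer, 7mer-m8, 7mer-A1} with ≥ 1 site per
transcript; 6mers are reported but not counted, reflecting their marginal
efficacy in the canonical scheme. Both the counted set and the minimum site
count are configuration knobs. The engine is deliberately the seed-match
common denominator of the composite predictors: seed identity is the only
miRNA-side quantity a seed SNP changes, so created/lost/maintained
classification does not require context scoring, and adding it would only
re-rank targets the diff already identifies.

## Folding model

MFE is computed by a Nussinov-style dynamic program over additive per-pair
energies (defaults GC −3, AU −2, GU −1 kcal/mol) with hairpin loops of at
least `min_loop` = 3 unpaired bases and N treated as unpairable. This is not
a nearest-neighbor thermodynamic model: absolute energies are not
comparable to a Turner-parameter folder. The quantity consumed downstream is
the *difference* between two sequences differing at one base, which is
dominated by pairing gained or lost at that base and is captured by the
pair-energy model; the `FoldingBackend` protocol lets callers substitute an
external thermodynamic folder, and the ΔΔG classification is
backend-agnostic. Traceback ties are resolved deterministically (prefer the
left position unpaired, then the smallest partner), so outputs are
byte-stable. The ΔΔG threshold defaults to 2.0 kcal/mol; the boundary value
itself counts as altering, and the cohort summary reports both the
two-sided tally (|ΔΔG| ≥ t) and the one-sided tally (ΔΔG ≥ t) since either
reading of "altering" is defensible. Note that under the default model with
G·U wobble, MFE is *not* invariant under reverse complement (a G·U pair
maps to C·A); invariance holds exactly when wobble pairing carries no
energy, and is tested in that form.

## Genomic context

QTL overlap is judged on the SNP position by default (an interval-tree
containment query, verified against an all-pairs oracle); `--by-precursor`
switches to precursor-interval intersection, since trait tables are often
phrased per miRNA. Conservation lookup takes a non-overlapping bedGraph
track plus an optional coordinate-mapping table (source position → track
position, identity by default) standing in for a cross-species homology
mapping; uncovered positions are reported missing and excluded from class
denominators. Classification is by sign with a 1e−9 neutral band.

## Statistics

Welch's t-test is implemented from the textbook formulas with the
Welch–Satterthwaite degrees of freedom and a two-sided p from the t
distribution; zero-variance degenerate cases return t = 0, p = 1 (equal
means) or an infinite statistic (different means), and an underflowing df
denominator falls back to the pooled df. No multiple-testing correction is
applied across the two reported comparisons (ΔΔG and target-alteration
counts by substitution type); p-values are reported in full precision.
Pooled target proportions aggregate gained/lost/maintained counts over all
seed variants, alongside the per-variant table.

## Synthetic cohorts

The generator emulates the structure, not the scale, of a real cohort:

* **Precursors** are perfect hairpins (5' arm + loop + reverse-complement
  arm; stems 28–34 nt, loops 8–14 nt), so folding tests have constructive
  truth. The 22-nt mature is a substring of the 5' arm. Strand is drawn
  fairly to force strand-handling coverage. Defaults: 50 miRNAs, 1–3 SNVs
  each — desk-scale numbers that keep every acceptance run in seconds.
* **Region classes** are drawn i.i.d. (defaults: 22% seed, 45% mature
  overall), and alternate alleles are uniform over the three non-reference
  bases, giving the neutral 1:2 Ts:Tv expectation used as a calibration
  check.
* **Planted target truth.** UTR backgrounds are scrubbed of every active
  seed 6mer core (reference and variant, all cohort miRNAs), and seed cores
  are kept unique across the cohort, so the only counted sites in the
  database are planted ones. Gains plant the variant allele's site into a
  UTR the reference cannot hit; losses plant the reference site. Seed SNPs
  sharing a mature share its reference sites, so planted losses are
  recorded per mature; when any sibling sits at seed position 8 the plants
  fall back to 7mer-m8 with a non-A tail, because an 8mer there would leave
  the other allele a counted 7mer-A1. Planting rates default to 0.55
  (gain) and 0.5 (loss), putting roughly three quarters of seed variants in
  the altered class. A `noise` flag disables scrubbing for
  realism-oriented statistics at the cost of exact recovery.
* **QTLs** (default 12, 5–50 kb) are placed to contain randomly chosen
  precursors, with trait labels from a cattle-style vocabulary; the
  manifest records every actual (SNP, QTL) containment including
  incidental ones, so recovery checks are exact rather than intended-only.
* **Conservation** plants a positive score (0.5–5) with probability 0.86
  and a negative one otherwise, one single-base bedGraph interval per SNP
  locus.

What the fixtures deliberately lack: realistic chromosome sizes, linkage
and allele-frequency structure, imperfect hairpins (bulges, internal
loops), 3'-supplementary pairing, overlapping mature products, and
UTR base composition bias. Passing the planted-truth tests therefore
demonstrates the correctness of the pipeline's bookkeeping — coordinates,
strand handling, set algebra, thresholds — not predictive accuracy on real
transcriptomes. Because every variant sits in a perfect stem or loop, the
fraction of |ΔΔG| ≥ 2 calls on synthetic cohorts (~75–80%) is higher than
one should expect on natural, imperfect hairpins.

## Numerical and reproducibility choices

All randomness flows from a single integer seed through one `numpy`
Generator; a fixed seed yields byte-identical files (checked by SHA-256 in
the tests). Numeric TSV columns are printed with six significant digits.
Energies are small integer multiples of 1.0 in floating point, so DP
tie-break comparisons are exact. Acceptance-style statistical checks use
99% binomial intervals around their analytic expectations (type-I error of
the Welch test over 200 null replicates at n = 100/group; transition
fraction over ≥ 3000 simulated SNVs; conservation fraction over 500 loci).

## Known limitations

The energy model ignores stacking, dangles and loop-size penalties, so
absolute MFE values are not thermodynamic; only signs and differences are
meaningful. Target prediction is presence/absence, with no site-efficacy
scoring and no mRNA-side variants. The loop/star-region SNPs that overlap
no mature product are counted as `precursor_only` and reported separately,
since their contribution to mature-miRNA counts is ambiguous in public
annotation dumps.
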