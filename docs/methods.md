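# Methods

This note records the models, conventions and numerical choices behind
`transchar`, and what the synthetic-data tests do and do not establish
about behaviour on real assemblies.

## ORF calling

Transcripts are scanned in all six frames (a forward-only switch exists
for assemblies of known orientation). A candidate ORF runs from an `ATG`
to the first in-frame stop codon, or to the sequence end when no stop is
reached — assembled transcripts are frequently fragments, and unknown
(`N`-masked) 3′ ends can hide stop codons. Any codon containing a base
outside `{A,C,G,T}` translates to `X` and never terminates the frame:
zero-coverage consensus positions must not be allowed to truncate or
split frames.

The qualifying threshold (default 20 aa) applies to the *effective*
length, i.e. residues excluding `X`; the reported residue count `n_aa`
keeps `X`. A `count_x` switch applies the threshold to all residues for
sensitivity analysis. Among qualifying candidates the call with maximal
`n_aa` wins; ties break deterministically to forward strand, then lower
frame index, then the leftmost start on the scanned strand. Coordinates
are 0-based half-open on the forward transcript strand, with the stop
codon excluded from the coding span (BED-compatible). UTRs are defined in
reading orientation: 5′UTR before the start codon, 3′UTR after the stop
codon; for reverse-strand calls the 5′UTR therefore sits at the
transcript's high-coordinate end.

## SSR scanning

A microsatellite is a maximal perfect run of a primitive 2–4 bp motif
with at least five complete units. Conventions:

* runs are attributed to their smallest period only — `(AT)6` is a
  dinucleotide locus, never `(ATAT)3` — keeping period-class tallies
  disjoint;
* `N` terminates any run ("perfect" forbids unconfirmed bases);
* the reported interval is the maximal run including a trailing partial
  unit; the unit count is the floor of run length over period;
* within a period class the scan is left-to-right greedy: a reported run
  consumes its interval and the scan resumes past its end, so same-period
  loci never overlap. (A purely alignment-maximal convention would let
  two adjacent runs share the base where one run's trailing partial unit
  starts the next run.)
* two same-period runs separated by even one non-repeat base are distinct
  loci; no compound or interrupted-repeat merging is attempted.

Motif classes are canonicalized as the lexicographic minimum over all
rotations of the motif and of its reverse complement, so complementary
strand scans produce identical class tallies.

## Context classification

Each SSR on an ORF-bearing transcript receives exactly one label. The
coding span for containment is `[start, end)`; the stop codon's three
bases belong to neither the coding span nor — for demotion purposes — the
3′UTR, so a repeat touching only the stop codon and downstream sequence
is a UTR3 locus. A repeat overlapping the coding span and extending
upstream of the start (in reading orientation) is STRADDLE5; extending
past the end, STRADDLE3. For the pathological case of a repeat crossing
both boundaries of a very short ORF, the 5′ label takes precedence; this
is a determinism choice for a vanishingly rare configuration.

Amino-acid homopolymers are maximal single-residue runs in ORF
translations, with `X` runs excluded. The minimum run length is a free
parameter defaulting to 5 residues, mirroring the nucleotide-repeat unit
threshold; composition tables report each residue's share of all runs in
the chosen ORF subset.

## Enrichment statistics

Term enrichment between two ORF sets uses the one-sided (greater) Fisher
exact test — the hypergeometric upper tail — because only
over-representation is of interest; under-representation is deliberately
not tested. A two-sided switch exists for comparisons where the original
tool's convention is unknown. The ORF universe of each set is its
distinct annotated ORFs; duplicate (orf, term) pairs are dropped with a
warning; terms present in only one set are still tested (the exact test
needs no continuity handling for zero cells). Multiple testing is
controlled by Benjamini–Hochberg step-up adjustment at α = 0.05
(`statsmodels` provides the adjustment behind `bh_adjust`).

A note on BH fixed points: textbook BH is not idempotent —
`bh([0.01, 0.04, 0.03]) = [0.03, 0.04, 0.04]`, but re-adjusting that
output yields `[0.04, 0.04, 0.04]`. Only constant vectors are fixed
points (at any fixed point `q_(i) = min(m q_(i)/i, q_(i+1))` with
`m/i > 1` forces `q_(i) = q_(i+1)`). The property tests therefore assert
the step-up definition, rank monotonicity and constant-vector fixed
points rather than general idempotence.

For SSR-bearing ORF enrichment, the target set per motif class is the
annotated ORFs carrying that repeat class inside the coding span and the
background is all remaining annotated ORFs; non-annotated ORFs are
excluded from both sides, matching the use of annotated ORFs only.

## Selection-screen statistics

Only the decision layer is implemented; clustering, alignment and codon
model fitting are consumed as inputs. Single-copy core clusters are those
with exactly one member per requested species and no others. Alignment
columns with posterior probability < 0.6 are removed; an alignment is
discarded when strictly more than 50 % of its columns are removed, so an
exactly-half-filtered alignment is kept. The LRT statistic
2(lnL_alt − lnL_null) is floored at zero (negative values are optimizer
noise and trigger a warning) and referred to χ²(1); a 50:50 point-mass /
χ²(1) mixture — sometimes preferred for boundary nulls in codeml
practice — is available as a switch but is not the default, since the
plain χ²(1) reference is the stated procedure. Gene selection reuses the
BH machinery; BY or q-value variants were considered out of scope, BH
being the standard reading of a generic FDR procedure at 0.05.

## Synthetic data: what it emulates and what it does not

The generator emulates transcript-like contigs: i.i.d. background bases
at configurable GC (default 45 %, typical of vertebrate transcriptomes),
0.3–1.5 kb lengths, a planted forward- (optionally reverse-) strand ORF
of 30–150 codons in half the transcripts, planted repeats in controlled
regions, and Poisson-placed `N` runs (0.2/kb, 2–15 bp) emulating
zero-coverage consensus sites. Sizes were chosen once as realistic
mid-range contig conditions; the 1,000-transcript cohort used for
recovery measurements keeps a full characterization run in seconds.

Guards keep the planted truth exact rather than approximate:

* flank bases that would extend a planted repeat are resampled, and
  cohort transcripts are redrawn if any incidental ≥ 5-unit repeat
  appears (a switch disables this for realism studies);
* competitor ORFs at least as long as the planted one are mutated away —
  preferentially by breaking their start codon, otherwise by inserting a
  stop into their frame — without touching planted start/stop codons or
  repeats, and keeping planted in-frame codons sense codons;
* non-coding transcripts are generated free of ATG/CAT trigrams outside
  the planted repeat, which guarantees no qualifying ORF on either
  strand; rejection-sampling ORFs away is infeasible because essentially
  every random kb-scale sequence contains a ≥ 20 aa ORF. NONCODING plan
  entries whose repeat contains ATG or CAT are rejected as configuration
  errors;
* straddling repeats are co-designed with the ORF boundary: the repeat's
  trailing bases supply a prefix of the start codon (5′ straddle) or of a
  stop codon (3′ straddle), with rotation/overlap chosen by a
  deterministic feasibility search; infeasible motif/region combinations
  raise configuration errors;
* `N` runs avoid planted repeats and start/stop codons.

The guard checks use the package's own scanners, so planted-truth
recovery tests the generator↔scanner contract; scanner correctness is
established independently by brute-force oracle equivalence tests.
Passing recovery tests therefore shows the pipeline is internally exact,
not that the i.i.d. background reproduces real transcriptome base
composition, codon usage, isoform structure, or assembly artifacts other
than `N` masking. Annotation tables assign a designated term with
separate probabilities inside and outside a target subset (default: the
ORFs carrying a planted trinucleotide repeat in the coding span),
independently per ORF, plus independent background terms.

All generation is driven by one `numpy` Generator stream seeded from the
configuration; a fixed seed yields byte-identical FASTA and truth tables.

## Numerical choices

* Fisher p-values come from `scipy.stats.fisher_exact`; tests pin them to
  exact rational enumeration within 1e-12 for all tables with total ≤ 25.
* χ² tails come from `scipy.stats.chi2.sf`.
* Log-likelihood differences more negative than −1e-8 warn before
  flooring; smaller ones floor silently.
* Proportions are kept at full precision in memory; report TSVs format
  floats at 6 significant digits.
* Degenerate inputs: empty SSR catalogs summarize to empty tables (not
  errors); empty ORF collections and empty posterior vectors are errors;
  an empty enrichment target set yields an empty result with a warning.

## Known limitations

* Only the longest ORF per transcript is characterized, matching the
  study design; polycistronic or multi-ORF transcripts are out of scope.
* Mononucleotide repeats, periods > 4, and imperfect/compound repeats are
  out of scope.
* The exact tie-breaking of the original repeat-finding and ORF tools is
  undocumented; where conventions were open (tie order, partial-unit
  inclusion, greedy non-overlap) this package fixes them explicitly as
  documented above, so counts on real data may differ marginally from
  other tools' output.
* The homopolymer minimum run length has no published reference value;
  results for that analysis should always state the threshold used.
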