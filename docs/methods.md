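# Methods

This note documents the models and procedures paralogsift implements, the
defaults it ships with, and what its simulation-based tests do and do not
demonstrate.

## Locus mapping

A multi-copy gene family appears in a genome-vs-mRNA local-alignment search
as runs of exon-sized hits separated by intronic gaps, with much larger
gaps between copies. Clustering is single-linkage along the subject axis:
hits are sorted by start and a new copy opens whenever the gap to the
previous hit's end exceeds `max_gap`. The default `max_gap` of 10,000 bp
sits an order of magnitude above typical intronic gaps in a compact
three-exon gene (~0.3–2.1 kb here) and well below inter-copy gaps
(~20 kb and up), so the clustering is insensitive to the exact value over
a wide range. Copy orientation is the majority hit strand; an exact tie is
resolved to "+" with a warning rather than silently. Coordinates are
1-based inclusive everywhere in the API; conversion to 0-based half-open
happens only when writing BED.

The module deliberately reports exons in chromosome order and does not
assign mRNA exon numbers for reverse-orientation copies: hit tables alone
do not establish which hit carries which exon, and guessing would encode an
assumption the data cannot support.

## Consensus and signature model

Replicate sequences (e.g. duplicate amplicons from many animals) are
reduced to a consensus column by column: a base reaching the
`ambiguity_threshold` fraction (default 0.75) of non-gap observations is
called outright; otherwise the minimal IUPAC code covering every base with
frequency above 1 − threshold is emitted. The 0.75 default is chosen so a
genuine two-allele polymorphism near 50/50 — like a C/A signature base
segregating in a population — surfaces as an ambiguity code instead of an
arbitrary majority pick.

A signature scheme is an ordered set of alignment columns plus one allele
*set* per copy per column (sets, so polymorphic signature bases are
representable). Validity requires every copy pair to have disjoint allele
sets in at least one column. Discovery is exhaustive over subsets of the
variable columns in increasing size, returning the smallest set (ties:
lexicographically smallest positions). Exhaustive search is exact and cheap
at the scale this problem has (a few hundred cDNA columns, a handful of
copies); no heuristic is needed.

Classification reads the bases at the signature columns (an explicit
integer offset or callable maps cDNA coordinates onto the read — the
mapping is input, never inferred) and assigns the unique copy whose allele
sets are violated at most `tolerance` times and strictly less often than
every other copy. The default tolerance is 0 — an exact signature match —
and ties are UNCLASSIFIED, never arbitrarily assigned. This mirrors how
single-molecule Sanger traces are scored by eye and keeps the false
assignment rate at zero cost to sensitivity when reads are clean.

Codon-consequence annotation compares equal-length coding sequences codon
by codon from the annotated start and labels each difference synonymous,
missense, stop_gained or stop_lost. Isoelectric points solve
Henderson–Hasselbalch net charge = 0 by bisection on pH ∈ [0, 14] (the
charge function is strictly decreasing, so the root is unique); the pKa
table defaults to the EMBOSS values, selectable by name, since predicted pI
depends materially on the scale chosen.

## Assay design

Primer sites are scanned on both strands with IUPAC-degenerate primer bases
matching any template base in their set; templates are concrete ACGT (the
degenerate positions in real primer sets live in the primers, not the
templates). The final `three_prime_exact` bases (default 3) must match
exactly, reflecting that 3'-terminal mismatches abolish extension. In-silico
PCR pairs every plus-strand forward site with every downstream minus-strand
reverse site, spanning the two primers' 5' ends inclusive.

Copy-specificity of a primer is the count of primer-covered alignment
columns where the target copy's base differs from *every* other copy; the
assay passes at ≥3 unique bases, the anchoring rule used when designing
copy-specific primers against near-identical paralogs.

Digestion scans the top strand for exact recognition sites and cuts after
`cut_offset` bases (HindIII: A^AGCTT, offset 1); fragments always partition
the template. Only palindromic enzymes are bundled, so top-strand scanning
is complete. Two fragment fingerprints are gel-discriminable when at least
one fragment of either set has no counterpart in the other within
`gel_resolution` relative length (default 5%, typical for agarose run by
eye). Printed gel sizes are estimates: sequence-level fragments must sum
exactly to the template length, but gel-read sizes need not, and the
package never validates gel estimates by summation.

## EPLD quantification

The limiting-dilution model assumes templates are distributed over
reactions as Poisson(λ), so P(positive) = 1 − e^(−λ). The limiting dilution
is the *highest* concentration with a positive fraction strictly below
50% ("less than 50%" is strict: exactly half does not qualify). From the
positive fraction p̂ at that dilution, λ̂ = −ln(1 − p̂), and
P(single template | positive) = λ̂e^(−λ̂)/(1 − e^(−λ̂)) (limit 1 as λ̂ → 0).
A fully positive plate leaves λ undefined and raises rather than reporting
a pseudo-estimate. Efficiency is simply positives/total, reported both as a
fraction and as the rounded integer percent used in print.

Proportions of classified amplicons are counts/total with per-copy Wilson
score intervals (copy-vs-rest binomial). Wilson rather than Wald because
counts are small and proportions can sit near 0 or 1, where Wald intervals
degenerate. An optional multi-template correction (dividing counts by the
single-template probability before renormalizing) is exposed but off by
default: under the uniform-template-pick readout model it cancels exactly,
and the default analysis applies no correction.

Note that λ̂ = −ln(1 − p̂) is convex in p̂, so it carries a small upward
finite-sample (Jensen) bias of order p/(2n(1−p)) — about 0.02 at λ = 1.5 on
a 96-well plate. The calibration tests account for this by comparing
Monte-Carlo means against the estimator's exact finite-sample expectation
(enumerated over the binomial well-count distribution) and by checking
recovery of λ itself on pooled counts, where the bias is negligible.

## Expression quantification

Densitometry: relative OD is band/reference; categories are high (> 0.50),
low (0.01–0.50, the boundary 0.50 inclusive), absent (not detected or
< 0.01). Categorization operates per sample; ranges across animals are not
modeled.

qPCR standard curves are ordinary least squares of Cq on log10
concentration over the calibrator series (defaults 100, 10, 1, 0.1, 0.01,
0.001 ng/µL); the slope must be negative, amplification efficiency is
10^(−1/slope) − 1. Unknowns average replicate Cq values (triplicates by
convention) *before* inversion — the same rule applied to calibrator
crossing points. Normalization divides by the geometric mean of the
reference-gene quantities (GAPDH and 18S by default), the standard
multi-reference convention; the package records explicitly that this factor
cancels in the SCGB1A1A/SCGB1A1 ratio, which is therefore invariant to any
common rescaling of the references. Group dispersion is reported as SD (not
SEM), and the group test is the unpaired pooled Student's t by default with
Welch available by flag; both accept raw ratios or (mean, SD, n) summaries
and give identical statistics on equivalent input.

## Synthetic data: what it emulates and what it does not

The generators default to the study's own scale: three copies with exons of
55/194/34 bp and introns of 2,066/298 bp (a 2,647 bp gene body), inter-copy
gaps of 19,703 and 483,631 bp, orientations −/−/+, and pairwise cDNA
distances of exactly 9 including planted signature columns (one
odd-one-out column per copy, the structure real signatures had); amplicon
reads carry i.i.d. substitution error, uniform over the three alternative
bases; EPLD wells draw Poisson template counts and report one uniformly
picked template label per positive well; Cq values are linear in log10
concentration with Gaussian noise (ideal slope −1/log10 2 ≈ −3.32,
intercept 20 Cq, calibrators at the series above, triplicates). The
two-cohort expression generator uses true ratios 2.4 (control, n = 9) and
5.1 (affected, n = 5) with 0.2 Cq measurement noise. Every generator takes
a mandatory seed and one numpy Generator stream, so outputs are
byte-reproducible.

Deliberately not modeled: insertions/deletions (not observed between these
copies), chimeric amplicons, amplification bias between paralogs,
chromatogram-level artifacts, per-animal biological variance in the cohort
generator (only Cq noise enters), and trace quality. Consequently, passing
tests demonstrate the *estimators and classifiers are correct under the
stated model* — they do not demonstrate robustness to chimeras, primer
bias, or inter-individual variation, which real experiments must control
upstream.

## Numerical and degenerate-input choices

* Saturated EPLD plates, all-gap consensus columns, indistinguishable
  copies, flat standard curves, and single-observation groups all raise
  with specific messages instead of returning degenerate numbers.
* Consensus ties within a column break deterministically by base order;
  classification ties are UNCLASSIFIED.
* pI bisection runs an order of magnitude past the reported 0.01 pH
  resolution before rounding, so reported values agree with a fine
  pH-grid search within 0.01.
* Percent values are rounded to integers where print convention demands it,
  but full-precision values are always retained in returned objects.
* Workflow runs are pure functions of (inputs, config, seed); reruns are
  byte-identical, and all intermediates (FASTA, plate CSV, classification
  CSV, curve diagnostics) are written for stage-by-stage inspection.

## Problem sizes used in the test suite

The statistical tests run at sizes chosen to make their Monte-Carlo error
small relative to the tested effect while completing in seconds: 10,000
reads for exact-classification checks, 500 plates of 96 wells per λ for
Poisson calibration, 500 simulated experiments of 100 amplicons for
interval coverage, 1,000 plates for positive-fraction calibration, and 200
end-to-end cohort runs for power. Coverage and bias statements are
additionally verified by exact enumeration over the relevant binomial
distributions, which removes seed dependence from the property itself.

## Known limitations

* The aligner provided is a plain Needleman–Wunsch pairwise aligner
  (match 1, mismatch −2, gap −2) intended for the short, nearly identical
  sequences this workflow sees; it is not a general multiple-alignment
  engine.
* Restriction digestion supports non-degenerate palindromic sites only.
* Signature discovery is exact but exponential in the number of candidate
  columns; it targets small alignments (hundreds of columns), not genomes.
* The EPLD estimator uses a single dilution; a joint most-probable-number
  estimate across dilutions is out of scope.
* Genomic pairwise-identity figures over arbitrary flanking-region
  extracts depend entirely on the extraction boundaries chosen and are not
  reproducible from hit tables alone; the identity statistics here apply to
  explicit alignments given to them.
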