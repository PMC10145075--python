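# Methods

## Genotype model and encoding

All analyses operate on diploid biallelic SNP genotype *classes*:
reference homozygote, heterozygote, alternate homozygote, or missing.
Phase is discarded on VCF read (`0|1` ≡ `0/1`) and half-calls (`./1`) are
treated as missing — the conservative convention, matching depth-masked
call sets. Multi-allelic and indel records are skipped (or rejected on
request); the package never emits a genotype code outside this four-value
alphabet.

## Per-locus statistics

With genotype-class counts (n_RR, n_RA, n_AA) over n called samples and
alt-allele frequency p = (n_RA + 2·n_AA)/(2n):

- MAF = min(p, 1−p); missing rate = fraction of uncalled samples
  (computed as n_missing/n_total so decimal boundaries are exact);
- Ho = n_RA / n (observed heterozygosity);
- GD = 1 − Σ f_i² (gene diversity / expected heterozygosity);
- PIC = 1 − Σ f_i² − Σ_{i<j} 2 f_i² f_j² (Botstein informativeness).

GD and PIC are offered in two conventions: **allele** (f over the two
allele frequencies; maxima 0.5 and 0.375) and **genotype** (f over the
three genotype-class frequencies among called samples; maxima 2/3 and
≈0.593). Published tea-tree panel tables report GD up to 0.54 and PIC up
to 0.44 — above the biallelic allele-based ceilings — which only the
genotype-class convention can reach, while the genome-wide summary ranges
(PIC ≤ 0.375, GD ≤ 0.5) match the allele convention. Both are therefore
computed; the allele convention is the default used for filtering and
tie-breaking. Missing genotypes are excluded from every denominator, and
a locus with no called genotypes propagates flagged NaN statistics, never
zeros.

## Core-SNP filtering

Stage one (candidates): MAF > 0.1 (strict), missing rate < 0.20 (strict),
and no other variant within 150 bp on the same chromosome. The flanking
rule is operationalised on the call set itself — a locus is dropped when
any other *called* variant lies within the window (both members of a close
pair fall); true flanking invariance would need the underlying reads,
which the package does not consume. Stage two (core): MAF > 0.15
(strict), missing rate ≤ 0.05 (inclusive), PIC > 0.15 (strict). The
inequality directions follow the thresholds' published typography and are
asserted at the boundaries in the test suite.

"Uniform genome coverage" has no published procedure, only resulting
per-chromosome counts; it is implemented as optional fixed-width binning
per chromosome keeping the single highest-PIC SNP per bin (ties by locus
id). Bin width is a configuration knob (`bin_width`, base pairs,
default off). A core set smaller than `min_core_size` (default 300)
warns rather than fails, since cohort size governs what is attainable.

## Genetic similarity and EDV classification

GS(a, b) = NS/(NS + ND) over loci called in both samples
(pairwise-complete deletion; the published method does not state its
missing-data rule, and this matches the NTSYSpc convention). Genotype
classes are compared exactly: heterozygote vs homozygote counts as
different. A pair with no co-called loci has undefined GS and is flagged.
The all-pairs matrix is computed with genotype-class indicator matrix
products, exact in float64 for any realistic locus count.

Classification uses two thresholds: GS > 0.9 (strict) → *putative*
derivation (the ISF recommendation); GS ≥ threshold_ind → *indisputable*.
threshold_ind is calibrated from same-variety positive-control pairs as
floor(min control GS × 100)/100 — the tail principle; the raw minimum is
also reported. Within a classified pair, roles are assigned only when
both registration years are known and unequal (earlier = IV, later = EDV);
landrace or equal-year pairs stay `unresolved` rather than guessing. For
"non-EDV" sample sets, the designated EDV member of each pair is
excluded; in unresolved pairs the lexicographically later id is excluded
so exactly one member of every derived pair drops out.

## Core-variety (backbone) selection

Within each population, each sample's kinship rank is its total count of
differential genotype classes against the other members (the ND of the
similarity stage; missing treated as null). Smaller totals = closer to
the population centre. The top `fraction` (default 20%) of the
population, by ascending total with lexicographic tie-break, is selected
after dropping samples with admixture membership < 0.8 ("extremely
admixed", per the structure-analysis convention). A selected candidate
that is the EDV of an already-selected IV, one member of an unresolved
indisputable pair with a selected sample, or the offspring of a selected
parent, is skipped and replaced by the next rank, iterating until the
quota fills or candidates run out.

The 20% quota is computed on the full labelled population size with
configurable rounding (`half_up` default, `floor`, `ceil`) because the
published per-population quotas (32/159, 14/72, 10/51, 10/50, 4/17) are
not reproduced by any single standard rule — 4/17 in particular matches
ceiling while the others match half-up; the discrepancy is recorded, not
resolved. The mean differential count (total/(n−1)) is reported alongside
the total; with uniform MCAR missingness the two orderings agree.

## Minimal identification panels

A panel distinguishes a pair when some panel locus is co-called with
different genotype classes; missing data never distinguishes (fingerprint
blanks are uninformative). Selection is greedy forward search: each step
adds the locus distinguishing the most still-undistinguished pairs, ties
broken by higher PIC then lexicographic locus id (the last tie-break is a
determinism choice; the published procedure is silent). Termination: when
panel discernibility reaches that of the full candidate set — asserted on
every run — so clonal duplicates, invisible to any panel, are reported as
indistinguishable pairs rather than stalling the search. On every random
instance small enough for exhaustive subset search (≤12 samples × ≤10
loci, 200 instances in the acceptance suite) the greedy optimum equals
the global maximum. The "non-EDV" panel variant reruns the search with
the discrimination target restricted to samples not flagged as derived.

Fingerprints are per-sample strings over the panel: `0` = reference
homozygote (XX), `1` = heterozygote (XY), `2` = alternate homozygote
(YY), `N` = missing.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with defaults mirroring a five-population tea-germplasm cohort:

| parameter | default | meaning |
|---|---|---|
| pop_sizes | 159, 72, 51, 50, 17 | samples per population (total 349) |
| n_loci / n_chromosomes | 1000 / 15 | SNPs and their chromosomes |
| fst | 0.15 | Balding–Nichols differentiation |
| admixed_fraction | 0.06 | samples drawing from two populations (≈21 of 349) |
| edv_pairs / edv_mutation_rate | 12 / 0.02 | clone pairs and per-locus change rate |
| control_pairs / control_mutation_rate | 6 / 0.01 | same-variety duplicates |
| miss_rate | 0.02 | MCAR missingness |
| n_close_loci / min_spacing | 10 / 400 bp | loci exercising the flanking filter |

Mechanics: ancestral allele frequencies ~ Uniform(0.05, 0.95); population
frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F); founders Binomial(2, p_pop)
per locus (Hardy–Weinberg within populations); admixed samples draw from
the 50/50 mean of two populations' frequencies and get membership
coefficients in (0.4, 0.6) versus (0.85, 0.99) for founders. Clones copy
a same-population founder, resampling each locus to a *different*
genotype class with the stated probability — class-level rather than
allele-level mutation, because GS operates on genotype classes. Derived
clones receive registration years later than their parents; control
copies are labelled landraces sharing a `control_group`. With a 2% clone
mutation rate over 1000 loci, E[GS] = 0.98 with standard error ≈ 0.0045,
so every clone pair clears the 0.9 putative threshold by a wide margin
while cross-founder similarities stay far below it — the basis of the
parameter-recovery acceptance checks.

What the generator does **not** emulate: linkage disequilibrium,
realistic chromosome lengths or marker spacing, pedigree depth beyond one
clonal generation, informative (non-MCAR) missingness, genotyping error
in non-clone samples, and selection. Passing tests therefore demonstrate
the pipeline's correctness under its stated model, not robustness to
these real-data features.

All randomness flows from a single root seed through one generator
stream; identical configurations give byte-identical outputs, and the
pipeline itself is a pure function of (inputs, configuration).

## Problem sizes and numerical choices

The default test cohort (349 × 1000) runs the full pipeline, including
panel selection, in about a second; the acceptance suite's exhaustive
panel oracle enumerates all locus subsets via pair-bitmask dynamic
programming. Threshold flooring rounds to 9 decimals before taking the
floor so that a control minimum stored as 0.96999… still floors to 0.97.
Missing rates are computed as integer-count ratios so inclusive decimal
boundaries (e.g. exactly 5%) compare exactly. Degenerate inputs
(all-missing loci, populations emptied by exclusions, clone-only cohorts,
empty core sets) yield flagged values or warnings, never silent zeros or
crashes.

## Known limitations

- The flanking-uniqueness rule sees only called variants, not raw
  sequence; sites with unsequenced flanking variation pass.
- The greedy panel is not guaranteed minimal in general (only verified
  optimal-size on exhaustively searchable instances); set-cover ILP is out
  of scope.
- EDV classification is similarity-only; it does not use pedigree
  likelihoods or morphology and cannot orient pairs without registration
  years.
- GS thresholds are crop- and marker-set-specific; the calibrated value
  transfers only to cohorts genotyped on a comparable marker set.
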