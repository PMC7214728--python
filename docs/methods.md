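# Methods

## Coordinates and genetic maps

All intervals are 0-based half-open internally; GFF3 (1-based inclusive)
is converted at the parsing boundary, which keeps arm/amplicon arithmetic
free of off-by-one corrections. A genetic map is a per-chromosome list of
(bp, cM) anchors with strictly increasing bp and non-decreasing cM.
Conversion is piecewise-linear between anchors. Two deliberate departures
from a naive interpolator:

* **Extrapolation, not errors, beyond terminal anchors.** Telomeric
  regions are legitimate CTL territory, and marker-predicted positions
  routinely fall outside the anchored span. Queries beyond the ends use
  the terminal segment's slope and return an `extrapolated` flag.
* **cM plateaus are legal.** Real maps contain recombination deserts where
  cM is flat over Mb of sequence. The inverse lookup of a plateau value
  returns the plateau's left edge with an `ambiguous` flag. Both flags are
  data carried in the return value — downstream spacing logic must be able
  to see them, so they are never demoted to log messages. Extrapolating a
  cM query across a *flat terminal* segment has no defined inverse and
  raises.

## CTL region scan

Thresholded criteria: minimum haplotype conservation per pool (default
0.30), maximum gene density (25 genes/cM), maximum physical-to-genetic
ratio (0.7 Mb/cM). The defaults were set so that all four published CTL
descriptor sets (conservation down to 34%, densities up to 21 genes/cM,
ratios up to 0.6 Mb/cM) would pass; they are deliberately permissive and
meant to be tightened per programme. Conservation of a region is the
fraction of pool lines whose haplotype labels equal the pool's modal label
vector over every panel window overlapping the region (per-window modal
label, lexicographic tie-break for determinism). This is the simplest
statistic producing one conservation number per pool per region; whether
the original percentages were computed on marker haplotypes or sequence
identity is not recoverable, so the panel's label semantics are left to
the caller.

The 10-cM window gates chromosomes: one shorter than the window is skipped
with a warning rather than an error. Subregions of 4–5 cM are enumerated
at 0.5 cM steps (resolves the span range without quadratic blowup), scored
as

`w_cons·(cons_SS+cons_NSS)/2 − w_dens·density/max_density −
w_ratio·ratio/max_ratio + bonus·[contains a known trait locus]`

with equal unit weights by default, and overlapping candidates are merged
keeping the higher score; ties break by (chromosome order, start bp).
"Not used in forward breeding" is not computable from these inputs and is
exposed as an optional exclusion-interval list instead.

## CRISPR target-site selection

Candidates are NGG PAMs with a 20 nt protospacer by default (17–24
allowed); the cut is modelled blunt, 3 bp 5′ of the PAM — standard SpCas9
geometry. Filters, in cost order:

1. **Gene distance**: cut position ≥2 kb (inclusive) from any annotated
   gene; 0 if inside a gene.
2. **Exact uniqueness**: the protospacer+PAM, and each 400 bp flank
   (configurable 200–500 bp), must occur exactly once genome-wide counting
   both strands. Occurrences are located with a multiplicative rolling-hash
   index (mod 2⁶⁴) over the concatenated genome, every hash hit confirmed
   by direct byte comparison, so collisions cannot create false counts; a
   palindromic site is counted once per locus. Near-match flank similarity
   is out of scope — the flanks serve as homology arms and primer landing
   zones, for which the exact-uniqueness criterion suffices.
3. **Seed off-target rule**: over every *other* genomic NGG locus (NAG
   opt-in), the Hamming distance between seed 10-mers (protospacer
   positions 1–10 counting from the PAM, compared 5′→3′ on each PAM's
   strand) must be ≥2. Implemented as a vectorised comparison against a
   precomputed PAM-seed matrix; the test suite holds it, and the
   uniqueness index, to exact agreement with brute-force scans on ≥20
   random 0.2–1 Mb genomes with planted duplicates and 0/1/2-mismatch
   off-targets.
4. **Spacing**: a greedy left-to-right cM sweep keeps sites ≥0.1 cM apart;
   within a 0.1 cM bin the candidate with the largest minimum seed
   mismatch count wins, then larger gene distance, then leftmost bp.
   The 3 cM upper bound of the useful spacing range is advisory (it bounds
   the segregation cost of separating traits), not a filter.

No on-target activity scoring and no probabilistic off-target cleavage
models: the selection criteria here are exact-match and seed-mismatch
rules by design.

## Repair template and amplicons

The template is `left_arm | PSA | payload | PSB | right_arm` with the arms
exact genomic substrings ending/starting at the cut. HDR is modelled as a
pure insertion at the blunt cut (no resected reference bases), so the
repaired allele is `genome[:cut] + PSA+payload+PSB + genome[cut:]`.
Because the cut splits the protospacer 17|3 relative to the PAM, neither
junction of the repaired allele reconstitutes an intact protospacer+PAM;
`build_repair_template` verifies this and fails rather than emit a
re-cuttable design (mutating PAM bases instead would be the alternative
strategy; it is noted but not implemented). PSA/PSB default to random
30-mers regenerated until absent from the genome. The default payload
mirrors the real landing pad's composition and size (UBI promoter, FRT-A,
NPTII, PINII terminator, FRT-B, loxP; ~3.2 kb) with synthetic placeholder
sequences; FRT spacer differences (1 nt for FRT1/87, 3 nt for FRT1/6) are
metadata, not modelled recombination chemistry.

Amplicons are computed arithmetically on the repaired allele with default
primer placements (HR1f/HR2r 100 bp outside the arms; tag primers at tag
termini): `junction5 = HR1f→PsaR`, `junction3 = PsbF→HR2r`, and the
overlapping long products `long5 = HR1f→PsbR`, `long3 = PsaF→HR2r`, whose
shared stretch is exactly PSA+payload+PSB. Primer thermodynamics are out
of scope; users may override placements.

## Event classification

Rules are applied in fixed order (biallelic 2×HDR, monoallelic 2×HDR,
1×HDR 5′/3′, NHEJ mutant, unmodified), with `ambiguous` as the sink for
records whose unknown fields block a confident call — including a positive
junction paired with an *unknown* one, since that cannot exclude 2×HDR.
Ambiguous plants stay in the denominator (plants regenerated) and never
enter a numerator. Frequencies round half-up on exact integer arithmetic:
modification frequency to integer percent, 2×HDR frequency to one decimal
— the printed formats of screening tables (198/214 → 93%, 3/214 → 1.4%).
Long PCR is recorded but is confirmatory follow-up, not a classification
gate; 1×HDR events are reported but never promoted to usable events, as
they are frequently truncated or rearranged.

## BC1 stacking model

Two-point analysis only: each BC1 individual is an independent draw over
the four genotype classes, double crossovers within the interval are
ignored (intervals of interest are ≤ ~3 cM), and phase defaults to
repulsion because F1s come from crossing two homozygous single-locus
lines. The direct map rule (1% recombinants = 1 cM) is the default
estimator scale; Haldane differs by <0.1 cM below 3 cM (property-tested)
and is available by configuration. Distance estimates round half-up to two
decimals; the confidence interval is Clopper–Pearson (exact) on the
recombinant proportion. `required_population` inverts the binomial tail by
binary search: the smallest n with P(Bin(n, r) ≥ k) ≥ confidence.

## Synthetic data

The fixture generator emulates the *inputs* of a CTL programme, not maize
biology: background sequence is i.i.d. uniform A/C/G/T (which makes
uniqueness probabilities analyzable), genes are regular 1 kb intervals
every 3 kb outside the planted region, and the haplotype panel assigns a
shared label to 10 of 12 lines per pool inside the planted region versus
labels drawn from 8 alternatives elsewhere. The standard bundle plants one
conserved, gene-poor region of 4.5 cM spanning 45 kb (0.01 Mb/cM) on a
16 cM chromosome, a verbatim duplicated target site, and a 1-mismatch seed
off-target, all recorded in a truth manifest. Two caveats define what
passing tests show: (i) a random background of a few hundred kb routinely
contains seed 10-mers within one mismatch of an arbitrary site, so planted
off-target mismatch counts are upper bounds on the genome-wide minimum,
and truth-based tests assert `≤`; (ii) real genomes have repeats,
transposons, and structured haplotypes that i.i.d. sequence does not
imitate, so fixture results demonstrate algorithmic correctness, not
expected yields on a real assembly. Screening and BC1 generators have an
exact-counts mode (deterministic class realisation) alongside the
stochastic mode so printed-table checks are exact.

## Problem sizes and numerical choices

Fixture genomes are 0.2–1 Mb (600 kb for the standard bundle) — large
enough that uniqueness and seed scans are non-trivial while the whole
suite stays interactive. The oracle-equivalence suite uses 20 genomes with
planted features; the stacking recovery checks use 1,000 replicate
populations of 2,000–2,688 individuals, matching the scale of the real
crosses. All RNG flows through explicit integer seeds into numpy
`default_rng`; rounding of printed quantities uses exact integer half-up
arithmetic rather than binary-float `round`. Degenerate inputs fail loudly
with directed messages: zero-cM regions for density/ratio, arms running
off chromosome ends (reporting the maximum feasible arm length), non-unique
tags, and zero-distance population planning.
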