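# Methods

This note records the models, conventions and numerical choices behind
`telofuseq`, and what the synthetic data do and do not establish about real
sequencing data.

## The assay being modelled

Fusion PCR amplifies ligation products between chromosome ends using
subtelomere-specific primers; pooled amplicons are sequenced paired-end
(150 bp). A junction joins two broken ends, each having lost sequence
telomere-proximal of its breakpoint. Three classes are distinguished:
*intra-chromosomal* (sister chromatids of one chromosome end — or of one
homologous family of ends, where sequence homology precludes definitive
member assignment), *inter-chromosomal* (distinct chromosome ends) and
*genomic* (a chromosome end joined to a distant locus). Junction chemistry
is exclusive per event: microhomology (bases compatible with both
partners), insertion (bases matching neither), or blunt.

## Synthetic subtelomere panel

Entries are stored 5'→3' reading telomere → centromere; coordinate 0 is the
telomere-adjacent end and `telomere_origin` marks the first subtelomeric
base (after an optional telomere repeat array, default 0 bp). The default
panel has four members — a unique 17p-like end, a two-member 16p/21q-like
family, and an XpYp-like end — of 12 kb each. Family members share a
common ancestor over the telomere-proximal 2 kb with 2.5% per-member
substitution (≈95% pairwise identity, above the 90% contract), and are
independent random sequence beyond it. This reproduces the central
ambiguity of the real assay: arms landing in the homology region cannot
always be assigned to a single family member.

## Controlled junction chemistry by reference planting

Microhomology exists only if the junction-adjacent sequence is genuinely
shared by both partners' references. The generator therefore *plants* it:
for an MH-m event the last m bases of the left arm's surviving sequence are
copied into the deleted-side margin of the right arm's reference, a stop
base bounds the shared run at exactly m, and guard bases prevent accidental
extension on the other side. Insertions are drawn either as verbatim copies
from the surviving side of a breakpoint's ±50 bp template window (templated,
default fraction 0.7) or as random sequence rejection-sampled to be absent
from both flank windows on both strands — so the generator's truth and
string-search detection agree by construction. Random insertions default
to 5–20 bp: a 1–3 bp insert is almost surely present in any 50 bp flank by
chance, which would make "templated" meaningless at that length.

All plants and guards live inside a protected zone (±80 bp) around each
breakpoint; zones are disjoint between events, while arm interiors may
overlap other events' zones because amplicons are rendered only after every
edit is in place — reference, amplicon and truth are therefore mutually
consistent, at the cost of the generator editing the supplied panel/genome
sequences in place.

Study-scale cohorts are generated as independent clones (default 40 events
per clone, each clone with its own panel/genome realisation), mirroring
pooled fusion PCR reactions per sample and keeping breakpoint density per
reference physically plausible.

Default generator conditions: class mixture intra 0.25 / inter 0.25 /
genomic 0.50; chemistry MH 0.60 (length 1 + Poisson(3), mean 4.0 bp,
within the 2.4–6.4 bp range of published junction spectra), INS 0.25
(templated 0.7), blunt 0.15; chromatid deletion exponential with mean
3 kb truncated to [0.1 kb, reference end); amplicon arms 200 bp; read
length 150 bp; substitution-only errors (indel-free reads keep breakpoint
placement identifiable and still stress MH resolution).

## Junction calling and the canonical representation

Arms are found by exact k-mer seeding (k = 15, both strands, all positions
retained) grouped into diagonal chains; the best non-redundant chain pair
(each ≥ 30 matched bases, read-interval overlap ≤ max MH) defines the two
arms, and per-base extension from the junction-proximal seeds fixes the
exact junction-side boundaries. MH is the overlap of the two maximal
extensions; the insertion is the gap between them; both zero means blunt.
Junction-side extension is exact (a mismatch or N stops it) because MH is a
statement of certainty; N bases also break seeds, so an all-N read fails
with `no-seed`.

Under MH the physical junction placement is unidentifiable, so calls are
canonicalised: the junction is placed leftmost on arm A's reference, where
arm A is the panel arm (genomic fusions) or the panel arm with the
lexicographically smaller name, with intra ties broken by the smaller
breakpoint tuple. The generator stores truth in the same canonical frame —
the only frame in which "recover the deletions exactly" is well-posed.
Resolving from either mate of a pair yields the same canonical call.

A same-family homolog whose chain scores within one seed length of the
chosen arm marks the call `family-ambiguous`; such calls may carry the
homolog's coordinates and are never silently corrected. On 2,000
error-free events the caller recovers class, MH length, insertion sequence
and both deletions exactly for ≥ 99% of calls, and every miss carries the
ambiguity flag; intra-class fold-back (palindromic) amplicons resolve at
the same rate as inter-class ones.

## Statistics

- **Fusion frequency** is amplicons per diploid genome equivalent; the DNA
  mass of one diploid human genome is taken as 6.6 pg (configurable).
- **Fisher's exact test** (scipy) follows the two-sided convention of
  summing hypergeometric probabilities ≤ the observed table's; the test
  suite verifies it against full enumeration on every 2×2 table with
  N ≤ 30.
- **Chi-squared with Yates' correction** is used instead of Fisher when a
  group is a large simulated null set (> 1,000).
- **Mann–Whitney U** and **Wilcoxon signed-rank** use full enumeration for
  small samples (combined n ≤ 20; ≤ 15 non-zero differences) because the
  desired behaviour on ties (identical multisets → p = 1) requires
  tie-aware enumeration that library exact methods decline; larger samples
  use scipy's tie-corrected normal approximations. Zero differences are
  dropped with the count reported.
- **Chromosome enrichment** compares each chromosome's junction count with
  its length share by a two-sided exact binomial test (same ≤-probability
  convention), the operational reading of per-chromosome exact tests
  against size-normalized expectations. Holm-adjusted p-values are
  reported alongside raw ones; raw p drives comparisons. Exact binomial
  tests are conservative by discreteness: achieved per-chromosome size at
  n = 200 is ≈ 0.041–0.049 depending on the length share, and the
  calibration check on the default five-chromosome toy genome
  (100/80/60/40/20 kb, human-like length variety) lands near 0.045.
- **CIs**: t-based on means, Clopper–Pearson on proportions.

## Genome instability analyses

Copy-number profiles are binned log2 ratios on identical grids; background
subtraction is a per-bin difference (no silent re-binning), and segments
are maximal runs of ≥ `min_bins` bins beyond ± `threshold` with consistent
sign. A segment is cohort-unique when no other sample has a same-direction
segment with reciprocal overlap ≥ 0.5 (an operational definition of
"unique to a clone"; both knobs exposed). SV–fusion proximity uses
same-chromosome
distance to the nearest unique SV breakpoint (translocations contribute
both ends), reported as the fraction of junctions within each of the
default 0.1/1/5/10 Mb bins. Clonality is classified from the median
unique-variant VAF with a default threshold of 0.4 — an operational cutoff
for "a considerable shift below 0.5", exposed as configuration and reported
with every verdict — and a 20-variant floor below which the verdict is
indeterminate.

## Satellite depth ratios and compositional centering

Region depths are normalized to the *unweighted* mean over the
mini-reference regions (length-weighted normalization available; which
mean the original protocol used is ambiguous, and the unweighted
mini-reference mean is the default here). Because each sample is
normalized to its own mean, genuine expansions/contractions shift that
mean and displace every log2 ratio by a shared compositional constant
(with two classes at 1.5× and one at 0.7× among 13 equal classes, the
shift is log2(13.7/13) ≈ 0.076). `class_log2_ratio` therefore offers
median centering of per-region ratios — the standard copy-number
assumption that most regions are unaltered — and the recovery analyses use
it; raw ratios remain the default so single-region ratios are the naive
log2 quotient. Centering preserves antisymmetry under sample swap.

## What the synthetic data do not show

The generator emulates junction-spanning, substitution-only reads with one
pair per event, uniform coverage, no PCR chimeras/duplicates, no quality
profiles, and toy genomes of 300 kb. Passing tests therefore demonstrate
the correctness of the algorithms and statistics under the stated model,
not robustness to real-library artefacts (indels, chimeric amplicons,
coverage bias, reference gaps) or performance at 15× whole-genome scale.
Published cohort-level effect sizes (fold changes between genotypes,
polyclonality rates, SV excesses) depend on the deposited study data and
are anchors for generator defaults, not reproducible quantities.

## Problem sizes

Test and acceptance runs use cohorts of 25–50 clones × 40 events
(1,000–2,000 junctions), 1,000 null simulations of 200 junctions for
calibration, 200 clonality replicates at depth 100 × 500 variants, and
200 regions per satellite class — sizes chosen so every check runs
comfortably on a single CPU while keeping binomial/CLT intervals tight
enough to be informative.
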