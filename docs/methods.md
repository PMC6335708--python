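# Methods

This note documents the models, conventions and numerical choices behind
lncnet, in the order data flows through the package.

## Coordinate and sequence conventions

All in-memory intervals are 0-based half-open; GTF I/O converts to and from
the 1-based inclusive file convention at the boundary, and the conversion is
a bijection (read → write reproduces canonical records byte for byte).
Strand "." is accepted on input — assemblers emit unstranded models — and
recorded; the ORF search always scans both strands anyway, so an unreliable
strand cannot hide coding capacity.

## Stop-to-stop ORF statistic

The coding-capacity statistic is the longest run of stop-free codons in any
of the six reading frames, bounded by stop codons (TAA/TAG/TGA) *or* by the
sequence ends. Design choices:

* no start codon is required ("stop-to-stop" reading); boundary-truncated
  runs count. Both choices are conservative toward calling coding potential:
  a fragmentary transcript with a long stop-free run is treated as possibly
  coding even if no ATG survives in the assembly.
* codons containing N are treated as non-stop, so ambiguity extends runs
  rather than fragmenting them — an N-rich transcript cannot become a
  spurious lncRNA by having its ORFs broken into short pieces.
* ties between frames are broken deterministically (+ strand first, lower
  frame first, leftmost run first), making reported coordinates reproducible.

The implementation is vectorized; the test suite checks it against an
independent split-based enumerator on hundreds of random sequences,
including N-containing ones.

## Filter cascade

Stage order is fixed: homology → length → ORF → coding potential → domain.
A transcript is assigned the first stage at which it fails, so the per-stage
counts partition the input and the intermediate candidate count (after the
ORF stage) and the final count are both reportable. Thresholds (defaults:
homology E ≤ 1e-3, length ≥ 200 nt, ORF < 100 aa, with "less than 100 aa"
kept and exactly 100 removed) are all configurable. The homology-exclusion
cutoff reuses the only protein-search cutoff the parameterization states
(1e-3); no separate exclusion cutoff is published, so it is exposed as a
config field rather than hard-coded. The coding-potential and domain stages
are label-table plug-ins: external classifiers are out of scope and their
outputs are consumed as data, which also makes the cascade testable without
them (both stages pass everything through when no table is supplied and not
required).

## Alternative-splicing modes

Isoform pairs within a locus (loci = connected components of exonic overlap
on one strand) are compared intron chain against intron chain:

* *intron retention*: an exon of one isoform spans an intron of the other,
  extending strictly past both flanking exon edges;
* *exon skipping*: an internal exon of one isoform is absent from the other
  while the other carries exactly the fused intron between the shared
  flanking boundaries;
* *alternative donor / acceptor*: two introns overlap and differ at exactly
  one end, and the differing region is fully exonic in the shorter-intron
  isoform (this containment condition is what separates a genuine
  donor/acceptor shift from the intron side of an exon-skipping pattern);
  the donor/acceptor label is strand-aware, so the same coordinates labeled
  on the other strand swap alt-5′ and alt-3′;
* *mutually exclusive exons*: one internal exon per isoform, mutually
  non-overlapping, between shared flanking boundaries, each absent from the
  other isoform.

A pair may emit several events; for mode-distribution tables, events with
identical (locus, mode, coordinates) are counted once (configurable), since
distributions count event types, not isoform pairs.

Transcript identity across assemblies/statuses uses a structural key:
(chrom, strand, intron chain) for multi-exon transcripts, exact exon
coordinates for mono-exon ones. This is a deterministic convention chosen
here; ragged 5′/3′ ends therefore do not split multi-exon identities, while
mono-exon transcripts must match exactly.

## Normalization and correlation

Size factors follow the median-of-ratios convention: the reference is the
per-transcript geometric mean over libraries (computed over transcripts
positive everywhere), and a library's factor is its median ratio to that
reference. Correlations are computed on log1p of normalized counts by
default: the expression scale is not dictated by the screening rule itself,
and the log transform stabilizes the negative-binomial variance so that the
t-based p-value (exact under a bivariate-normal null) is a good
approximation; raw normalized values remain available via a flag.

Edge calling uses |r| ≥ 0.95 (inclusive — the boundary value is kept) and
raw two-sided p < 0.05 with no multiplicity adjustment, which is the
screening convention this rule set comes from; BH adjustment is available
as a separate operation. Undefined correlations (constant vectors) are
excluded from both the edge scan and the permutation pool and counted in a
QC report — silent NaN propagation is the main corruption risk in a
million-pair scan.

The permutation validation samples a panel of lncRNAs without replacement,
permutes each sampled vector independently (a shared-permutation variant is
available by flag), recomputes all correlations against the unchanged
mRNAs, and pools |r| values across repetitions. Defaults are a panel of 100
and 1000 repetitions. The run is driven entirely by one seed and is
reproducible bit for bit.

## Network

Edges with per-site hybridization energies get SUMENERGY = Σ|eᵢ| over their
sites by default. The aggregation is configurable (sum of magnitudes,
magnitude of the signed sum, or the single strongest site) because the
aggregate is only ever defined through its log₁₀ display bins, which are all
positive; the magnitude sum is the reading consistent with that. Bins are
lower-inclusive: thin for log₁₀ < 1, dotted for [1, 2), thick for ≥ 2.
Bipartiteness is enforced at construction and on every validate call; the
DE join defaults missing nodes to "ns" and the energy join is a left join.
A k-mer-counting duplex scorer is included strictly as synthetic test
plumbing for the energy path; it is labeled non-physical and models no
thermodynamics.

## Enrichment

Fisher p is the hypergeometric upper tail P(X ≥ k); the EASE score
re-evaluates the same tail at k − 1 (one overlapping member removed), so
terms supported by a single gene are never significant (k ≤ 1 ⇒ ease_p = 1).
Significance defaults to raw EASE ≤ 0.05, matching the convention of the
screening context; BH adjustment is an option. Annotation content is user
data with an explicit background; no ontology structure is assumed.

## Synthetic study generator

The generator emulates the study design this pipeline targets: six statuses
(control/infected × 4/12/48 h) with a 3/3/2/2/3/3 replicate layout (16
libraries). What it models, and what it does not:

* **Sequences.** Noncoding designs are random sequences repaired (and
  verified with the package's own ORF finder) until every six-frame
  stop-free run is < 90 aa, leaving a 10-aa safety margin below the 100-aa
  filter cap; coding designs embed a stop-bounded ORF of ≥ 110 aa. Coding
  transcripts (and their injected splice isoforms) appear in the homology
  table at E ≤ 1e-6; noncoding ones never do. Class length ranges are
  separate config fields (noncoding 200–1000 nt, coding 600–2500 nt) so the
  length separation real lncRNA sets show is explicit.
* **Toy genome and splicing.** Each locus occupies a block of a synthetic
  chromosome (one chromosome per ~50 loci). Injected isoform pairs differ by
  exactly one canonical event; the partner's spliced sequence is derived
  from the genome block, so shared regions are identical by construction.
* **Counts.** Counts are gamma-Poisson (negative binomial, dispersion
  α = 0.01) around log-uniform means (50–2000). Every transcript has
  independent per-library latent log-normal variation (σ = 0.25)
  representing biological condition noise; independence across transcripts
  keeps non-planted pairs on the correlation null.
* **Planted pairs.** Pair members share a latent Gaussian per-library factor
  (σ = 2.0 on the log scale) instead of independent noise. Because counting
  noise attenuates correlation, the latent correlation is
  attenuation-corrected per pair: with per-transcript noise variance
  v = α + E[1/μ], the realized log-scale correlation is ≈ ρ·s²/√((s²+v_ℓ)(s²+v_m)),
  and ρ is set so this equals the configured value (default 0.99). Pair
  members draw means from the high end (1000–3000) so the correction stays
  feasible. Even at a realized correlation of 0.99, a sample correlation
  over 16 libraries has non-trivial spread (Fisher-z SD ≈ 0.28), which is
  the irreducible limit on recovering every planted pair at the 0.95 cutoff.
* **Planted DE.** Singly-planted transcripts shift their mean by the
  configured log2 fold change (default −2) in the infected-4 h libraries
  only. The DE table is computed from the counts with a variance-moderated
  two-sample z-test (per-transcript residual variance shrunk toward the
  across-transcript median with prior weight d0 = 20, BH-adjusted): with
  3 vs 3 replicates a raw t-test cannot reliably carry a 4-fold shift past
  FDR ≤ 0.05, whereas variance moderation — the standard small-n remedy —
  can. A separate small "DE pair" class (default 8 pairs, shift −5 log2,
  shared latent σ = 0.5) plants pairs that are simultaneously co-expressed
  and down-regulated, so the down-regulated sub-network extraction has
  non-trivial input; singly-planted DE transcripts are kept disjoint from
  correlation-planted pairs because those pairs' large shared variation
  would mask a mean shift in a 3 vs 3 comparison.
* **Not modeled:** read-level sampling and alignment artifacts, library-size
  trends, batch effects, GC/length biases, dependence between the homology
  table and actual protein content beyond the planted design. Passing tests
  on this generator demonstrate the pipeline's statistical behavior under a
  clean negative-binomial world with known truth, not performance on real
  assemblies.

## Problem sizes and tolerances

The test suite runs the cascade-exactness check on a 1000+1000-transcript
study, correlation-screen recovery with 50 planted pairs against ~6,000
scanned pairs, permutation calibration at 100 lncRNAs × 1000 repetitions
against 100 mRNAs, and a 10⁶-draw Monte-Carlo null for the correlation
p-value; stochastic comparisons use three binomial/Monte-Carlo standard
errors, and deterministic oracle comparisons use 1e-12 absolute tolerance.
The Monte-Carlo null draws fresh iid Gaussian vectors per draw (rather than
permuting one fixed dataset) because that is exactly the distribution the
t transform describes; conditional permutation nulls differ from it at
O(1/n). All randomized tests and examples fix seed 0.

## Known limitations

* The AS classifier compares isoform pairs; complex nested events are
  reported as their pairwise canonical components, not as compound events.
* The permutation test's pooled proportion treats pooled correlations as
  exchangeable; within a repetition, correlations sharing a vector are
  weakly dependent (negligible for the Gaussian-like data tested, but the
  pooled count is not strictly binomial).
* The energy path consumes an external predictor's per-site table; the
  bundled k-mer scorer is a placeholder for exercising the plumbing only.
* `validate_config` checks paths and ranges, not the semantic consistency of
  user-supplied tables (e.g., whether the DE table came from the same count
  matrix).
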