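# Methods

This note documents the models, parameter choices and numerical conventions
behind `ssurna`, and what the synthetic validation does and does not show.

## Read preprocessing

Quality trimming keeps the longest 5'-anchored prefix in which every full
sliding window has mean phred ≥ the floor (default Q20). The window is
max(20 bp, 10% of the current length); because the window tracks the length,
the cut is iterated to a fixed point, which makes trimming idempotent.
Reads shorter than 20 bp after trimming are dropped. The floor is the only
constant the protocol fixes; the windowing scheme is this package's
realisation of sliding-window trimmers and is tested against a brute-force
oracle of its own definition.

Merging reverse-complements R2 and scores every ungapped 3' overlap by
matches − mismatches (computed for all overlaps at once via FFT correlation
of one-hot encodings); the best-scoring overlap wins, ties going to the
longer one, subject to a minimum overlap of 10 bp and a mismatch fraction
≤ 0.08 — the documented defaults of common overlap joiners, exposed in
`PipelineConfig` because the upstream protocol does not state them.
Conflicting columns take the higher-quality base. Indel sequencing errors
are not modelled, so indel-aware merging is deliberately out of scope.

Screens: any non-ACGT character rejects the read ("ambiguous"); a
mononucleotide run of nine or more rejects it ("longer than eight");
sequences of 250 bp or less ("longer than 250" read strictly) are counted
but excluded from classification. The boundary is configurable
(`min_length`, menu 200/250/360 used in the cut-off sensitivity analysis).

## Taxonomic classification

The classifier is the RDP/Wang naive-Bayes scheme with k = 8: references
are grouped by full lineage ("genus" unit); word priors are
p_w = (n_w + 0.5)/(N + 1) and genus conditionals
(m_g(w) + p_w)/(M_g + 1), scored over the query's distinct k-mers.
Bootstrap confidence is the fraction of 100 resamples (⌈m/8⌉ words each,
drawn with replacement) whose winner agrees with the full-data lineage down
to the rank in question; this is computed by lineage-prefix agreement, so
per-rank confidences are non-increasing from domain to genus by
construction. The lineage is truncated at the deepest rank whose confidence
meets the cut-off (80% for reads, 50% for OTU representatives); deeper ranks
report "unclassified". Whether the published cut-off was applied per rank or
only terminally is not documented anywhere we could verify; standard
per-rank truncation is implemented. Ties in the argmax are broken by
lexicographic taxon name for determinism. Both strands are scored and the
better one kept, since merged 5'-adaptor inserts can be antisense relative
to the reference set.

## Sequence-type triage

The cascade: a read is SSU rRNA if the SSU classifier's domain-rank
bootstrap reaches 80%; otherwise it is LSU rRNA if the maximum per-domain
LSU alignment score reaches the floor (10) *and* the LSU classifier reaches
80% at the domain rank, with the domain fixed by the best-scoring
partition; everything else goes to a pluggable mRNA-annotation hook
(callable `SeqRecord -> str | None`, default always `None`), and
hook-negative reads are "other". The alignment score is computed from an
infix edit-distance alignment (whole read inside the reference, free end
gaps on the reference) re-scored as match +1 / mismatch −1 / gap −2; the
score units are arbitrary and the floor is exposed in config. Three
per-domain LSU partitions are used (Archaea/Bacteria/Eukaryota).
The protein-database search for mRNA identification is out of scope by
design — the hook is the integration point. Contaminant removal is
lineage-based: accepted lineages containing chloroplast, mitochondria, or
human/*Homo* are dropped and tallied under "Others".

## Reference mapping and window trimming

16S reads are placed on a single ungapped *E. coli*-style 1542-nt template
by infix alignment, strand auto-detected, and reported as 1-based inclusive
coordinates with a full column pairing. A read is unmapped below 60%
identity over the aligned span — loose enough for archaeal divergence from
the bacterial template, configurable. Pairwise alignment to one template
(rather than a NAST-style multiple alignment) is a deliberate desk-scale
simplification; one bacterial template serves archaea too, as both domains
are trimmed to the same window. Trimming to the window (positions 8–242)
requires the alignment to span it completely; the trimmed product keeps
read insertions in its sequence but also carries a fixed-width
one-character-per-template-column string (gaps for deletions) so that OTU
distances can be computed column-wise without fresh pairwise DP — an
O(n·L) replacement for O(n²·L²) re-alignment.

## Primer evaluation

8F is AGAGTTTGATYMTGGCTCAG anchored at template positions 8–27 (window
derived from the 8F-V1-V2 region starting at position 8). A read counts
only if its alignment fully spans the window; a mismatch is a window
position whose read base is outside the primer base's IUPAC set, and
indels inside the window count as mismatches at each unpaired position —
a primer cannot anneal across an indel. A read N fails every primer base
(conservative). The non-coverage rate denominator is window-covering reads
of the taxon; the count of all classified reads of the taxon is reported
alongside, since published tabulations have used either denominator. Taxa
with fewer than 10 non-covered reads can be flagged for suppression in
figures. Single mismatches count — no mismatch is "allowed".

## OTU clustering and alpha diversity

Distances between window-trimmed reads are mismatched / compared template
columns; a one-sided gap column is a mismatch, both-gap columns and
terminal-gap columns are not compared. Identical aligned strings are
de-replicated before the distance matrix is built. Clustering is
average-neighbor (UPGMA) hierarchical clustering cut at the distance
threshold (0.03 for the main analysis; nearest/furthest available through
the `method` argument), via `scipy.cluster.hierarchy`; partitions are
permutation-invariant for distinct distances (exact distance ties may
resolve by merge order). The representative of an OTU is the member with
the minimum summed distance to co-members, ties to the smallest id.
Representatives are re-classified at the 50% cut-off and organelle OTUs
dropped.

Richness and diversity are computed with scikit-bio's estimators —
observed OTUs, bias-corrected Chao1 (S + n₁(n₁−1)/(2(n₂+1))), ACE with
rare cut-off 10, Shannon in nats — as means over 100 subsamples drawn
without replacement at fixed depth (multivariate hypergeometric; defaults
500 reads for archaea, 5000 for bacteria), deterministic given the seed.
Cut-off menus {0.01, 0.03, 0.05} are supported for the distance threshold;
0.03 is the analysis default.

## Mock-community evaluation

Composition tables are proportions at a chosen rank among reads above a
length floor; "unclassified" at the rank is itself a reportable taxon.
Compositions are compared by unweighted OLS of observed on expected
proportions over the taxon union (absent taxa contribute 0) — no arcsine or
logit transform, matching how such comparisons are conventionally
summarised by slope and r². A regression against a uniform expected
composition is degenerate (zero x-variance) and raises; quantitative
recovery is therefore scored on a tenfold-span mock
(0.50/0.25/0.125/0.075/0.05). Fold-error tables report observed/expected
per taxon per length cut-off, flagging folds outside [0.5, 2]. Length
histograms are at 1-bp resolution with peaks called by prominence (default
1% of the taxon's reads; histogram edges padded so a boundary maximum is
still a peak). Fisher's exact test is two-tailed by the method of small
p-values (sum of hypergeometric probabilities not exceeding the observed
table's), delegated to `scipy.stats.fisher_exact` and verified against a
full enumeration oracle in the tests.

## The simulator and the synthetic reference set

The simulator emulates the library chemistry generatively. Defaults, chosen
once as the study conditions the package validates under:

- **5'-anchoring** — SSU inserts start at molecule position 1 with
  probability 0.8 (the remainder uniform along the molecule, modelling
  degradation); the true anchoring fraction of the chemistry is not
  quantified anywhere, so validation asserts recovery of the configured
  value, not a literature value. LSU molecules start at 1 with probability
  0.5 and otherwise near mid-molecule (Gaussian, mean L/2, sd 0.1·L) —
  the mid-molecule breakdown that produces SSU-sized LSU fragments.
- **Insert length** — a mixture of Gaussian peaks over a uniform
  background (default single peak 300±30 bp, weight 0.6). Per-member peak
  overrides model non-random hexamer priming;
  `isolate_length_peaks()` gives the two GC-extreme members their published
  signatures (219/355 bp and 294/449 bp).
- **PCR bias** — 15 cycles with weight
  exp(−cycles·(c_len·(L−300)/100 + c_gc·|GC−0.5|)), realised by rejection
  sampling. The clean default is c_len = c_gc = 0. The bias preset
  (c_len = 0.18, c_gc = 0.2) was calibrated analytically from the weights so
  the short-peaked AT-rich member overestimates about twofold and the
  GC-rich member underestimates two-to-threefold at the 200 bp cut-off.
- **Size selection** — 205–465 bp on insert coordinates, the image of a
  400–600 bp product selection after ~180 bp of adaptor/tag, widened
  slightly because gel cuts are soft-edged and the observed isolate peaks
  (219, 449 bp) must survive selection.
- **Sequencing** — 2×300 reads, uniform substitutions at 0.001/base
  (decoupled from the emitted qualities), logistic quality profile decaying
  from ~Q38 to ~Q22 (mild enough that Q20 trimming rarely cuts; quality
  truncation would otherwise confound merge-rate accounting). Indel errors
  and chimeras are not simulated.

All randomness flows from a single spec-level seed through explicit
generators; truth records (source molecule, insert coordinates, planted
primer-variant flag) are emitted per pair. An exact analytic account of the
breakpoint × length × size-selection × PCR-weight model
(`analytic_region_fraction`) predicts the fraction of SSU reads fully
containing the 8–242 window; simulation recovers it within one percentage
point at n = 50,000, which is the region-accounting check.

The synthetic reference set mirrors the five-isolate mock design: three
bacteria, one archaeon, one fungal 18S analogue, built by mutating a random
1542-nt template with conserved/variable region structure (nine
hypervariable windows at the *E. coli*-style coordinates), plus per-domain
LSU partitions, a chloroplast contaminant, and sixteen decoy genera
balanced across domains. The decoys matter: with only five genera in the
index, chance k-mer hits concentrate bootstrap confidence at the domain
rank and non-SSU reads leak through the 80% cut-off; a realistically sized
genus set restores the bootstrap scatter that large reference databases
give. The archaeal and AT-rich bacterial members are adjusted to 68% and
34% 16S GC — the contents that drive the GC-bias story — while keeping
≥60% identity to the template and no homopolymer above eight. The primer
window is held at exact 8F expansions in all bacterial references so that
non-coverage arises only from planted variants.

## What the validation shows — and does not

All validation is against the simulator's ground truth. Passing tests show
the pipeline recovers what the generative model implies: proportions on
clean mocks, configured bias distortions, planted primer variants,
configured breakpoint fractions, and agreement with independent brute-force
oracles for trimming, alignment, clustering, diversity and Fisher
computations. They do not show robustness to features the simulator lacks:
indel sequencing errors, chimeras, within-genus reference ambiguity,
secondary-structure-driven coverage gaps, or the taxonomic breadth of real
reference databases. Real-data numbers (sequence-type percentages,
non-coverage rates of environmental datasets) depend on the reference
database version and the deposited runs, and are outside what a
self-contained synthetic validation can reproduce.

## Problem sizes

Validation runs use 5,000–50,000 read pairs per scenario (20,000 for
proportion recovery, 50,000 for region accounting, 10,000 for bias folds,
6,000 for primer recovery, 5,000 for triage accuracy), sizes at which the
binomial/multinomial error bars are several times tighter than the asserted
tolerances.
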