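# Methods

## Data model

All analysis operates on per-site, per-sample read counts: total depth,
alt-supporting read count and the forward/reverse split of the alt reads,
plus variant annotations (dbSNP membership, COSMIC membership,
nonsynonymous flag, gene label). Alignment, duplicate marking and candidate
generation are upstream of this package; read counts are inputs, never
computed from alignments. Coordinates are 1-based fully-closed (VCF
convention). VAF is always derived as `alt_count / depth` against total
site depth, never `alt/(ref+alt)`, and is never stored.

## Somatic filter cascade

Rules are evaluated in a fixed order (germline database, case depth, normal
depth, alt support, VAF, and for plasma only: normal contamination, strand)
and every failing rule is recorded, so audit tables show the complete
reason a site was rejected; the call decision itself is order-independent
because the rules are conjunctive. Thresholds (defaults): case depth ≥30×,
normal depth ≥10×, VAF ≥0.10 for tumor/metastasis roles and ≥0.015 for
plasma, ≥2 alt reads, and for plasma: normal alt reads ≤1 and at least one
alt read on each strand. All comparisons are inclusive at the boundary
(VAF exactly 0.015 passes). A dbSNP variant is rejected unless it is also
in COSMIC — known oncogenic hotspots commonly appear in both. Database
membership arrives as annotation booleans keyed on (chrom, pos, ref, alt);
no live database is queried.

Two conventions that the wording of such rule sets leaves open:

* the case-depth rule applies to the sample being classified, not jointly
  to all case samples — per-sample calling is what cross-sample
  concordance figures need;
* the contamination and strand rules apply to plasma-role samples only;
  tissue calls use the first five rules.

## Tumor fraction

For clonal heterozygous mutations in a diploid genome, each tumor-derived
cfDNA molecule carries the mutant allele with probability 1/2, so the
expected VAF of a clonal site is `TF/2` and the estimator is
`TF = min(2 · mean(VAF), 1)`. The estimator is monotone and 2-Lipschitz
below the clip. Copy-number change and LOH shift individual sites in
either direction and are deliberately out of scope; averaging over tens of
clonal sites is what makes the ×2 convention serviceable. Percentages are
reported rounded half-away-from-zero at the printed precision.

Which sites to average is a modelling choice: this package averages over
sites called in the plasma sample that are shared with a tissue sample
(the demo uses tissue∩plasma calls), which conditions on detection and so
carries a slight upward bias at low TF; at the simulated study conditions
(TF 0.074, 524×) the net bias is ≈1–2% relative, well inside the ±15%
recovery tolerance the tests assert.

## Concordance and longitudinal tracking

Concordance partitions a reference call set against calls re-derived in a
query sample: shared, reference-only, query-only, and — within query-only —
sites with ≥1 alt read in the reference but VAF below the reference role's
cutoff ("present but below the calling cutoff"). `|shared| +
|reference_only| = |reference calls|` always. VAF correlation is Pearson,
matching scatter-plot usage; it is undefined below 3 points or at zero
variance rather than silently returning NaN. Longitudinal comparison
reports per-site VAF pairs plus, per timepoint, the mean VAF over sites
with ≥1 alt read and the count of sites with zero alt reads — undetected
sites are reported, not averaged in as zeros, because at low tumor
fraction zeros carry censoring information, not a VAF of 0.

## Parsimony tree

Samples are taxa; each called mutation is a binary character; the normal
is the all-absent outgroup (its row is validated as such). Rooting an
unrooted binary tree at the normal leaf identifies unrooted topologies
over n samples with rooted topologies over the n−1 case samples, which are
enumerated exhaustively ((2n−5)!! topologies; the implementation refuses
more than 8 samples — these cohorts have 3–4). Each topology is scored
with Fitch's algorithm, vectorized across characters with 2-bit state
sets. Branch lengths come from the standard Fitch backtrace with the root
forced to the absent state (always a member of the root's state set, since
the normal leaf is absent): mutations are gained on the path toward the
leaves and losses are not modeled, which is the right prior for somatic
mutations on a germline background. Ties between equally parsimonious
topologies are broken lexicographically on the canonical (sorted) newick
string, so output is deterministic and independent of input order. Newick
serialization uses integer branch lengths and lexicographic child
ordering.

On homoplasy-free matrices (every character compatible with the clone
topology) the total tree length equals the number of distinct mutations —
the property the simulator-based tests assert.

## Detection power

At true plasma VAF `f`, depth `D` and per-read error `e` toward the alt
allele, alt reads are `K ~ Binom(D, p)` with `p = f + (1−f)e` (error reads
are indistinguishable from real alt reads; specificity questions are asked
by evaluating at `f = 0`). The plasma filter detects the site when
`K ≥ k_min`, `k_min = max(min_alt_reads, ceil(min_vaf_plasma · D))`, with
`ceil` computed with a 1e-9 slack so an exact integer boundary passes
(inclusive ≥). Strand assignment is modeled as an independent fair coin
per alt read — real strand composition depends on library geometry and is
out of scope — giving a both-strands factor `1 − 2(1/2)^k` for `k ≥ 1`.
The analytic form uses the binomial survival function plus the closed form
`Σ pmf(k)(1/2)^k = (1 − p/2)^D · P(K' ≥ k_min)` with
`K' ~ Binom(D, (p/2)/(1 − p/2))`, so no O(D) summation is needed. Power is
0 below the case-depth rule (30×), mirroring the actual cascade.

The Monte-Carlo implementation draws alt counts and strand splits and runs
the real `classify_variant` plasma path against a clean matched normal,
memoizing decisions over unique (alt, forward) outcomes; it is the
independent check of the analytic form (3-SE agreement asserted on a
depth × VAF grid at 1e5 replicates per cell).

Power is monotone in `f` everywhere, and monotone in `D` only for `f`
strictly above the plasma VAF cutoff: below it `k_min` grows faster than
the expected alt count and power decays to 0 with depth; exactly at the
cutoff it hovers near 1/2. Consequently "minimum depth for target power"
is well-posed only above the cutoff; `min_depth_for_power` does a doubling
search (asserting non-decrease along that coarse path) followed by
bisection, and raises a capped-search error at 1e7× when the target is
unreachable. The small sawtooth in depth (from the ceil) makes the
returned depth the boundary of the monotone envelope rather than a strict
minimum in pathological threshold-straddling cases.

## Synthetic cohorts

The simulator emulates a metastatic patient's cohort with three clonal
mutation sets — trunk (all lineages), primary-private, metastasis-private —
plus null (non-mutant) candidate sites. True VAFs: `purity/2` in a tissue
containing the clone; `TF · w/2` in plasma, where `w` is the lineage's
share of the tumor-derived cfDNA (trunk has `w = 1`); 0 in the normal.
Observed counts: depth ~ negative binomial (mean, dispersion); alt ~
`Binom(depth, vaf + (1−vaf)e)`; strand split ~ `Binom(alt, 1/2)`; normal
alt ~ `Binom(depth, normal_alt_rate)`. Everything derives from one seed.

Defaults and why:

* **Dispersion 12** — per-site exome depths at ~500× mean typically range
  ≈180–1200×; a negative binomial with size 12 reproduces that spread.
* **Error rate 1e-4** — post-filter substitution error of a well-behaved
  short-read exome pipeline; at 309–524× this produces occasional 1–2-read
  artifacts at null sites (what the strand/contamination rules exist for)
  but essentially never 5+ reads.
* **Normal trace rate 5e-4** — low-level contamination/artifact reads in
  the germline sample, so the >1-read contamination rule is exercised.
* **200 null sites** — enough candidate non-mutant sites to measure
  cascade specificity without dominating runtime.
* **Tissue purity 0.6** — a typical FFPE/biopsy tumor content; clonal
  tissue VAF 0.3, comfortably above the 10% cutoff.
* **patient1 preset** — 48 trunk + 1 primary-private mutations, plasma
  TF 0.074 at 524× (normal 226×, primary 118×). Eleven
  metastasis-private mutations belong to an *unsampled* lesion (no
  metastasis tissue in the cohort) whose lineage sheds 45% of the tumor
  cfDNA, so they surface only in plasma at ≈1.7% VAF — the
  "mutations unique to cfDNA" class. Trunk sites are carried by both
  lineages, so their plasma VAF stays TF/2 regardless of the mixture.
* **patient2 preset** — 30 trunk + 10 primary-private + 8
  metastasis-private (48 tissue mutations total), plasma is purely the
  metastatic lineage at TF 0.28 and 309× (normal 201×, primary 118×,
  metastasis 183×). The first primary-private site is a clonal
  PIK3CA-like hotspot (absent from metastasis and plasma); the first
  metastasis-private site is an ESR1-like endocrine-resistance hotspot
  (present in metastasis and plasma). Both markers are flagged
  dbSNP+COSMIC so the germline-rescue path is exercised. All mutations
  are nonsynonymous in this preset, so the parsimony tree over
  nonsynonymous characters counts the full clone structure.

A second plasma draw at a different tumor fraction (treatment response)
reuses the same mutation truth with rescaled plasma VAFs; a during >
pre fraction warns (progression) but proceeds.

What the simulator does *not* model, and hence what passing tests do not
show about real data: copy-number and LOH (tissue and plasma VAFs are
purely purity/TF-driven), subclonal structure within a clone, FFPE
deamination artifact spectra, site-specific error rates, mappability or
capture-efficiency variation in depth beyond the negative binomial,
germline SNP contamination of candidate lists beyond the dbSNP flag, and
fragment-level features of cfDNA. Parameter-recovery results here
demonstrate internal consistency of the pipeline under the stated
generative model, not field performance.

## Problem sizes in the test suite

Tests run simulation-backed checks at the preset scale (≈250 sites ×
3–4 samples), 20 seeds for parameter recovery, 100 random cohorts for the
filter oracle, 50 random matrices (≤6 taxa, ≤25 characters) for the
parsimony brute-force comparison, and 1e5 Monte-Carlo replicates per cell
of a 5×5 power grid — sizes at which every assertion is sharp while the
whole suite stays fast on one core.
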