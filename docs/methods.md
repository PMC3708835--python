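# Methods

This note records the models the package implements, the defaults it ships,
and the choices made where the underlying procedures are commonly described
but rarely fully parameterized.

## Biological setting

Genes can end at alternative cleavage/polyadenylation (pA) sites. Use of a
pA inside an intron (a "composite terminal exon" event) truncates the
transcript; use of alternative pAs in the 3'-most exon changes 3'UTR length.
The CstF complex (via its CstF-77 and CstF-64 subunits) stimulates cleavage,
and intronic pA usage competes with splicing: a large intron with a weak
donor (5'SS) splices slowly and leaves its intronic pA exposed. The package
provides the quantitative machinery for studying this competition: splice
site strength scores, intron size-by-strength density maps, 3'-end-read pA
quantification, APA regulation tests, the RUD global-3'UTR index,
cis-element enrichment around pAs, and CLIP cross-link profiles.

## Splice-site scoring (`splice_scoring`)

Donor windows span −3..+6 around the exon/intron boundary (3 exonic + 6
intronic nt, L=9); acceptor windows span −22..+2 (22 intronic + 2 exonic nt,
L=24). A PSSM estimated with per-cell pseudocount 0.25 (default; avoids
−infinity on unseen bases) gives scores

S(x) = Σ_i log2( p_i(x_i) / q(x_i) ),

with the background q defaulting to the pooled base frequencies of the
training windows (uniform 0.25 available by flag). Percentile rank of a
score against a reference set is the percent of reference values *strictly*
below it, so it lies in [0, 100) for members of the set; the percentile
machinery accepts externally computed scores (e.g. maximum-entropy scores)
unchanged. Only GT..AG introns enter PSSM training by default; introns
shorter than 28 nt are skipped because the two windows would overlap.

Donor strength is also expressed as the free energy of the gap-free
antiparallel duplex between the 9-nt donor (as RNA) and the 5' end of U1
snRNA (5'-ACUUACCUG-3'), summing nearest-neighbor stack terms over
consecutive paired positions. Watson–Crick stacks use Turner-style values;
any stack containing a G·U wobble gets a flat −0.5 kcal/mol, strictly weaker
than the weakest Watson–Crick stack. This model is *ordinal* by design: the
perfect complement is provably minimal and losing pairs can only raise the
energy (both properties are brute-force-verified in the tests). It does not
claim numerical equivalence with a full RNA-folding model, which would add
loop, terminal and dangling-end terms.

## Intron density maps (`intron_density`)

Introns are placed on a 20×20 grid of equal-count (quantile) fractions of
intron size and splice-site score; bins are left-inclusive with the last bin
closed. The expected grid is the mean over N (default 100) uniform
permutations of the score column against the size column — this preserves
both marginal distributions exactly, which independent resampling would not.
Cells report observed/expected; 0/0 cells are flagged undefined (NaN plus a
boolean mask) rather than silently propagated. Queries outside the data
range clamp to the boundary bin and equal-count binning means values tied at
a quantile edge travel together (marginals are equal up to tie multiplicity).

## 3'-end read quantification (`pa_quant`)

Reads arrive as a tabular alignment format (read id, chrom, strand, position
of the transcript-3'-most aligned base, non-genomic-T count, sample), i.e.
already converted to sense-of-transcript orientation by the upstream
aligner; a BAM converter is deliberately out of scope so the pipeline has no
alignment-tool dependency. A read is PASS (poly(A)-site supporting) iff it
has **more than 2** non-genomic Ts. PASS 3' ends are clustered per
(chrom, strand) by single linkage with a 24-nt window (the convention of
3'READS-lineage site calling; configurable), the representative being the
modal position with ties resolved to the transcript-5'-most. Clusters map to
the unique gene whose span (plus a configurable downstream extension,
default 0 in the library, 24 nt in the bundled pipeline, to catch cleavage
scatter past the annotated end) contains the representative; clusters
hitting zero or two genes are set aside with reasons. Counts are conserved:
Σ cluster counts = number of PASS reads, asserted in the tests.

## Statistics (`apa_stats`)

* **APA test**: per gene, the top two isoforms by summed count across both
  conditions (ties: 5'-most first) form a 2×2 isoform-by-condition table;
  two-sided Fisher exact test; Δ = distal-isoform fraction (B − A) over the
  tested pair. A gene is called regulated iff p < 0.05 and |Δ| > 0.05. The
  effect size is measured on the top-2 pair, not on all isoforms.
* **Differential expression**: gene vs rest-of-library 2×2, two-sided
  Fisher; library-size-normalized fold change; called iff p < 0.01 and fold
  > 1.5 in either direction. Zeros get +0.5 continuity in the *reported*
  fold only, never inside the test.
* **RUD**: reads-per-nt density of the aUTR (between first and distal pA of
  the 3'-most exon) over that of the cUTR (upstream of the first pA); genes
  qualify with ≥ 10 cUTR reads (default); the per-sample median over
  qualifying genes is the global 3'UTR-length index. Depth-scale invariant
  by construction.
* **Set-level statistics**: 1-df goodness-of-fit chi-squared against a 50:50
  split for direction concordance; two-sample Kolmogorov–Smirnov (asymptotic
  p) for gene-set expression-shift comparisons; Pearson r/r² with the
  least-squares line for isoform-ratio vs median-RUD correlation.
* No multiple-testing correction enters any call (the decision rules are
  raw-p plus effect-size filters); Fisher p-values are delegated to
  `scipy.stats.fisher_exact` and verified in the test suite against an
  exhaustive hypergeometric-enumeration oracle in exact integer arithmetic
  (every 2×2 with margins ≤ 30, both sidednesses, 1e−10).

## Cis elements (`cis_elements`)

Four disjoint windows around the cleavage site (offset 0): −100..−41,
−40..−1, +1..+40, +41..+100. A flank counts as containing a k-mer only when
an occurrence lies fully inside the window (occurrences straddling a
boundary count for no window); presence/absence per sequence, not occurrence
counts, feeds a one-sided (greater-in-A) Fisher test per k-mer, and all 4^5
pentamers are ranked by p (ties: more A-set hits first). Matching is done in
DNA space; reports print RNA (U). A Benjamini–Hochberg column is available
to users but never used in ranking decisions.

## CLIP binding (`clip_binding`)

Only deletion-bearing reads are used (reverse transcriptase skips
cross-linked bases); the cross-link is the 5'-most deletion. Profiles cover
offsets −100..+100 in transcript orientation, normalized to reads per
thousand pAs per million mapped reads, so they are invariant to duplicating
reads-with-depth or pAs-with-reads (asserted exactly). Regional binding sums
offsets −10..+40 inclusive. The comparison statistic is
aggregate(UP) − aggregate(DN); pAs (not reads) are resampled with
replacement B=1000 times per set, because the contrast is between pA sets.
The two-sided p is 2·min(frac ≤ 0, frac ≥ 0) clipped to (1/B, 1]. Each set's
resampling stream is keyed by the seed plus that set's own count vector, so
relabeling UP↔DN mirrors the bootstrap distribution exactly and the p is
swap-invariant by construction, not just in distribution. Null calibration
(equal rates, 500 pAs/set, Poisson rate 2) holds the nominal 5% level within
Monte-Carlo error.

## Synthetic data (`synthetic_data`)

All generators draw from named streams derived from one root seed
(`default_rng([seed, crc32(name)])`), so outputs are byte-stable under
re-ordering of stages. What each generator emulates, and what it does not:

* **Intron populations**: log-normal sizes (default log-nt mean 7.3, sd 1.2,
  median ≈ 1.5 kb — the scale of human introns) and normal splice scores,
  coupled by a Gaussian copula with chosen correlation. Real intron size
  distributions are heavier-tailed and score distributions skewed; the maps
  only need controllable marginals and dependence.
* **APA experiments**: 200 single-exon genes with a proximal and a distal pA
  (two suffice: the APA test uses only the top two isoforms), base proximal
  fraction 0.5, a planted +0.20 proximal shift in condition B for regulated
  genes, 500 reads/gene/condition, 3'-end jitter ±2 nt, 10% non-PASS decoys
  with 0–2 non-genomic Ts, PASS tails uniform on 3–10 Ts. Depth and
  replicate structure of real libraries are not reconstructed (the source
  protocol leaves them unstated); there are no biological replicates, so
  the Fisher test's overdispersion behavior on real replicates is untested
  here.
* **Flank sets**: i.i.d. uniform background (the simplest null for
  enrichment; real pA flanks are AU-rich) with the pentamer written at a
  uniform in-region position at per-sequence rates.
* **CLIP reads**: Poisson counts per pA, offsets from an arbitrary
  positional profile, plus a 10% no-deletion fraction that the cross-link
  filter must remove. No sequence bias or mismatch-type errors.
* **RUD cohorts**: per-gene Poisson region counts with aUTR/cUTR density
  ratio g, cUTR 300–800 nt, aUTR 500–1500 nt, depth 50; each gene's expected
  RUD is exactly g.

Passing tests on these cohorts demonstrates the *correctness of the
computations and decision rules* under known truth — not robustness to
alignment artifacts, internal priming beyond the PASS rule, overlapping
genes, or annotation errors in real data.

## Problem sizes and calibration checks

The bundled demonstration and acceptance computations use: 200-gene cohorts
(40 regulated) at depth 500 for recovery; 1000 null genes for p-value
calibration; n = 200,000 intron pairs with 50 randomizations for the density
null (expected ≈ 500 per cell, giving the [0.8, 1.25] sampling envelope);
100 seeded null runs for the pentamer familywise check; 200 replicates of
500 pAs/set for bootstrap calibration. These sizes make every planted effect
detectable with large margin while each driver finishes in seconds to a few
minutes on one core.

## Known limitations

* The donor:U1 energy model is ordinal, not thermodynamically complete.
* Single-linkage clustering can chain dense scatter across a long run of
  closely spaced ends; with the 24-nt window and well-separated synthetic
  pAs this does not arise, but real tandem pAs closer than the window merge.
* `test_gene_expression` treats the library as the Fisher margin, which is
  anti-conservative for highly expressed genes with biological replication;
  it matches the stated decision rule rather than a dispersion-aware model.
* The GTF reader assumes one transcript per gene (multi-isoform exon
  structures are out of scope; pA isoforms are modeled via pA sites, not
  transcript records).
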