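# Methods

`selconv` re-implements, as one tested pipeline, the comparative-genomic and
transcriptomic workflow used to dissect a convergently evolved trait (here:
superfine cashmere in Tibetan antelope, Siberian ibex and cashmere goats):
codon-model selection tests, ancestral-reconstruction-based convergence
detection, a population-genomic sweep scan, coexpression-module discovery,
negative-binomial differential expression, and gene-set integration with
pathway enrichment. Every stage can be exercised on synthetic data with
planted ground truth; this note records the models, the defaults, and the
places where a genuinely open design choice was made.

## Codon models and selection tests

Substitution follows a Goldman–Yang (GY94) process on the 61 sense codons of
the universal code: `q_ij = pi_j * kappa^[transition] * omega^[nonsyn]` for
single-nucleotide neighbours. Equilibrium codon frequencies are F1x4
(products of observed nucleotide frequencies), chosen over F3x4 or
empirical-61 to keep nuisance parameters few at desk scale; the frequency
model is recorded in output headers. Likelihoods are computed by Felsenstein
pruning over site patterns, using the spectral decomposition of the
symmetrized generator (one `eigh` per (kappa, omega) serves all branches).

Branch lengths are taken from the input tree, in expected substitutions per
codon, and held fixed; only rate parameters are optimised (bounded L-BFGS-B,
three starts with kappa in {1,2,4} and omega in {0.1,0.5,1.5}, absolute
log-likelihood tolerance 1e-6; the L-BFGS-B relative `ftol` is divided by
the likelihood magnitude so the tolerance really is absolute). The tree with
lengths is an input to this pipeline — tree estimation is out of scope — so
fixing lengths removes 2n-3 nuisance dimensions per gene. Alignment columns
containing any gap/ambiguous codon are dropped gene-wide (complete-case
sites; the count is logged).

Two detectors are provided, both df = 1 chi-square LRTs at alpha = 0.05
(raw p-values, matching the protocol; BH q-values are reported alongside):

* **Branch model (REG detector).** One-ratio vs two-ratio (foreground
  omega free). The candidate verdict additionally requires the foreground
  omega estimate to *exceed* the background's — "rapidly evolving" implies
  elevation — while the directionless significance and a direction flag are
  both emitted, since the original rule's directionality is ambiguous.
* **Branch-site model (PSG detector).** Model A: classes 0 (omega0),
  1 (neutral), 2a/2b (omega2 on the foreground, omega0/1 on the
  background), with p2 split proportionally to p0:p1; the null pins
  omega2 = 1. The alternative fit is seeded from the null optimum. The
  p-value uses the plain chi-square, per the described procedure; a
  configuration switch enables the stricter 50:50 boundary mixture.

**Rate normalization.** The uniform-omega models scale each generator to
one expected substitution per codon, so a branch length means the same
thing under any omega. The branch-site mixture instead shares a single
normalization across its site classes — the proportion-weighted mean rate
of the *background* classes — so branch lengths stay calibrated on the
background process and an elevated omega2 raises the foreground
substitution rate, as in codeml. Without a shared scale the mixture
proportions absorb nearly all of the omega2 signal and the test has no
power; with it, planted omega2 = 4 on 15% of sites is detected reliably
when the foreground branch is long enough to accumulate substitutions
(the shipped power check uses a 0.4-substitutions/codon foreground branch
and 600-codon genes).

A Nei–Gojobori-style counting estimate of per-branch dN/dS over ancestral
codon states (single-step paths averaged for multi-hit codons; mutations
through stop codons excluded) provides a likelihood-free cross-check; it
agrees with the ML one-ratio estimate within 20% at 2000 codons.

## Ancestral reconstruction and convergence

Genes must carry at least 75% canonical amino-acid cells (>= at the
boundary). Marginal ancestral states come from an up–down pruning pass
under a Poisson model with alignment-wide observed frequencies (closed-form
transition matrix `P(t) = e^{-st} I + (1 - e^{-st}) 1 pi^T`). A
frequency-dominated model suffices at the shallow divergences involved and
avoids an external exchangeability matrix; a hook accepts user frequencies.
Ties in the argmax break toward the residue observed in more leaves, then
alphabetically. Fitch parsimony is included as an enumeration-friendly
oracle; the two agree on zero-homoplasy columns.

A site is *convergent* for a focal branch pair when both child states equal
one derived residue and each differs from its parent's state; all four
posteriors must reach `posterior_min` (default 0.8 — the source protocol
filters "to reduce false positives" without a numeric gate, so the gate is
explicit and configurable). Parallel substitutions (equal parent states)
are *not* excluded — the rule requires only derived-state identity and
change from each parent — but a flag distinguishes parallel from
strict-convergent sites. The **CCS filter** then demands that every valid
non-focal leaf carry one shared residue differing from the derived residue
and every focal leaf carry the derived residue, giving the strict filtration
CCS ⊆ convergent ⊆ double-substitution sites. Gene-level output uses the
standard substitution notation (parent residue, 1-based site, derived
residue: `K136R`). Profile-change detection (tools such as PCOC) is out of
scope: in practice profile-based calls form a superset of
reconstruction-based ones, so the informative intersection this package
ships is detection ∩ CCS.

## Sweep scan

Sites are filtered as in the stated vcftools protocol: biallelic, overall
MAF >= 0.05, missingness <= 10% over the union of both populations; missing
genotypes reduce called-allele denominators and are never imputed. Windows
are 50 kb with a 20 kb step. Window Fst is the Weir–Cockerham (1984)
diploid estimator as a ratio of summed variance components (what windowed
vcftools reports); negative values are retained for ranking and only
clamped in a display column. Per-site pi is `2*c_ref*c_alt/(n(n-1))`,
summed and divided by window size. The pi-ratio is
pi(reference)/pi(selected) — orientation chosen (and config-switchable) so
sweeps in the selected population land in the upper tail; the ratio is
undefined when both diversities are zero and capped when only the
denominator is. Top-window calling uses the empirical order-statistic
quantile with ties kept. Candidates are the interval intersection of the
two methods' merged top-1% windows; genes annotate by >= 1 bp overlap, and
the final list is the intersection of the two per-method gene lists. Both
the window-pair count and the merged-region count are reported, since
"common regions" can mean either.

## Coexpression

Genes with sample SD < 0.5 are removed (>= kept). Sample outlier detection
is report-only by default (average-linkage tree on Euclidean distances),
mirroring a study in which no outlier was dropped. The network is unsigned
(`|cor|^beta`; a signed option exists). The soft power is the smallest
beta in 1..20 whose scale-free fit index reaches 0.85, where the index is
`-sign(slope) * R^2` of the log-log connectivity regression (the WGCNA
convention: a power-law has negative slope, so a good fit scores positive).
TOM follows the standard formula; modules come from a deterministic
static-height cut (0.99 x the maximum merge height) of the average-linkage
dissTOM dendrogram, with branches of >= 30 leaves becoming modules — a
documented simplification of the dynamic hybrid tree cut that recovers
block-structured truth exactly and keeps the pipeline free of tuning
randomness. Eigengenes are the first principal component of the per-gene
z-scored module submatrix, sign-aligned to the module mean profile and
unit-variance; modules with eigengene dissimilarity below 0.25 are merged
iteratively to a fixed point. Module–trait, gene–trait (GS) and
gene–eigengene (MM) statistics are Pearson correlations with two-sided
t-based p-values (raw, heatmap convention); hub genes pass |GS| > 0.2 and
|MM| > 0.8 within the selected key modules. Traits enter as four binary
indicators for the hair-follicle stages (anagen Apr–Sep, catagen Oct–Dec,
telogen Jan–Feb, late-telogen Mar).

## Differential expression

Median-of-ratios size factors (total-count fallback when no gene is
positive everywhere); method-of-moments NB dispersion per gene with a 1e-8
floor and no shrinkage; per-gene NB GLM (log link, intercept + group,
log size factors as offsets) fitted by Fisher scoring; Wald z on the group
effect with normal reference; BH over tested genes (all-zero genes are
excluded from testing and the BH denominator). Complete separation caps the
effect at |log2FC| <= ~21.6 and flags the gene. DEGs require |log2FC|
strictly > 1 and q strictly < 0.05, with up/down counts reported. This is a
transparent NB core, not a DESeq2 re-implementation: no dispersion
shrinkage, no independent filtering, no lfcShrink — acceptance is
planted-truth recovery, not parity.

## Integration and enrichment

A gene-set ledger collects named sets with provenance; intersections are
exact with pairwise Venn counts. Enrichment is the upper-tail
hypergeometric p (`P[X >= k]`), significant at raw p < 0.05 per the stated
protocol, with BH q alongside. The default universe is every gene in the
declared annotation (config-switchable to the tested set); the original
study's universe is unstated, so the choice is explicit and logged.
Pathway tables are inputs — no live database is queried. A bipartite
gene–pathway edge list is exported for plotting tools.

## Synthetic data: what it emulates and what it does not

The generator is first-class, tested code whose defaults define the study
conditions at desk scale:

* **Codon alignments** evolve root-to-tips by Gillespie simulation using
  the *same* rate-matrix code as the estimator, recording every
  substitution, so simulator/estimator consistency is exact by
  construction and realized dN/dS can be counted from the true history.
  Planted convergent sites rewrite one column: focal leaves get a derived
  residue; in conservative mode all other leaves get one shared background
  residue, so the site must pass CCS.
* **Variant panels** are site-independent: a shared Beta(0.6, 0.6)
  frequency jittered per population (sd 0.02), diploid genotypes binomial,
  uniform missingness. In sweep windows the selected population moves to
  within `reduction` x (distance to fixation) of a target allele chosen
  against population 1 with probability `divergence`; `reduction=1,
  divergence=0` reproduces the background exactly, so null plantings
  propagate to null detections. Defaults: 30 diploids per population, one
  6 Mb chromosome at 0.002 SNPs/bp, three 50 kb sweep windows aligned to
  the window grid, reduction 0.1, divergence 0.9, 2% missingness. There is
  no linkage and no coalescent history — window exchangeability is the
  point, and no implemented statistic uses LD — so these tests say nothing
  about haplotype-based methods or about LD-induced correlation between
  neighbouring windows in real data.
* **Expression** separates the two views the way the source study does:
  a normalized (FPKM-like, Gaussian) matrix carries four stage-linked
  modules of 60 genes among 1000, with heterogeneous loadings centred on
  sqrt(0.8) (mean within-module correlation ~0.8, and the loading spread
  gives the network the hub structure a scale-free fit needs); counts are
  an independent NB draw (dispersion 0.2, lognormal base means) with
  100 planted two-fold-change genes between two balanced breeds across 60
  samples (DE runs use a 10 vs 10 subset design). Counts and normalized
  values are *not* coupled, so cross-view consistency of real RNA-seq is
  not emulated.
* **Annotation/pathways**: disjoint gene intervals tile the chromosome
  with designated genes strictly inside sweep windows (1 kb margins so no
  gene straddles a sweep boundary), and one pathway collects exactly the
  designated gene set.

## Numerical choices and degenerate inputs

Zero-length branches give identity transition matrices; all-invalid
protein columns are skipped; dS = 0 flags counting-omega as undefined;
windows without usable sites carry NaN and are excluded from quantiles;
equal-valued windows at a quantile threshold are all flagged with a logged
warning; a zero-variance trait column yields NaN correlations and a
warning; optimizer non-convergence flags the gene and excludes it from
verdicts. All randomness flows from explicit seeds; identical seed and
configuration give byte-identical outputs.

## Problem sizes

The shipped tests and the acceptance script run at desk scale on one CPU:
6-taxon trees, 100–2000 codons per gene, 150–200 genes for null
calibration (40–80 for the costlier branch-site null), one 6 Mb chromosome
with 60 diploids, 1000 x 60 expression matrices. These sizes were chosen so
each statistical check retains enough replication to be meaningful (e.g.
binomial confidence bands around the 5% nominal LRT rate) while the whole
pipeline remains a coffee-break run.

## Known limitations

Branch lengths are not re-estimated per gene; codon frequencies are F1x4
only; the amino-acid model is Poisson (no JTT/WAG); the tree cut is static
rather than dynamic-hybrid, so nested or elongated modules that the hybrid
algorithm would split can land in one branch; NB inference has no
shrinkage, so small-sample dispersion estimates are noisy (the Wald test
is anti-conservative at n < ~5 per group); the sweep generator's lack of
LD makes window p-values optimistic relative to real genomes. None of
these affect the planted-truth recovery guarantees the test suite
establishes, but all matter when interpreting results on real data.
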