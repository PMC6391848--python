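# Methods

`cernet` infers competing-endogenous-RNA (ceRNA) relationships between
lncRNAs, miRNAs and mRNAs from a two-condition expression experiment, builds
the resulting tripartite interaction network, and annotates it functionally.
This note describes the models, the parameters that matter, the synthetic
data the package validates itself on, and the numerical choices made where
the design was open.

## The inference model

The ceRNA hypothesis holds that transcripts sharing miRNA response elements
compete for a limited miRNA pool, so a lncRNA can de-repress an mRNA by
sponging their shared miRNA. The pipeline operationalizes this as a
conjunction of evidence:

1. **Differential expression.** All three RNA classes are contrasted between
   the two stages (stage2 vs stage1, e.g. adult vs embryo). Selection uses
   |log2FC| ≥ 4 for lncRNAs and miRNAs, ≥ 2 for mRNAs, and p < 0.001 — the
   thresholds are deliberately stringent, trading sensitivity for a network
   of manageable size.
2. **miRNA–mRNA pairs** come from a curated interaction table (a file-based
   stand-in for a ceRNA-triplet database), restricted to differentially
   expressed ids.
3. **miRNA–lncRNA pairs** are predicted from sequence: a perfect
   Watson–Crick match to miRNA positions 2–8 (the seed; G:U excluded there)
   plus a hybridization minimum free energy below a cutoff (default −20
   kcal/mol) computed by the dynamic program below.
4. **Triplets** are the Cartesian join of (2) and (3) on the shared miRNA.
   The "co-expression" RNAs are those appearing in at least one triplet —
   network co-membership, not expression correlation; no correlation filter
   is applied and no minimum number of shared miRNAs is required per
   lncRNA–mRNA pair.

## Duplex energy model

`duplex_mfe` minimizes free energy over *intermolecular-only* secondary
structures: monotone, non-crossing, antiparallel base pairs (Watson–Crick or
G:U) between the miRNA and a target window, with no intramolecular pairs and
no pseudoknots. The energy of a structure is

    E = E_init + Σ stacks + Σ loop penalties

with parameters in the versioned table `src/cernet/data/nn_energies.json`:
Watson–Crick stacking free energies from the standard nearest-neighbor set
(e.g. GC/CG −3.42, AA/UU −0.93 kcal/mol), a single generic value for stacks
involving one G:U pair (−1.0) or two (−0.3), affine loop penalties
(bulge 3.2 + 0.6/nt, interior 1.6 + 0.5/nt, each side capped at 15 nt) and a
duplex initiation term of +4.09 kcal/mol. If no structure is stabilizing the
reported MFE is 0 with an empty structure, so every reported duplex has
negative energy. The DP is O(n·L·c²) for miRNA length n, window length L and
loop cap c; windows of 75 nt are centered on each seed site and the best
window wins. Among co-optimal structures the traceback prefers stacking over
loop opening, then smaller target index.

This is a deliberately simplified energy function — no dangling ends, no
terminal-AU or loop-sequence corrections, no target-site accessibility — and
all of the package's energy statements are defined relative to this table.
Its correctness claim is exact agreement (≤ 1e-9 kcal/mol) with brute-force
enumeration of all valid structures under the same table, which the test
suite and acceptance script verify on hundreds of random short pairs.

A practical consequence of the model: an isolated 7-bp seed helix scores
only about −9 kcal/mol and does not pass the −20 kcal/mol default cutoff;
passing sites need substantial pairing beyond the seed, as strong sponge
sites do.

## Differential expression

Counts are normalized to CPM per sample (configurable off for
pre-normalized input), fold changes use a 1-CPM pseudocount, and p-values
come from a two-sided Welch t-test on log2(CPM + 1) across replicates.
Degenerate cases are resolved deterministically: an RNA with zero counts
everywhere gets log2FC = 0 and p = 1; zero within-group variance in both
stages gives p = 0 when the means differ and p = 1 otherwise (this makes
noise-free simulations well defined). Precomputed DE tables are accepted
as first-class input, since in the original workflow DE calling and
threshold filtering are separable steps.

Small-sample behavior worth knowing: with 3–6 replicates per group the
Welch test on log counts is mildly *conservative* (observed fraction of null
p < 0.05 is ≈ 0.033–0.045), which protects specificity at the stringent
0.001 cutoff; calibration is uniform within 3 binomial SEs by 10 replicates
per group, and the calibration tests run at that size (2500 null genes).

qPCR support: `delta_delta_ct` implements 2^−ΔΔCt with the calibrator ΔCt
aggregated by arithmetic mean.

## Network topology

The network has typed nodes (class, up/down direction) and only
miRNA–lncRNA and miRNA–mRNA edges. Conventions match the common
network-analyzer definitions: raw degree; unordered-pair betweenness without
normalization; closeness = (nodes reachable)/(sum of shortest-path
distances) within a component. The scale-free check fits an OLS line to
(log10 k, log10 N(k)) over the observed degree histogram and reports slope
and R² on the logarithmized values; a discrete maximum-likelihood exponent
is available separately (`power_law_mle_exponent`) as the statistically
preferable but differently-scaled estimate. Centrality differences between
RNA classes use the tie-corrected Kruskal–Wallis H with a chi-square
p-value (df = classes − 1); all-identical inputs return H = 0, p = 1. The
chi-square approximation is known to be loose at very small n (at total
n = 6 it differs from the exact permutation p by ≈ 0.035); at realistic
network sizes (tens of nodes per class) it is accurate, and the test suite
cross-checks against exhaustive permutation at small n.

## Enrichment and annotation transfer

Per term, a two-sided hypergeometric test (doubled smaller tail, capped at
1) over the background universe (default: all genes in the annotation
collection; configurable). Multiplicity is controlled by the Bonferroni
step-down (Holm) adjustment. Retained terms (adjusted p ≤ cutoff, default
0.05) are grouped by connecting term pairs whose membership agreement —
Cohen's kappa over the universe — reaches 0.4; groups are the connected
components of that graph. This is a transparent simplification of the
iterative leading-group merging some enrichment plug-ins perform. lncRNAs
are annotated by guilt-by-association: each lncRNA inherits the enriched
terms carried by mRNAs that share a triplet miRNA with it.

## Pre-ranked GSEA

Genes are ranked by log2FC (the only stage-contrast statistic the DE tables
carry; configurable) with deterministic tie-breaking. The enrichment score
is the classic weighted Kolmogorov–Smirnov running sum (hits weighted by
|score|^p, default p = 1, normalized over hits; misses decrement by
1/(N − Nh)); significance comes from gene-label permutations (1000 by
default in the pipeline), the only permutation scheme available for
pre-ranked input. NES = ES / mean(|null ES| of the same sign); the nominal
p is the same-sign null tail fraction; the FDR q follows the standard
NES-pooling estimate (null-tail fraction over observed-tail fraction,
clamped to [0, 1] and made monotone so a more extreme NES never has a
larger q). A hit set whose members all carry zero score falls back to
uniform hit weights. Heavily degenerate rankings (almost all scores equal)
compress the null and observed ES distributions together and make the FDR
insensitive; rankings computed from replicated noisy data do not have this
problem.

## Synthetic data: what it emulates, what it does not

The generator plants a known answer in data whose statistical shape follows
the emulated study: two stages with six replicate samples each (matching
the six RNA samples pooled per stage in the emulated design), three RNA
classes (defaults 24 lncRNA / 8 miRNA / 200 mRNA), negative-binomial counts
(gamma–Poisson, dispersion 0.05, expected library 1e6), planted effects of
|log2FC| = 5 with miRNAs down-regulated from stage1 to stage2 and
lncRNAs/mRNAs up, 16 planted triplets (4 DE miRNAs × 2 lncRNA × 2 mRNA
partners each), target sites planted as the reverse complement of the full
miRNA at random non-overlapping lncRNA positions (so planted duplexes pass
the default energy cutoff; the site length is configurable), an interaction
table holding the planted miRNA–mRNA pairs plus 15 uniform-random decoys,
and one gene set drawn ≥ 90% from the planted up-regulated mRNAs among
random sets. Planted up-regulated RNAs reach a typical abundance in their
high stage and sit 2^−5 below it in the other, keeping stage library sizes
close so CPM normalization compresses fold changes only mildly (≈ 0.1–0.2
log2 units). Every output is a pure function of config + seed.

What passing on this generator does *not* show about real data: no isoform
or positional read structure (counts are drawn directly, not aligned), no
compositional extremes, no correlated genes, uniform-random background
sequence (real lncRNAs have repeat and GC structure), decoy database rows
drawn uniformly rather than biased toward well-studied genes, and planted
sites that are perfect full-length complements rather than the bulged,
wobbly sites of real targets. The recovery numbers (precision ≈ 0.93,
recall ≈ 1.0 over 30 seeds; exactly the planted triplets on noise-free,
decoy-free input) therefore validate the pipeline's logic and wiring, not
its sensitivity on real sequencing data. Residual false positives are decoy
database pairs that happen to involve differentially expressed ids; these
produce structurally valid triplets that no filter described in the
emulated workflow can reject.

## Determinism and problem sizes

Every stochastic component takes an explicit seed; reruns of the pipeline
with identical inputs, config and seed are byte-identical (wall-clock
timestamps are logged but never written into `report.json` for this
reason). The shipped test and acceptance problem sizes — 500 oracle duplex
pairs, 200 oracle graphs, 30 recovery seeds, 400 GSEA null draws, 2500 null
genes — were chosen to give stable estimates at interactive runtimes; the
full suite runs in well under a minute of compute per check.

## Known limitations

- The energy table is simplified; absolute MFE values are not comparable
  with thermodynamic folding software, only relative to this table.
- The −20 kcal/mol duplex cutoff, unstated in the emulated workflow, is a
  package default and is logged prominently; results are sensitive to it.
- No ontology-graph propagation in enrichment; terms are flat sets.
- Betweenness/closeness are reported unnormalized; only rank-based
  comparisons across classes are made, which are invariant to monotone
  normalization.
- The DE module is intentionally minimal (no dispersion shrinkage, no
  multi-factor designs); for real count data a dedicated DE framework
  should produce the input DE table, which the pipeline accepts directly.
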