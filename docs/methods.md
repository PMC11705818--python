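# Methods

This note documents the models, procedures, numerical choices, and known
limitations behind `mycoscan`. Empirical claims below are the ones the
test suite and `scripts/acceptance.py` themselves compute.

## Genome catalog curation

Assemblies are filtered on two quality statistics: N50 (the scaffold
length at which the descending cumulative sum first reaches half the
assembly) and scaffold count. A genome is removed when N50 < 2,000 bp or
when it has more than 10,000 scaffolds; both comparisons are strict, so
the boundary values are retained.

Bacterial decontamination works at the scaffold level: a scaffold is
dropped when at least half of its canonical 31-mers occur in the
bacterial reference's k-mer index. 31 is the standard read-classification
k-mer size — long enough that chance collisions between random sequences
are negligible (4⁻³¹ per pair), short enough to tolerate a few percent
divergence.

ANI between two genomes is estimated with a MinHash bottom sketch
(k = 21, sketch size 2,000, splitmix64 hashing): the Jaccard index j of
the two canonical k-mer sets is estimated from the union's bottom
sketch, converted to a Mash distance d = −(1/k)·ln(2j/(1+j)), and
reported as ANI = 1 − d clamped to [0, 1]. The estimator is symmetric by
construction and, at 200 kb and the defaults, lands within ±0.01 of a
planted identity of 0.95 (verified by simulation in the test suite).

Species clustering is greedy representative-linkage (dRep-style):
genomes are visited in (N50 desc, total length desc, id asc) order, each
joins the first cluster whose representative it matches at ANI ≥ 0.95,
else founds a new cluster. The total sort key makes the partition
deterministic and independent of input order. Representative selection
by N50 favors the best assembly as the species exemplar.

## Read quality control

Pairs are evaluated after trimming a trailing run of ≥ 10 G's (the
two-color-chemistry artifact). Four rules run in a fixed order — length
< 90 bp, mean Phred < 20, more than 30% of bases below Q20, complexity
< 30% — and a pair is removed under the first rule either mate fails;
this makes the per-reason counts an exact partition of the input.
Complexity is the distinct 3-mer fraction, |{3-mers}|/(L−2): a
homopolymer scores 1/(L−2) ≈ 0, a dinucleotide repeat 2/(L−2), a random
100-mer ≈ 1. An adjacent-mismatch definition (as in fastp) would score
perfect dinucleotide repeats as maximally complex, which contradicts
their role as the canonical low-complexity artifact; the distinct-k-mer
definition ranks both artifact classes low.

All thresholds are strict inequalities; filtering is idempotent and
removal is pair-level so downstream pairing stays intact.

## Profiling and TPM normalization

Reads surviving QC are screened against decoy references (host genome,
prokaryotic catalog, rRNA database — any FASTA set): a pair is removed
when either mate shares ≥ 50% of its canonical 31-mers with the decoy
index. Remaining pairs are scored against every catalog genome by the
number of distinct canonical 31-mers shared over both mates and assigned
to the unique top scorer; ties and zero-score pairs are discarded as
ambiguous. The same conservative tie rule applies when importing
external alignments (SAM best hits). Pseudo-alignment by k-mers replaces
a gapped aligner deliberately: the package's contribution is the
counting and normalization; real alignments can be dropped in via the
assignment-table reader.

Counts become abundances in two steps: divide each genome's count by its
genome length (so read yield proportional to genome size cancels), then
close each sample to one million. Closure is exact up to float error
(measured < 1e-9 per sample, bound 1e-3 asserted); doubling a genome's
length together with its read count leaves its TPM unchanged to 1e-9
relative. Taxon roll-ups are column sums over the lineage map and
preserve row sums exactly. Note the normalization divides by genome
size only — not by read length, which is constant within a run and
cancels in the closure.

## Diversity and ordination

Richness counts taxa with abundance > 0; Shannon is −Σ p ln p (natural
log, the convention of the common ecology packages). Alpha diversity is
computed on untransformed fraction-scale profiles. Bray–Curtis operates
on square-root transformed fractions — the transform damps the dominance
of the most abundant taxa; the sqrt scope is Bray–Curtis only. PCoA is
the classical Gower construction: B = −½·J·D²·J, eigendecomposition,
coordinates eᵢ√λᵢ for positive eigenvalues; negative eigenvalues (from
non-Euclidean dissimilarities) are dropped from both the coordinates
and the explained-variance denominator. On distances from collinear
points the embedding is exact to 1e-9, which the suite asserts.

PERMANOVA partitions squared distances: SS_total = Σ_{i<j} d²ᵢⱼ/n,
SS_within summed per group, pseudo-F = (SS_between/(g−1)) /
(SS_within/(n−g)), and p from label permutations with the +1 correction
(p ∈ [1/(n_perm+1), 1]). The statistic matches a full-enumeration oracle
exactly on n = 6 and an independent implementation (scikit-bio) on
random tables; type-I error at α = 0.05 is calibrated to 0.05 ± 0.02
over 500 null simulations (n = 30, 199 permutations).

## Differential abundance

Per taxon: a two-sided Wilcoxon rank-sum p (exact enumeration when
n ≤ 12 without ties, else the normal approximation with tie-corrected
variance and continuity correction), BH adjustment across taxa, fold
change (max mean + 1e-6)/(min mean + 1e-6) — the pseudocount is one TPM
on the fraction scale and bounds ratios against zero denominators — and
an LDA effect score.

The LDA score is a deliberately simplified, fully specified LEfSe-style
statistic: over 30 bootstrap rounds, subsample each group without
replacement at 2/3, take |mean_A − mean_B| on the per-million scale, and
report log10(1 + mean over rounds). On noiseless 10,000-vs-100 TPM
separation this gives ≈ 4.0; the conventional > 2 cutoff corresponds to
a ~100 TPM mean separation. Full multivariate LEfSe (Kruskal–Wallis
gate, per-subject LDA axis) is intentionally out of scope; the variant
here is deterministic given a seed and reproduces the ">2 on per-million
data" operating point.

A taxon passes the cascade when FC > 1.2, LDA > 2, the larger group
mean exceeds 0.01 on the fraction scale (max-of-group-means, so a taxon
present in only one group remains detectable; 0.01 TPM would be
vacuous), and q < 0.05 — all strict. On planted FC-4 taxa at 5% mean
abundance (n = 50/50, log-noise 0.5) the screen reaches sensitivity 1.0
with 0 false passes among 95 nulls (mean over 20 replicates).

## Synthetic data

Genomes are i.i.d. base strings at a set GC content. `mutate_to_ani`
substitutes exactly round((1−ANI)·L) positions chosen without
replacement, so the realized identity equals the target to rounding.
Reads are drawn from fragments with uniform starts (insert 350 bp,
2×100 bp by default), strand flipped with probability 0.5, per-base
substitution errors, constant Q30 qualities, and a recorded true origin
per read; contaminant pairs are mixed in at a set fraction.

Abundance studies are log-normal per taxon: log x = log(base mean) +
log(FC, enriched group only) + σ·z with σ = `noise_sd_log` (default
0.5, a typical between-subject spread for gut taxa). Correlation blocks
share a latent factor in a **variance-preserving** way: z = ρ·f +
√(1−ρ²)·ε, so a block member keeps the same marginal variance as a null
taxon and the within-block log-scale correlation is ρ². An additive
latent factor (marginal variance σ² + loading²) was rejected: it makes
block members swing ~10× more than the rest of the community, and after
closure that mass swing leaks strong spurious correlations into all
other taxa. Base means default to a log-uniform draw over [1e-4, 1e-1],
the span from rare to dominant detectable gut taxa; tests that isolate
correlation-recovery behavior set equal base means so compositional
dominance does not confound the question under study. Rows are closed
to the TPM scale at the end.

What the generator does **not** emulate: indels and chimeras, GC bias,
strain mixtures, zero inflation (log-normal abundances are never exactly
zero, so prevalence filters are exercised with explicitly constructed
tables), and real taxon-taxon interaction structure. Passing tests
therefore demonstrate the correctness and calibration of the machinery,
not performance on real cohorts.

## Co-occurrence networks

Input taxa (typically the differential set) pass a prevalence filter
(detected in strictly more than 10% of samples), then a Spearman
correlation matrix (midranks; Spearman because relative abundances are
compositional and zero-inflated; Pearson available). The correlation
cutoff is selected by the random-matrix-theory criterion: for each
candidate threshold, entries below it are zeroed (diagonal kept), and
the nearest-neighbor spacing distribution (NNSD) of the masked matrix's
eigenvalues is tested against the Poisson law P(s) = e^(−s) by
Kolmogorov–Smirnov. Eigenvalues are deduplicated up to numerical noise
(1e-9 relative — exact multiplicities come out of `eigh` perturbed at
machine precision) and unfolded through a monotone PCHIP fit to the
empirical spectral CDF at max(8, ⌈n/10⌉) evenly spaced knots; spacings
are normalized to unit mean. The knot floor of 8 matters: with the ~30
distinct eigenvalues a modular spectrum can have, a stiffer fit cannot
absorb the global level density and the test wrongly rejects Poisson on
genuinely modular matrices. The scan ascends from 0.30 in steps of 0.01
and returns the smallest threshold that is Poisson (p ≥ 0.05) and stays
Poisson for two further steps; if none qualifies it returns 0.99 with a
warning. Calibration: the test accepts diagonal-random (Poisson)
spectra and rejects dense GOE (Wigner) spectra in ≥ 90% of seeds each.

Indirect edges are pruned by network deconvolution. Per connected
component with weight matrix G (zero diagonal), the spectrum of G is
scaled into (−0.9, 0.9) — the closed form diverges as the smallest
eigenvalue approaches −1, which any dense module induces — and
S = G'(I+G')⁻¹ splits observed associations into direct and
transitive-path contributions. S is rescaled to G's largest
off-diagonal magnitude (the diagonal of S is not an edge and grows
large for dense modules) and edges whose |S| falls below the network
threshold are dropped; edges with |weight| ≥ 0.999 are removed as
pathological. The output edge set is always a subset of the input's; a
0.9/0.9/0.81 triangle loses exactly the 0.81 product edge.

Topology follows the Cytoscape conventions: average neighbors 2E/N,
density 2E/(N(N−1)), characteristic path length averaged over connected
pairs only (unweighted BFS), heterogeneity sd(k)/mean(k) (population
sd), Freeman degree centralization (N/(N−2))·(k_max/(N−1) − density)
(undefined below 3 nodes), and the 10 highest-degree hubs with kingdom
labels. The panel matches hand-computed star/complete-graph values and
an independent graph library (igraph) on random graphs.

**Known limitation.** On tables of a few hundred independent null taxa,
spurious |r| ≥ 0.30 correlations are too sparse (a handful per graph at
n = 150 samples) to move the spacing distribution away from Poisson, so
the scan settles at its 0.30 floor and those few edges survive as
appendages to, or rare bridges between, planted modules. The RMT
criterion only pushes the threshold upward when sub-threshold structure
is dense, as it is in real correlation matrices; with clean simulated
nulls, planted blocks are recovered as network components with mean
Jaccard ≈ 0.95 against truth, but exact recovery in every seed is not
achievable. Cross-kingdom note: fungal and bacterial profiles are each
closed to one million separately before being correlated jointly, so
cross-kingdom compositional coupling is assumed, not derived.

## Classification

Stratified k-fold assignments are built per repeat with derived
sub-seeds (per-fold class counts within one sample of proportionality).
Defaults mirror the study design: random forest at 10-fold × 5 repeats
with 500 trees; L1-penalized logistic regression at 5-fold × 5 repeats,
features standardized on the training split and the penalty chosen by
inner 5-fold CV. Features enter on the fraction scale. Scores are
strictly out-of-fold; per repeat they are pooled into one AUC (the
rank-statistic estimator with midranks, identical to the trapezoidal
ROC area and verified against a brute-force all-pairs oracle), and the
reported AUC is the mean over repeats. The 95% CI is a stratified
bootstrap (resampling within each class, 2,000 draws) on the first
repeat's scores. Importance is the mean across folds of per-fold ranks
(impurity decrease for RF, |standardized coefficient| for LASSO), which
avoids scale artifacts between folds. Null tables give AUC ≈ 0.5 and
planted fold-change signal is detected at AUC ≥ 0.9 for both models.

A compositional caveat that matters for interpretation: enriching a
large share of the community in one group depresses every other taxon's
relative abundance there, so with many strongly planted taxa the null
taxa themselves become informative features. Importance-recovery checks
therefore plant signal in a modest share of the community (10 of 100
taxa), where the planted features dominate the rankings.

## Problem sizes

Simulation-based checks use: 500 null PERMANOVA datasets (n = 30, 199
permutations), 20 differential-screen replicates (100 taxa, n = 50/50),
100 seeds per NNSD calibration arm (120×120 matrices), 10 network
studies (200 taxa, n = 150), 10 catalog replicates (30 genomes of 30 kb
in 10 species), one 20,000-pair profiling run over 50 kb genomes, and
5 null + 1 planted classifier studies (n = 200, 200-tree forests for
the repeated arms). These sizes give stable rates (binomial SE ≤ ~0.03
on the calibration estimates) while keeping the whole suite fast on a
single core.
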