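# Methods

This note documents the models, algorithms, and numerical choices behind
`rumenomics`, and what the synthetic-study tests do and do not demonstrate
about real data.

## Study design being modelled

Two diet groups (low vs medium non-fiber carbohydrate, labelled `LC`/`MC`),
three animals each by default. Three measurement layers per animal: a 16S
OTU count table from ruminal fluid at slaughter (8 h after feeding), an
epithelial expression matrix in RPKM, and SCFA concentrations plus pH at 0,
2, 5, and 8 h after the morning feed. The integration questions are (i) does
the community differ by diet, (ii) which receptor/deacetylase genes respond,
and (iii) which taxa, SCFAs, and genes co-vary.

## Community statistics

**Count filter.** An OTU is kept iff its count is *strictly greater* than
`min_count` (default 3) in at least one sample. The detectable filter is
inclusive: relative abundance ≥ 1 % in at least one sample. Both
thresholds read "more than 3" strictly and "at least 1 %" inclusively; the
order (count filter → normalise → detectable filter) is configurable because
the two filters are logically independent.

**Aggregation.** Lineage labels missing at a rank are pooled into a single
`unclassified` column rather than dropped, so per-sample mass is conserved
exactly at every rank — aggregation is a partition of columns.

**Group overlap.** "Present in a group" means nonzero abundance in at least
one sample of the group; this is the weakest defensible presence rule and is
stated rather than hidden because at depth 50k even one read counts.

**Diversity.** Shannon entropy in nats over nonzero proportions; Simpson is
reported as the Gini–Simpson form 1 − Σp² (users of Σp² subtract from 1).
Within-clade diversity renormalises member-OTU abundances inside each sample
first; a sample where the clade is absent is flagged missing (NaN), never 0.
Group comparisons use the Welch t-test, chosen for its robustness to unequal
variances at n = 3; with both group variances zero, p is 1 for equal means
by convention.

## Ordination and separation

**Bray–Curtis** is computed directly from the definition on relative
abundances; a pair of all-zero samples has no defined dissimilarity and is
an error.

**NMDS** minimises Kruskal stress-1,
√(Σ(d̂ᵢⱼ − δᵢⱼ)² / Σδᵢⱼ²), where δ are configuration distances and d̂ the
isotonic (pool-adjacent-violators) fit of δ against the rank order of the
input dissimilarities. Ties use Kruskal's primary treatment, realised by
ordering tied input pairs by their current configuration distance before the
PAV fit. The optimiser is SMACOF: disparities are rescaled to Σd̂² = Σδ²,
then a Guttman transform updates the configuration. The recorded stress
sequence is non-increasing; iteration stops when the improvement drops below
`tol` (default 1e-10) or at `max_iter` (500). The best of `n_starts` (8)
random Gaussian starts is returned, with all randomness derived from one
seed via `numpy.random.SeedSequence` spawning, so results are exactly
reproducible.

**ANOSIM** ranks all pairwise dissimilarities jointly (average ranks on
ties); R = (r̄_between − r̄_within)/(M/2) with M = n(n−1)/2, so R ∈ [−1, 1].
The p-value uses the (1 + exceedances)/(1 + permutations) convention and can
never be zero — with 3 + 3 samples the floor is ~0.1 regardless of effect
size, a fact the package surfaces rather than papers over.

## Expression and the co-expression network

RPKM = 10⁹·count/(mapped total·length). "Expressed" means RPKM ≥ 1 in at
least one sample. Differential expression is a Welch t-test on
log2(RPKM + 1) — the pseudocount handles zeros and slightly shrinks fold
changes of weakly expressed genes. A read-level differential engine is out
of scope; results are method-comparable, not identical, to count-based
testers. The default significance rule is unadjusted p < 0.05 with
Benjamini–Hochberg available (`adjust="BH"`), because the network stage
deliberately mirrors the unadjusted convention of small-n receptor studies;
the q-value is always reported either way.

**Exact Spearman p.** With n samples, the two-sided p attached to a rank
correlation is the proportion of all n! permutations of one vector whose
tie-aware coefficient is at least as extreme as observed (the observed
ordering is one of the n!, so p ≥ 2/n!). Ties are handled correctly because
the ranks of a permuted vector are the permuted ranks, so the tie-aware
coefficient can be evaluated for every permutation at once; the null
distribution depends only on the two rank multisets and is cached on them.
Enumeration runs for n ≤ `exact_limit` (default 8; hard ceiling 9, beyond
which the permutation matrix would not fit in memory) and falls back to the
t-approximation above it, with the method tagged on every result.

At n = 6, p < 0.01 is achievable only by |ρ| = 1 (the next rung of the null
distribution is 12/720 ≈ 0.017), so every reported edge at the 0.85/0.01
thresholds reflects perfect rank agreement — the suite asserts this.

**Thresholds.** The edge rule is signed ρ > 0.85 by default (`absolute=True`
thresholds |ρ| instead, since negative co-regulation is biologically real);
the same switch exists for the OTU screen at 0.6/0.05. Seed neighbourhoods
keep seed genes, their direct neighbours that are differentially expressed,
and only seed–neighbour edges; two-hop nodes never appear. Pathway
annotation is a plain user-supplied gene → tag join (no online retrieval).

## Integration

**Molar proportions** default to the 8 h sample, matching the slaughter-time
microbiota sample; proportions are stable across time by design of the
generator and, empirically, of rumen fermentation.

**SCFA statistics** are classic fixed-effects one-way ANOVA across time
points within each group (no repeated-measures correction, matching the
simple design) plus Welch t-tests between groups per time point and on the
molar proportions.

**OTU screen.** An OTU is retained iff some SCFA molar proportion gives
ρ > 0.6 and exact p < 0.05. Constant abundance vectors have undefined
correlations and are removed with a logged reason. The removed fraction is
reported; an empty input yields a NaN (0/0) sentinel.

**CCA.** Let P be the community table divided by its grand total, r and c
its row/column sums, and Q̄ = (P − rcᵀ)/√(rcᵀ) the chi-square standardised
residuals; total inertia ‖Q̄‖² equals the chi-square statistic over the
grand total. Constraints are weighted-centred and, by default, scaled to
unit weighted variance (scale invariance of biplot scores; `standardize=False`
available). Q̄ is projected onto the column space of D_r^{1/2}X by least
squares with a pseudo-inverse, so rank-deficient constraint sets are legal;
the fitted matrix's SVD gives constrained eigenvalues λₖ = σₖ² and axes, and
the residual gives the unconstrained ones — constrained + unconstrained
inertia equals the total identically, which the suite checks to 1e-8 against
an independent QR + symmetric-eigenproblem solution and against vegan's
implementation. Species scores are V/√c, linear-combination site scores
U/√r, weighted-average site scores D_r^{-1/2}Q̄V, and biplot scores the
weighted correlations of constraints with the LC axes. Axes with σ² below
1e-10 × total inertia are dropped as numerical zeros.

With 6 sites and ~18 constraints (6 proportions + 12 genes) the constraint
space always spans the full site space: CCA then degenerates to plain
correspondence analysis. The package warns when rank = n − 1 and reports the
rank rather than hiding the degeneracy; at this design scale the triplot is
descriptive, not inferential.

**Genus centroids** are the (column-mass-weighted by default, or uniform)
means of member-OTU species scores. **Association signs** report the exact
Spearman ρ, p, and sign for named SCFA/gene/taxon pairs — at n = 6 the sign
is the robust quantity, not the p.

## The synthetic-study generator

One latent variable per sample — the butyrate molar proportion — couples the
three layers: it sets the SCFA table, multiplies the expected abundance of
"producer" OTUs (assigned to the genus Clostridium_IV) by
exp(1.5·z) on the log scale, and enters two genes' expression (HDAC1 with a
negative loading, GPR1 positive). This is precisely the covariation the
integration stage must recover.

- **Counts**: Dirichlet-multinomial at fixed depth 50 000 with concentration
  300 — overdispersed relative to a plain multinomial, the standard
  microbiome count model. 300 OTUs in 40 genera (≥ 1 OTU each, ~10 %
  genus-unclassified), lognormal(0, 1.5) base abundances with producers set
  near 1 % each; 20 group-shifted OTUs at ±1.5 log2 fold in MC.
- **Expression**: log2 values = gene baseline N(4, 1.5) + group effect
  (±3 log2 for the 12-gene GPR/HDAC panel, directions matching the diet
  response the design emulates) + a shared N(0,1) block factor per seed gene
  and its 4 planted neighbours + N(0, 0.25) noise, exponentiated to RPKM.
  Block members inherit the seed's group effect, so planted neighbours are
  differentially expressed, as the neighbourhood analysis expects; with
  noise at 0 a block is exactly monotone (pairwise ρ = 1).
- **SCFAs**: per-sample proportions drawn once (logn jitter 0.15 around a
  typical rumen profile 65/20/10/2/1.2/1.8 %) and held across time; MC gets
  +0.05 butyrate proportion. Totals follow a postprandial curve
  (70→95→90→72 mmol/L) with +25 mmol/L in MC at 2 and 5 h, so acetate,
  butyrate, and total all rise together in MC; pH dips after feeding with a
  +0.25 MC shift at 5 h. All concentrations are clipped strictly positive.
- **Seeding**: the three generators draw from independent child streams of
  one `SeedSequence`, so changing the transcriptome size cannot perturb the
  microbiome draw; identical configs give byte-identical tables.

Two presets are the study conditions: the design-faithful 3 per group
(documented as low-power: the exact-p floor at n = 6 and the ANOSIM floor at
0.1 are features, not bugs) and `SyntheticConfig.recovery()` with 20 per
group for recovery measurements. At recovery scale the screen reaches
sensitivity ≥ 0.9 at a false-positive rate ≤ 0.1 and the two headline
association signs are recovered in ≥ 95 % of replicates; at study scale only
the direction (producers retained more often than non-producers) is
guaranteed.

**What the generator does not emulate**: read-level artifacts (chimeras, PCR
bias), phylogenetic signal in the taxonomy, compositional spike-ins,
repeated-measures correlation beyond the shared latent, or realistic
gene–gene correlation beyond the planted blocks. Passing tests therefore
demonstrate correctness of the statistics and recoverability of planted
effects under a clean generative model, not performance on messy field data.

## Problem sizes and tolerances

Monte-Carlo calibrations use 200–500 replicates at reduced table sizes
(40–60 OTUs, 2 000 reads); recovery measurements use 100 replicates at the
full default sizes. Eigen-quantities are compared to oracles at 1e-8;
closed-form diversity indices at 1e-12; permutation p-values exactly.
Stress histories are non-increasing by construction of the recorded
sequence; NMDS coordinate reproducibility is exact for a fixed seed.

## Known limitations

- The differential-expression stage is a two-group location test on
  normalised values; it does not model count overdispersion and will not
  match read-level testers numerically.
- ANOSIM/NMDS operate on a single dissimilarity; no phylogenetic
  (UniFrac-style) distances, which would need a tree.
- CCA significance is not assessed (no permutation test on constrained
  inertia); at 6 sites with a saturating constraint set it would be
  meaningless.
- The exact-p machinery is quadratic in gene count when many pairs pass the
  ρ threshold; for thousands of genes with many ties, expect the cache to
  matter.
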