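# Methods

## Model and assumptions

The package treats "functional linkage" as an undirected relation between
gene symbols, evidenced by heterogeneous sources that are filtered
separately and then pooled without weighting: one surviving record = one
line of evidence, and a pair may carry many. No attempt is made to model
evidence reliability beyond the per-source filters; downstream tallies
(internode ranking, the ≥ 3-evidence confidence filter) simply count
records. Gene identity is a plain uppercase symbol; ortholog and probe
mapping are out of scope, so inputs must already be on a common symbol
space.

An *internode* is defined purely combinatorially: a gene outside both parts
lists with at least one edge to each. This is a one-hop notion — paths
through two or more consecutive linkers are deliberately not considered, and
edge direction (which none of the sources provides reliably) is ignored.

## Per-source filters and their parameters

| parameter | default | meaning |
|---|---|---|
| `lab_count_min` | 2 | independent laboratories required for `PPIhigh` |
| `corr_method` | pearson | co-expression statistic for `PPIcorr` (spearman available) |
| `corr_fdr_alpha` | 0.05 | Benjamini–Hochberg FDR level on the correlation test |
| `currency_metabolites` | ATP, ADP, AMP, NAD(H), NADP(H), H2O, H+, CO2, Pi, CoA | excluded from reaction adjacency |
| `tissues` | adipose, muscle, liver, heart | tissue-expression requirement (≥ 1 of these) |
| `min_evidence` | 3 | per-side evidence for the high-confidence internode subset |

Choices worth explaining:

- **PPIcorr significance.** The source procedure for rescuing single-lab
  interactions by co-expression does not state a statistic or cutoff. We
  test the pairwise correlation across the compendium samples (two-sided;
  either sign counts, since negative co-regulation is still co-regulation)
  and keep pairs significant at BH-FDR < 0.05 across the candidate edges.
  Both the method and the level are config keys.
- **Currency metabolites.** Without an exclusion list, ATP/H2O/NAD link
  most of metabolism into one clique and reaction adjacency loses meaning.
  The default list is the conventional one; it is configurable because the
  right list depends on the reconstruction in use.
- **Genes absent from inputs fail closed.** A gene without tissue calls is
  treated as unexpressed; a gene absent from the co-expression matrix cannot
  gain `PPIcorr` support. Both events are logged with counts rather than
  silently passing.
- **Parts-list overlap.** A gene appearing in both systems is a system
  member twice over, not a linker: it is excluded from internode candidacy
  and counts for either side of a direct link, with a warning.

## Ranking and connectivity accounting

Internodes are ordered by total evidence, then total links, then symbol —
every output of the package has a deterministic order. "Indirect
connections" of a system gene are counted as distinct (internode,
opposite-system partner) pairs, i.e. the number of length-2 paths through a
linker; this is one of several defensible units (per-evidence accounting
gives larger numbers) and is stated in the export header.

## Null machinery

Empirical p-values use add-one smoothing, p = (b + 1)/(n + 1), which keeps
p ≥ 1/(n + 1) and is standard for Monte-Carlo tests; the raw frequency b/n
is exposed alongside for comparison with literature that reports it.
Network randomization defaults to degree-preserving double-edge swaps
(5–10 swaps per edge mixes the graphs used here; the Jaccard overlap with
the original edge set falls below 0.5). An Erdős–Rényi matched-density mode
exists because the randomization behind a published "simulated network" is
rarely specified; degree preservation is the stricter and default control.
All random operations take an explicit seed; there is no global RNG state.

## Signature enrichment

Pearson χ² without continuity correction on the 2×2 overlap table, matching
the large-count regime the test is meant for; Fisher's exact is a config
option for small tables. Sets overlapping the query in fewer than
`min_overlap = 10` genes are excluded *before* testing, and the Bonferroni
denominator is the number of sets actually tested. Note the min-overlap
filter makes the procedure meaningful only when expected overlaps are of
order 10 or more (large sets and/or large queries); applying it when
E[overlap] ≪ 10 selects upper-tail outliers and inflates apparent
significance — the negative-control check in the acceptance suite therefore
uses collection sizes in that valid regime, and counts significant
*enriched* sets (odds ratio > 1), which is the claim a negative control of
an enrichment analysis tests.

## Expression GSEA

Ranking uses the signal-to-noise statistic (μ₁−μ₀)/(σ₁+σ₀) with each group
standard deviation floored at max(0.2·|μ|, 0.2), so near-constant genes
cannot dominate; a Welch-t metric is available. Ties are broken
alphabetically for determinism. The enrichment score is the signed maximum
deviation of the weighted running sum (hits add |stat|^w normalized over
hits, default w = 1; misses subtract 1/(N−hits)). Significance restricts
the permutation null to the sign of the observed ES: p is the add-one
fraction of same-sign null ES with magnitude ≥ |ES|, NES divides ES by the
mean magnitude of same-sign null ES, and the FDR q compares same-sign null
and observed NES distributions. Permutation is by condition label with
re-ranking when both groups have ≥ 7 samples, by gene-set membership
otherwise ('auto'); a set with no same-sign null draws gets p = 1 and is
flagged rather than given a fabricated value.

## GWAS gene scores

SNPs map to every gene whose ±`window_bp` (default 500 kb) interval
contains them, 1-based inclusive on both ends; a SNP may serve several
genes. The gene score is −log10 of the best SNP p (ties broken by lowest
position), residualized by OLS on log10(region length) and log10(SNP
count). This is a deliberate simplification of the published gene-score
procedure, whose confounder set also includes linkage-disequilibrium-derived
covariates from a genotype panel this package does not consume; the
regression accepts extra covariate columns when the caller has them, and
the simplification is logged. Cutoff enrichment counts set genes strictly
above the empirical score quantile (ties at the cutoff excluded) against
size-matched random sets from the scored universe; genes with no mapped SNP
are excluded from both the set and the sampling universe. No HLA-region
exclusion is applied by default.

## Risk score

For SNPs in linkage equilibrium the effect of the unweighted allele-count
score on a trait is estimable from summary statistics: β̂ = Σwⱼβⱼ/Σwⱼ. The
default weights are wⱼ = 1/seⱼ², under which the estimator converges to the
individual-level least-squares slope of trait on score (seⱼ² is inversely
proportional to SNP j's genotype variance, i.e. its leverage in that
regression); the acceptance suite verifies this against an explicit
individual-level simulation. A literal 1/seⱼ weighting is provided as an
option because the defining formula in the source material is ambiguous.
Risk-allele orientation must come from the *discovery* trait (an external
SNP→allele map); self-orientation on the test trait's own signs is
supported for defining risk but would bias a test-trait pooled effect
upward under the null, which is why `score_test_for_gene_set` takes the
orientation map separately. Under a simulated global null the two-sided p
is uniform (checked by Kolmogorov–Smirnov in the test suite).

## Synthetic data: what it does and does not emulate

`gen_interactome` plants linker genes with known per-side link and evidence
counts, confines background genes to a single system (so planted linkers
are exactly the recoverable ones), and emits every raw input the assembly
filters read, including a co-expression matrix in which planted
co-expressed pairs share a latent factor (r ≈ 0.98) and everything else is
independent noise. `gen_expression` adds a constant shift (in noise-sd
units) to planted sets in one condition over iid normal baselines.
`gen_sumstats` simulates independent SNPs (genotype ~ Binomial(2, maf),
additive phenotype with N(0,1) noise) and computes per-SNP marginal
regressions; genes are spaced 2.2 Mb apart so every SNP has an unambiguous
gene at the 500 kb window.

None of these reproduce real-data complications: linkage disequilibrium,
expression heteroskedasticity and batch structure, scale-free interactome
degree distributions, literature-bias in evidence multiplicity. Passing
tests therefore demonstrate correctness of the algorithms under their own
stated assumptions, not robustness to violations of those assumptions.

## Problem sizes and numerical choices

The test and acceptance workloads use deliberately modest sizes — synthetic
networks of 100–600 genes, expression matrices of 2000 genes × 24 samples
with 1000 permutations, GWAS cohorts of 5000 individuals × 18 SNPs, 50-fold
replication for calibration checks — chosen so the whole suite reruns in
minutes while leaving the statistical assertions well-powered. Floats are
written with full repr precision and read back with round-trip parsing, so
writer/reader pairs are exact identities. Degenerate inputs (zero-variance
expression groups, beta = 0 risk direction, single scored gene, sets
covering the whole ranked list, empty overlap after filtering) are either
handled by a documented floor/flag or rejected with a specific error, never
silently.

## Known limitations

- Evidence records are unweighted; a promiscuous complex contributes as
  many records as a replicated physical interaction.
- The gene-score confounder regression omits LD structure entirely.
- GSEA FDR uses the pooled same-sign null comparison without monotonicity
  enforcement across sets, so q-values from very small set collections are
  coarse.
- The internode definition is one-hop; systems linked only through chains
  of two or more non-system genes are invisible to it.
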