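# Methods

This note records the models implemented in picotrait, the defaults and the
reasoning behind them, what the synthetic-data generators do and do not
emulate, and the numerical choices that matter for reproducing results.

## Trait model and ancestral reconstruction

The trait is binary (0 = pathway absent, 1 = present) and evolves on a rooted
phylogeny with branch lengths in substitutions per site.

**Sankoff parsimony.** Costs are per-event: `cost_gain` for 0→1 and
`cost_loss` for 1→0, both finite and positive. The dynamic program computes
the exact minimum total cost; a second (outside-subtree) pass recovers, for
every node, the full set of states attainable in *some* minimum-cost
reconstruction. Ties are therefore reported as ambiguity rather than broken
arbitrarily — downstream summaries should see them. Tips with missing state
contribute zero cost to either assignment and are never dropped, because
trait matrices routinely mix assembled genomes with PCR-screened cells that
have no assembly.

**Mk likelihood.** The 2-state chain with gain rate q01 and loss rate q10
has the closed-form transition matrix (q = q01 + q10, π₁ = q01/q):
P₀₀(t) = π₀ + π₁e^(−qt), P₀₁(t) = π₁(1 − e^(−qt)), etc. Felsenstein pruning
runs over a flattened postorder in scalar arithmetic with per-node rescaling;
missing tips carry the flat partial (1, 1). The root prior is configurable:
`"equal"` (default) or `"stationary"`. Tools differ silently on this
convention and the choice shifts the fitted rates on asymmetric data, so
both are exposed and the choice should be reported with any result.

**Rate fitting.** Maximum likelihood in log-rate space from a fixed 5×5
start grid spanning [1e-4, 1e3] (5 points when symmetric), refining the
three best starts with L-BFGS-B inside [1e-6, 1e4] at an lnL tolerance of
about 1e-8. The result is deterministic and is floored at the best grid
point. When a rate's events are absent from the data (e.g. no gains), its
MLE runs to the lower bound; the likelihood is flat there and the reported
value should be read as "indistinguishable from zero".

**Model comparison.** `likelihood_ratio_test` computes 2(lnL_alt − lnL_null)
against the upper χ² tail. A negative statistic (alternative converged
epsilon-worse than the null) is reported as-is with a warning and p = 1.
For the symmetric-vs-asymmetric Mk comparison the regularity conditions
hold (the null is interior), so χ²₁ is the correct reference; for
branch-site tests χ²₁ is the standard conservative choice.

## Gene content with partial assemblies

Single-cell assemblies are incomplete, so presence counts under-estimate
true frequencies. With n genomes at median recovery M, a cluster present in
every *cell* is expected in about n·M *assemblies*; the core threshold is
therefore ⌊n·M⌋ (floor, fixed by the worked example 22 × 0.87 → 19).
Clusters at/above the threshold (core) and in fewer than 3 genomes (too
sparse to be informative) are excluded; the filter is idempotent.

Covariation among the flexible remainder uses Jaccard distance between
genome-presence sets and average linkage (scipy's UPGMA on the condensed
distance matrix). Enrichment relative to a marker-positive genome set
evaluates both hypergeometric tails — over- and under-representation are
reported as separate rows, each BH-corrected across clusters within its
direction, since the GO-style tools this mirrors treat the two sides as
separate tests. The test universe is the post-filter flexible set.

Concordance arithmetic: integer percents use round-half-up (59/61 → 97%,
59/81 → 73%); raw fractions are kept alongside. The expected number of
annotated positives among screen positives is round(screen⁺ × median
recovery), and the post hoc false-negative rate is (expected − observed)/
expected, reported as missing when the expectation is zero.

## Distances and population divergence

`percent_difference` defaults to mothur-style `onegap` handling: a
contiguous gap run in one sequence of a pair counts as a single difference,
terminal gap overhangs are excluded, and both-gap columns are skipped. An
`ignore` mode (drop any column with a gap in the pair) is provided; the
mode is part of any reported result. Representative-sequence clustering
cuts the average-linkage tree at the distance cutoff (default 0.01) and
picks the member with minimum summed within-cluster distance, ties broken
lexicographically.

Unweighted UniFrac is the branch length leading exclusively to one
population's leaves divided by the total branch length below the root
(root edge excluded); the tree must be rooted — midpoint rooting is the
intended preparation and is implemented directly (longest leaf-to-leaf
path, root at its midpoint) rather than delegated. The P-test is the
Fitch/Hartigan minimum number of population-label changes, which also
handles multifurcations. Significance permutes leaf labels preserving
group sizes, with p = (k + 1)/(n + 1): unbiased under exchangeability and
never zero. "Extreme" is ≥ observed for UniFrac and ≤ observed for the
P-test (fewer changes = more segregation). On small trees both statistics
take few distinct values, so null p-values are discrete and conservative
(super-uniform) rather than exactly uniform — the calibration tests check
exactly that property. Subsampling replicates are independent draws
without replacement (not a partition), default 9 per population × 3
replicates.

## Codon models

The GY94 rate matrix on the 61 sense codons of the universal code:
q_ij = π_j·κ^[transition]·ω^[nonsynonymous] for single-nucleotide changes,
zero otherwise, scaled to one expected substitution per unit time at π.
Codon frequencies come from F3x4 (position-specific nucleotide frequencies,
renormalized over sense codons, floored at 1e-6 to keep the chain
irreducible) or are uniform. P(t) uses the reversible eigendecomposition
(symmetrization by √π), so mixtures over many ω classes reuse one
decomposition per class across all branches.

Site models: M0 (one ω); M1a (ω₀ ∈ (0,1) estimated, neutral class ω₁ = 1);
M2a (M1a plus ω₂ ≥ 1); M7 (Beta(p, q) discretized into K = 10
equal-probability classes at their conditional means; K configurable);
M8 (M7 plus a positive class). A strict-neutral legacy switch fixes
ω₀ = 0 in M1 for comparison with older analyses; the default is M1a.
Branch-site model A has classes 0/1/2a/2b with the standard proportion
structure; a branch is foreground when its descendant leaf set equals one
of the supplied clades, matching the single-marked-branch convention. H0
fixes the foreground ω₂ = 1.

Branch lengths are taken as given and held fixed; a single global rate
multiplier is estimated to absorb the nucleotide-units vs codon-units
difference. Fitting is bounded L-BFGS-B on transformed parameters
(log rates, logit proportions, ω₂ = 1 + e^x), with each alternative model
seeded from its null's optimum plus one exploratory start containing a real
positive-selection class — the nested seed alone is a stationary boundary
point the optimizer cannot leave. Nesting (lnL(M2a) ≥ lnL(M1a),
lnL(M8) ≥ lnL(M7)) then holds at convergence and is additionally guarded.
M0 is nested in M1a only when its fitted ω < 1 (the boundary p₀ → 1 is
open), so that inequality is asserted to 1e-3 rather than exactly.
Gapped or ambiguous codons are marginalized per taxon (partial likelihood
over compatible sense codons), not dropped; in-frame stops are an error
with coordinates. Pruning is per-pattern with per-node rescaling;
mixtures combine class log-likelihoods by logsumexp.

The NG86 counting estimator (synonymous/nonsynonymous site and pathway
counts with Jukes–Cantor correction) is included purely as an independent
sanity check; changes to stop codons count as nonsynonymous in site counts
and pathways through stops are excluded when an alternative exists. Note
that NG86 pathway-averaging can assign nonsynonymous counts to codon pairs
produced by purely synonymous substitution histories (e.g. CGT→AGA via
CGA), so "ω = 0 implies NG86 dN = 0" holds only per substitution event —
the invariant actually guaranteed is that the protein sequence never
changes.

## Recombination statistics

The primitives per genomic region are κ, δ (mean import length, bp), ν
(import divergence per site) and R/θ (import initiation relative to
mutation), as estimated by ClonalFrameML-style inference, which this
package consumes rather than reimplements — the contribution here is the
derived statistics and their validation. Derived quantities are always
recomputed from primitives: ρ/θ = 2·(R/θ) and r/m = (R/θ)·δ·ν. Consistency
checks against published derived values default to a 5% tolerance because
published primitives are rounded to 3 significant figures; recomputing
from rounded inputs can differ by a few percent from values computed at
machine precision (e.g. a published 33.2 recomputes to 32.1).

## Synthetic-data generators

Every generator is a pure function of its inputs and a mandatory integer
seed (one `numpy` Generator per call, no global state).

* **Yule trees** (pure birth, exponential waits at rate b·k, tips extended
  to the present) stand in for externally inferred phylogenies. Default
  birth rate 1; a 500-leaf Yule tree carries roughly the hundreds of
  gain/loss events needed for rate recovery at (q01, q10) = (0.5, 1.0),
  the regime the recovery calibration uses.
* **Binary traits** evolve by exact waiting-time simulation; the full
  internal-node history is returned so reconstruction can be scored
  against truth.
* **Partial genomes**: each present gene retained i.i.d. Bernoulli(recovery).
  Real single-cell amplification bias is spatially correlated along the
  genome; independent thinning reproduces the marginal recovery fraction
  but not that correlation, so tests passing here say nothing about
  clustered dropout.
* **Recombinant alignments**: per branch, point mutations (rate θ per site,
  Jukes–Cantor moves, optional κ weighting) and import initiations (rate
  (R/θ)·θ per site) arrive as Poisson processes; each import covers a
  geometric tract with mean δ truncated at the linear sequence end, and
  every tract site is replaced with probability ν (drawn from a diverged
  donor pool, not a coalescent). Overlapping imports are permitted; events
  apply in time order. The event log records every event, so realized
  r/m = (import-substituted sites)/(point mutations) is measurable and
  converges to (R/θ)·δ·ν — the headline identity — up to an O(δ/L)
  truncation deficit.
* **Codon alignments**: each site draws a class once (no switching), then
  evolves under the class's GY94 matrix; stop codons cannot occur.
* **Two-population trees**: "complete" joins two independent Yule clades
  (reciprocal monophyly); "none" interleaves labels randomly on one tree.
  Real population structure is intermediate; these are the two calibration
  endpoints, not a demographic model.

## Problem sizes used in the shipped checks

The calibration battery uses: 200 random 6-leaf instances for the
parsimony-vs-enumeration check; 3–4-leaf trees for likelihood enumeration
(agreement to 1e-9); 50 replicates of 500-leaf trait recovery (pass =
both rates within a factor 1.5 in ≥ 90% of replicates); 200 random tables
for BH null FDR; 200 trees × 99 permutations for permutation-test
calibration; ≥ 1e6 site-branch units for realized r/m (within 10% of the
product); and 8 taxa × 200 codons for codon-model recovery with 20 null
replicates for LRT calibration. These sizes give comfortable Monte-Carlo
margins for the stated pass criteria while keeping the full battery around
a minute of CPU.

## Known limitations

* Only binary traits; no covarion or hidden-rate models; no stochastic
  character mapping.
* The Mk fit's agreement with any particular published reconstruction
  depends on the unstated root-prior and branch-length conventions of the
  original tool; both priors are provided but neither is asserted as "the"
  published setting.
* Codon machinery covers the universal code only; no BEB site
  identification; CodonFreq variants other than F3x4/uniform are not
  implemented.
* Tree inference itself (and alignment) is out of scope: trees are inputs,
  or come from the Yule generator in tests.
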