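# Methods

## Model and procedure

The pipeline scores each miRNA by how over-represented its target genes
are across a curated panel of pathways, in five steps.

**1. Pathway TF extension.**  Each pathway's gene set is extended with the
upstream transcription factors of its *core* members, taken from an
explicit regulator→target edge table.  The extension is single-pass and
one level deep: TFs of core genes are added, TFs of TFs are not, so the
operation is idempotent and pathway size cannot blow up transitively.
Gene identity is plain symbol equality after one normalization
(strip + uppercase); no identifier conversion is attempted.

**2. Contingency construction.**  The statistical background is the
*target universe* U, the union of all analyzed miRNAs' target sets.  Genes
never annotated as anyone's target carry no information about targeting
and are excluded: each pathway is restricted to P = extended ∩ U before
counting.  For a miRNA with target set T the table is
Np⁺ = |T ∩ P|, Np⁻ = |P| − Np⁺, Nm⁺ = |T|, Nm⁻ = |U| − |T|.
Since P does not depend on the miRNA, a pathway with P = ∅ is degenerate
for *every* miRNA; such pathways are dropped from the analysis (and their
weight from Σwᵢ) and logged, rather than contributing p = 1 — an
untestable pathway carries no evidence either way.

**3. One-tailed Fisher test.**  Enrichment is the hypergeometric upper
tail P(X ≥ Np⁺) with population N = |U|, K = |P| success states, n = |T|
draws (`scipy.stats.hypergeom.sf`).  Np⁺ = 0 gives exactly p = 1.

**4. FDR.**  Benjamini–Hochberg step-up, applied per miRNA across its
pathway p-values (default).  Per-miRNA scope is the default because the
subsequent combination is per miRNA; a global pool would couple miRNAs'
combined scores through each other's p-values.  A `global` scope switch
exists.  BH is implemented directly (sort, (p·m)/i, reversed cumulative
minimum) rather than through a library call so that the grouped scope is
first-class and the floating-point operation order is pinned down; a unit
test cross-checks against `statsmodels.multipletests(method="fdr_bh")`.

**5. Weighted Lancaster combination.**  Each adjusted p is transformed
through the (1−p) quantile of a chi-square with df = w, where w is the
pathway's relevance-class weight (A → 2.0, B → 1.0, C → 0.5, configurable).
The transform is realized as Gamma(w/2, scale = 2), which makes fractional
df exact and reduces to Fisher's −2 ln p at w = 2.  The statistic is
T = Σᵢ transform(pᵢ, wᵢ).  Combination is applied to *adjusted* p-values
(FDR first, combination second), which follows the reference procedure
even though combining adjusted p-values is statistically unconventional; a
`combine_on="raw"` switch supports sensitivity analysis.  Underflowed
p = 0 inputs are clamped to the smallest positive float and logged.
miRNAs selected at strict p < 0.01, ranked ascending by combined p with
ties broken by descending T, then name.

## The null distribution of T

Under independence T ~ χ²(Σwᵢ) — this limit is verified to 1e−10 against
the classical Fisher combined test when all weights are 2.  Two effects
break independence in practice: pathways share genes (positive correlation
between the single tests), and the BH step makes the combined inputs
strongly non-uniform even under the global null.  The default null is
therefore estimated by permutation: `n_permutations` (default 1000)
pseudo-miRNAs — uniform random gene subsets of the universe, sizes
resampled from the empirical real target-set sizes — are pushed through
the *identical* count → Fisher → FDR → Lancaster path, and T's null is
approximated by a Brown-style moment match, scale = Var(T)/(2 E[T]) and
df_eff = 2 E[T]²/Var(T).  The raw permutation statistics are retained so a
pure permutation p-value, (1 + #{T_perm ≥ T})/(1 + n_perm), is available
as a third option.  Degenerate permutation variance falls back to the
independent null with a warning.

Two empirical facts about this null are worth knowing.  First, with
adjusted-p combination the effective df is far below Σwᵢ (tenths instead
of tens): BH pushes most null p-values toward 1, so T concentrates near 0
and only the moment-matched/permutation nulls are calibrated — the
independent null is meaningless in this regime.  Second, even with raw-p
combination and disjoint pathways the fitted scale sits slightly below 1
(≈ 0.8 at the sizes used here): hypergeometric p-values are discrete and
stochastically larger than uniform, deflating E[T] below the continuous
chi-square value.  This is a property of exact tests on finite tables, not
an estimation error.

## Filters and the random control

The expression filter keeps miRNAs with at least one tissue/cell label in
a declared vocabulary (default: lung tissue, B lymphocytes, natural killer
lymphocytes, monocytes, dendritic cells, granulocytes, A549).  The
intragenic filter keeps miRNAs hosted inside any gene (core or TF) of the
analyzed pathways.  The two criteria combine by union by default —
intersection is available — and each retained miRNA carries provenance
saying which criterion admitted it.  Filters act *before* enrichment by
default (they define the analyzed set, and hence the target universe); a
post-hoc mode only masks the selection flags.  Filtering never changes a
p-value.

The random-pathway control samples k pathways (default 39) uniformly
without replacement from a pool, assigns relevance classes by policy
(`preserve_proportions` resamples labels from given class proportions,
uniform thirds when none are supplied; `all_B` is the neutral
alternative), and replays the full pipeline with the same seed discipline.

## Synthetic data: what it emulates and what it does not

The generator produces every input file the pipeline reads (GMT, class
table, TF edges, VMT/CMT target TSVs, expression and host tables, and a
truth table of planted signals) with deterministic names, so the whole
tool is testable offline.  Default study conditions: 4000 genes, 39
pathways of 25–60 genes split evenly across classes A/B/C (assigned in
deterministic blocks), 500 miRNAs with 100–300 targets, CMT = VMT plus 50%
extra uniform targets (guaranteeing the superset property), a TF pool of
5% of genes with edge density 0.01, 80% expression coverage, 30%
intragenic miRNAs.  These sizes keep every simulation-based check within
desk-scale runtimes while leaving the hypergeometric tests in a
near-continuous regime.

Pairwise pathway overlap is controlled by a shared gene pool: each pathway
draws a fraction f = 2j/(1+j) of its members from the pool, giving
expected pairwise Jaccard ≈ j; j = 0 carves exactly disjoint pathways and
fails loudly when the universe is too small.  Planted enrichment is biased
sampling: a planted miRNA draws targets with weight `enrichment_odds` on
the genes of its planted pathways and 1 elsewhere, so the expected
in-pathway count is |T|·(odds·|P|)/(odds·|P| + |U∖P|).  The weights are
applied over the *TF-extended* planted pathway sets, because the odds
parameter is meant to describe enrichment relative to the gene set the
analysis actually tests; planting into core genes only would let the TF
extension dilute the nominal odds by an arbitrary, edge-density-dependent
factor.

What the generator does **not** emulate: real pathway topology or
size distributions, miRNA nomenclature and family structure, the
heavy-tailed and correlated structure of real target annotations, or
annotation biases between validated and predicted target databases.
Passing calibration and recovery tests on these synthetics therefore shows
the statistics behave as designed under the stated sampling model — not
that any particular biological list is correct.

## Numerical choices

- Probabilities are clipped to [tiny, 1] (tiny = smallest positive
  float64); clamping is logged.
- All-pairs scoring is a single integer matrix product plus one vectorized
  hypergeometric call; a unit test pins the batch route to the scalar API.
- Ranking ties break by descending T then lexicographic name, so output
  files are byte-stable across runs; probabilities are serialized with 6
  significant digits.
- Every random draw (generator, permutation null, control sampling) flows
  from an explicit integer seed through `numpy.random.default_rng`.

## Known limitations

- Combining FDR-adjusted p-values is unconventional; the moment-matched
  null makes the resulting score calibrated, but T itself has no closed-form
  null and its nominal df is not interpretable.
- The moment match fits two moments only; extreme tail probabilities
  (far beyond the permutation range) rely on the scaled-chi-square shape.
- One flat gene namespace: inputs mixing identifier schemes must be
  harmonized upstream.
- The CMT mode assumes the caller supplies pre-aggregated predicted
  targets; no aggregation across prediction sources is performed.
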