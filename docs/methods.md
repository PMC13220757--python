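# Methods

## Study design being modelled

Each subject contributes up to two microbiome samples: one preoperative
faecal sample and one postoperative day-4 sample, the latter being
ileostomy effluent when a diverting ileostomy was formed (all preoperative
samples are faecal). Ileostomy status and SDD administration are
subject-level binary covariates; either sample may be missing. The three
scientific questions are the effect of surgery (pre vs post), of ileostomy
and of SDD on (i) overall community composition, (ii) within-sample
diversity and (iii) individual genera.

## Rarefaction and diversity

Counts are subsampled **without replacement** to a common depth (default
10 000) with `numpy`'s multivariate hypergeometric sampler; a single draw
is taken per sample under a recorded seed rather than averaging over draws,
and samples below the target depth are reported as excluded, not errors.

Shannon entropy is in natural log units; a base change is a constant factor
and all downstream comparisons are rank-based, so the choice is inert.
Faith's phylogenetic diversity is the branch-length sum of the union of
root-to-leaf paths over the observed taxa and **includes the root path** by
default (the most common convention); `include_root=False` yields the
minimal spanning subtree instead. Both Faith PD and weighted UniFrac are
computed from a postorder branch–membership table, so multifurcating and
star-shaped trees are handled exactly; Newick branches without lengths are
read as 0.0 with a warning.

Weighted UniFrac is the **raw** (non-normalised) variant
`d = Σ_b l_b |p_a(b) − p_b(b)|`; the abundance-normalised form is available
behind a flag since which variant a given study used is often unstated.
Raw weighted UniFrac is a metric, which the tests verify on random triples.

PCoA is classical scaling of the Gower-centred squared distance matrix:
eigenvalues are reported in full (negative ones included, since weighted
UniFrac need not be Euclidean-embeddable), but coordinates and explained
proportions cover only the positive spectrum, and no Cailliez/Lingoes
correction is applied.

## Complete-design PERMANOVA with subject strata

Sums of squares follow the McArdle–Anderson partition of
`G = −½·J·D²·J`: sequential (type-I) projections in the fixed term order
timepoint, ileostomy, SDD, computed by Gram–Schmidt orthonormalisation of
the centred design columns (a column whose residual norm² falls below
1e-9·n contributes zero df; a zero-df term in the observed design is an
error naming the term). Sequential SS is the default of the standard
distance-based ANOVA implementations and matches reporting three term-wise
R² values from one joint model; whether such values come from one joint or
three marginal models is often ambiguous in publications — the joint
sequential model is this package's default and the ambiguity is noted here
rather than resolved.

The permutation scheme operates on the complete subject × timepoint grid:
independent fair-coin timepoint flips within each subject, and a uniform
permutation of whole subject-level covariate vectors across subjects, drawn
jointly in each replicate. Observed flags and sample ids stay attached to
their grid cells, so restriction to observed cells after permutation drops
exactly the labels that landed on missing data. Under the complete null
this group leaves the data distribution invariant (samples within a subject
are exchangeable; covariates are independent of the data), so the test is
exact up to Monte-Carlo error. Free permutation of subjects is used for the
subject-level terms; restricting subject permutations to covariate cells is
a conceivable alternative that is not implemented.

Numerical conventions: exceedances use `F_perm ≥ F_obs − 1e-12` so
symmetry-equivalent schemes tie with the observed labelling despite
floating-point noise; ties count toward the null; Monte-Carlo
`p = (k+1)/(B+1)` (never zero), default B = 10 000; exhaustive enumeration
of all n!·2ⁿ schemes is auto-selected when that space is ≤ 100 000 and then
`p = k/N` with the identity included. A replicate in which a term loses all
degrees of freedom is counted as an exceedance (conservative) and a warning
is raised if this affects more than 1% of replicates.

Significance is declared at p < 0.05 (strict), the threshold convention of
the clinical literature this design comes from.

## Per-genus linear mixed models

For each taxon passing a 10% prevalence filter, untransformed relative
abundance is modelled as intercept + timepoint + SDD + ileostomy fixed
effects with a random subject intercept, fitted by REML (statsmodels
MixedLM) with Wald p-values. The proportion scale is chosen because effect
sizes are then directly scaled by the taxon's mean relative abundance into
a dimensionless quantity; log and arcsine-square-root responses are
available behind a flag, and whether any given study transformed before
fitting is typically unstated. If the default optimiser fails to converge
the fit is retried with Powell's method (variance components near the
boundary stall gradient methods); a still-unconverged or zero-variance
taxon is flagged and excluded rather than raising. With fewer than two
subjects contributing both samples the random intercept is unidentifiable
and the model falls back to OLS, marked in the output. BH adjustment is
applied within each factor across taxa, matching one volcano panel per
factor.

## Cohort and baseline statistics

2×2 tables use Pearson χ² **without** continuity correction — validated
against published baseline-table p-values, which reproduce to three
decimals only without the correction — switching to Fisher's exact test
when any observed cell is below 5 (the literal "counts < 5" convention,
rather than expected counts). Mann–Whitney U is exact for tie-free groups
of ≤ 25, else the tie-corrected normal approximation; Wilcoxon signed-rank
drops zero differences (Wilcoxon's original treatment), exact for ≤ 25
non-zero pairs. The two-group SDD comparison is run as a rank-sum test; a
two-group Kruskal–Wallis is the same test up to the statistic's
parameterisation, a discrepancy between methods sections and figure
captions that the package sidesteps by exposing the rank-sum form.
Alpha-diversity comparisons are paired (signed-rank) for pre-vs-post within
each ileostomy stratum — subjects missing a sample are excluded from the
pairing only — and unpaired (rank-sum) for SDD within each timepoint.

## The synthetic cohort generator

Per-sample taxon proportions are `softmax(baseline + subject intercept +
per-taxon subject deviation + Σ active effects)`, with counts multinomial
at fixed depth (Dirichlet-multinomial when an overdispersion concentration
is supplied; default off). Activation rules: `time` effects on
postoperative samples; `ileostomy` effects only on postoperative samples of
ileostomy subjects (their preoperative samples are ordinary faeces); `sdd`
effects on **all** samples of SDD subjects — the subject-level main-effect
structure the mixed model tests. The scalar subject intercept (SD 0.5)
shifts all taxa equally and hence cancels in the softmax; it documents the
absolute-scale model while the per-taxon deviations (SD 0.3) are what
induce within-subject correlation of relative abundances.

Defaults are the emulated study's margins: 214 subjects, P(SDD) = 85/214,
P(ileostomy) = 78/214, missingness 23/214 pre and 51/214 post (expected
191/163 samples), depth 10 000 (20 000 in the analysis scripts so that
rarefaction to 10 000 is a real subsampling step), 120 taxa in the library
default and 60 in the analysis scripts.

The default baseline is a deterministic geometric rank-abundance curve
(decay e^(−0.1·rank), ~0.3 SD log-normal jitter per cohort) with the
designated bloom taxa pinned at 0.4%: taxon 0 (*Enterococcus*-like) and 1
(*Klebsiella*-like) bloom after surgery (logit +3.5/+3.0), five abundant
Firmicutes-like taxa lose 1.0 logit, the rare tail (last ~40% of taxa)
loses 1.5 logits — this is what produces the postoperative **richness**
loss and hence the Faith-PD drop; evenness shifts alone leave PD flat —
ileostomy effluent additionally gains *Enterococcus*/*Escherichia*-like
mass (+1.0/+2.5) and loses *Parabacteroides*/*Lachnoclostridium*-like taxa
(−2.0 each, plus −1.5 on two Firmicutes-like taxa), and SDD adds +0.7 to an
abundant *Bacteroides*-like taxon. Effect sizes were calibrated once so
that the weighted-UniFrac variance partition shows the ordering
surgery > ileostomy > SDD with all terms significant, the qualitative
structure such cohorts display; a bloom from 0.4% to >10% is a logit shift
of ~3.5, so the magnitudes are realistic for perturbed gut communities.
The default effect table needs at least 11 taxa.

What the generator does **not** emulate: uneven sequencing depth (each
sample totals exactly `depth`, so rarefaction exclusions never occur on
synthetic data), taxonomic nomenclature, phylogenetic signal in effects
(the tree is an independent random coalescent with exponential branch
lengths, mean 0.1), missingness that depends on covariates (the real
study's postoperative missingness was concentrated in non-ileostomy
subjects), or overdispersion by default. Consequently, passing tests
demonstrate correctness of the statistical machinery under the designed
conditions, not robustness to every artefact of real sequencing data.

## Simulation studies and problem sizes

The calibration studies (in `perigut.simulations`, runnable via
`analysis/06_simulation_studies.py` and the acceptance script) use sizes
chosen to balance Monte-Carlo precision against a few minutes of runtime:

- **Type-I error**: 200 null cohorts (no injected effects; subject
  correlation retained) of 40 subjects with 20% postoperative missingness,
  499 permutations each; the per-term rejection rate at p < 0.05 estimates
  the size of the test. Note a 200-replicate binomial estimate of a 5% rate
  carries a standard error of ±1.5 percentage points.
- **Effect recovery**: 50 replicates of 200 subjects with a true
  proportion-scale time effect of 0.05 under the model's own Gaussian
  structure (subject SD 0.02, residual SD 0.03); reported as relative bias.
- **FDR**: 50 replicates of 60 subjects × 40 taxa, 10% of taxa carrying a
  time effect of 0.02, discoveries pooled at q < 0.05. Gaussian responses
  are used deliberately: in a compositional (softmax) cohort, injecting an
  effect into one taxon mechanically shifts every other taxon's relative
  abundance through the shared normalisation, so "null taxon" is only well
  defined outside the simplex and an FDR computed there would count real
  compositional spillover as false positives.
- **Recovery against the generator** (test suite): with a fixed baseline,
  no per-taxon subject deviation and no overdispersion, per-cell
  proportions are exactly `softmax(baseline + effects)`, giving a
  closed-form truth for the proportion-scale effect that the mixed model
  must recover across a grid of injected log-fold-changes.
- **Cohort fidelity**: 1 000 generator replicates at 214 subjects checking
  the realised pre/post sample margins against 191/163.

## Known limitations

- Sequential SS makes term R² order-dependent; the fixed order
  timepoint, ileostomy, SDD is a reporting convention, not a causal claim.
- Wald p-values from REML mixed models are approximate in small samples;
  no Satterthwaite/Kenward-Roger correction is applied.
- The LMM on raw proportions ignores heteroscedasticity near 0; the
  transform options mitigate but do not remove this.
- The permutation test's subject-permutation component treats subjects as
  exchangeable regardless of their missingness pattern; this is the point
  of the complete-design construction, but it assumes missingness is
  non-informative.
- `permute_complete_design` and exhaustive enumeration are pure-Python
  loops; they are comfortable up to a few hundred subjects and B = 10 000
  but are not tuned for much larger designs.
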