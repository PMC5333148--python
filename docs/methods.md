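# Methods

This note documents the statistical models, the numerical choices, and
what the synthetic cohort generator does and does not emulate.

## SRM preprocessing

The observation unit is one transition (precursor→fragment pair) in one
run, where a *run* is a single injection identified by
(subject, replicate); every sample is injected in duplicate. The fixed
pipeline order is

1. **log2 transform** — variance stabilization. Missing intensities are
   handled first: a transition absent or missing in more than 20 % of
   runs is dropped; remaining missings are imputed with the run's
   peptide mean on the raw scale, and every imputation is logged.
   Non-positive intensities after imputation abort with a
   record-identifying error.
2. **Run normalization** — each run is shifted so its median log2
   intensity equals the global median of run medians. This removes
   additive per-injection bias exactly, preserves within-run ranks, and
   is idempotent. Like any global-median method it assumes most of the
   panel is not co-regulated per subject; the generator's alternating
   coupling signs (below) respect that assumption.
3. **Interference filter** — a transition's score is the Pearson
   correlation across runs between its log2 intensity and the per-run
   mean over all transitions of the same peptide (the transition
   included). Scores below 0.8 are excluded. A zero-variance series
   scores 0 (fail-safe exclusion); a peptide's only transition scores 1
   trivially. Note that because the transition participates in its own
   peptide mean, the score is not invariant to rescaling one
   transition, and a heavily interfered transition in a 2-transition
   peptide can dominate the mean and evade the filter — one reason the
   generator plants interference only in ≥3-transition peptides.
4. **CV filter** — for each transition and subject, CV = sd/mean of the
   raw-scale duplicate intensities (log2 values are unlogged first; the
   values are post-normalization, i.e. injection bias has already been
   removed). A transition fails when CV > 10 % in more than 10 % of
   subjects. "Sample runs" are read as subjects here, because the
   duplicate injections are the only within-sample dispersion
   available; both thresholds are settable.
5. **Eigengene** — replicates are averaged per subject, the
   transition × subject matrix is row-standardized (ddof = 1;
   zero-variance rows are dropped, an all-constant protein is an
   error), and the protein summary is the first right-singular vector
   scaled by its singular value. The SVD sign is arbitrary, so the
   eigengene is oriented to correlate positively with the mean
   standardized transition profile; downstream group contrasts then
   have a fixed direction. A single-transition protein reduces exactly
   to that transition's standardized profile.

The outlier screen reports (never removes) subjects beyond 2 SD of the
cohort mean on either their average inter-subject Pearson correlation
or their first-two principal-component scores.

## Group comparison with single-step Tukey correction

With one value per subject and response there are no repeated measures,
so the group model is an ordinary least-squares fit of
`response ~ group + age + gender + nicotine + cannabis + alcohol +
mandrax`; a covariate that is constant in the cohort is dropped with a
warning. The three pairwise contrasts are tested jointly with the
single-step max-|t| method: adjusted
p_i = P(max_j |T_j| ≥ |t_i|), where (T_1…T_k) is multivariate t with
the contrast correlation implied by the design and the residual df.
With three groups the three contrasts are linearly dependent (rank 2),
so the reference distribution is evaluated by Monte-Carlo: a fixed
2×10⁵-draw sample of max|T| (T = Z/√(W/df), Z Gaussian with the —
possibly singular — contrast correlation via its eigenfactor,
W ~ χ²(df)), cached per design. Using one common sample makes adjusted
p-values exactly monotone in |t|; reporting max(raw, familywise)
guarantees adjusted ≥ raw; a single-contrast family returns the exact
t-test p. Agreement with the multivariate-t implementation in R's
multcomp is ~10⁻³ and is asserted in the test suite. The omnibus group
p is the Wald F on the two group coefficients from the same fit.

All 48 × 4 DTI responses go through the identical machinery in one
multi-response pass. Across the grid, omnibus p-values additionally get
a Bonferroni column whose family is either each metric's 48 ROIs
(default) or the full 192 cells. Clustering of the omnibus p matrix
uses raw p (not −log p; switchable), 1 − Pearson distance and average
linkage; constant rows, whose correlation is undefined, are appended
last with a warning.

Demographic variables: Shapiro–Wilk on the group-mean residuals at the
conventional 0.05 gate chooses one-way ANOVA (p ≥ 0.05) or tie-corrected
Kruskal–Wallis. Binary traits use H = ((N−1)/N)·Pearson χ², which is
identically the tie-corrected Kruskal–Wallis statistic on the 0/1
indicator and reproduces the recorded cohort's printed table exactly;
the plain χ² is available as an option.

Variance attribution fits, per protein, a mixed model with a random
intercept per level of each categorical covariate and age as a fixed
term; fractions are the variance components (age: β²·var(age)) over
their total plus the residual, renormalized to sum to one. A
non-convergent fit falls back to sequential-sum-of-squares partial R²
with a logged note.

Psychometric associations are plain Spearman correlations (EPQR-S
scores across all subjects; PANSS within MAP only), flagged at nominal
0.05 and at the Bonferroni level 0.01 used for three questionnaire
scales.

## Cross-modal integration

Pearson r for every protein × ROI × metric pair within a scope (all 42
subjects, or one group), two-sided p from t = r·√((n−2)/(1−r²)).
Thresholds: nominal 0.05; Bonferroni 0.001 for the 48-ROI family (the
conventional printed value; the literal 0.05/48 is 0.00104). Every
nominally significant pair is screened for single-point influence by
recomputing r with each observation left out (O(1) sum updates): the
pair is flagged when any removal moves p across the significance
threshold, and the most attenuating leave-one-out r is reported.
Flagged associations are reported both ways rather than silently
removed — a removal rule that cannot be stated precisely cannot be
reproduced.

The control-vs-patient comparison counts nominal associations per
paired unit — per protein by default (43 pairs), per ROI or per
(protein, metric) optionally — drops ties, and tests the winner counts
with the exact two-tailed binomial sign test at ½. The pairing unit is
a genuine analysis choice and is reported alongside the p-value.

## The cohort simulator

The generator emulates the study's measurement chain, not its biology:

* **Cohort**: 16/14/12 subjects (Control/MA/MAP); age, education and
  questionnaire scores drawn from the recorded per-group means ± SD;
  gender and substance-use indicators assigned with the recorded exact
  counts (so the categorical tests can be regenerated, not just
  recomputed from the printed counts). Note the recorded counts are
  heavily confounded with group — every MAP subject uses nicotine —
  which inflates covariate-adjusted contrast SEs by ≈1.35×; this is a
  property of the design being emulated, not an artifact.
* **Transitions**: log2 intensity = uniform transition baseline +
  protein signal + per-(transition, subject) preparation noise
  (SD 0.3) + per-injection run effect (SD 0.5) + replicate noise sized
  so duplicate injections hit a 4 % raw-scale CV, then exponentiated.
  With a two-point CV estimator, a 4 % target leaves the 10 %/10 % rule
  essentially inactive for clean transitions; at 5 % its sampling tail
  already removes ≈14 % of them.
* **Interference**: a planted transition tracks an independent
  co-eluting signal instead of its protein, plus occasional run spikes.
  Planting is restricted to peptides with ≥3 transitions whose protein
  keeps ≥2 clean transitions elsewhere: in a 2-transition peptide the
  interfered transition dominates its own peptide mean and the score
  stays above threshold, and an unrestricted planting can strip a
  protein from the panel entirely.
* **Group effects**: protein shifts in residual-SD units, optionally
  with a group-specific SD rescaling (APOH's MAP variance is reduced,
  as observed). Defaults are ±2.6 SD for APOC2/APOH and +2.5 SD on RD
  for eight bilateral tracts (corticospinal, fornix/stria terminalis,
  superior and inferior cerebellar peduncles). These are the effect
  sizes that the reported adjusted p-values (down to 3·10⁻⁴ at these
  group sizes) imply once the ≈1.35× covariate SE inflation is taken
  into account, and they give the designed ≥90 % joint recovery
  probability. ROI effects act on the eigenvalue (AD/RD) scale; MD
  inherits two thirds of an RD shift through MD = (AD + 2·RD)/3, and FA
  responds mechanically in the opposite direction, so "RD and MD up, FA
  down, AD flat" emerges from the tensor identity rather than being
  planted per metric.
* **Couplings**: protein–DTI co-linearity is induced by latent factors
  shared between a protein's signal and an ROI residual within a scope
  (all subjects or one group), with loadings chosen so the pairwise
  correlation hits the target r; for across-cohort couplings the
  loading corrects for the variance inflation that group shifts add to
  the protein. Within multi-protein blocks the protein-side loadings
  alternate in sign so the panel median — which run normalization
  subtracts — stays free of the factor; without this, normalization
  visibly erodes the planted structure. Control-only blocks covering
  most of the panel produce the broad excess of control-scope
  associations over the patient groups; a MAP-only PEDF coupling and an
  across-cohort APOH–fornix coupling mirror the reported scoped
  findings. MD/FA coupling targets are translated to AD/RD loadings
  through closed-form (MD) or linearized (FA) corrections; infeasible
  targets raise an error naming the coupling.
* **DTI values**: per-ROI AD baselines uniform in [1.1, 1.6]·10⁻³
  mm²/s with RD at 40–60 % of AD, between-subject SDs 5·10⁻⁵ and
  4·10⁻⁵ mm²/s, plus a shared per-subject physiological factor
  (loading 0.3). AD ≥ RD is enforced, and MD/FA are derived, so the
  tensor identities hold exactly by construction.

What the generator does **not** emulate: chromatographic or detector
noise physics, retention-time drift, missingness mechanisms, non-normal
biological variation, spatial correlation among neighbouring tracts
beyond the single global factor, and any realistic genetic/clinical
correlation between the protein panel and the questionnaires. Passing
recovery tests therefore demonstrate that the pipeline detects the
planted statistical structure at realistic sizes and noise levels — not
that it would detect biology in a new cohort.

## Numerical choices and degenerate inputs

* Tukey reference sample: 2×10⁵ draws, fixed internal seed (the
  reference distribution is part of the method); MC error ≈10⁻³ on
  p-values.
* Problem sizes in the standard checks: 1000 simulated null proteins
  for type-I calibration; 50 independent cohorts for recovery rates;
  60 cohorts for the coupling Monte-Carlo.
* CSV serialization at 15 significant digits; writer/reader pairs
  round-trip within 1e-12 relative error.
* Constant response vectors are an error in group models; constant
  correlation inputs are skipped with a warning; a protein losing all
  transitions is dropped with a warning and recorded in the QC report.
* Ties in Spearman/Kruskal–Wallis use the standard tie corrections via
  scipy; the sign test drops ties before the binomial.

## Known limitations

* The influence screen's "any removal crosses the threshold" rule flags
  many borderline associations by construction; it is a conservative
  audit trail, not an outlier-removal policy.
* The variance-components model with five binary random-intercept terms
  on 42 subjects is weakly identified; the sequential-SS fallback
  engages on a minority of proteins and is labelled in the output.
* Eigengene summarization assumes one dominant abundance signal per
  protein; proteoform-specific divergence among peptides would be
  averaged away.
* The sign-test pairing unit (per protein) is one of several defensible
  constructions; totals and p-values for alternative units can differ.
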