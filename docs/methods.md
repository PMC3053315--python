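# Methods

netens reverse-engineers an ensemble of causal Bayesian-network structures
from a cohort carrying genotypes (SNP dosages), whole-blood transcript
levels, and the four component scores of the rheumatoid-arthritis DAS28
(tender joints TJ, swollen joints SJ, Pain VAS, CRP), and then simulates
per-subject gene-knockdown interventions on the ensemble to rank
transcripts by their predicted clinical effect.

## The model

The joint distribution over variables X₁…Xₙ is factorized as
P(X) = ∏ᵢ Pᵢ(Xᵢ | parents(Xᵢ)), one conditional per variable ("network
fragment").  Every modeled output is continuous; SNPs enter only as
inputs.  A fragment's conditional is linear-Gaussian:

    Xᵢ | Y ~ Normal(θ₀ + Σⱼ θⱼ Yⱼ, σ)

with discrete parents handled by switching: a discrete parent contributes
no linear term — its value (or the joint state of several discrete
parents) selects a separate parameter set (θ₀, θⱼ…, σ).  Parameters are
maximum-likelihood (per-state OLS; σ is the per-state MLE residual SD,
floored at 1e-6 × SD(child) to keep likelihoods finite on degenerate
data).

Fragments are scored with the BIC energy

    S = S_MLE + (κ/2) ln N,

where S_MLE is the negative maximized log-likelihood, N the number of
subjects, and κ the parameter count: per discrete state, one intercept,
one slope per continuous parent, and one σ (so κ = #states × (2 + #cont)).
Whether σ should be shared across states or separate is a genuinely open
modeling choice; per-state σ was chosen because the switching construction
introduces "a different set of fitting parameters" per state, and the two
conventions coincide for purely continuous parents.  Lower S is more
probable; a network's score is the sum of its fragments' scores.

## Fragment enumeration

For every non-SNP child, all parent sets of size 0..2 are scored (SNPs and
transcripts may parent anything downstream; phenotypes may parent other
phenotypes but, by default, not transcripts).  Scoring uses precomputed
cross-product matrices, so each candidate costs a small linear solve; the
top 16 fragments per child are refitted for their full parameter tables
and retained, plus the parentless (root) fragment unconditionally so that
every child can be a root in some network.  Candidates with a discrete
state observed fewer than twice, or with collinear continuous parents, are
skipped.  The retained-per-child count is a truncation of the proposal
space, not of the posterior: raising it grows the move space and slows
sampling roughly linearly.

## Ensemble sampling

Networks are sampled from the Boltzmann posterior P(M|D) ∝ exp(−S(M)) by
Metropolis MCMC.  A state assigns one library fragment to each child; a
move replaces one uniformly chosen child's fragment by another uniformly
chosen entry of its library (a symmetric kernel that covers edge addition,
deletion and swap), candidates closing a directed cycle are rejected
outright (they still count as steps), and valid candidates are accepted
with probability min(1, exp(−ΔS/T)).

Simulated annealing accelerates equilibration: the initial temperature is
probed upward until ≥90% of valid proposals are accepted, and each cooling
step ΔT is chosen so that the normal approximations of the score
distribution at T and T+ΔT keep an overlap coefficient of 0.8 (the mean
shift is extrapolated with the slope d⟨S⟩/dT — finite differences across
stages, Var(S)/T² at the first stage via the fluctuation–dissipation
identity).  Because that linear extrapolation is local, a stage never
cools by more than a factor of 2; without this trust region a
small-variance first stage can quench the chain straight to T = 1 and trap
it in a local mode.  Cooling stops exactly at T = 1, where the chain
samples the posterior itself; going lower would overfit.  At T = 1 the
chain burns in (10 accepted moves per child, bounded) and records one
member every #children steps until its quota is reached.  The default
ensemble is 1024 members collected round-robin from 4 independent chains
whose seeds are spawned deterministically from the run seed; output is
bit-identical for a fixed (seed, n_chains).

Stage equilibration uses a stationarity heuristic (two half-window means
within 0.3 SD, at most two extensions).  `convergence_check` compares
replicate ensembles from different seeds by maximum per-edge frequency
difference (default tolerance 0.1); edge orientation between two
transcripts is identified only through their genetic (eQTL) anchoring, so
weakly anchored systems can legitimately fail this check by oscillating
between likelihood-equivalent orientations.

## Preprocessing

SNP QC removes sex-chromosome SNPs (when chromosome metadata is given) and
SNPs with call rate < 0.95 (exactly 0.95 is retained), minor-allele
frequency < 0.05, or Hardy-Weinberg 1-df goodness-of-fit p below 0.001
(the HWE alpha is a package default; common GWAS practice ranges 1e-6 to
1e-3).  SNPs are ranked per phenotype by the trend statistic n·r², the
continuous-phenotype generalization of the Armitage test (χ²₁ under the
null); an optional residualization of dosage and phenotype on the top
genotype principal components corrects population stratification.
Selection takes the top k by each SNP's best p across phenotypes, ties
broken by name.  Transcripts are optionally filtered to the top k by
sample variance (a variance-rank surrogate for informative/non-informative
gene calls).

Bounded clinical scores are mapped to the real line before modeling:
counts c in [0, m] by y = logit((c + 0.5)/(m + 1)) with m = 28 for TJ/SJ
and m = 100 for the Pain VAS (the +0.5/+1 continuity correction keeps both
endpoints finite and is symmetric about m/2), and CRP by natural log.
Inverses restore the clinical scale; joint counts are rounded to integers
in [0, m] only at reporting time.

## Intervention simulation and the virtual trial

A simulation sweep visits variables in topological order, copying clamped
(evidence) values and drawing each free variable from its fragment's
state-matched conditional.  A knockdown of transcript t with fold f is
graph surgery: t's incoming fragment is removed and t is clamped at the
subject's observed value minus ln f (expression is modeled on the natural-
log scale, so fold-f means a −ln f shift).  For each subject the
genotypes and all transcripts except the target are clamped to their
observed values, and the four phenotypes are sampled; 30 replicate sweeps
(each drawing one ensemble member uniformly at random — model averaging)
are summarized per phenotype by their median.  Baseline ("untreated")
predictions use the same machinery with no intervention, so perturbed and
untreated predictions are compared like for like.  A
`propagate_transcripts` switch instead lets downstream transcripts respond
to the knockdown, which full do-operator semantics would require; the
default clamps them because the subject's other expression measures are
treated as observed evidence.  Which of these the original protocol used
is not determinable from its description; the default changes which genes
can show effects (only direct transcript→phenotype and
phenotype→phenotype paths transmit).

Per gene, baseline and perturbed per-subject medians (back-transformed to
clinical scale) are compared: TJ and SJ by a paired sign-pattern χ² (among
subjects whose integer count changed, decreases vs increases against a
50/50 null, 1 df; no changes gives p = 1), Pain and CRP by a paired
two-sided t-test, and the composite by a paired t-test on
DAS28-CRP = 0.56√TJ + 0.28√SJ + 0.36 ln(CRP+1) + 0.014·Pain + 0.96
(the published clinical equation, with the Pain VAS standing in for the
patient-global VAS; coefficients configurable).  Raw p-values at
alpha = 0.05 drive the ranking — mirroring the screening protocol, no
multiplicity correction is applied — with Benjamini-Hochberg q-values
added as clearly-labeled extension columns.  Genes significant on DAS28
are category 1 (annotated "novel") or 2 (annotated TNF-dependent or
druggable), "1/2" when unannotated; genes moving TJ or SJ but not DAS28
are category 3; the partition over {1, 2, 3, 1/2, none} is exhaustive and
exclusive.

## Synthetic cohorts

The generator emulates the assumed data-generating process so every stage
is testable without any cohort download: SNP dosages are Binomial(2, MAF)
(Hardy-Weinberg) with MAF ~ U(0.15, 0.5); transcripts form a sparse
linear-Gaussian cascade on the log scale (cis-eQTL parent with probability
0.8, at most one upstream transcript parent with probability 0.3, effect
sizes U(0.6, 1.2) with random sign, residual SD 0.5); a planted subset of
transcripts drives latent phenotype scores (positive effects U(0.8, 1.2),
residual SD 0.4) which are squashed to the clinical scales — round(28 ·
expit) for joint counts, 100 · expit for Pain, exp for CRP.  Planted
causes are always eQTL-anchored, because genetic anchoring is what lets
the framework orient transcript→phenotype edges; an unanchored cause is
unidentifiable by design.  The default recovery conditions are 20 SNPs,
30 transcripts, 100 subjects and 3 planted causes.  Because the bounded
phenotypes are inverse-logit squashings of Gaussian latents, the
pipeline's logit transform is the correct inverse and the modeling
assumptions hold by construction — passing recovery tests therefore show
internal consistency, not robustness to real-data misspecification; a
heavy-tailed noise switch (Student-t, 3 df) produces deliberately
misspecified data for robustness checks.  The generator does not emulate
linkage disequilibrium between SNPs, batch effects, or informative
missingness.

`analytic_intervention_effect` gives the exact expected latent-scale
phenotype shift of a knockdown as −ln(f) times the sum over directed paths
of edge-coefficient products, optionally excluding paths through clamped
nodes; it is the oracle against which simulation output is tested.

## Numerical and scale choices

Problem sizes in the test and acceptance runs are deliberately compact —
ensembles of 64–1024 members over cohorts of 8–100 transcripts — chosen so
the full pipeline exercises every stage at desk scale; all sizes are
configuration, not algorithmic limits.  Scores serialize through JSON at
full double precision; ensemble files are versioned.  Ties are broken
deterministically everywhere (parent tuples, SNP and gene names), and all
randomness flows from numpy Generators seeded from a single run seed.

## Known limitations

- The virtual-trial screen is a prediction-ranking device, not a
  calibrated hypothesis test.  Under a global-null cohort (no
  transcript→phenotype effects), any gene carrying even small posterior
  edge mass into a phenotype produces a systematic shift between perturbed
  and baseline predictions that the high-precision median-of-30 paired
  comparison detects almost surely; the fraction of genes so affected
  scales as (distinct phenotype parents across the ensemble)/(number of
  genes) and only vanishes when genes vastly outnumber the phenotype
  parent slots, as in a transcriptome-scale screen.  Conversely the
  sign-pattern χ² on discretized counts is conservative.  Measured at 100
  genes the per-test false-positive rate is ≈0.09 rather than 0.05; the
  continuous tests are exactly calibrated when the structure is held null
  (fold = 1), which the test suite verifies.
- Edge orientation between transcripts rests entirely on eQTL anchoring;
  unanchored portions of the graph are likelihood-equivalent under
  reorientation and the ensemble will (correctly) spread mass across
  orientations, or (at finite sampling) stick in one.
- Conditioning on all non-target transcripts blocks indirect
  transcript-cascade effects of a knockdown by construction (see above).
- Fragment enumeration is quadratic in the number of variables; screens
  beyond a few hundred candidate parents per child need the preprocessing
  filters (trend-ranked SNPs, variance-ranked transcripts).
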