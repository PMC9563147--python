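# Methods

This note documents the statistical models implemented in `tcistate`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic cohorts do and do not emulate, and the numerical decisions that
matter in edge cases. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. Input matrices

**SGA matrix.** A gene is "altered" in a tumor iff it carries a somatic
mutation event and/or a qualifying thresholded copy-number call. The
qualifying call set defaults to {−2, +2} (deep deletion / high-level
amplification); shallow events (±1) can be included via configuration.
Tumors present in only one of the two input tables are kept, with zeros for
the missing data type. Mutation rows are used as given — restricting to
non-silent variant classes is available as a configurable row filter but is
not applied by default.

**DEG calling.** Per-gene log2 expression in normal tissue is modelled as
Gaussian. A tumor gene is a DEG iff its two-sided tail probability under
Normal(mean_g, sd_g) is strictly below the threshold (default 0.005). The
test is two-sided because both over- and under-expression are biologically
meaningful and the network stage later signs each edge. The reference can
be supplied directly (per-gene mean/SD) or estimated from a normal-sample
matrix by sample moments; estimated SDs are floored at σ_min = 10⁻⁶, and a
plug-in reference estimated from finitely many normals slightly inflates
the realised type-I rate relative to the nominal threshold (an intrinsic
property of plug-in Gaussian calls, visible when calibrating against a
known reference versus an estimated one). Genes absent from the reference
are dropped, not imputed.

## 2. Tumor-specific causal arc scoring

For each tumor and each of its DEGs, the candidate causes are the SGAs
observed in that tumor plus a non-specific catch-all A₀; the model assumes
exactly one cause per DEG per tumor. Cause and effect are binary, so the
marginal likelihood of an arc is the Dirichlet-multinomial score of the
2×2 cause-state × effect-state contingency table, with counts taken over
the *whole* cohort and pseudo-counts α_ijk (default 1, configurable):

log P(D | A_h → E_i) = Σ_j [log Γ(α_ij) − log Γ(α_ij + N_ij)
                       + Σ_k (log Γ(α_ijk + N_ijk) − log Γ(α_ijk))].

All arithmetic is in log space via `scipy.special.gammaln`; the pairwise
count tables are computed once per cohort by matrix products and cached.
The implementation is verified against an independent exact oracle that
evaluates the same Γ-ratio products in rational arithmetic (rising
factorials over `fractions.Fraction`), over all 2×2 tables with N ≤ 20 and
α ∈ {0.5, 1, 2}.

**The A₀ model.** A₀'s marginal likelihood is the single-block version of
the same score — the effect's marginal multinomial over all tumors. This
makes A₀ a Bayesian-Occam null: splitting the cohort by an SGA that carries
no information about the effect costs parameters without improving fit, so
A₀ wins precisely the DEGs no SGA explains.

**Priors.** The population-level arc prior is uniform over
{A₀} ∪ SGA_t by default (the least-informative reading); a "frequency"
mode weights each candidate SGA by its cohort alteration frequency and
gives A₀ a fixed configurable mass (default 1/(|SGA_t|+1)).

**Edge p-value.** Defined as 1 − posterior, with threshold 0.05. An
optional permutation mode additionally calibrates edge p against an
empirical null of winning posteriors obtained by independently shuffling
each SGA column across tumors B times.

**Ties and degeneracies.** Exactly tied posteriors resolve to A₀ first,
then to the lexicographically smallest gene ID (candidates are scored in
sorted order and the first maximum wins). A tumor with no SGA assigns all
its DEGs to A₀ with posterior 1 (logged); a tumor with no DEG yields an
empty result. Per-(tumor, DEG) posteriors sum to 1 within 10⁻¹⁰ by
construction (log-sum-exp normalisation).

## 3. Driver catalog

An SGA is designated a driver *in a tumor* when it is the winning cause of
at least `min_edges` = 5 DEGs, each with edge p ≤ 0.05. Retention is
two-pass: first drivers, by driver call rate = (#tumors designated) /
(#tumors hosting) ≥ 0.5 (inclusive); then target DEGs, by DEG call rate =
(#tumors in which the gene is a winning target of any *retained* driver
with a qualifying edge) / (#tumors in which the gene is a DEG) ≥ 0.5.
Winning arcs only are counted — a DEG supports at most one SGA per tumor,
consistent with the single-cause model. Genes hosted by zero tumors can
never enter the catalog (no division by zero). Retained edges are the
qualifying (retained driver, retained DEG) winning pairs with their tumor
support counts.

## 4. EM inference of activation states

Hidden Bernoulli states PRO_jt; observed continuous log2 expression of
each retained target of driver j, Gaussian given the state. The binary
DEG matrix plays no further role beyond having defined the catalog's
target sets — emissions are fitted to the continuous matrix. A DEG
retained for several drivers contributes to each driver's product
independently; the per-(j, t) posteriors factorise accordingly.

- **Initialisation** is deterministic: PRO := SGA; prior_j = mean state;
  emissions from the induced partition. There is no random restart, so the
  fit is reproducible by construction.
- **Hard EM (default)** discretises the posterior at 0.5 before the
  M-step — ties map to *active* — matching the two-step procedure the
  framework describes. Hard EM has no monotonicity guarantee; convergence
  is declared when max_(j,t) |ΔP(PRO_jt = 1)| < tol (default 10⁻⁴, the
  strictest reading of "the marginal probability"), with a 500-iteration
  budget; non-convergence is reported on the results object, never silent.
- **Soft EM (option)** uses posterior-weighted moments; its observed-data
  log-likelihood Σ_jt log Σ_s P(s) Π_k N(E_jkt; θ_jks) is non-decreasing by
  the standard EM argument, and the per-iteration path is recorded so the
  guarantee is assertable.
- **Degenerate partitions.** When one side of a state partition has
  effective count < 2, that side's emission falls back to the pooled
  (unweighted) mean and SD; all emission SDs are floored at σ_min = 10⁻³.
  A prior of exactly 0 or 1 short-circuits the posterior to that value,
  which is the correct limit of the update.

## 5. Signed regulatory network and biclusters

Each retained edge is signed by the point-biserial correlation between the
target's expression and the driver's dichotomous status — computed by the
classical formula r_pb = (M₁ − M₀)/s_n · √(n₁n₀/n²), which is
algebraically the Pearson correlation and is tested to machine precision
against it. The default dichotomous variable is SGA status (the causal
arcs were discovered at SGA level); `--use-states` switches to inferred
activation states. An edge is signed only when |r| clears a configurable
magnitude threshold (default 0) *and* the two-sided t-approximate p-value
is below 0.05; otherwise it is kept unsigned (0). Degenerate inputs
(single group, constant expression) yield 0 with a warning. Correlation
invariance makes the signs unaffected by affine rescaling of expression.

**ISA biclustering.** From a random column seed (each column included with
probability 0.5), alternate: score rows by their mean over the current
columns, z-score across rows, keep rows ≥ t_rows (default 1.5); then score
columns over the kept rows and threshold at t_cols (default 1.5); iterate
until row and column sets repeat exactly (a fixed point) or a 100-iteration
cap discards the start. Thresholding the z-scored row/column scores at
~1.5 SD is the conventional ISA operating point; the dense 0.5 seeding
makes every start see a planted module, so a genuine module is reproduced
by essentially all starts while unstructured matrices scatter across
irreproducible fixed points. Over n_runs = 100 random starts, fixed points
are merged greedily at Jaccard ≥ 0.8 over the union of row and column
members; a merged bicluster's stability is the fraction of all runs
reproducing it and only stability ≥ 0.5 (configurable) is reported.
Reported biclusters are genuine fixed points: re-applying the update map
returns them unchanged.

## 6. Consensus subtyping, survival, covariate association

Agglomerative clustering (Euclidean distance, average linkage — the
common default of the heatmap tooling this emulates; configurable) is
deterministic, so stability is probed by subsampling: 100 resamples each
draw ⌊0.8·n⌋ tumors without replacement and are cut at every K in the scan
range (default 2–6). The consensus entry for a tumor pair is its
co-clustering count divided by its co-sampling count (never-co-sampled
pairs get 0 with a warning). For each K the area under the empirical CDF
of the off-diagonal consensus entries is computed on a 100-bin grid;
**K is selected as the largest K whose relative area gain over K−1 is at
least 0.1** — the standard elbow heuristic for consensus CDF curves. (The
naive "maximise the gain" rule is degenerate: the first K always has the
largest increment.) A forced K (default 4 in the CLI's footsteps of
studies that fix the subtype count a priori) overrides selection. Final
labels come from re-clustering the consensus-derived distance
1 − consensus with the same linkage. Binary feature matrices are clustered
on Euclidean distance of 0/1 vectors as-is, not Jaccard.

**Survival.** Follow-up is administratively capped (default 2500 days:
times clipped, later events censored); groups are compared with the
multi-group log-rank test (one p per comparison, not pairwise with
correction) and per-group Kaplan–Meier curves, both via `lifelines`.

**Covariate association.** Subtype labels × categorical covariate use the
contingency chi-square, switching to Fisher's exact test for sparse 2×2
tables (expected counts < 5); continuous covariates use Kruskal–Wallis.
For an activation-state matrix and a binary covariate, the per-driver
table reports SGA frequency, inferred activation rate, and their gap in
each covariate group; the *flag* isolates crosstalk by testing, among
tumors *without* the driver's SGA, whether activation differs between
covariate groups (Fisher exact, Bonferroni-corrected across drivers) —
the signature of a clinical factor (e.g. HPV) activating a driver protein
without altering its gene.

## 7. The synthetic cohort generator

`generate_cohort` plants, per configuration: driver and passenger SGAs
with per-gene marginal frequencies drawn from `sga_freq_range`; a disjoint
driver → target bipartite graph (`n_target_degs_per_driver` edges per
driver); hidden states = SGA OR i.i.d. Bernoulli(`crosstalk_rate`);
target expression Normal(μ⁰ + state · effect_size · σ, σ) with per-gene
baselines μ⁰ ~ Normal(0, 1) (heterogeneous baselines stress DEG calling)
and a configurable fraction of repressing (negative-shift) edges; noise
genes always at baseline; a matched normal-sample matrix; and exponential
survival whose scale depends on the true subtype only — so subtype
recovery and survival separation are separable claims. Censoring occurs
with probability `censor_rate`, the censored time drawn uniformly below
the event time. One seeded generator drives everything; identical seeds
give bit-identical cohorts.

**Subtype structure.** Tumors carry one of `n_subtypes` equiprobable
labels; each driver is assigned a home subtype round-robin and its SGA
probability is raised in home-subtype tumors and lowered elsewhere by a
marginal-preserving mixture controlled by `subtype_assoc_strength`
(0 = homogeneous Bernoulli; the default 1 concentrates alterations
maximally, giving each subtype a characteristic driver set — "distinct
activation-state profiles" — while every gene's marginal frequency is
preserved exactly at any strength). Passenger frequencies are always
homogeneous.

**Latent-factor mode.** Optionally, a binary clinical covariate (modelled
on HPV status) raises the crosstalk rate of a configurable subset of
drivers in covariate-positive tumors, emulating a factor that activates
driver proteins without genomic alteration; default off.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium-like co-occurrence
and mutual exclusivity between drivers beyond subtype structure;
copy-number segments (alterations are per-gene); overlapping target sets
between drivers; heavy-tailed or heteroscedastic expression noise;
batch effects; non-exponential survival and informative censoring;
missing clinical data. Recovery rates measured on these cohorts are
upper bounds for messier real cohorts.

## 8. Problem sizes and study conditions used by the checks

The recovery studies run at: 300 tumors / 20 drivers (frequency 0.2–0.4) /
50 passengers / 10 targets per driver / 200 noise genes, effect 3σ, no
crosstalk, for causal-structure recovery; 500 tumors with crosstalk 0.2
and effect 2σ for activation-state recovery (the regulatory structure is
supplied from the planted truth there, isolating the EM stage from
causal-discovery error — at effect 2σ a true target is called a DEG in
only ~20% of active tumors, so the 5-edge driver rule is designed for
stronger effects); the zero-crosstalk exactness check uses effect 5σ,
where initialisation is provably at the optimum; 400 tumors for subtype
recovery with survival scales (400, 400, 800, 1200) days, plus 200
equal-scale replicates for log-rank type-I calibration; a 30×300 matrix
with a planted 8×40 block for bicluster recovery. These sizes are chosen
so each statistical claim is comfortably powered while the whole battery
remains desk-scale.

## 9. Known limitations

- The single-cause-per-DEG assumption misattributes targets that are
  genuinely co-regulated; with subtype-correlated drivers, credit for a
  target can be shared across co-occurring drivers (visible as extra
  retained edges in the README example).
- Hard EM can in principle cycle; the iteration cap converts cycling into
  a reported non-convergence rather than an error.
- The permutation p-value mode pools winning posteriors into one global
  null rather than a per-pair null; it is a calibration aid, not an exact
  test.
- Consensus-K selection is a heuristic; the delta-area threshold (0.1) is
  a convention, and forcing K is supported precisely because real studies
  often fix it from prior knowledge.
- The catalog's call-rate filters assume a cohort large enough that
  per-tumor designation rates estimate stable frequencies; tiny cohorts
  (tens of tumors) make the 50% cutoffs noisy.
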