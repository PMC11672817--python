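# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `daysopen`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Trait and data model

Days open (DO) is the interval from calving to the subsequent conception,
recorded per lactation (parities 1–3).  A record is *censored* when
neither a conception date nor a later calving of the same cow confirms
pregnancy; its recorded DO is then a lower bound.  Only a cow's final
record can be censored — a later calving confirms the earlier pregnancy —
and `flag_censored` encodes exactly that rule.

### Editing pipeline

`edit_records` applies, in a fixed order: (1) keep parities 1–3; (2) drop
missing and duplicate calving dates per cow; (3) drop cows with first
calving before 530 days of age; (4) drop records whose age at calving or
days-in-milk at first AI exceed mean + 3 SD; (5) drop uncensored DO < 20
days; (6) keep uncensored DO within mean ± 3 SD within parity; (7) build
herd × calving-year × calving-season (HYS) groups and drop groups with
fewer than 3 records.  Choices made where the procedure is genuinely
open:

* The rule order is fixed as above and the per-rule removal ledger makes
  order effects auditable; counts always sum to `n_in − n_out`.
* The ±3 SD thresholds are computed **once** on the data entering each
  rule (not re-iterated), which keeps editing idempotent in practice; the
  suite checks idempotence on a simulated dataset.
* Censored records are exempt from the two DO filters — their DO is a
  bound, not an observation, and the censoring models re-impute it — and
  they do count toward HYS group sizes (they need a group maximum later).
* The covariate outlier filter is applied overall by default; a
  `covariate_filter_within_parity` switch is provided.
* Dates are strict ISO-8601; anything else is a hard error.

## Pedigree algebra

Pedigrees are renumbered to dense 1..n ids in a topological order obtained
by iterative Kahn sorting (no recursion, so deep pedigrees are safe);
cycles and duplicate ids are hard errors.  Unknown parents are unrelated,
non-inbred base-population draws; no genetic groups.  Inbreeding uses the
Meuwissen–Luo ancestor-accumulation algorithm; the dense A (tabular
method) is a debugging/oracle path guarded at 5,000 animals; all model
fitting uses the sparse A⁻¹ assembled from Henderson's rules with
Mendelian-sampling variances `d_i = 0.5 − 0.25 (F_s + F_d)` (0.75 −
0.25 F with one known parent, 1 for founders).  `prune_to_phenotyped`
optionally restricts a pedigree to phenotyped animals plus ancestors;
evaluations default to the full pedigree.

## Gibbs samplers

All three models run a single chain (matching common practice for this
model family; no multi-chain R-hat — a documented limitation).

* **Location effects**: single-site updates, swept in block order (fixed,
  additive, permanent environment), via a numba kernel over the CSR
  structures of `M = T'T` and A⁻¹.  For 1 or 2 traits sharing one
  incidence structure the conditional at site (j, t) has precision
  `C_jj = Rinv[t,t] M_jj + Prior[t,t] d_jj`.
* **Variances (Gaussian models)**: scaled inverse-χ² conditionals, e.g.
  `σ²ᵤ | u ~ (u'A⁻¹u + ν S) / χ²(q + ν)`.  Priors default to the flat
  limit ν = −2, S = 0 on each variance and flat priors on fixed effects —
  the conventional non-informative setting in animal-breeding Gibbs
  software — and are configurable per component.
* **PTM**: bivariate with trait 1 = DO (censored records held fixed at
  their penalty-imputed value, identical to PLM's) and trait 2 = the
  censorship liability.  Liabilities are redrawn each iteration from the
  normal full conditional given the DO residual, truncated to (0, ∞) for
  censored and (−∞, 0] for uncensored records.  2×2 genetic and
  permanent-environment covariance matrices get inverse-Wishart
  conditionals (flat prior: df = n_levels − 3, scale = the crude
  cross-product); the residual matrix likewise, followed by the
  identification step below.  The liability trait shares the DO trait's
  full fixed/random structure.
* **Identification of the liability scale**: the liability residual
  variance is fixed at 1.  After each unconstrained residual
  inverse-Wishart draw the whole liability axis is rescaled by
  c = sqrt(R₀[l,l]): liabilities, trait-2 location effects and the
  liability rows/columns of G₀, P₀, R₀ are divided by c.  This
  parameter-expansion move is exact because the liability scale is
  unidentified; it leaves the identified parameters (DO variances,
  correlations) with their correct posterior.
* **Truncated normals** use inverse-CDF sampling in log space
  (`log_ndtr` / `ndtri_exp`), stable for means tens of SDs beyond the
  threshold (a draw at standardized distance 40 stays finite and
  correctly signed).
* **Reproducibility**: one seeded `numpy` Generator drives everything,
  including the innovations consumed by the numba kernel (pre-drawn per
  sweep); chains are bit-reproducible for a given seed and platform.
* **Divergence guard**: a variance draw exceeding 10¹² × var(y) aborts
  with a diagnostic rather than overflowing silently.

Chain defaults are desk-scale — 20,000 iterations, 4,000 burn-in,
thinning 10 — chosen so a full three-model fit plus LR validation of a
simulated population (~4,000 pedigree animals, ~2,000 records) completes
in minutes; production-scale settings (e.g. 500,000 / 100,000 / 50) are
plain configuration.  Stored-draw count is `floor((n_iter − burn_in) /
thin)` exactly.

### Diagnostics

`geweke_z` compares the first 10% of a chain against the last 50% using
Bartlett-windowed spectral-density variance estimates (window length
≈ n^(1/3)); a constant chain returns 0 by convention.  On iid chains the
statistic is calibrated (93–97% within ±1.96 across 200 seeds — checked
in the suite).  `autocorrelation` is the standard sample ACF
(statsmodels, FFT).

## Censoring treatments

* `impute_penalty`: censored DO ← max uncensored DO of its HYS group +
  21 days.  A group whose records are *all* censored (extreme-class
  group) falls back to the dataset-wide maximum uncensored DO, with a
  prominent warning — extreme-class groups are a known hazard of
  threshold models and the fallback keeps the pipeline total.
* With zero censored records LM and PLM are identical code paths and
  produce draw-for-draw identical chains under the same seed (asserted).
* PTM reports DO-scale EBVs; liability-trait EBVs are exported as
  auxiliary output.  Whether the ordering σ²ᵤ(PTM) ≥ σ²ᵤ(LM) holds is
  data-dependent and deliberately *not* asserted as an invariant; the
  models are compared through the LR module instead.

## LR validation

`make_split` removes the phenotypes of cows born on/after a cutoff (year
or date); `cutoff_for_fraction` picks the cutoff capturing a target share
(e.g. the youngest 30%) of phenotyped cows.  Accuracy uses the square
root of `cov(û_w, û_p) / ((1 − F̄) σ²ₐ)` — the rooted form of the LR
accuracy; the unrooted ratio is exposed as `acc_lr_squared` since
published reports are not always explicit about the radical.  σ²ₐ is each
model's own posterior-mean additive variance from its whole-data fit.
Negative EBV covariance yields NaN with a warning (accuracy undefined).
Rank agreement uses Spearman with average-rank ties; top-k is
`ceil(fraction · n)` with boundary ties broken by animal id for
determinism, and "top" means **lowest** EBV (shorter days open is
favourable) with a flag to flip.

## Synthetic-data generator

The generator defines the study conditions for every test: true variance
components default to (437.64, 705.76, 11932.0) days² (h² ≈ 0.0335), the
overall censoring target is 14.51%, records span four herds over
2017–2023 with three-parity careers (continuation probabilities 0.62 and
0.45), HYS effects ~ N(0, 15²), covariate slopes 0.5 d/d (days in milk at
first AI) and 0.01 d/d (age at calving) — magnitudes a herd analyst would
call realistic for this trait.  Breeding values are drawn recursively
(`u_i = ½(u_s + u_d) + N(0, d_i σ²ᵤ)`); phenotypes are Gaussian with an
optional log-normal residual stress test, floored at 20 days.

Censoring applies only to each cow's final record (consistency with
`flag_censored`), with per-record probabilities rescaled so the expected
*overall* censored fraction hits the target.  Mechanisms:

* `random` — status independent of everything;
* `value_dependent` (default) — records above their HYS 85th latent-DO
  percentile are censored with 4× elevated probability, calibrated
  against the realized high-fraction so small groups do not inflate the
  rate; mirrors real right-censoring of long intervals;
* `liability_correlated` — a second breeding-value vector with chosen
  genetic correlation drives a probit censoring liability.

What the generator does **not** emulate: insemination-event sequences and
heat detection, seasonal fertility physiology, herd-life culling tied to
the trait, non-random mating, and the heaped/recorded-date artefacts of
field data.  Passing tests therefore demonstrate correctness of the
algebra and samplers under the model's own assumptions — not robustness
to every field-data pathology (the log-normal residual option probes
skewness only).

Default scale is ~1,000 founders → ~4,000 pedigree animals, ~1,200
phenotyped cows and ~2,000 records, so a full three-model comparison runs
in minutes.  The acceptance script uses this scale with 60,000-iteration
chains: EBVs of unphenotyped validation animals carry little data
information, and the longer chains reduce Monte-Carlo attenuation of the
LR regression/correlation statistics.  With populations this small and a
trait at h² ≈ 0.03, LR accuracies are low and cross-model rank agreement
is noisy; those statistics stabilize only with real-data-sized inputs.

## Numerical details

* MME solving: sparse `spsolve` with a relative-residual check (1e-6
  hard error on near-singularity); identifiability from HYS one-hot
  (absorbing the intercept), drop-first parity contrasts, centred
  covariates.  Any full-rank parameterization yields the same û.
* Inverse-Wishart scale matrices get a symmetric jitter
  (1e-10 × trace) before sampling to guard against accumulated
  round-off indefiniteness.
* Sampler/BLUP equivalence tests standardize deviations by the Geyer
  initial-positive-sequence Monte-Carlo SE; because those z's are
  pivotal N(0,1) variables, the checks bound the fraction beyond 3 SE at
  the 1% chance level rather than demanding literally all of hundreds of
  effects stay below 3.
* h² is computed per draw, so the posterior mean of h² is the mean of
  ratios (the ratio of posterior means is also derivable from the
  reported components and differs slightly, as ratio estimators do).

## Limitations

* Single-chain inference with Geweke + ACF diagnostics only.
* PTM holds penalty-imputed DO values fixed (no re-sampling of censored
  DO above its bound); the flag-gated alternative is future work.
* No genomic information, genetic groups, metafounders, or
  survival-model treatment of DO; no multiple imputation or interval
  censoring.
* Desk-scale defaults trade Monte-Carlo precision for runtime; EBV-level
  statistics (rank agreement in particular) are noisy at that scale.
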