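# Methods

## Observation model

The unit of observation is the replicate-mean log2 fold change D[p, l] of a
guide-pair construct p between an early reference and a late time point in
sample l.  Writing g_i, h_j for the two guides and g, h for their target
genes,

    D[p, l] ~ Normal( x[g_i] y[g, l] + x[h_j] y[h, l] + x[g_i,h_j] s[g,h,l],
                      tau[p, l]^-1 ).

Each latent effect is the product of a sample-independent reagent term (x)
and a sample-dependent biological term (y or s).  The x terms absorb guide
efficacy, promoter strength and other screen-wide technical variation; they
are deliberately not interpretable as pure cutting efficiency.  Gene-pair
identity is orientation-free: constructs annotated (g, h) and (h, g)
contribute to the same y and s factors.  Constructs whose two guides target
the same gene are retained, modelled with the single y term carried by both
guide products plus their own pair term, and flagged in the outputs.

Priors: x ~ N(mu_x=1, sigma_x^2=1) for every guide and guide-pair activity
(activity 1 = fully representative reagent); y, s ~ N(0, 10), diffuse because
most gene and combination effects are near zero but a few are strongly
depleting.  With fewer than 3 samples the x scale is weakly identified and a
tighter prior (sigma_x ~ 0.1) is advisable; the fitter warns but does not
silently change the prior.

## Log-fold changes

From counts, the per-replicate LFC is the log2 ratio of construct frequencies
(reads over column total, pseudocount 1 by default) between a replicate's
late column and its early reference; a replicate's early reference is its own
early column when the sample sheet provides one, otherwise the shared early
pool (e.g. plasmid DNA).  D is the replicate mean; the unbiased
across-replicate variance drives the precision prior and is flagged undefined
below two replicates.  With pseudocount 0 the LFC is exactly invariant to
sequencing depth.  Pre-corrected LFC tables (e.g. after copy-number
adjustment) can be supplied directly and bypass count normalization.

## Precision priors

tau[p, l] has a Gamma(alpha, beta) prior moment-matched to the replicate
variance: with pseudo-observation weight w (replicate-equivalents, default
2), alpha = w/2 and beta = (w/2) * max(rep_var, floor_var).  The floor
(default 1e-3) bounds the precision implied by near-duplicate replicates,
which otherwise explodes; observations lacking replicates inherit the
sample-wide median variance.  A smoothed mode shrinks each observation's
variance toward the sample-wide mean by a factor `shrink` before the same
mapping — the standard remedy when few replicates make raw variance
estimates unstable.  Per-observation empirical weighting is the default: it
exploits the genuine information in replicate agreement and, on synthetic
screens, recovers gene effects better than uniform or fully smoothed
precision.

## Inference

All posteriors are inferred by deterministic coordinate ascent on a fully
factorized variational family (one Gaussian factor per x, y, s latent; one
Gamma factor per tau).  Every update is the closed-form conjugate one: a
latent v entering an observation's mean as v*c + m receives

    precision = 1/sigma_v^2 + sum_obs E[tau] <c^2>
    mean      = precision^-1 (mu_v/sigma_v^2 + sum_obs E[tau] (<c> D - <c m>)),

and each tau factor receives shape alpha + 1/2 and rate
beta + E[(D - mu)^2]/2 with the expected squared residual taken under q
(including the variance of each product and, for same-gene constructs, the
exact covariance of the two guide terms, which share y).

**Moment convention.**  Two conventions are implemented for the coefficient
moments <c>, <c^2> in the Gaussian updates.  The textbook fully-factorized
choice <c^2> = E[c]^2 + Var[c] turns out to be unusable on this bilinear
model at realistic screen geometries: a guide targeting a gene with no
phenotype accumulates variance pseudo-evidence (sum of E[tau] Var[y]) carrying
no signal, which drives its activity toward zero and the compensating y
toward infinity — the analogue of the exact zero-forcing long known for
fully-factorized variational matrix factorization.  Empirically the collapse
occurs even when iteration starts at the ground truth, and a fixed-point
analysis shows no stable solution at the correct scale whenever
n_samples / guides_per_gene exceeds ~1/4.  The default is therefore the
plug-in convention <c^2> = E[c]^2, <c m> = E[c] E[m]: each factor still
receives its exact Bayesian conjugate posterior given the current point
estimates of the other factors (the two conventions coincide whenever the
other factors are held at point values), the correct decomposition is a
stable fixed point, and on synthetic screens fitted gene effects track the
truth with r ~ 0.98.  The full convention remains available
(`moment_mode="full"`) for study.  Tau updates use the full uncertainty-aware
residual in both modes.

**Schedule and initialization.**  One sweep updates the y block (genes in
sorted order, all samples jointly), the s block, the per-guide x block, the
per-construct pair-activity block, then all tau factors; within the s, pair
and tau blocks no two factors share an observation, so their vectorized
parallel update equals the sequential one.  Sample-dependent blocks come
first because at initialization y and s still carry their diffuse prior
variances, which would distort the first x update.  y[g, l] starts at the
median LFC of g's constructs paired with a negative control (all of g's
constructs when no control pairing exists), x factors at mu_x, s at mu_s,
variances at prior values, tau at its prior.  The fit is deterministic:
repeated runs are bit-identical, and posterior summaries are invariant to
construct row order.

**Convergence.**  The fitter tracks the mean absolute change (MAE) of all
Gaussian posterior means between consecutive sweeps and stops below tol
(default 1e-3) or at max_iter (default 50).  On the default synthetic
geometry the largest MAE drop occurs by sweep 2 and the scored quantities
(y, s, all scores) are stable to well under 1% within ~20 sweeps, but the
full-parameter MAE has a long shallow tail: the per-construct pair activities
have only n_samples observations each and the optimum lies along a nearly
flat, weakly identified scale direction that coordinate ascent approaches
slowly (the trace decays roughly like 1/t, crossing 1e-3 at ~100-150 sweeps
regardless of schedule or precision-prior settings).  A default-budget run
therefore commonly reports `converged=False` while the scientific outputs are
fully stable; raising max_iter changes interaction scores only in the third
decimal place.

## Scoring

From posterior means, per (gene pair, sample):

* strong score = |s| - max(|y_g|, |y_h|), tagged lethality (s < 0) or
  recovery (s > 0); large positive values mean the combination effect
  dominates both single-gene effects.
* sensitive lethality = min(y_g, y_h) - (y_g + y_h + s), defined only when
  y_g > c*lambda AND y_h > c*lambda; captures extra dropout beyond the
  stronger single knockout among pairs where neither gene is strongly
  depleting alone.
* sensitive recovery = (y_g + y_h + s) - min(y_g, y_h), defined only when
  y_g < c*lambda OR y_h < c*lambda.

c is the empirical 0.01-quantile (linear interpolation) of the fitted y means
over unique genes in the sample — a negative anchor marking the screen's
strongest depletion — and lambda = 0.5, so the lethality constraint excludes
genes more than half as depleted as that anchor.  Alternatively c can be the
median y of user-supplied positive-control (known essential) genes.
Constraints are strict inequalities; values exactly at c*lambda are
ineligible.  Ineligible scores are reported as NaN with an eligibility flag.

## Significance

Pairs involving a declared negative-control gene (plus any user-declared
non-interacting pairs) form the null; they are excluded from the tested set.
Null pools are per sample and per score type: strong-lethality pools take
null pairs with s < 0, strong-recovery pools s > 0, and sensitive pools only
eligible null pairs.  Right-tail p-values default to the Gaussian tail of the
null distribution, p = P(N(mean_null, sd_null) >= score), equivalent to the
normal tail of the z-score used for cross-method comparison.  The choice is
forced by arithmetic: these libraries yield on the order of a hundred null
pairs, so the assumption-free add-one counting estimate
(1 + #{null >= score}) / (1 + #null) — also implemented and selectable —
cannot resolve p below ~0.01, while interaction calling operates at
FDR < 0.01 and real top pairs reach q-values many orders of magnitude
smaller.  Benjamini-Hochberg correction is applied within each (sample,
score type) family; pools with fewer than 20 null scores trigger a warning.
On null screens (nothing planted) the Gaussian tail is mildly conservative:
the realized false-positive fraction at FDR < 0.01 is ~3e-4.

## Synthetic screens

The generator runs the observation model forwards and is the basis of all
tests.  Defaults describe a desk-scale synthetic-lethality screen: 25 genes
x 3 guides plus 4 negative controls in an all-by-all pair layout (a
set-by-set-with-controls layout is also available), 6 samples, 2 replicates.
Guide and pair activities are N(1, 0.2^2) (optionally truncated at zero); 20%
of genes are essential with per-sample effects N(-1.5, 0.5^2), the rest
N(0, 0.05^2), controls exactly zero; 5 planted lethal interactions
(s = -3 in every sample) are placed on pairs of non-essential, non-control
genes so they remain eligible for sensitive-lethality scoring; replicate
noise is Gaussian with sd 0.5, consistent with the ~0.9 replicate
correlations of published screens.  A counts mode inverts the LFC definition
into integer read counts (uniform early pool, late frequencies proportional
to f_early * 2^LFC at 10M reads); depth normalization makes the recomputed
LFCs match the input only up to one additive constant per sequencing column.
Guide-pair downsampling (seeded uniform subset of k constructs per gene pair)
supports guide-count titration experiments.

What the simulation does not emulate: PCR/sequencing count noise beyond the
Gaussian LFC noise, sequence-dependent guide activity (reagent variation
enters only through the x factors), copy-number artefacts, or
between-replicate structure.  Passing tests therefore demonstrate correct
inference under the model's own assumptions and realistic effect sizes — not
robustness to the full messiness of real screens.

## Numerical and degenerate-input conventions

Zero-total count columns, unannotated constructs, duplicate construct IDs and
constructs pairing a guide with itself are rejected at parse time with named
errors.  Replicate variance is undefined (NaN, flagged) below two replicates;
the tau prior then falls back to the sample median variance.  Identical
replicates hit the variance floor rather than yielding infinite precision.
Non-finite values arising during inference abort the fit with the MAE trace
attached.  All tie-breaking is deterministic (sorted gene, guide and pair
order); no randomness exists outside the simulator, whose seed fully
determines its output.

## Known limitations

* The convergence flag is conservative (see Inference): parameter-space MAE
  converges far more slowly than the scored quantities.
* The fully-factorized "full" moment convention collapses weak effects and is
  provided for methodological comparison, not production use.
* Gaussian null tails extrapolate beyond the observed null scores; with
  heavy-tailed nulls the resulting FDRs are optimistic in the extreme tail,
  though control-involving pairs on synthetic screens show no such excess.
* Interaction effects are assumed sparse and are not penalized adaptively; a
  dense interaction structure would partially leak into single-gene effects.
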