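# Methods

## Measurement model

The pipeline treats the crossing point CP as the atomic observable (no
fluorescence-curve modeling). For a primer pair with per-cycle
amplification factor E, starting template is proportional to E^(−CP);
the log2-scale relative abundance used throughout is

    Ca = −CP · log2(E).

Efficiencies are estimated per gene by ordinary least squares of CP on
log2(input amount) over a serial-dilution standard curve, E = 2^(−1/slope).
The regression is unweighted (nothing in the assay suggests
heteroscedastic weighting) and R² is reported but not gated. Estimates
outside the accepted range [1.85, 2.15] set `qc_pass=False` — a flag, not a
rejection: in practice such primer pairs get redesigned, but the pipeline
must still process flagged genes, with a warning.

Technical duplicates (independent runs) are averaged on the **Ca scale**,
because every downstream model is linear in Ca. Duplicates further apart
than 1.5 cycles (configurable) are flagged as discordant but kept. Cells
with no measurement stay as explicit missing values; nothing is dropped
silently.

Normalization subtracts, per sample, the arithmetic mean of the control
genes' Ca from every other gene. On the linear scale this equals dividing
relative amounts by the control genes' geometric mean (verified
numerically in the test suite). Samples missing some control genes are
normalized against the mean of the available ones (warned); a sample
missing all controls is an error.

## Reference-gene stability

Pairwise variation V(a, b) is the n−1 standard deviation over samples of
Ca_a − Ca_b; a gene's M value is its mean V against all other candidates;
ranking iteratively removes the highest-M gene until two remain. The two
survivors share the final two-gene V (pairwise variation cannot order
them) and are listed lexicographically. Ties in the maximal M are broken
by removing the lexicographically first tied gene — deterministic and
documented rather than meaningful. Because V is computed on within-sample
differences, per-sample loading shifts cannot create apparent
instability (a tested invariant).

The control-variation report normalizes the candidate controls against
all of them and fits a condition-means model per gene:
`between_condition_fold` = 2^(max − min condition mean), and
`within_condition_fold` = 2^(k · pooled residual sd) with k = 1 by
default. The within-condition multiplier is configurable because "how
much a control fluctuates within a condition" admits several
fold-conventions (1·sd, 2·sd, observed range); 1·sd is the most
conservative interpretable choice.

## Differential expression

Each gene is modeled individually, response = normalized Ca (or the index
D), fixed effects per design (treatment; treatment + time +
treatment×time; site), colony as a random intercept for paired designs
and tank as an additional crossed random intercept for the tank
experiment. Estimates are REML; contrasts reported for the factorial are
the treatment effect at each time point, the time effect in controls, and
the interaction.

Inference defaults (`method="auto"`):

* balanced paired two-level designs with colony as the only random
  factor collapse to the **exact paired t** — identical point estimate to
  the mixed model (orthogonality; asserted to 1e-8 in tests) with exact
  small-sample p-values;
* everything else uses **REML + Wald z** contrasts (the standard
  mixed-model default), or plain OLS when no random factor is present.

A seeded **parametric-bootstrap likelihood-ratio test** (default 1000
draws, `method="bootstrap"`) is available for single-factor colony
designs as a reproducible substitute for sampler-based p-values; it is
opt-in because at 1000 refits per gene it is two orders of magnitude more
expensive than the defaults while targeting the same asymptotic answer.

Numerical notes. Variance components are bounded at zero and boundary
fits are flagged. The general-purpose MixedLM optimizer can fail with a
singular Hessian exactly on boundary fits (common when one gene carries a
~10 log2-unit effect and the colony variance estimate collapses to 0); a
dense profile-REML fallback (closed-form GLS given the variance ratios,
k-dimensional optimization over the ratios) then produces the same REML
estimates robustly — agreement with the library fit is tested on
well-conditioned data. Noise-free inputs (zero residual variance, as in
analytic fixtures) short-circuit to exact arithmetic: B from cell means,
p = 0 for nonzero contrasts, rather than a degenerate model fit.

Multiple testing: Benjamini–Hochberg step-up across the gene panel,
applied per term (not pooled across terms), controlling FDR at 5% by
default.

## The two-gene stress index

D = Ca(Hsp16) − Ca(actin) on non-normalized Ca. The sign convention
follows the defining formula (induced gene minus repressed gene), so D is
negative at baseline and rises under stress; the simulation tests assert
exactly this behavior. Samples missing either gene are omitted with a
warning. Group comparisons of D reuse the mixed-model machinery
(colony random for paired designs, colony+tank for the tank experiment,
two-group OLS for field sites).

Marker selection: PCA on the centered (not scaled — all genes already
share the log2 scale; scaling is a switch) normalized-Ca matrix.
Component signs are indeterminate, so PC1 is oriented to score stressed
samples above the rest before reading loadings; the genes with the
extreme positive and negative PC1 loadings are proposed as the assay
pair. Selection reports whatever pair is extreme rather than hard-coding
Hsp16/actin, so the logic transfers to other panels.

## Synthetic-data generator

The generator emulates the paired-colony designs the analysis assumes.
For sample s and gene g,

    a(s,g) = baseline_g + colony(s,g) + tank(s,g) + effect(g, cell(s)) + residual(s,g)
    CP(s,g,run) = −(a(s,g) + L(s)) / log2(E_g) + technical noise,

with the loading factor L(s) shared by all genes of a sample. Random
effects and residuals are Gaussian on the log2 (Ca) scale — biology is
multiplicative — while technical noise is Gaussian on the CP scale —
cycle-calling error is additive. Colony (and tank) effects are drawn
independently per gene by default, matching the gene-wise model fits; a
shared-across-genes mode is a config switch. All stochastic operations
take an explicit seed; identical config + seed reproduces the CP table
bit for bit.

Default variance components: loading_sd 1.0, colony_sd 0.5, residual_sd
0.5 (log2 units), technical_sd 0.2 CP — plausible qPCR magnitudes, all
config-visible. Default effect sizes encode the stress scenario the
pipeline targets: Hsp16 +log2(800), chromoprotein +1, actin −2, C3
−log2(6) in the acute exposure; Hsp16 +log2(700) / actin −2 / Hsp60 +2 /
Hsp90 +log2(6) at the factorial's stress point with only Hsp16 (+3)
persisting at recovery. The tank preset uses a deliberately weaker
response (index shift 3 log2 units; its controls were themselves mildly
stressed in the motivating design) and the field preset a 2-log2-unit
site shift split between the two index genes. Field samples are distinct
colonies, so colony variance is folded into the residual there. The
stress/recovery preset's colony count is a parameter (default 8).

What the generator does *not* emulate: amplification-curve kinetics,
symbiont cross-amplification, pipetting-batch structure beyond the
loading factor, non-Gaussian outliers, or censoring of late CPs. Passing
parameter-recovery tests therefore demonstrates correctness of the
analysis under its own assumptions, not robustness to every real-world
artifact.

## Replicated studies and summaries

`coralstress.studies` reruns the full path per replicate — standard
curves are simulated (7 points, 2-fold steps, 0.15-cycle noise) and
regressed, so the analysis never sees the generator's true E. Recovery is
assessed on the log2 scale, where the estimators are unbiased; fold
summaries across replicates use the geometric mean 2^(mean B), the
natural average for ratio-scale quantities (the arithmetic mean of 2^B
is inflated by Jensen's inequality). Monte-Carlo assertions in the test
suite use 3-standard-error bands: an exactly unbiased estimator falls
outside 2 SE in ~5% of seeded runs by construction, whereas any real bias
grows in z as replicates accumulate, so the 3-SE band separates defect
from design. Study sizes (200 replicates for the headline recovery and
error-control runs, 60–100 for the secondary designs) keep the whole
suite around a minute on one CPU while leaving MC standard errors well
below the effects being recovered.

## Known limitations

* Wald z intervals for the factorial/unbalanced designs are asymptotic;
  at 5–8 colonies they are mildly anti-conservative compared to the exact
  paired t or the bootstrap LRT.
* geNorm's V(n/n+1) criterion for "how many reference genes suffice" is
  deliberately not implemented.
* The index is not calibrated to physiological outcomes (bleaching or
  mortality risk); it orders stress states, it does not predict fate.
* CP calling, melting-curve analysis and instrument-file parsing are out
  of scope; the pipeline starts at a CP table in CSV form.
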