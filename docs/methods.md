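# Methods

This note documents the models, the synthetic data they are validated
against, and the numerical and design choices a maintainer would want to
know. Nothing here states a result the test suite or
`scripts/acceptance.py` does not itself compute.

## Screen model

### Generative model

Sorted-fraction screen counts are modeled as negative binomial in
mean/dispersion form (variance μ + μ²/φ):

    K[s,f,i] ~ NB(μ, φ),
    log μ    = log d[s,f] + α_i + x_f · S_s · P_i · G_g(i),
    x_hi = +1,  x_lo = −1.

The symmetric ±1 fraction coding makes the hi/lo log-ratio of a perfectly
efficient guide and screen equal 2G; an equivalent one-sided coding (effect
only in one fraction) would shift α and halve the identifiable effect scale,
so the convention matters and is fixed here. S and P are attenuations in
[0,1]: an inefficient guide (incomplete knockout) or a sloppy sort shrinks
the observed contrast without changing its sign. Depth factors d default to
column total over the geometric mean of column totals (a median-of-ratios
style size factor; overridable).

Priors: P_i, S_s ~ Beta(2,2) (mildly concentrated away from the
boundaries); G_g ~ N(0,1); α_i ~ N(α̂_i, 2) with α̂_i the empirical log mean
normalized count plus a 0.5 pseudocount; log φ ~ N(log 10, 1). The [0,1]
bounds on S and P plus the unit-variance prior on G resolve the S·P·G
scale ambiguity (only the product is likelihood-identified). Non-targeting
controls form a pseudo-gene with G pinned to 0; they inform α, P, S and φ.
The dispersion is a single shared scalar — the simplest identifiable
choice at typical guide counts; per-guide dispersion would need far more
screens per guide to estimate.

### Inference

Conditional on the global parameters (S, φ), the likelihood factorizes over
guides, and over genes for G. The sampler exploits this: each sweep makes
five vectorized random-walk Metropolis block updates (α per guide, P per
guide with reflection into [0,1], G per gene, S per screen with reflection,
log φ globally), accepting coordinates independently within a block.
Per-coordinate proposal scales adapt by Robbins–Monro (target acceptance
0.44, step (t+1)^-0.6) during warmup only and are frozen afterwards, so the
post-warmup chain is a valid time-homogeneous MCMC. Chains start from
independent prior draws (over-dispersed starts); warmup is the first half
by default. Defaults are 12 chains × 800 steps; the calibration runs in the
acceptance script use 4 chains × 2000 steps on a 200-gene × 3-guide ×
2-screen simulation, which completes in well under a minute on one CPU.

Convergence is summarized per scalar by the Gelman–Rubin potential scale
reduction √(((n−1)/n·W + B/n)/W); parameters with R-hat > 1.1 are flagged.
Constant chains (zero within-chain variance) return NaN with a warning.

Measured on the standard simulation (seeds 1 and 7): Spearman rank
agreement between posterior-mean and true effects restricted to truly
nonnull genes 0.92–0.98; 90% credible intervals on truly null genes cover
zero for ~94% of them. Over *all* genes the Spearman is ~0.45 regardless of
fit quality: with 90% of true effects exactly zero, truth ranks are
massively tied and any continuous estimate scatters them, which caps the
statistic near √(Var(rank_true)/Var(rank_est)) ≈ 0.52. The all-genes value
is reported for completeness but is not an informative recovery metric at
this null fraction.

## Hit calling

r = min(r_pos, r_neg) per screen with the positive side winning exact ties;
geometric-mean composite across screens, computed in log space; ties broken
by average rank throughout, and top-N selections tie-break on gene symbol
so outputs are stable. Tier cutoffs use ceiling (strong: r ≤ ⌈0.01n⌉; hit:
r ≤ ⌈0.05n⌉). Fisher enrichment reports raw one-sided p-values by default
(Benjamini–Hochberg behind a flag) on the 2×2 hits×term table over the
supplied universe. The combiner accepts external per-screen rank files, so
any ranking engine can feed it.

## Time-course differential expression

Expression is analyzed as log(x + 0.5) with Gaussian errors. The full model
is intercept + condition + B(t) + condition:B(t) and the reduced model
intercept + B(t), where B is a natural cubic spline basis with 5 degrees of
freedom excluding the constant (truncated-power construction; interior
knots at quantiles of the distinct observed times, boundary knots at
min/max, linear extrapolation beyond them). The basis is written in-house
because the available cubic-regression-spline implementation parameterizes
its df to include the constant function, which collapses the intercept and
breaks the 6-parameter contrast. The column span is invariant to affine
rescaling of the time axis.

The nested comparison returns the LR statistic n·log(RSS_r/RSS_f) and
df_diff = 6, with the p-value taken from the exact-under-Gaussian F
reference by default: at 36 samples and 12 full-model parameters the χ²₆
approximation rejects ~6% of nulls at nominal 1% (its classical
small-sample anti-conservativeness), while the F reference is calibrated —
measured null rejection at 0.01 is 0.0095–0.011 over 2000 simulated null
genes. χ² is available via `method="chisq"` for comparison with
asymptotic-LRT pipelines. Degenerate designs (rank-deficient, or zero full-
model residual) are flagged rather than silently reported.

The early window is t ≤ 6 h; the late window is the 0 h anchor plus
t > 6 h (the alternative strict t > 6 h membership is a config option; the
0 h/6 h boundary assignment is genuinely ambiguous in the source material
and both are supported). On the default nine-point grid the late window has
four distinct times and therefore cannot support a df=5 spline; window
analyses choose a feasible df explicitly (`--df` on the CLI) rather than
silently reducing it.

Axis contrasts use a Welch t-test on log2(x+1) — a deliberate, documented
simplification of count-model engines: the axis is defined by its contrast
(activation: Th0 72 h vs 0 h; differentiation: Th2 vs Th0 at 72 h), its
threshold (p < 10⁻¹⁰) and its orientation (positive = activated / Th2),
not by the test engine. Note the Welch degrees of freedom bound the
attainable p: with 2 replicates per group p < 10⁻¹⁰ is unreachable, so
axis construction requires a replicated design — the validation runs use 6
replicates with log-scale noise sd 0.1, under which the axes recover >90%
of strongly planted genes with ≤1% false inclusions.

## Axis projection

score = ⟨x, u⟩ / ‖u‖ over the genes the profile and axis share; the
restriction-normalized form keeps scores comparable across profiles with
different coverage, and self-projection of an axis returns its norm.
All axis genes present in the profile are used (restricting to the
profile's own significant genes is available behind a flag but introduces a
thresholding degree of freedom). Axes are not orthogonalized by default —
their cosine similarity is reported so the shear is visible — with optional
Gram–Schmidt of the differentiation axis against the activation axis.
Overexpression profiles get both coordinates negated (flip flag) so KO and
OE of the same gene agree in sign; a configurable neutrality radius (default
0) marks near-zero perturbations. Fewer than 10 shared genes is an error.
On 40 simulated knockouts with planted mixture weights and noise sd 0.2 the
recovered coordinates achieve R² ≈ 0.97 per axis.

## Motif activities

Connectivity N[g,m] counts distinct peaks carrying motif m that overlap the
half-open window [tss−w, tss+w), w = 20 kb, on the merged (time-pooled)
peak set. Activities solve E ≈ N·A per condition via ridge,
A = (NᵀN + λI)⁻¹NᵀE, on row-centered log2(TPM+1); λ defaults to
10⁻³·mean(diag NᵀN), and λ=0 requires a nonsingular NᵀN (error advises a
positive penalty). The ridge solution is a deterministic, closed-form
stand-in for a full Bayesian motif-activity treatment; at λ→0 on full-rank
systems it matches the pseudo-inverse to 10⁻⁸, and on planted-activity
simulations per-motif recovery correlation exceeds 0.99. The
differentiation score is the mean Th2−Th0 activity difference over time;
the activation score is Th0's last-minus-first activity. Where several
motifs map to one TF, the selector keeps the longest motif, breaking ties
by lowest mean entropy, then name.

## Peak operators

Replicate consistency: a peak is kept iff a peak from another replicate of
the same time point overlaps it by ≥50% of the *shorter* peak's length
(reciprocal mode available); retained peaks are merged transitively into
union-coordinate peaks with mean member height. Overlap is strict
(touching intervals do not merge). Signal normalization divides by the
per-sample background and then by the second-time-point anchor column, so
the anchor is identically 1; zero-anchor peaks are excluded with a warning.
Motif trajectories average normalized signal over member peaks. The
72 h/24 h ratio uses a pseudocount of 1 normalized unit on both sides;
top/bottom-n selection tie-breaks on peak id. Jaccard is basepair
intersection over union of the two interval unions (bedtools semantics).
TF networks connect a TF to a gene when some peak's midpoint lies strictly
within 20 kb of the gene's TSS and that gene is the peak's nearest; distance
ties break on gene symbol. All interval operators are verified against
per-basepair/per-pair brute-force oracles on hundreds of random instances,
including the exact-50%-overlap and exact-20 kb boundary cases.

## Synthetic data: what it does and does not emulate

The screen generator draws from exactly the model the estimator fits (one
shared mean-function implementation), so parameter-recovery results
validate the inference, not robustness to model misspecification. Defaults
are the calibration conditions used throughout: 200 genes × 3 guides, 30
non-targeting controls, 2 screens, 10% nonnull effects of sd 1, Beta(2,2)
guide efficiencies, screen efficiency 0.9, φ = 10, unit log-sd baselines,
depth 500 reads/guide/fraction. The time-course generator produces
Gaussian log2-scale expression with a saturating activation trend shared by
both conditions and a Th2-only differentiation offset ramping on after 6 h
(exercising the early/late split); it does not model counts-level noise,
library-size variation or batch. The peak generator plants multiplicative
height trajectories per dynamics class and class-biased motif placement,
with jitter/dropout/height-noise knobs for replicate imperfection; it does
not emulate read pileups or peak-calling artifacts. KO profiles are exact
linear mixtures of the unit axis vectors plus i.i.d. Gaussian noise.
Consequently, passing tests demonstrate correctness and calibration of the
implemented procedures under their assumed models — not performance on
real sequencing data with overdispersion beyond NB, batch structure, or
misannotated motifs.

Every generator is a pure function of (config, seed); reruns are
byte-identical, which the CLI tests assert for every subcommand.

## Known limitations

- The screen model shares one dispersion across guides and screens;
  strongly guide-dependent overdispersion would be absorbed into P and α.
- Joint fitting shares G only within the screens passed to one fit; there
  is no cross-readout hierarchical pooling.
- Axis projections inherit the axes' non-orthogonality; interpret
  coordinates jointly with the reported cosine similarity.
- The ridge motif-activity solver reports no posterior uncertainty.
- Guide counting is exact-window string matching (configurable offset and
  length, no mismatch tolerance); reads with sequencing errors in the
  window are discarded, which undercounts but never misassigns.
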