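# th2screen

Analysis toolkit for genome-wide pooled CRISPR knockout screens and the
multi-omic time courses used to characterize T helper 2 (Th2) cell
**activation** (TCR-driven response shared with Th0 cells) versus
**differentiation** (the IL4-driven Th2 program). It is written for
computational biologists analyzing sorted-fraction screens and companion
RNA-seq/ATAC-seq/ChIP-seq time courses, and ships truth-known synthetic data
generators so every stage can be validated end to end without sequencing
data.

## What it computes

**Bayesian screen model (BaIOPSE-style).** Cells carrying a pooled sgRNA
library are FACS-sorted into reporter-high and reporter-low fractions and
the guide abundances sequenced. For screen *s*, fraction *f* ∈ {hi, lo} and
guide *i* targeting gene *g*:

```
K[s,f,i] ~ NB(μ, φ),   log μ = log d[s,f] + α_i + x_f · S_s · P_i · G_g
```

with x_hi = +1, x_lo = −1, guide efficiency P_i ∈ [0,1], screen efficiency
S_s ∈ [0,1], guide baseline α_i, shared NB dispersion φ (variance
μ + μ²/φ) and the signed gene effect G_g — the hi/lo log-ratio of a perfect
guide is 2G. Non-targeting controls are pinned to G = 0. Inference is
MCMC (adaptive Metropolis-within-Gibbs, default 12 chains × 800 steps)
with Gelman–Rubin R-hat convergence reporting.

**Hit calling.** Per screen r = min(r_pos, r_neg); across screens the
composite score is the geometric mean (r₁r₂…r_n)^{1/n}; a gene is a *hit*
in the top 5% of ranks and a *strong* hit in the top 1%; term
over-representation among top hits uses one-sided Fisher exact tests.

**Time-course DE and axes.** Per-gene nested-model spline test between Th0
and Th2 trajectories (natural spline with 5 df, condition and
condition×time interaction; Gaussian likelihood on log(x+0.5), exact F
reference). The *activation axis* is the Th0 72 h-vs-0 h log2 fold-change
vector (genes at p < 10⁻¹⁰), the *differentiation axis* the Th2-vs-Th0
contrast at 72 h.

**Perturbation projection.** A knockout or overexpression fold-change
profile is summarized by its scalar projections onto the two axes
(⟨x, u⟩/‖u‖ over shared genes; overexpression coordinates are sign-flipped
so KO and OE of a gene land in the same quadrant).

**MARA-lite motif activities.** Gene×motif connectivity counts
motif-bearing accessible peaks within 20 kb of each TSS; per-sample motif
activities solve E ≈ N·A by ridge regression, per condition; per motif the
differentiation score is the mean Th2−Th0 activity difference over time and
the activation score the Th0 last-vs-first activity difference.

**Peak dynamics.** Replicate-consistent peak merging (≥50% overlap of the
shorter peak, union coordinates), background and second-time-point anchor
normalization, per-motif mean signal trajectories, 72 h/24 h ratio ranking
with nearest-gene assignment, basepair Jaccard of interval unions, and
TF→gene networks from ChIP peaks with TSS distance < 20 kb.

## Worked example

Simulate a two-screen sorted-fraction experiment (100 genes × 3 guides,
10% of genes with a true effect), fit the screen model, and call hits:

```python
import th2screen as t2

cfg = t2.ScreenSimConfig(n_genes=100, guides_per_gene=3, n_controls=20,
                         n_screens=2, seed=42)
counts, truth = t2.simulate_screen(cfg)
model = t2.BaiopseScreenModel(n_chains=4, n_steps=1000, seed=42).fit(counts)
print(model.gene_effects_.head())
```

The strongest posterior gene effects (|mean| descending):

```
    gene   mean    sd    q05    q95  rhat
gene0037  4.938 0.511  4.078  5.808 1.006
gene0087 -4.213 0.557 -5.161 -3.368 1.015
gene0077  1.631 0.519  0.740  2.463 1.018
gene0050  1.227 0.537  0.415  2.186 1.000
gene0001 -1.064 0.503 -1.898 -0.287 1.006
```

`gene0037` is strongly positively enriched in the reporter-high fraction
(posterior-mean effect ≈ 4.9, 90% credible interval well away from 0, R-hat
≈ 1 indicating converged chains) — a candidate repressor of the reporter is
a negative G, a driver positive. Combining ranks and applying the 1%/5%
tiers:

```python
ranks = model.rank_table()
r, _ = t2.combine_pos_neg(ranks["r_pos"], ranks["r_neg"])
hits = t2.call_hits(ranks.assign(r=r), n_genes=100)
```

```
    gene   r   tier
gene0037 1.0 strong
gene0087 1.0 strong
gene0077 2.0    hit
gene0001 2.0    hit
```

Against the simulation truth, the Spearman rank correlation between
posterior-mean and true effects over the truly perturbing genes is 0.952.

The same pipeline is scriptable from the shell:

```sh
th2screen simulate screen --out sim/ --seed 42
th2screen fit-screen --counts sim/counts.tsv --library sim/library.tsv \
    --chains 4 --steps 1000 --seed 42 --out posterior.tsv
th2screen combine-ranks --ranks posterior.ranks.tsv --out composite.tsv
```

All subcommands are deterministic: rerunning with the same seed and inputs
reproduces outputs byte for byte.

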