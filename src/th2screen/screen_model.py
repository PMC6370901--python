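"""Hierarchical negative-binomial model for sorted-fraction CRISPR screens.

The screened cell pool is FACS-sorted into reporter-high and reporter-low
fractions and the sgRNA abundances in each fraction are sequenced.  A guide
targeting a gene that drives the reporter up is enriched in the high fraction
and depleted in the low fraction; the model captures this with a signed
contrast.  For screen ``s``, fraction ``f`` (hi/lo) and guide ``i`` targeting
gene ``g(i)``::

    K[s,f,i] ~ NB(mean = mu, dispersion = phi)
    log mu   = log d[s,f] + alpha_i + x_f * S_s * P_i * G_g(i)

with ``x_hi = +1`` and ``x_lo = -1``, so the hi/lo log-ratio for a perfectly
efficient guide and screen equals ``2 G``.  ``alpha_i`` is the guide's log
baseline abundance, ``P_i`` in [0,1] its knockout efficiency, ``S_s`` in
[0,1] the screen's sorting/selection efficiency, ``G_g`` the signed gene
effect, and ``phi`` a shared NB dispersion (variance ``mu + mu^2/phi``).
Non-targeting control guides are assigned a pseudo-gene whose effect is
fixed at 0.

Priors (weakly informative; the [0,1] bounds on S and P together with the
standard-normal prior on G resolve the S*P*G scale ambiguity)::

    P_i, S_s ~ Beta(2,2);  G_g ~ N(0,1);  alpha_i ~ N(alpha_hat_i, 2);
    log phi ~ N(log 10, 1)

where ``alpha_hat_i`` is the empirical log mean normalized count of guide i.

Inference is by adaptive Metropolis-within-Gibbs: conditional on the global
parameters, the likelihood factorizes over guides (and, for G, over genes),
so each block proposes all coordinates at once and accepts them
independently.  Proposal scales are tuned by Robbins-Monro during warmup and
frozen afterwards.  Convergence is reported via the Gelman-Rubin potential
scale reduction (R-hat) per scalar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator

from .io_formats import GuideCountTable, GuideLibrary

__all__ = [
    "BaiopseParams",
    "PriorConfig",
    "McmcConfig",
    "PosteriorSummary",
    "CONTROL_PSEUDOGENE",
    "gene_indexing",
    "model_log_mean",
    "nb_logpmf",
    "log_likelihood",
    "log_posterior",
    "rhat",
    "BaiopseScreenModel",
    "fit_baiopse",
    "rank_from_posterior",
]

CONTROL_PSEUDOGENE = "__nontargeting__"


# ---------------------------------------------------------------------------
# parameters and priors
# ---------------------------------------------------------------------------


@dataclass
class BaiopseParams:
    """One point in parameter space (see module docstring for meanings)."""

    alpha: np.ndarray  # (n_guides,)
    P: np.ndarray  # (n_guides,) in [0,1]
    S: np.ndarray  # (n_screens,) in [0,1]
    G: np.ndarray  # (n_genes,) — last entry is the control pseudo-gene if present
    phi: float  # > 0

    def validate(self, n_screens: int, n_guides: int, n_genes: int) -> None:
        if self.alpha.shape != (n_guides,) or self.P.shape != (n_guides,):
            raise ValueError("alpha/P dimension mismatch with count table")
        if self.S.shape != (n_screens,):
            raise ValueError("S dimension mismatch with count table")
        if self.G.shape != (n_genes,):
            raise ValueError("G dimension mismatch with gene set")
        arrs = [self.alpha, self.P, self.S, self.G, np.atleast_1d(self.phi)]
        if not all(np.isfinite(a).all() for a in arrs):
            raise ValueError("non-finite parameter")
        if (self.P < 0).any() or (self.P > 1).any():
            raise ValueError("P out of [0,1]")
        if (self.S < 0).any() or (self.S > 1).any():
            raise ValueError("S out of [0,1]")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")


@dataclass
class PriorConfig:
    efficiency_a: float = 2.0
    efficiency_b: float = 2.0
    g_sd: float = 1.0
    alpha_sd: float = 2.0
    log_phi_mean: float = math.log(10.0)
    log_phi_sd: float = 1.0


@dataclass
class McmcConfig:
    n_chains: int = 12
    n_steps: int = 800
    warmup_frac: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2")
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if not 0.0 < self.warmup_frac < 1.0:
            raise ValueError("warmup_frac must be in (0,1)")


@dataclass
class PosteriorSummary:
    """Posterior means/sds/quantiles and R-hat per scalar parameter."""

    params: pd.DataFrame  # columns: param, mean, sd, q05, q95, rhat
    gene_summary: pd.DataFrame  # columns: gene, mean, sd, q05, q95, rhat
    flagged: list[str] = field(default_factory=list)  # params with R-hat > 1.1
    gene_draws: np.ndarray | None = None  # (n_chains, n_kept, n_real_genes)
    genes: list[str] | None = None


# ---------------------------------------------------------------------------
# model kernel (shared with the synthetic-data generator)
# ---------------------------------------------------------------------------


def gene_indexing(library: GuideLibrary) -> tuple[np.ndarray, list[str]]:
    """Map each guide to a gene index; controls share a trailing pseudo-gene."""
    is_ctrl = library.table["is_control"].to_numpy()
    real = sorted(set(library.genes[~is_ctrl]))
    genes = list(real) + ([CONTROL_PSEUDOGENE] if is_ctrl.any() else [])
    lookup = {g: i for i, g in enumerate(genes)}
    gene_idx = np.array(
        [lookup[CONTROL_PSEUDOGENE] if c else lookup[g] for g, c in zip(library.genes, is_ctrl)],
        dtype=np.int64,
    )
    return gene_idx, genes


def model_log_mean(
    alpha: np.ndarray,
    P: np.ndarray,
    S: np.ndarray,
    G: np.ndarray,
    gene_idx: np.ndarray,
    log_depths: np.ndarray,
) -> np.ndarray:
    """log mu[s,f,i] = log d[s,f] + alpha_i + x_f * S_s * P_i * G_g(i)."""
    x = np.array([1.0, -1.0])  # fraction axis order (hi, lo)
    effect = P * G[gene_idx]  # (n_guides,)
    signed = x[None, :, None] * S[:, None, None] * effect[None, None, :]
    return log_depths[:, :, None] + alpha[None, None, :] + signed


def nb_logpmf(k: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """NB log-pmf in mean/dispersion form (variance mu + mu^2/phi)."""
    return (
        gammaln(k + phi)
        - gammaln(phi)
        - gammaln(k + 1.0)
        + phi * np.log(phi / (phi + mu))
        + k * np.log(mu / (phi + mu))
    )


def log_likelihood(params: BaiopseParams, counts: GuideCountTable) -> float:
    """Total NB log likelihood of the count table at ``params``."""
    gene_idx, genes = gene_indexing(counts.library)
    params.validate(counts.n_screens, counts.n_guides, len(genes))
    log_mu = model_log_mean(
        params.alpha, params.P, params.S, params.G, gene_idx, np.log(counts.depths)
    )
    return float(nb_logpmf(counts.counts.astype(float), np.exp(log_mu), params.phi).sum())


def _beta_logpdf(x: np.ndarray, a: float, b: float) -> np.ndarray:
    c = gammaln(a + b) - gammaln(a) - gammaln(b)
    with np.errstate(divide="ignore"):
        return c + (a - 1.0) * np.log(x) + (b - 1.0) * np.log(1.0 - x)


def _normal_logpdf(x: np.ndarray, mean, sd) -> np.ndarray:
    return -0.5 * np.log(2.0 * math.pi) - np.log(sd) - 0.5 * ((x - mean) / sd) ** 2


def empirical_alpha_center(counts: GuideCountTable) -> np.ndarray:
    """alpha_hat_i = log(mean normalized count + 0.5), the alpha prior center."""
    norm = counts.counts / counts.depths[:, :, None]
    return np.log(norm.mean(axis=(0, 1)) + 0.5)


def log_prior(params: BaiopseParams, priors: PriorConfig, alpha_center: np.ndarray) -> float:
    """Sum of prior log densities; G of the control pseudo-gene is excluded
    (it is a point mass at 0, not a free parameter)."""
    a, b = priors.efficiency_a, priors.efficiency_b
    lp = _beta_logpdf(params.P, a, b).sum() + _beta_logpdf(params.S, a, b).sum()
    lp += _normal_logpdf(params.alpha, alpha_center, priors.alpha_sd).sum()
    lp += _normal_logpdf(np.log(params.phi), priors.log_phi_mean, priors.log_phi_sd)
    return float(lp)


def log_posterior(
    params: BaiopseParams,
    counts: GuideCountTable,
    priors: PriorConfig | None = None,
    g_free: np.ndarray | None = None,
) -> float:
    """log likelihood + log priors (G prior over free genes only)."""
    priors = priors or PriorConfig()
    gene_idx, genes = gene_indexing(counts.library)
    if g_free is None:
        g_free = np.array([g != CONTROL_PSEUDOGENE for g in genes])
    ll = log_likelihood(params, counts)
    lp = log_prior(params, priors, empirical_alpha_center(counts))
    lp += _normal_logpdf(params.G[g_free], 0.0, priors.g_sd).sum()
    return ll + lp


# ---------------------------------------------------------------------------
# convergence diagnostic
# ---------------------------------------------------------------------------


def rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction for one scalar.

    ``chains`` has shape (n_chains, n_draws).  Returns
    sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain variance and
    B the between-chain variance of chain means (times n).  Degenerate input
    (zero within-chain variance everywhere) returns NaN.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains with >= 2 draws each")
    m, n = chains.shape
    means = chains.mean(axis=1)
    W = chains.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0.0:
        import warnings

        warnings.warn("zero within-chain variance in all chains; R-hat undefined")
        return float("nan")
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


def _reflect_unit(x: np.ndarray) -> np.ndarray:
    """Fold a random-walk proposal back into [0,1] (symmetric)."""
    x = np.abs(x) % 2.0
    return np.where(x > 1.0, 2.0 - x, x)


class _ChainState:
    """One chain's parameters, cached per-cell log likelihood, and scales."""

    def __init__(self, model: "_ModelData", priors: PriorConfig, rng: np.random.Generator):
        m = model
        self.rng = rng
        self.alpha = rng.normal(m.alpha_center, priors.alpha_sd)
        self.P = rng.beta(priors.efficiency_a, priors.efficiency_b, m.n_guides)
        self.S = rng.beta(priors.efficiency_a, priors.efficiency_b, m.n_screens)
        self.G = np.where(m.g_free, rng.normal(0.0, priors.g_sd, m.n_genes), 0.0)
        self.phi = float(np.exp(rng.normal(priors.log_phi_mean, priors.log_phi_sd)))
        # per-coordinate proposal scales (log-scale adapted during warmup)
        self.sc_alpha = np.full(m.n_guides, 0.3)
        self.sc_P = np.full(m.n_guides, 0.3)
        self.sc_G = np.full(m.n_genes, 0.3)
        self.sc_S = np.full(m.n_screens, 0.1)
        self.sc_phi = 0.3
        self.cells = self._cells(m)

    def _cells(self, m: "_ModelData", **over) -> np.ndarray:
        log_mu = model_log_mean(
            over.get("alpha", self.alpha),
            over.get("P", self.P),
            over.get("S", self.S),
            over.get("G", self.G),
            m.gene_idx,
            m.log_depths,
        )
        return nb_logpmf(m.K, np.exp(log_mu), over.get("phi", self.phi))


class _ModelData:
    def __init__(self, counts: GuideCountTable, priors: PriorConfig):
        self.K = counts.counts.astype(float)
        self.log_depths = np.log(counts.depths)
        self.gene_idx, self.genes = gene_indexing(counts.library)
        self.n_screens, _, self.n_guides = self.K.shape
        self.n_genes = len(self.genes)
        self.g_free = np.array([g != CONTROL_PSEUDOGENE for g in self.genes])
        self.alpha_center = empirical_alpha_center(counts)
        self.priors = priors


def _sweep(st: _ChainState, m: _ModelData, adapt_gamma: float | None) -> None:
    """One full update sweep over the five parameter blocks."""
    rng = st.rng
    pr = m.priors

    def tune(log_scales, accepted, target=0.44):
        if adapt_gamma is not None:
            log_scales *= np.exp(adapt_gamma * (accepted.astype(float) - target))

    # --- alpha (per guide) ---
    prop = st.alpha + st.sc_alpha * rng.standard_normal(m.n_guides)
    new = st._cells(m, alpha=prop)
    d_guide = (new - st.cells).sum(axis=(0, 1))
    d_guide += _normal_logpdf(prop, m.alpha_center, pr.alpha_sd) - _normal_logpdf(
        st.alpha, m.alpha_center, pr.alpha_sd
    )
    acc = np.log(rng.random(m.n_guides)) < d_guide
    st.alpha = np.where(acc, prop, st.alpha)
    st.cells[:, :, acc] = new[:, :, acc]
    tune(st.sc_alpha, acc)

    # --- P (per guide, reflected into [0,1]) ---
    prop = _reflect_unit(st.P + st.sc_P * rng.standard_normal(m.n_guides))
    new = st._cells(m, P=prop)
    d_guide = (new - st.cells).sum(axis=(0, 1))
    d_guide += _beta_logpdf(prop, pr.efficiency_a, pr.efficiency_b) - _beta_logpdf(
        st.P, pr.efficiency_a, pr.efficiency_b
    )
    acc = np.log(rng.random(m.n_guides)) < d_guide
    st.P = np.where(acc, prop, st.P)
    st.cells[:, :, acc] = new[:, :, acc]
    tune(st.sc_P, acc)

    # --- G (per gene; control pseudo-gene fixed at 0) ---
    prop = np.where(m.g_free, st.G + st.sc_G * rng.standard_normal(m.n_genes), 0.0)
    new = st._cells(m, G=prop)
    d_guide = (new - st.cells).sum(axis=(0, 1))
    d_gene = np.bincount(m.gene_idx, weights=d_guide, minlength=m.n_genes)
    d_gene += _normal_logpdf(prop, 0.0, pr.g_sd) - _normal_logpdf(st.G, 0.0, pr.g_sd)
    acc = (np.log(rng.random(m.n_genes)) < d_gene) & m.g_free
    st.G = np.where(acc, prop, st.G)
    acc_guides = acc[m.gene_idx]
    st.cells[:, :, acc_guides] = new[:, :, acc_guides]
    tune(st.sc_G, acc)

    # --- S (per screen, reflected into [0,1]) ---
    prop = _reflect_unit(st.S + st.sc_S * rng.standard_normal(m.n_screens))
    new = st._cells(m, S=prop)
    d_screen = (new - st.cells).sum(axis=(1, 2))
    d_screen += _beta_logpdf(prop, pr.efficiency_a, pr.efficiency_b) - _beta_logpdf(
        st.S, pr.efficiency_a, pr.efficiency_b
    )
    acc = np.log(rng.random(m.n_screens)) < d_screen
    st.S = np.where(acc, prop, st.S)
    st.cells[acc, :, :] = new[acc, :, :]
    tune(st.sc_S, acc)

    # --- phi (global, random walk on log phi) ---
    lp_prop = math.log(st.phi) + st.sc_phi * rng.standard_normal()
    phi_prop = math.exp(lp_prop)
    new = st._cells(m, phi=phi_prop)
    d = (new - st.cells).sum()
    d += _normal_logpdf(lp_prop, pr.log_phi_mean, pr.log_phi_sd) - _normal_logpdf(
        math.log(st.phi), pr.log_phi_mean, pr.log_phi_sd
    )
    acc_phi = math.log(rng.random()) < d
    if acc_phi:
        st.phi = phi_prop
        st.cells = new
    if adapt_gamma is not None:
        st.sc_phi *= math.exp(adapt_gamma * (float(acc_phi) - 0.44))


class BaiopseScreenModel(BaseEstimator):
    """Bayesian hierarchical NB model of sorted-fraction screen counts.

    Parameters
    ----------
    n_chains, n_steps : int
        Independent MCMC chains and steps per chain (defaults 12 x 800).
    warmup_frac : float
        Fraction of steps discarded as warmup (proposal adaptation happens
        only during warmup).
    seed : int or None
        Seed for all chains (spawned independently per chain).
    priors : PriorConfig or None
        Prior hyperparameters; defaults documented in the module docstring.

    Attributes (after :meth:`fit`)
    ------------------------------
    posterior_ : PosteriorSummary
        Summaries and R-hat for every scalar parameter.
    gene_effects_ : pandas.DataFrame
        Per-gene posterior mean/sd/q05/q95/rhat of G (real genes only).
    flagged_ : list of str
        Parameter names with R-hat > 1.1.
    """

    def __init__(self, n_chains=12, n_steps=800, warmup_frac=0.5, seed=None, priors=None):
        self.n_chains = n_chains
        self.n_steps = n_steps
        self.warmup_frac = warmup_frac
        self.seed = seed
        self.priors = priors

    def fit(self, counts: GuideCountTable, y=None):
        cfg = McmcConfig(self.n_chains, self.n_steps, self.warmup_frac, self.seed)
        priors = self.priors or PriorConfig()
        if counts.n_screens < 1:
            raise ValueError("need at least one screen with both fractions")
        gene_idx, genes = gene_indexing(counts.library)
        if np.bincount(gene_idx, minlength=len(genes)).min() < 1:
            raise ValueError("every gene must have at least one guide")
        m = _ModelData(counts, priors)

        n_warm = int(round(cfg.n_steps * cfg.warmup_frac))
        n_keep = cfg.n_steps - n_warm
        seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
        names, slices = _param_layout(m)
        draws = np.empty((cfg.n_chains, n_keep, slices["total"]))
        for c in range(cfg.n_chains):
            st = _ChainState(m, priors, np.random.default_rng(seeds[c]))
            for t in range(cfg.n_steps):
                gamma = (t + 1.0) ** -0.6 if t < n_warm else None
                _sweep(st, m, gamma)
                if t >= n_warm:
                    draws[c, t - n_warm] = np.concatenate(
                        [st.alpha, st.P, st.S, st.G[m.g_free], [math.log(st.phi)]]
                    )

        self.posterior_ = _summarize(draws, names, m)
        self.gene_effects_ = self.posterior_.gene_summary
        self.flagged_ = self.posterior_.flagged
        return self

    def rank_table(self) -> pd.DataFrame:
        return rank_from_posterior(self.posterior_)


def _param_layout(m: _ModelData):
    names = (
        [f"alpha[{i}]" for i in range(m.n_guides)]
        + [f"P[{i}]" for i in range(m.n_guides)]
        + [f"S[{s}]" for s in range(m.n_screens)]
        + [f"G[{g}]" for g in np.array(m.genes)[m.g_free]]
        + ["log_phi"]
    )
    return names, {"total": len(names)}


def _summarize(draws: np.ndarray, names: list[str], m: _ModelData) -> PosteriorSummary:
    n_chains, n_keep, n_par = draws.shape
    flat = draws.reshape(n_chains * n_keep, n_par)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    q05, q95 = np.quantile(flat, [0.05, 0.95], axis=0)
    rh = np.empty(n_par)
    for j in range(n_par):
        with np.errstate(invalid="ignore"):
            chains = draws[:, :, j]
            W = chains.var(axis=1, ddof=1).mean()
            if W == 0.0:
                rh[j] = np.nan
                continue
            B = n_keep * chains.mean(axis=1).var(ddof=1)
            rh[j] = math.sqrt(((n_keep - 1) / n_keep * W + B / n_keep) / W)
    params = pd.DataFrame(
        {"param": names, "mean": mean, "sd": sd, "q05": q05, "q95": q95, "rhat": rh}
    )
    flagged = params.loc[params["rhat"] > 1.1, "param"].tolist()
    real_genes = list(np.array(m.genes)[m.g_free])
    g_start = 2 * m.n_guides + m.n_screens
    g_stop = g_start + len(real_genes)
    gene_summary = params.iloc[g_start:g_stop].copy()
    gene_summary.insert(0, "gene", real_genes)
    gene_summary = gene_summary.drop(columns="param").reset_index(drop=True)
    return PosteriorSummary(
        params=params,
        gene_summary=gene_summary,
        flagged=flagged,
        gene_draws=draws[:, :, g_start:g_stop],
        genes=real_genes,
    )


def fit_baiopse(
    counts: GuideCountTable,
    mcmc: McmcConfig | None = None,
    priors: PriorConfig | None = None,
) -> PosteriorSummary:
    """Functional wrapper over :class:`BaiopseScreenModel`."""
    mcmc = mcmc or McmcConfig()
    est = BaiopseScreenModel(
        n_chains=mcmc.n_chains,
        n_steps=mcmc.n_steps,
        warmup_frac=mcmc.warmup_frac,
        seed=mcmc.seed,
        priors=priors,
    )
    return est.fit(counts).posterior_


def rank_from_posterior(summary: PosteriorSummary) -> pd.DataFrame:
    """Per-gene enrichment ranks from posterior-mean gene effects.

    r_pos ranks G descending (1 = most positive), r_neg ascending; ties get
    average rank.
    """
    gs = summary.gene_summary
    if gs.empty:
        raise ValueError("no gene summaries present")
    g = gs["mean"]
    return pd.DataFrame(
        {
            "gene": gs["gene"],
            "r_pos": g.rank(ascending=False, method="average"),
            "r_neg": g.rank(ascending=True, method="average"),
        }
    )
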