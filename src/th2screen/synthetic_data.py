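"""Truth-known generators for every pipeline stage.

Each generator is a pure function of its configuration and seed: identical
reruns produce byte-identical outputs.  The screen generator draws counts
from exactly the generative model the screen estimator fits (the mean
function is a single shared implementation, imported from
:mod:`th2screen.screen_model`), so simulation-based calibration checks are
meaningful.  The other generators emulate the structure of the real assays
— two-condition expression time courses, dynamic peak sets carrying motif
annotations, and knockout fold-change profiles that are linear mixtures of
the activation and differentiation axes — without modeling read-level or
wet-lab detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GuideCountTable, GuideLibrary, PeakSet
from .screen_model import model_log_mean
from .timecourse_de import AxisSignature

__all__ = [
    "ScreenSimConfig",
    "ScreenTruth",
    "simulate_screen",
    "TimecourseSimConfig",
    "TimecourseTruth",
    "simulate_timecourse",
    "simulate_peaks",
    "PeakTruth",
    "simulate_ko_profiles",
]


# ---------------------------------------------------------------------------
# sorted-fraction screen counts
# ---------------------------------------------------------------------------


@dataclass
class ScreenSimConfig:
    """Study conditions for the screen generator.

    Defaults mirror the simulation used throughout the package's calibration
    checks: 200 genes x 3 guides, 30 non-targeting controls, two screens,
    10% of genes with a nonzero effect of sd 1, Beta(2,2) guide efficiencies,
    screen efficiency 0.9, NB dispersion 10, unit-log-sd guide baselines and
    a mean depth of 500 reads per guide per fraction.
    """

    n_genes: int = 200
    guides_per_gene: int = 3
    n_controls: int = 30
    n_screens: int = 2
    frac_nonnull: float = 0.1
    effect_sd: float = 1.0
    efficiency_prior: tuple[float, float] = (2.0, 2.0)
    screen_efficiency: tuple[float, ...] | None = None  # default 0.9 per screen
    dispersion: float = 10.0
    sigma_alpha: float = 1.0
    depth: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.guides_per_gene, self.n_screens) < 1:
            raise ValueError("n_genes, guides_per_gene, n_screens must be >= 1")
        if not 0.0 <= self.frac_nonnull <= 1.0:
            raise ValueError("frac_nonnull must be in [0,1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.screen_efficiency is not None:
            s = np.asarray(self.screen_efficiency, float)
            if s.shape != (self.n_screens,) or (s <= 0).any() or (s > 1).any():
                raise ValueError("screen_efficiency must give one value in (0,1] per screen")


@dataclass
class ScreenTruth:
    alpha: np.ndarray
    P: np.ndarray
    S: np.ndarray
    G: pd.Series  # indexed by gene
    gene_of_guide: pd.Series  # guide_id -> gene (controls: "")
    config: ScreenSimConfig = field(repr=False, default=None)


def _random_sequences(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    bases = np.array(list("ACGT"))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        for _ in range(n - len(out)):
            s = "".join(bases[rng.integers(0, 4, length)])
            if s not in seen:
                seen.add(s)
                out.append(s)
    return out


def simulate_screen(cfg: ScreenSimConfig) -> tuple[GuideCountTable, ScreenTruth]:
    """Draw K[s,f,i] ~ NB(mu, phi), log mu = log d + alpha_i + x_f S_s P_i G_g."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"gene{j:04d}" for j in range(cfg.n_genes)]
    rows = []
    seq_pool = iter(_random_sequences(rng, cfg.n_genes * cfg.guides_per_gene + cfg.n_controls))
    for g in genes:
        for k in range(cfg.guides_per_gene):
            rows.append((f"{g}_sg{k}", g, next(seq_pool), False))
    for k in range(cfg.n_controls):
        rows.append((f"ctrl_sg{k}", "nontargeting", next(seq_pool), True))
    library = GuideLibrary(
        pd.DataFrame(rows, columns=["guide_id", "gene", "sequence", "is_control"])
    )
    n_guides = len(library)
    is_ctrl = library.table["is_control"].to_numpy()

    # latent truth
    alpha = rng.normal(0.0, cfg.sigma_alpha, n_guides)
    a, b = cfg.efficiency_prior
    P = rng.beta(a, b, n_guides)
    S = (
        np.asarray(cfg.screen_efficiency, float)
        if cfg.screen_efficiency is not None
        else np.full(cfg.n_screens, 0.9)
    )
    G = np.zeros(cfg.n_genes)
    n_nonnull = int(round(cfg.frac_nonnull * cfg.n_genes))
    nonnull = rng.choice(cfg.n_genes, size=n_nonnull, replace=False)
    G[nonnull] = rng.normal(0.0, cfg.effect_sd, n_nonnull)

    gene_lookup = {g: j for j, g in enumerate(genes)}
    # controls use an extra zero-effect slot
    gene_idx = np.array(
        [cfg.n_genes if c else gene_lookup[g] for g, c in zip(library.genes, is_ctrl)]
    )
    G_ext = np.append(G, 0.0)
    depths = np.full((cfg.n_screens, 2), float(cfg.depth))
    log_mu = model_log_mean(alpha, P, S, G_ext, gene_idx, np.log(depths))
    mu = np.exp(log_mu)
    phi = cfg.dispersion
    K = rng.negative_binomial(phi, phi / (phi + mu))

    table = GuideCountTable(counts=K, depths=depths, screens=[f"screen{s}" for s in range(cfg.n_screens)], library=library)
    truth = ScreenTruth(
        alpha=alpha,
        P=P,
        S=S,
        G=pd.Series(G, index=pd.Index(genes, name="gene")),
        gene_of_guide=pd.Series(
            np.where(is_ctrl, "", library.genes), index=pd.Index(library.guide_ids, name="guide_id")
        ),
        config=cfg,
    )
    return table, truth


# ---------------------------------------------------------------------------
# two-condition expression time course
# ---------------------------------------------------------------------------


@dataclass
class TimecourseSimConfig:
    """Two-condition (Th0/Th2) time-course generator conditions.

    Expression is generated on the log2 scale (gene baseline + activation
    trend shared by both conditions + Th2-only differentiation offset that
    switches on after ``onset`` hours + Gaussian noise) and exponentiated to
    TPM-like linear units.  The default grid is the nine-point design
    0, 0.5, 1, 2, 4, 6, 24, 48, 72 h with two replicates.
    """

    n_genes: int = 2000
    time_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 24.0, 48.0, 72.0)
    n_replicates: int = 2
    conditions: tuple[str, str] = ("Th0", "Th2")
    frac_activation_de: float = 0.1
    frac_differentiation_de: float = 0.1
    lfc_sd: float = 2.0
    noise_sd: float = 0.25
    onset: float = 6.0
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if 0.0 not in self.time_grid or 72.0 not in self.time_grid:
            raise ValueError("time grid must include 0 and 72 h")
        if self.frac_activation_de + self.frac_differentiation_de > 1.0:
            raise ValueError("DE fractions must sum to <= 1")
        if self.n_replicates < 2:
            raise ValueError("generator requires >= 2 replicates (DE needs them)")


@dataclass
class TimecourseTruth:
    classes: pd.Series  # gene -> {"null", "activation", "differentiation"}
    activation_lfc: pd.Series  # true log2 change 0 -> 72 h (shared trend)
    differentiation_lfc: pd.Series  # true Th2 - Th0 log2 offset at 72 h
    config: TimecourseSimConfig = field(repr=False, default=None)


def simulate_timecourse(
    cfg: TimecourseSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TimecourseTruth]:
    """Returns (expression genes x samples, sample metadata, truth)."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"g{j:05d}" for j in range(cfg.n_genes)]
    n_act = int(round(cfg.frac_activation_de * cfg.n_genes))
    n_diff = int(round(cfg.frac_differentiation_de * cfg.n_genes))
    order = rng.permutation(cfg.n_genes)
    act_idx, diff_idx = order[:n_act], order[n_act : n_act + n_diff]
    classes = np.array(["null"] * cfg.n_genes, dtype=object)
    classes[act_idx] = "activation"
    classes[diff_idx] = "differentiation"

    act_amp = np.zeros(cfg.n_genes)
    act_amp[act_idx] = rng.normal(0.0, cfg.lfc_sd, n_act)
    diff_amp = np.zeros(cfg.n_genes)
    diff_amp[diff_idx] = rng.normal(0.0, cfg.lfc_sd, n_diff)
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)

    times = np.array(cfg.time_grid, float)
    act_shape = np.log1p(times) / np.log1p(72.0)  # saturating activation trend, 0 -> 1
    span = 72.0 - cfg.onset
    diff_shape = np.clip((times - cfg.onset) / span, 0.0, 1.0)  # ramps on after onset

    cols, meta_rows, data = [], [], []
    for cond in cfg.conditions:
        is_th2 = cond == "Th2"
        for ti, t in enumerate(times):
            for rep in range(1, cfg.n_replicates + 1):
                name = f"{cond}_t{t:g}_r{rep}"
                log2 = (
                    baseline
                    + act_amp * act_shape[ti]
                    + (diff_amp * diff_shape[ti] if is_th2 else 0.0)
                    + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
                )
                cols.append(name)
                meta_rows.append((name, cond, t, rep))
                data.append(np.exp2(log2))
    expr = pd.DataFrame(
        np.column_stack(data), index=pd.Index(genes, name="gene"), columns=cols
    )
    meta = pd.DataFrame(meta_rows, columns=["sample", "condition", "time", "replicate"])
    gi = pd.Index(genes, name="gene")
    truth = TimecourseTruth(
        classes=pd.Series(classes, index=gi),
        activation_lfc=pd.Series(act_amp, index=gi),
        differentiation_lfc=pd.Series(diff_amp, index=gi),
        config=cfg,
    )
    return expr, meta, truth


# ---------------------------------------------------------------------------
# dynamic peak sets with motifs
# ---------------------------------------------------------------------------


@dataclass
class PeakTruth:
    peaks: pd.DataFrame  # chrom, start, end, id, dynamics class
    heights: pd.DataFrame  # peak id x time point, noiseless
    motif_hits: pd.DataFrame  # motif, peak_id
    class_ratios: dict


def simulate_peaks(
    n_peaks: int = 300,
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 24.0, 48.0, 72.0),
    motifs: "dict[str, dict[str, float]] | list[str] | None" = None,
    dynamics_classes: dict[str, float] | None = None,
    seed: int = 0,
    n_replicates: int = 2,
    jitter: int = 0,
    dropout: float = 0.0,
    height_noise_sd: float = 0.1,
) -> tuple[list[PeakSet], pd.DataFrame, PeakTruth]:
    """Peak sets per (time point, replicate) with planted dynamics and motifs.

    ``dynamics_classes`` maps a class name to its multiplicative height ratio
    per successive time point (default increasing x1.5, flat x1, decreasing
    /1.5).  ``motifs`` maps motif name to per-class planting probabilities;
    a bare list of names round-robins over the classes with in-class
    probability 0.7 and out-of-class probability 0.2.  Replicate sets are
    jittered copies of the consensus with the given coordinate jitter (bp),
    dropout probability and multiplicative log-normal height noise; the truth
    records the consensus coordinates and noiseless height trajectories.
    """
    if len(timepoints) < 2:
        raise ValueError("need >= 2 timepoints")
    rng = np.random.default_rng(seed)
    dynamics_classes = dynamics_classes or {
        "increasing": 1.5,
        "flat": 1.0,
        "decreasing": 1.0 / 1.5,
    }
    class_names = list(dynamics_classes)
    if motifs is None:
        motifs = ["GATA3", "BATF_JUN", "YY1", "FOXO1"]
    if isinstance(motifs, (list, tuple)):
        motifs = {
            m: {c: (0.7 if class_names[i % len(class_names)] == c else 0.2) for c in class_names}
            for i, m in enumerate(motifs)
        }

    width = rng.integers(200, 801, n_peaks)
    gap = rng.integers(2000, 8001, n_peaks)
    start = 1000 + np.cumsum(gap) + np.concatenate([[0], np.cumsum(width)[:-1]])
    end = start + width
    cls = rng.choice(class_names, n_peaks)
    base = np.exp(rng.normal(np.log(10.0), 0.5, n_peaks))
    ratios = np.array([dynamics_classes[c] for c in cls])
    steps = np.arange(len(timepoints))
    heights = base[:, None] * ratios[:, None] ** steps[None, :]

    ids = [f"p{j:05d}" for j in range(n_peaks)]
    truth_peaks = pd.DataFrame(
        {"chrom": "chr1", "start": start, "end": end, "id": ids, "class": cls}
    )
    height_df = pd.DataFrame(
        heights, index=pd.Index(ids, name="id"), columns=[f"t{t:g}" for t in timepoints]
    )

    hit_rows = []
    for m, probs in motifs.items():
        pr = np.array([probs.get(c, 0.0) for c in cls])
        present = rng.random(n_peaks) < pr
        hit_rows.extend((m, pid) for pid in np.array(ids)[present])
    motif_hits = pd.DataFrame(hit_rows, columns=["motif", "peak_id"])

    sets = []
    for ti, t in enumerate(timepoints):
        for rep in range(1, n_replicates + 1):
            keep = rng.random(n_peaks) >= dropout
            js = rng.integers(-jitter, jitter + 1, n_peaks) if jitter > 0 else np.zeros(n_peaks, int)
            je = rng.integers(-jitter, jitter + 1, n_peaks) if jitter > 0 else np.zeros(n_peaks, int)
            h = heights[:, ti] * np.exp(rng.normal(0.0, height_noise_sd, n_peaks))
            df = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": np.maximum(0, start + js),
                    "end": end + je,
                    "id": [f"{pid}_t{t:g}_r{rep}" for pid in ids],
                    "height": h,
                }
            )[keep]
            df = df[df["start"] < df["end"]]
            sets.append(PeakSet(df.reset_index(drop=True), time=t, replicate=f"r{rep}", assay="ATAC"))
    truth = PeakTruth(
        peaks=truth_peaks, heights=height_df, motif_hits=motif_hits, class_ratios=dynamics_classes
    )
    return sets, motif_hits, truth


# ---------------------------------------------------------------------------
# KO fold-change profiles as axis mixtures
# ---------------------------------------------------------------------------


def simulate_ko_profiles(
    act_axis: AxisSignature,
    diff_axis: AxisSignature,
    weights: list[tuple[float, float]],
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """KO log2 fold-change profiles ``a * u_act + d * u_diff + eps``.

    ``u`` are the unit-normalized axis vectors embedded (zero-padded) in the
    union gene universe; ``eps`` is i.i.d. Gaussian with sd ``noise_sd``.
    Returns (profiles genes x KOs, truth table with the planted weights).
    """
    rng = np.random.default_rng(seed)
    if act_axis.norm == 0.0 or diff_axis.norm == 0.0:
        raise ValueError("axis with zero norm")
    universe = act_axis.genes.union(diff_axis.genes).sort_values()
    u_act = act_axis.lfc.reindex(universe, fill_value=0.0).to_numpy()
    u_diff = diff_axis.lfc.reindex(universe, fill_value=0.0).to_numpy()
    u_act = u_act / np.linalg.norm(u_act)
    u_diff = u_diff / np.linalg.norm(u_diff)
    cols, data, rows = [], [], []
    for j, (a, d) in enumerate(weights):
        name = f"KO{j:02d}"
        eps = rng.normal(0.0, noise_sd, len(universe)) if noise_sd > 0 else 0.0
        data.append(a * u_act + d * u_diff + eps)
        cols.append(name)
        rows.append((name, a, d))
    profiles = pd.DataFrame(np.column_stack(data), index=universe, columns=cols)
    truth = pd.DataFrame(rows, columns=["ko", "a", "d"])
    return profiles, truth
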