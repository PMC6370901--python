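"""Rank combination, hit tiers and Fisher-exact term enrichment.

Per screen, a gene gets a rank from the positive-enrichment side (r_pos,
1 = most positively enriched) and from the negative side (r_neg); its
per-screen rank is r = min(r_pos, r_neg), with the positive direction
winning exact ties.  Across screens the composite score is the geometric
mean (r1 r2 ... rn)^(1/n), computed in log space.  Hit nomenclature: a gene
is a "hit" in a screen when r falls in the top 5% of ranked genes and a
"strong" hit in the top 1%.  Term over-representation among the top hits
(default top 300 by composite score) is assessed per term with a one-sided
Fisher exact test; raw p-values are reported by default, Benjamini-Hochberg
adjustment optionally.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "combine_pos_neg",
    "composite_score",
    "combine_rank_tables",
    "call_hits",
    "term_enrichment",
]

DEFAULT_THRESHOLDS = {"hit": 0.05, "strong": 0.01}


def combine_pos_neg(r_pos, r_neg):
    """r = min(r_pos, r_neg); direction = side of the minimum (pos wins ties).

    Accepts scalars or aligned arrays; returns (r, direction).
    """
    rp = np.asarray(r_pos, dtype=float)
    rn = np.asarray(r_neg, dtype=float)
    if (rp <= 0).any() or (rn <= 0).any():
        raise ValueError("ranks must be positive")
    r = np.minimum(rp, rn)
    direction = np.where(rp <= rn, "pos", "neg")
    if r.ndim == 0:
        return float(r), str(direction)
    return r, direction


def composite_score(ranks) -> float:
    """Geometric mean of per-screen ranks, computed in log space."""
    r = np.asarray(ranks, dtype=float)
    if r.size < 1:
        raise ValueError("need at least one rank")
    if (r <= 0).any() or not np.isfinite(r).all():
        raise ValueError("ranks must be positive and finite")
    return float(math.exp(np.mean(np.log(r))))


def combine_rank_tables(rank_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine per-screen (gene, r_pos, r_neg) tables into composite scores.

    Genes missing from any screen are excluded with a warning.  Output
    columns: gene, per-screen r and direction, composite.
    """
    import warnings

    combined = []
    for k, t in enumerate(rank_tables):
        r, direction = combine_pos_neg(t["r_pos"].to_numpy(), t["r_neg"].to_numpy())
        combined.append(
            pd.DataFrame({"gene": t["gene"], f"r_{k}": r, f"dir_{k}": direction})
        )
    out = combined[0]
    for t in combined[1:]:
        out = out.merge(t, on="gene", how="outer")
    rcols = [c for c in out.columns if c.startswith("r_")]
    missing = out[rcols].isna().any(axis=1)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} gene(s) not ranked in every screen; excluded from composite"
        )
        out = out.loc[~missing]
    logs = np.log(out[rcols].to_numpy(float))
    out = out.assign(composite=np.exp(logs.mean(axis=1)))
    return out.sort_values(["composite", "gene"]).reset_index(drop=True)


def call_hits(
    ranks: pd.DataFrame,
    n_genes: int,
    thresholds: dict[str, float] | None = None,
    rank_col: str = "r",
) -> pd.DataFrame:
    """Assign tier per gene: strong if r <= ceil(0.01 n), hit if <= ceil(0.05 n).

    ``ranks`` needs columns gene and ``rank_col`` (optionally direction).
    """
    th = thresholds or DEFAULT_THRESHOLDS
    strong_cut = math.ceil(th["strong"] * n_genes)
    hit_cut = math.ceil(th["hit"] * n_genes)
    r = ranks[rank_col].to_numpy(float)
    tier = np.where(r <= strong_cut, "strong", np.where(r <= hit_cut, "hit", "none"))
    out = ranks.copy()
    out["tier"] = tier
    return out


def term_enrichment(
    top_hits: set[str],
    terms: dict[str, set[str]],
    universe: set[str],
    adjust: bool = False,
) -> pd.DataFrame:
    """One-sided Fisher exact over-representation test per term.

    The 2x2 table for a term is (hits-in-term, hits-not-in-term,
    non-hits-in-term, non-hits-not-in-term) over the gene universe.  Reports
    p, fold enrichment and the table counts; terms are restricted to the
    universe and hits must be a subset of it.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not top_hits <= universe:
        raise ValueError("top_hits must be a subset of the universe")
    n_u, n_h = len(universe), len(top_hits)
    rows = []
    for term in sorted(terms):
        members = terms[term] & universe
        a = len(top_hits & members)
        b = n_h - a
        c = len(members) - a
        d = n_u - n_h - c
        p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        expected = n_h * len(members) / n_u
        fold = a / expected if expected > 0 else float("nan")
        rows.append((term, a, b, c, d, fold, p))
    out = pd.DataFrame(
        rows, columns=["term", "hits_in", "hits_out", "rest_in", "rest_out", "fold", "p"]
    )
    if adjust:
        out["p_adj"] = _benjamini_hochberg(out["p"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = m - rank_from_end
        running = min(running, p[idx] * m / k)
        adj[idx] = running
    return adj
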