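"""Time-course differential expression and activation/differentiation axes.

Th cells activated without polarizing cytokine ("Th0") and IL4-driven Th2
cells are profiled over a shared time grid.  Genes whose trajectory differs
between the two conditions are found by a nested-model comparison: the full
model has an intercept, a condition main effect, a natural-spline time trend
(df=5) and a condition x time interaction; the reduced model keeps only the
intercept and the shared time trend.  Expression is analyzed as
``log(value + 0.5)`` with Gaussian errors; the nested comparison is assessed
with the exact-under-Gaussian F reference by default (the asymptotic chi2_6
reference is available but anti-conservative at typical time-course sizes).

Two one-dimensional "axes" summarize the biology: activation is the Th0
72 h-vs-0 h contrast, differentiation the Th2-vs-Th0 contrast at 72 h; each
axis is the log2 fold-change vector over its significant genes
(p < 1e-10 by default) oriented so positive means activated / Th2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "AxisSignature",
    "SplineLrtResult",
    "split_early_late",
    "natural_spline_basis",
    "spline_lrt",
    "SplineTimecourseDE",
    "two_group_de",
    "build_axis",
    "intersect_orthologs",
]

DE_P_THRESHOLD = 0.01  # declared differentially expressed below this p
AXIS_P_THRESHOLD = 1e-10


@dataclass
class AxisSignature:
    """Gene set + log2 fold-change vector defining one axis.

    Orientation: positive lfc means toward the activated (activation axis)
    or Th2 (differentiation axis) state.
    """

    kind: str  # "activation" | "differentiation"
    table: pd.DataFrame  # index gene; columns lfc, p
    threshold: float

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "differentiation"):
            raise ValueError(f"unknown axis kind {self.kind!r}")
        if (self.table["p"] > self.threshold).any():
            raise ValueError("axis contains genes above its own p threshold")
        if self.norm == 0.0:
            raise ValueError("axis lfc vector has zero norm")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    @property
    def lfc(self) -> pd.Series:
        return self.table["lfc"]

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.table["lfc"].to_numpy()))


def split_early_late(
    times: "np.ndarray | pd.Series | list[float]", convention: str = "main"
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean (early, late) masks over samples.

    ``convention="main"``: early = t <= 6 h; late = t == 0 or t > 6 h (the
    0 h anchor belongs to both windows, 6 h to early only).
    ``convention="star"``: early = t <= 6 h; late = t > 6 h.
    Degenerate windows (too few distinct times for the spline) surface as
    errors downstream in the model fit, not here.
    """
    t = np.asarray(times, dtype=float)
    early = t <= 6.0
    if convention == "main":
        late = (t == 0.0) | (t > 6.0)
    elif convention == "star":
        late = t > 6.0
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return early, late


def natural_spline_basis(times: np.ndarray, df: int = 5) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns, excluding the constant.

    Interior knots at quantiles of the distinct observed times, boundary
    knots at min/max, linear beyond the boundaries (truncated-power
    construction).  Together with an intercept the basis spans a
    (df+1)-dimensional natural-spline space; the column span is invariant to
    affine rescaling of the time axis (modulo the intercept).
    """
    t = np.asarray(times, dtype=float)
    uniq = np.unique(t)
    if len(uniq) <= df:
        raise ValueError(f"need > {df} distinct time points for a df={df} spline basis")
    probs = np.linspace(0.0, 1.0, df + 1)[1:-1]
    interior = np.quantile(uniq, probs)
    knots = np.unique(np.concatenate([[uniq[0]], interior, [uniq[-1]]]))
    if len(knots) != df + 1:
        raise ValueError("degenerate knot sequence for the requested df")
    kK = knots[-1]

    def d(k):
        return (np.clip(t - k, 0.0, None) ** 3 - np.clip(t - kK, 0.0, None) ** 3) / (kK - k)

    d_last = d(knots[-2])
    cols = [t] + [d(k) - d_last for k in knots[:-2]]
    return np.column_stack(cols)


@dataclass
class SplineLrtResult:
    lrt_stat: float
    df_diff: int
    p: float
    flag: str | None = None  # "rank_deficient" | "degenerate" | None

    def __iter__(self):  # tuple-like unpacking (lrt_stat, df_diff, p)
        return iter((self.lrt_stat, self.df_diff, self.p))


def _ols_rss(X: np.ndarray, z: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    return float(resid @ resid)


def spline_lrt(
    y: np.ndarray,
    time: np.ndarray,
    condition: np.ndarray,
    df: int = 5,
    method: str = "f",
) -> SplineLrtResult:
    """Nested-model test for condition-dependent expression dynamics.

    Full model: intercept + condition + B(t) + condition:B(t); reduced:
    intercept + B(t), fitted by Gaussian maximum likelihood on
    ``log(y + 0.5)``.  Returns the likelihood-ratio statistic
    ``n log(RSS_red/RSS_full)``, the parameter-count difference
    (1 + df = 6 by default) and a p-value from the F reference
    (``method="f"``, exact under the Gaussian model) or the chi2 upper tail
    (``method="chisq"``).
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(time, dtype=float)
    cond = np.asarray(condition)
    n = len(y)
    if not (len(t) == len(cond) == n):
        raise ValueError("y, time, condition must have equal length")
    levels = np.unique(cond)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 condition levels, got {list(levels)}")
    z = np.log(y + 0.5)
    B = natural_spline_basis(t, df=df)
    c = (cond == levels[1]).astype(float)
    X_red = np.column_stack([np.ones(n), B])
    X_full = np.column_stack([np.ones(n), c, B, c[:, None] * B])
    q = X_full.shape[1] - X_red.shape[1]  # 1 + df
    if np.linalg.matrix_rank(X_full) < X_full.shape[1] or n <= X_full.shape[1]:
        return SplineLrtResult(float("nan"), q, float("nan"), flag="rank_deficient")
    rss_f = _ols_rss(X_full, z)
    rss_r = _ols_rss(X_red, z)
    if rss_f <= 0.0:
        return SplineLrtResult(float("inf"), q, 0.0, flag="degenerate")
    lrt = n * np.log(rss_r / rss_f)
    lrt = max(lrt, 0.0)  # guard tiny negative from round-off
    if method == "chisq":
        p = float(stats.chi2.sf(lrt, q))
    elif method == "f":
        fstat = ((rss_r - rss_f) / q) / (rss_f / (n - X_full.shape[1]))
        p = float(stats.f.sf(max(fstat, 0.0), q, n - X_full.shape[1]))
    else:
        raise ValueError(f"unknown method {method!r}")
    return SplineLrtResult(float(lrt), q, p)


class SplineTimecourseDE(BaseEstimator):
    """Per-gene spline nested-model DE over a two-condition time course.

    Parameters
    ----------
    df : int
        Spline degrees of freedom (default 5).
    window : {"early", "late", None}
        Optional time window; early is t <= 6 h, late is the 0 h anchor plus
        t > 6 h (``convention`` switches to the strict t > 6 h variant).
    alpha : float
        DE call threshold on p (default 0.01).
    method : {"f", "chisq"}
        Reference distribution for the nested comparison.

    Attributes
    ----------
    results_ : pandas.DataFrame
        Per-gene lrt_stat, df_diff, p, de flag, fit flag.
    """

    def __init__(self, df=5, window=None, convention="main", alpha=DE_P_THRESHOLD, method="f"):
        self.df = df
        self.window = window
        self.convention = convention
        self.alpha = alpha
        self.method = method

    def fit(self, expr: pd.DataFrame, meta: pd.DataFrame):
        meta = meta.set_index("sample").reindex(expr.columns)
        if meta.isna().any().any():
            raise ValueError("metadata missing for some expression columns")
        meta.index.name = "sample"
        meta = meta.reset_index()
        if self.window is not None:
            if self.window not in ("early", "late"):
                raise ValueError(f"unknown window {self.window!r}")
            early, late = split_early_late(meta["time"], self.convention)
            mask = early if self.window == "early" else late
            meta = meta.loc[mask]
            expr = expr.loc[:, meta["sample"]]
        counts = meta.groupby(["condition", "time"]).size()
        if (counts < 2).any():
            raise ValueError("DE needs >= 2 replicates per (condition, time) group")
        t = meta["time"].to_numpy(float)
        cond = meta["condition"].to_numpy()
        rows = []
        for gene, y in expr.iterrows():
            res = spline_lrt(y.to_numpy(float), t, cond, df=self.df, method=self.method)
            rows.append((gene, res.lrt_stat, res.df_diff, res.p, res.flag))
        out = pd.DataFrame(rows, columns=["gene", "lrt_stat", "df_diff", "p", "flag"])
        out["de"] = out["p"] < self.alpha
        self.results_ = out
        return self


def two_group_de(
    expr: pd.DataFrame, group_a: list[str], group_b: list[str]
) -> pd.DataFrame:
    """Welch t-test per gene on log2(value + 1); lfc = mean(B) - mean(A)."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    A = np.log2(expr[group_a].to_numpy(float) + 1.0)
    B = np.log2(expr[group_b].to_numpy(float) + 1.0)
    lfc = B.mean(axis=1) - A.mean(axis=1)
    va, vb = A.var(axis=1, ddof=1), B.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(B, A, axis=1, equal_var=False)
    degenerate = (va == 0.0) & (vb == 0.0)
    p = np.where(degenerate & (lfc == 0.0), 1.0, p)
    p = np.where(degenerate & (lfc != 0.0), 0.0, p)
    out = pd.DataFrame({"lfc": lfc, "p": p}, index=expr.index)
    out.index.name = "gene"
    if degenerate.any() and (lfc[degenerate] != 0).any():
        warnings.warn("zero-variance genes with unequal means: p set to 0 (degenerate)")
    return out


def _samples(meta: pd.DataFrame, condition: str, time: float) -> list[str]:
    sel = meta[(meta["condition"] == condition) & (meta["time"] == time)]
    return sel["sample"].tolist()


def build_axis(
    expr: pd.DataFrame,
    meta: pd.DataFrame,
    axis_kind: str,
    p_threshold: float = AXIS_P_THRESHOLD,
    t_end: float = 72.0,
) -> AxisSignature:
    """Axis from its defining contrast.

    activation: Th0 at t=0 (A) vs Th0 at t_end (B) — positive = activated.
    differentiation: Th0 at t_end (A) vs Th2 at t_end (B) — positive = Th2.
    """
    if axis_kind == "activation":
        a = _samples(meta, "Th0", 0.0)
        b = _samples(meta, "Th0", t_end)
    elif axis_kind == "differentiation":
        a = _samples(meta, "Th0", t_end)
        b = _samples(meta, "Th2", t_end)
    else:
        raise ValueError(f"unknown axis kind {axis_kind!r}")
    if not a or not b:
        raise ValueError(f"missing samples for the {axis_kind} contrast")
    de = two_group_de(expr, a, b)
    keep = de[de["p"] < p_threshold]
    if keep.empty:
        raise ValueError(
            f"no gene passes p < {p_threshold:g} for the {axis_kind} axis; "
            "consider raising the threshold"
        )
    return AxisSignature(kind=axis_kind, table=keep[["lfc", "p"]].copy(), threshold=p_threshold)


def intersect_orthologs(
    de_a: set[str], de_b: set[str], ortholog_map: list[tuple[str, str]]
) -> set[str]:
    """Genes of A whose mapped partner (many-to-many) is in B."""
    if not ortholog_map:
        warnings.warn("empty ortholog map: intersection is empty")
        return set()
    partners: dict[str, set[str]] = {}
    for a, b in ortholog_map:
        partners.setdefault(a, set()).add(b)
    return {g for g in de_a if partners.get(g, set()) & de_b}
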