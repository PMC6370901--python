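"""Motif activity response analysis (MARA-lite).

A transcription factor's motif is linked to a gene when an accessible
chromatin peak carrying the motif lies within a window of the gene's TSS
(default 20 kb), pooled over time points; the number of such peaks is the
connectivity N[g, m].  Given a log-expression matrix E (genes x samples,
row-centered), per-sample motif activities A solve the linear model
E ~ N A by ridge regression::

    A = (N'N + lambda I)^-1 N' E

fitted independently per condition (Th0, Th2).  A motif's activity is high
when it consistently explains the upregulation of its putative targets
(negative for a repressor).  Two summary scores per motif: the
differentiation score is the mean Th2 - Th0 activity difference over time;
the activation score is the Th0 activity difference between the last and
first time points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io_formats import PeakSet

__all__ = [
    "build_connectivity",
    "MotifActivityRidge",
    "fit_activities",
    "tf_scores",
    "select_motif_per_tf",
]


def build_connectivity(
    peaks: PeakSet,
    motif_hits: pd.DataFrame,
    tss_table: pd.DataFrame,
    window_bp: int = 20_000,
    genes: "pd.Index | list[str] | None" = None,
) -> pd.DataFrame:
    """Gene x motif counts of motif-bearing peaks near each TSS.

    A peak counts for gene g if it overlaps the half-open window
    [tss - w, tss + w); N[g, m] is the number of distinct such peaks
    containing at least one hit of motif m (time point union is assumed to
    have happened upstream, in the merged peak set).  Genes without a TSS
    entry are dropped with a warning.
    """
    import warnings

    tss = tss_table
    if genes is not None:
        genes = pd.Index(genes)
        missing = genes.difference(tss["gene"])
        if len(missing):
            warnings.warn(f"{len(missing)} gene(s) absent from the TSS table; dropped")
        tss = tss[tss["gene"].isin(genes)]
    peaks_by_motif = motif_hits.groupby("motif")["peak_id"].agg(set)
    pt = peaks.table
    motifs = sorted(peaks_by_motif.index)
    N = pd.DataFrame(
        0, index=pd.Index(tss["gene"].to_numpy(), name="gene"), columns=motifs, dtype=int
    )
    for chrom, tgroup in tss.groupby("chrom"):
        pc = pt[pt["chrom"] == chrom]
        if pc.empty:
            continue
        starts = pc["start"].to_numpy()
        ends = pc["end"].to_numpy()
        pids = pc["id"].to_numpy()
        for g, pos in zip(tgroup["gene"], tgroup["tss_position"]):
            lo, hi = pos - window_bp, pos + window_bp
            near = set(pids[(starts < hi) & (ends > lo)])
            if not near:
                continue
            for m in motifs:
                N.loc[g, m] = len(near & peaks_by_motif[m])
    return N


class MotifActivityRidge(BaseEstimator):
    """Ridge inference of per-sample motif activities from E ~ N A.

    Parameters
    ----------
    alpha : float or "auto"
        Ridge penalty lambda; "auto" uses 1e-3 * mean(diag(N'N)).
        ``alpha=0`` requires N'N nonsingular and reduces to least squares.
    log_transform : bool
        Apply log2(x + 1) to the expression before row-centering
        (default True; pass False if E is already on a log scale).

    Attributes
    ----------
    activities_ : pandas.DataFrame, motifs x samples.
    alpha_ : float, the penalty actually used.
    """

    def __init__(self, alpha="auto", log_transform: bool = True):
        self.alpha = alpha
        self.log_transform = log_transform

    def fit(self, N: pd.DataFrame, E: pd.DataFrame):
        genes = N.index.intersection(E.index)
        if len(genes) < len(N.index) or len(genes) < len(E.index):
            N = N.loc[genes]
            E = E.loc[genes]
        Nm = N.to_numpy(float)
        Em = E.to_numpy(float)
        if self.log_transform:
            Em = np.log2(Em + 1.0)
        Em = Em - Em.mean(axis=1, keepdims=True)  # row-center per gene
        G = Nm.T @ Nm
        if self.alpha == "auto":
            lam = 1e-3 * float(np.mean(np.diag(G)))
        else:
            lam = float(self.alpha)
            if lam < 0:
                raise ValueError("alpha must be >= 0")
        if lam == 0.0 and np.linalg.matrix_rank(G) < G.shape[0]:
            raise np.linalg.LinAlgError(
                "N'N is singular at lambda=0; use a positive ridge penalty"
            )
        A = np.linalg.solve(G + lam * np.eye(G.shape[0]), Nm.T @ Em)
        self.alpha_ = lam
        self.activities_ = pd.DataFrame(A, index=N.columns, columns=E.columns)
        return self

    def fit_transform(self, N: pd.DataFrame, E: pd.DataFrame) -> pd.DataFrame:
        return self.fit(N, E).activities_


def fit_activities(E: pd.DataFrame, N: pd.DataFrame, lam="auto", log_transform=True) -> pd.DataFrame:
    """Functional wrapper over :class:`MotifActivityRidge` (one condition)."""
    return MotifActivityRidge(alpha=lam, log_transform=log_transform).fit_transform(N, E)


def tf_scores(A_th0: pd.DataFrame, A_th2: pd.DataFrame, times=None) -> pd.DataFrame:
    """Per-motif activation and differentiation scores.

    differentiation(m) = mean over time of A_th2(m, t) - A_th0(m, t);
    activation(m) = A_th0(m, last time) - A_th0(m, first time).
    Columns of the two activity matrices must align time-wise; ``times``
    optionally gives the time order (defaults to column order).
    """
    if not A_th0.index.equals(A_th2.index):
        if set(A_th0.index) != set(A_th2.index):
            raise ValueError("mismatched motif sets between conditions")
        A_th2 = A_th2.loc[A_th0.index]
    if A_th0.shape[1] != A_th2.shape[1]:
        raise ValueError("mismatched time grids between conditions")
    cols = list(A_th0.columns)
    if times is not None:
        order = np.argsort(np.asarray(times, float), kind="stable")
        cols = [cols[i] for i in order]
        A_th0 = A_th0[cols]
        A_th2 = A_th2[A_th2.columns[order]]
    diff = (A_th2.to_numpy() - A_th0.to_numpy()).mean(axis=1)
    act = A_th0.iloc[:, -1].to_numpy() - A_th0.iloc[:, 0].to_numpy()
    return pd.DataFrame(
        {"activation_score": act, "differentiation_score": diff},
        index=A_th0.index.rename("motif"),
    )


def select_motif_per_tf(motif_meta: pd.DataFrame) -> pd.DataFrame:
    """One motif per TF: prioritize the longest motif, then lowest mean entropy.

    ``motif_meta`` columns: motif, tf, length, mean_entropy.  Ties beyond
    entropy break deterministically on motif name.
    """
    ordered = motif_meta.sort_values(
        ["tf", "length", "mean_entropy", "motif"], ascending=[True, False, True, True]
    )
    return ordered.groupby("tf", as_index=False).first()[["tf", "motif", "length", "mean_entropy"]]
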