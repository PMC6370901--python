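"""Interval operators for ATAC/ChIP peak sets.

All coordinates are 0-based half-open.  Overlap fractions are measured
against the shorter peak by default (reciprocal mode optional); bp-level
set operations (Jaccard) follow bedtools semantics on interval unions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PeakSet

__all__ = [
    "PeakSignalMatrix",
    "replicate_consistent_peaks",
    "normalize_signal",
    "motif_trajectory",
    "peak_ratio_rank",
    "jaccard_peaks",
    "tf_network",
    "nearest_tss",
]


# ---------------------------------------------------------------------------
# interval primitives
# ---------------------------------------------------------------------------


def _union_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge strictly overlapping intervals (touching intervals stay apart)."""
    if len(starts) == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    s, e = starts[order], ends[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a < out_e[-1]:  # strict overlap
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.array(out_s), np.array(out_e)


def _overlap_bp(s1, e1, s2, e2) -> int:
    """Total bp overlap between two sorted disjoint interval unions."""
    total, i, j = 0, 0, 0
    while i < len(s1) and j < len(s2):
        lo = max(s1[i], s2[j])
        hi = min(e1[i], e2[j])
        if hi > lo:
            total += hi - lo
        if e1[i] <= e2[j]:
            i += 1
        else:
            j += 1
    return total


# ---------------------------------------------------------------------------
# replicate-consistent merging
# ---------------------------------------------------------------------------


def replicate_consistent_peaks(
    rep_sets: list[PeakSet], min_frac: float = 0.5, mode: str = "shorter"
) -> PeakSet:
    """Keep peaks supported by another replicate, then merge to union coords.

    A peak is retained iff some peak in a *different* replicate of the same
    time point overlaps it by at least ``min_frac`` of the shorter peak's
    length (``mode="reciprocal"``: the fraction must hold for both peaks'
    lengths).  All retained peaks, across replicates and time points, are
    then merged transitively into union-coordinate peaks; the merged height
    is the mean of the member heights.  Overlapping peaks within one
    replicate are merged first with a warning.
    """
    if len(rep_sets) < 2:
        raise ValueError("need >= 2 replicate peak sets")
    if mode not in ("shorter", "reciprocal"):
        raise ValueError(f"unknown overlap mode {mode!r}")

    cleaned = [_merge_within(ps) for ps in rep_sets]

    # group replicate sets by time point; unlabeled sets form one group
    groups: dict[object, list[int]] = {}
    for k, ps in enumerate(rep_sets):
        groups.setdefault(ps.time, []).append(k)

    retained = []
    for members in groups.values():
        if len(members) < 2:
            continue  # a lone set has no supporting replicate
        for k in members:
            mine = cleaned[k]
            others = pd.concat([cleaned[j] for j in members if j != k], ignore_index=True)
            keep = _supported(mine, others, min_frac, mode)
            retained.append(mine[keep])
    if not retained:
        return PeakSet(pd.DataFrame(columns=["chrom", "start", "end", "id", "height"]))
    allp = pd.concat(retained, ignore_index=True)

    rows = []
    n = 0
    for chrom, grp in allp.groupby("chrom", sort=True):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        s = grp["start"].to_numpy()[order]
        e = grp["end"].to_numpy()[order]
        h = grp["height"].to_numpy()[order]
        cur_s, cur_e, members = s[0], e[0], [h[0]]
        for a, b, hh in zip(s[1:], e[1:], h[1:]):
            if a < cur_e:
                cur_e = max(cur_e, b)
                members.append(hh)
            else:
                n += 1
                rows.append((chrom, cur_s, cur_e, f"merged_{n}", float(np.mean(members))))
                cur_s, cur_e, members = a, b, [hh]
        n += 1
        rows.append((chrom, cur_s, cur_e, f"merged_{n}", float(np.mean(members))))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "height"]))


def _merge_within(ps: PeakSet) -> pd.DataFrame:
    t = ps.table
    out = []
    warned = False
    for chrom, grp in t.groupby("chrom", sort=True):
        order = np.argsort(grp["start"].to_numpy(), kind="stable")
        g = grp.iloc[order]
        s, e = g["start"].to_numpy(), g["end"].to_numpy()
        h, ids = g["height"].to_numpy(), g["id"].to_numpy()
        i = 0
        while i < len(s):
            cur_s, cur_e, hh, member_id = s[i], e[i], [h[i]], ids[i]
            j = i + 1
            while j < len(s) and s[j] < cur_e:
                if not warned:
                    warnings.warn(f"overlapping peaks within replicate {ps.replicate!r}; merged")
                    warned = True
                cur_e = max(cur_e, e[j])
                hh.append(h[j])
                j += 1
            out.append((chrom, cur_s, cur_e, member_id, float(np.mean(hh))))
            i = j
    return pd.DataFrame(out, columns=["chrom", "start", "end", "id", "height"])


def _supported(
    mine: pd.DataFrame, others: pd.DataFrame, min_frac: float, mode: str
) -> np.ndarray:
    keep = np.zeros(len(mine), dtype=bool)
    for chrom, grp in mine.groupby("chrom", sort=False):
        oc = others[others["chrom"] == chrom]
        if oc.empty:
            continue
        os_, oe = oc["start"].to_numpy(), oc["end"].to_numpy()
        for row_pos, (a, b) in zip(grp.index, zip(grp["start"], grp["end"])):
            ov = np.minimum(b, oe) - np.maximum(a, os_)
            lens_other = oe - os_
            shorter = np.minimum(b - a, lens_other)
            if mode == "shorter":
                ok = ov >= min_frac * shorter
            else:
                ok = (ov >= min_frac * (b - a)) & (ov >= min_frac * lens_other)
            ok &= ov > 0
            if ok.any():
                keep[mine.index.get_loc(row_pos)] = True
    return keep


# ---------------------------------------------------------------------------
# signal normalization and motif trajectories
# ---------------------------------------------------------------------------


@dataclass
class PeakSignalMatrix:
    """Merged-peak x time normalized heights; anchor column is identically 1."""

    matrix: pd.DataFrame  # peaks x time points
    background: pd.Series  # per time point
    anchor: str  # anchor column name

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix[self.anchor].to_numpy(float), 1.0):
            raise ValueError("anchor column must be identically 1 after normalization")


def normalize_signal(
    heights: pd.DataFrame, background: pd.Series, anchor_index: int = 1
) -> PeakSignalMatrix:
    """Background-normalize, then scale each peak to its anchor time point.

    h~[p,t] = (h[p,t] / bg[t]) / (h[p,anchor] / bg[anchor]); the anchor is
    the second time point by default.  Peaks with zero height at the anchor
    are excluded with a warning.
    """
    if not (background > 0).all():
        raise ValueError("background must be > 0 for every sample")
    if not 0 <= anchor_index < heights.shape[1]:
        raise ValueError("anchor_index out of range")
    bg = background.reindex(heights.columns)
    if bg.isna().any():
        raise ValueError("background missing for some time points")
    rel = heights.to_numpy(float) / bg.to_numpy(float)[None, :]
    anchor_col = heights.columns[anchor_index]
    anchor_vals = rel[:, anchor_index]
    zero = anchor_vals == 0.0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} peak(s) with zero height at the anchor; excluded")
    norm = rel[~zero] / anchor_vals[~zero, None]
    return PeakSignalMatrix(
        matrix=pd.DataFrame(norm, index=heights.index[~zero], columns=heights.columns),
        background=bg,
        anchor=anchor_col,
    )


def motif_trajectory(
    signal: "PeakSignalMatrix | pd.DataFrame", motif_hits: pd.DataFrame
) -> pd.DataFrame:
    """Per-motif mean normalized peak signal over time.

    traj(m, t) = mean over peaks containing motif m of h~[p, t]; motifs with
    no peak in the signal matrix are omitted with a warning.
    """
    mat = signal.matrix if isinstance(signal, PeakSignalMatrix) else signal
    rows = {}
    skipped = []
    for m, grp in motif_hits.groupby("motif"):
        members = mat.index.intersection(grp["peak_id"])
        if len(members) == 0:
            skipped.append(m)
            continue
        rows[m] = mat.loc[members].mean(axis=0)
    if skipped:
        warnings.warn(f"motif(s) with zero peaks omitted: {sorted(skipped)}")
    out = pd.DataFrame(rows).T
    out.index.name = "motif"
    return out.sort_index()


# ---------------------------------------------------------------------------
# ratio ranking, Jaccard, TSS networks
# ---------------------------------------------------------------------------


def nearest_tss(peaks: PeakSet, tss_table: pd.DataFrame) -> pd.DataFrame:
    """Nearest gene per peak by |peak midpoint - TSS| on the same chromosome.

    Distance ties break on gene symbol.  Peaks on chromosomes without any
    TSS get gene = NA and infinite distance.
    """
    rows = []
    for r in peaks.table.itertuples(index=False):
        cand = tss_table[tss_table["chrom"] == r.chrom]
        if cand.empty:
            rows.append((r.id, pd.NA, float("inf")))
            continue
        mid = (r.start + r.end) // 2
        dist = (cand["tss_position"] - mid).abs()
        best = cand.assign(dist=dist).sort_values(["dist", "gene"]).iloc[0]
        rows.append((r.id, best["gene"], float(best["dist"])))
    return pd.DataFrame(rows, columns=["id", "gene", "distance"])


def peak_ratio_rank(
    heights_t72: pd.Series,
    heights_t24: pd.Series,
    peaks: PeakSet,
    tss_table: pd.DataFrame,
    n: int = 1000,
    pseudocount: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top/bottom n peaks by the (72 h + c)/(24 h + c) height ratio.

    Returns (increasing, decreasing) tables with peak id, ratio and the
    nearest gene (unrestricted distance).  Ties break deterministically on
    peak id; if n exceeds the number of peaks, all are used with a warning.
    """
    ids = heights_t72.index
    if not ids.equals(heights_t24.index):
        raise ValueError("mismatched peak ids between time points")
    if n > len(ids):
        warnings.warn(f"n={n} exceeds {len(ids)} peaks; using all")
        n = len(ids)
    ratio = (heights_t72.to_numpy(float) + pseudocount) / (
        heights_t24.to_numpy(float) + pseudocount
    )
    tab = pd.DataFrame({"id": ids, "ratio": ratio})
    genes = nearest_tss(peaks, tss_table).set_index("id")
    tab = tab.join(genes, on="id")
    top = tab.sort_values(["ratio", "id"], ascending=[False, True]).head(n).reset_index(drop=True)
    bottom = tab.sort_values(["ratio", "id"], ascending=[True, True]).head(n).reset_index(drop=True)
    return top, bottom


def jaccard_peaks(a: PeakSet, b: PeakSet) -> float:
    """Basepair Jaccard index of the two interval unions."""
    if len(a) == 0 or len(b) == 0:
        warnings.warn("empty peak set: Jaccard defined as 0")
        return 0.0
    inter = 0
    len_a = 0
    len_b = 0
    chroms = set(a.table["chrom"]) | set(b.table["chrom"])
    for chrom in chroms:
        ta = a.table[a.table["chrom"] == chrom]
        tb = b.table[b.table["chrom"] == chrom]
        sa, ea = _union_intervals(ta["start"].to_numpy(), ta["end"].to_numpy())
        sb, eb = _union_intervals(tb["start"].to_numpy(), tb["end"].to_numpy())
        len_a += int((ea - sa).sum()) if len(sa) else 0
        len_b += int((eb - sb).sum()) if len(sb) else 0
        inter += _overlap_bp(sa, ea, sb, eb)
    union = len_a + len_b - inter
    return inter / union if union > 0 else 0.0


def tf_network(
    chip_sets: dict[str, PeakSet], tss_table: pd.DataFrame, max_dist: int = 20_000
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """TF -> gene edges from ChIP peaks near TSSs.

    Edge TF -> g iff some peak of the TF has midpoint distance to g's TSS
    strictly below ``max_dist`` and g is that peak's closest gene.  Returns
    (edge list, binary TF x gene target matrix).
    """
    edges = set()
    for tf in sorted(chip_sets):
        assigned = nearest_tss(chip_sets[tf], tss_table)
        hits = assigned[(assigned["distance"] < max_dist) & assigned["gene"].notna()]
        edges.update((tf, g) for g in hits["gene"])
    edge_df = pd.DataFrame(sorted(edges), columns=["tf", "gene"])
    tfs = sorted(chip_sets)
    genes = sorted(edge_df["gene"].unique()) if not edge_df.empty else []
    mat = pd.DataFrame(0, index=pd.Index(tfs, name="tf"), columns=genes, dtype=int)
    for tf, g in edges:
        mat.loc[tf, g] = 1
    return edge_df, mat
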