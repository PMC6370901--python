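"""Scalar projection of perturbation transcriptomes onto the two axes.

A knockout's (or overexpression's) log2 fold-change profile is summarized
by two numbers: its scalar projection onto the activation axis and onto the
differentiation axis.  For a profile ``x`` and an axis with fold-change
vector ``u`` restricted to the genes the two share::

    score = <x, u> / ||u||

i.e. the projection onto the unit axis vector, so a profile equal to the
axis itself scores the axis norm, and scores are comparable across profiles
with different gene coverage.  Overexpression is approximately the opposite
of knockout, so OE profiles have both scores negated by default
("axis flipping") to land KO and OE of the same gene in the same quadrant.
The two axes are generally not orthogonal; the fitted projector reports
their cosine similarity, and optional Gram-Schmidt orthogonalization of the
differentiation axis against the activation axis is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .timecourse_de import AxisSignature

__all__ = ["PerturbationProfile", "project_profile", "AxisProjector", "map_perturbations"]

MIN_SHARED_GENES = 10


@dataclass
class PerturbationProfile:
    """One perturbation's log2 fold changes vs control."""

    perturbation: str
    lfc: pd.Series  # indexed by gene
    mode: str = "KO"  # "KO" | "OE"

    def __post_init__(self) -> None:
        if self.mode not in ("KO", "OE"):
            raise ValueError(f"mode must be KO or OE, got {self.mode!r}")
        if not np.isfinite(self.lfc.to_numpy(float)).all():
            raise ValueError("profile lfc must be finite")


def project_profile(profile: "PerturbationProfile | pd.Series", axis: AxisSignature) -> float:
    """Scalar projection of a profile onto the unit axis vector.

    Uses all axis genes present in the profile; requires at least
    ``MIN_SHARED_GENES`` shared genes and a nonzero restricted axis norm.
    """
    lfc = profile.lfc if isinstance(profile, PerturbationProfile) else profile
    shared = axis.genes.intersection(lfc.index)
    if len(shared) < MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(shared)} axis genes present in profile (need >= {MIN_SHARED_GENES})"
        )
    u = axis.lfc.loc[shared].to_numpy(float)
    x = lfc.loc[shared].to_numpy(float)
    norm = np.linalg.norm(u)
    if norm == 0.0:
        raise ValueError("axis restricted to the shared genes has zero norm")
    return float(x @ u / norm)


class AxisProjector(BaseEstimator):
    """Map perturbation profiles to (activation, differentiation) coordinates.

    Parameters
    ----------
    flip_oe : bool
        Negate both scores for OE profiles (default True).
    neutral_radius : float
        Profiles with coordinate norm <= this radius are flagged neutral
        (default 0: only exactly-zero projections).
    orthogonalize : bool
        Gram-Schmidt the differentiation axis against the activation axis
        over their shared gene universe before projecting (default False;
        the axes' shear is instead reported as ``cosine_similarity_``).

    Attributes
    ----------
    act_axis_, diff_axis_ : AxisSignature
    cosine_similarity_ : float
        Cosine of the two axes over the union universe (zero-padded).
    """

    def __init__(self, flip_oe: bool = True, neutral_radius: float = 0.0, orthogonalize: bool = False):
        self.flip_oe = flip_oe
        self.neutral_radius = neutral_radius
        self.orthogonalize = orthogonalize

    def fit(self, act_axis: AxisSignature, diff_axis: AxisSignature):
        if act_axis.norm == 0.0 or diff_axis.norm == 0.0:
            raise ValueError("axes must have nonzero norm")
        universe = act_axis.genes.union(diff_axis.genes).sort_values()
        a = act_axis.lfc.reindex(universe, fill_value=0.0).to_numpy(float)
        d = diff_axis.lfc.reindex(universe, fill_value=0.0).to_numpy(float)
        self.cosine_similarity_ = float(
            a @ d / (np.linalg.norm(a) * np.linalg.norm(d))
        )
        self.act_axis_ = act_axis
        if self.orthogonalize:
            d_orth = d - (a @ d / (a @ a)) * a
            keep = diff_axis.genes  # keep original gene support
            table = pd.DataFrame(
                {"lfc": pd.Series(d_orth, index=universe).loc[keep], "p": diff_axis.table["p"]}
            )
            self.diff_axis_ = AxisSignature(
                kind=diff_axis.kind, table=table, threshold=diff_axis.threshold
            )
        else:
            self.diff_axis_ = diff_axis
        return self

    def transform(self, profiles: list[PerturbationProfile]) -> pd.DataFrame:
        """Coordinates per perturbation; per-row failures are recorded and
        other rows continue."""
        rows = []
        for prof in profiles:
            try:
                act = project_profile(prof, self.act_axis_)
                diff = project_profile(prof, self.diff_axis_)
                if prof.mode == "OE" and self.flip_oe:
                    act, diff = -act, -diff
                neutral = float(np.hypot(act, diff)) <= self.neutral_radius
                rows.append((prof.perturbation, prof.mode, act, diff, neutral, ""))
            except ValueError as exc:
                rows.append((prof.perturbation, prof.mode, np.nan, np.nan, False, str(exc)))
        return pd.DataFrame(
            rows, columns=["perturbation", "mode", "act_score", "diff_score", "neutral", "error"]
        )

    def fit_transform(self, act_axis, diff_axis, profiles):
        return self.fit(act_axis, diff_axis).transform(profiles)


def map_perturbations(
    profiles: list[PerturbationProfile],
    act_axis: AxisSignature,
    diff_axis: AxisSignature,
    flip_oe: bool = True,
    neutral_radius: float = 0.0,
) -> pd.DataFrame:
    """Functional wrapper over :class:`AxisProjector`."""
    return AxisProjector(flip_oe=flip_oe, neutral_radius=neutral_radius).fit_transform(
        act_axis, diff_axis, profiles
    )
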