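"""Readers, writers and validation for the tabular and interval formats.

All genomic intervals are 0-based half-open (BED convention) everywhere in the
package.  Tables are plain TSV with a header row (GMT and BED excepted, per
their format definitions).  Readers validate on load and raise
:class:`SchemaError` with row/column locations; writers are exact inverses of
the readers on valid files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "GuideLibrary",
    "GuideCountTable",
    "PeakSet",
    "GuideCountDiagnostics",
    "count_guides",
    "read_table",
    "read_guide_library",
    "read_sample_metadata",
    "read_bed_peaks",
    "write_bed",
    "write_tsv",
]

FRACTIONS = ("hi", "lo")


class SchemaError(ValueError):
    """An input file violates its declared schema."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GuideLibrary:
    """sgRNA library: one row per guide with its target gene.

    Non-targeting control guides carry ``is_control=True`` and are grouped
    under a single pseudo-gene whose effect is fixed at zero by the screen
    model.
    """

    table: pd.DataFrame  # columns: guide_id, gene, sequence, is_control

    def __post_init__(self) -> None:
        t = self.table
        required = {"guide_id", "gene", "sequence", "is_control"}
        missing = required - set(t.columns)
        if missing:
            raise SchemaError(f"guide library missing columns: {sorted(missing)}")
        if t["guide_id"].duplicated().any():
            dup = t.loc[t["guide_id"].duplicated(), "guide_id"].iloc[0]
            raise SchemaError(f"duplicate guide_id {dup!r}")
        seqs = t["sequence"].astype(str)
        bad = ~seqs.str.fullmatch(r"[ACGT]+")
        if bad.any():
            gid = t.loc[bad, "guide_id"].iloc[0]
            raise SchemaError(f"guide {gid!r}: sequence must be non-empty uppercase A/C/G/T")
        self.table = t.reset_index(drop=True)

    @property
    def guide_ids(self) -> np.ndarray:
        return self.table["guide_id"].to_numpy()

    @property
    def genes(self) -> np.ndarray:
        return self.table["gene"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GuideCountTable:
    """Sorted-fraction sgRNA counts K[s, f, i] with per-column depths d[s, f].

    ``counts`` has shape (n_screens, 2, n_guides); fraction axis order is
    ("hi", "lo").  ``depths`` are library-size factors, by default column total
    over the geometric mean of column totals.
    """

    counts: np.ndarray
    depths: np.ndarray
    screens: list[str]
    library: GuideLibrary

    def __post_init__(self) -> None:
        K = np.asarray(self.counts)
        if K.ndim != 3 or K.shape[1] != 2:
            raise SchemaError("counts must have shape (n_screens, 2, n_guides)")
        if not np.isfinite(K).all() or (K < 0).any():
            raise SchemaError("counts must be finite and >= 0")
        if K.shape[2] != len(self.library):
            raise SchemaError("counts guide axis does not match library size")
        d = np.asarray(self.depths, dtype=float)
        if d.shape != K.shape[:2]:
            raise SchemaError("depths must have shape (n_screens, 2)")
        if (d <= 0).any():
            raise SchemaError("all depths d[s,f] must be > 0")
        self.counts = K
        self.depths = d

    @property
    def n_screens(self) -> int:
        return self.counts.shape[0]

    @property
    def n_guides(self) -> int:
        return self.counts.shape[2]

    @classmethod
    def from_long(
        cls,
        long: pd.DataFrame,
        library: GuideLibrary,
        depths: np.ndarray | None = None,
    ) -> "GuideCountTable":
        """Build from a long table (guide_id, screen, fraction, count)."""
        screens = sorted(long["screen"].unique())
        gidx = {g: i for i, g in enumerate(library.guide_ids)}
        K = np.zeros((len(screens), 2, len(library)), dtype=np.int64)
        seen = np.zeros_like(K, dtype=bool)
        for row in long.itertuples(index=False):
            if row.guide_id not in gidx:
                raise SchemaError(f"count row references unknown guide {row.guide_id!r}")
            s = screens.index(row.screen)
            f = FRACTIONS.index(row.fraction)
            i = gidx[row.guide_id]
            if seen[s, f, i]:
                raise SchemaError(
                    f"duplicate primary key (guide={row.guide_id}, screen={row.screen}, "
                    f"fraction={row.fraction})"
                )
            K[s, f, i] = row.count
            seen[s, f, i] = True
        if depths is None:
            depths = default_depths(K)
        return cls(counts=K, depths=np.asarray(depths, float), screens=screens, library=library)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for s, screen in enumerate(self.screens):
            for f, frac in enumerate(FRACTIONS):
                rows.append(
                    pd.DataFrame(
                        {
                            "guide_id": self.library.guide_ids,
                            "screen": screen,
                            "fraction": frac,
                            "count": self.counts[s, f],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def default_depths(K: np.ndarray) -> np.ndarray:
    """Column total / geometric mean of column totals (overridable upstream)."""
    totals = K.sum(axis=2).astype(float)
    totals = np.where(totals <= 0, np.nan, totals)
    if np.isnan(totals).any():
        raise SchemaError("all-zero count column: depth undefined")
    log_gm = np.mean(np.log(totals))
    return totals / math.exp(log_gm)


@dataclass
class PeakSet:
    """Genomic intervals (chrom, start, end, id, height), half-open 0-based."""

    table: pd.DataFrame  # columns: chrom, start, end, id, height
    time: float | None = None
    replicate: str | None = None
    assay: str | None = None

    def __post_init__(self) -> None:
        t = self.table
        required = {"chrom", "start", "end", "id", "height"}
        missing = required - set(t.columns)
        if missing:
            raise SchemaError(f"peak table missing columns: {sorted(missing)}")
        if (t["start"] >= t["end"]).any():
            bad = t.loc[t["start"] >= t["end"]].iloc[0]
            raise SchemaError(f"peak {bad['id']!r}: start >= end")
        if t["id"].duplicated().any():
            dup = t.loc[t["id"].duplicated(), "id"].iloc[0]
            raise SchemaError(f"duplicate peak id {dup!r}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)


# ---------------------------------------------------------------------------
# guide counting from reads
# ---------------------------------------------------------------------------


@dataclass
class GuideCountDiagnostics:
    total: int = 0
    assigned: int = 0
    unmatched: int = 0
    ambiguous: int = 0

    def check_conserved(self) -> None:
        assert self.assigned + self.unmatched + self.ambiguous == self.total


def count_guides(
    reads: Iterable[str],
    library: GuideLibrary,
    match_offset: int = 0,
    match_length: int | None = None,
) -> tuple[pd.Series, GuideCountDiagnostics]:
    """Exact-match guide counting at a fixed read window.

    Each read is matched by string equality of ``read[offset:offset+L]``
    against the guide sequences truncated to ``L`` (default: full guide
    length; guides of differing lengths each use their own window).  Reads
    matching no guide, or more than one guide, are discarded and tallied.
    Counting is conserved: assigned + unmatched + ambiguous == total reads.
    """
    seqs = library.table["sequence"].astype(str).to_numpy()
    gids = library.guide_ids
    min_len = min(len(s) for s in seqs)
    if match_length is not None and match_length > min_len:
        raise ValueError(f"match_length {match_length} exceeds shortest guide ({min_len} nt)")

    # one lookup dict per distinct window length
    lengths = sorted({match_length if match_length is not None else len(s) for s in seqs})
    tables: dict[int, dict[str, str]] = {L: {} for L in lengths}
    collisions: dict[str, list[str]] = {}
    for gid, seq in zip(gids, seqs):
        L = match_length if match_length is not None else len(seq)
        key = seq[:L]
        if key in tables[L]:
            collisions.setdefault(key, [tables[L][key]]).append(gid)
        else:
            tables[L][key] = gid
    if collisions:
        pairs = "; ".join(f"{k}: {v}" for k, v in sorted(collisions.items()))
        raise ValueError(f"duplicate guide sequences at the chosen window: {pairs}")

    counts = pd.Series(0, index=pd.Index(gids, name="guide_id"), dtype=np.int64)
    diag = GuideCountDiagnostics()
    for read in reads:
        diag.total += 1
        hits = []
        for L in lengths:
            window = read[match_offset : match_offset + L]
            if len(window) == L:
                gid = tables[L].get(window)
                if gid is not None:
                    hits.append(gid)
        if len(hits) == 1:
            counts[hits[0]] += 1
            diag.assigned += 1
        elif not hits:
            diag.unmatched += 1
        else:
            diag.ambiguous += 1
    diag.check_conserved()
    return counts, diag


# ---------------------------------------------------------------------------
# tabular readers
# ---------------------------------------------------------------------------

_SCHEMAS = ("guide_counts", "expression_matrix", "rank_table", "motif_hits", "tss_table", "gmt")


def read_table(path: str | Path, schema: str):
    """Read and validate a typed table.

    Schemas:
      - ``guide_counts``: long TSV (guide_id, screen, fraction, count)
      - ``expression_matrix``: TSV, first column ``gene``, one column per sample
      - ``rank_table``: TSV (gene, r_pos, r_neg), one screen per file
      - ``motif_hits``: TSV (motif, peak_id)
      - ``tss_table``: TSV (gene, chrom, tss_position, strand)
      - ``gmt``: GMT lines (term, description, member genes) -> dict term -> set
    """
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {_SCHEMAS}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema == "gmt":
        return _read_gmt(path)
    df = pd.read_csv(path, sep="\t")
    if schema == "guide_counts":
        _require_cols(df, ["guide_id", "screen", "fraction", "count"], path)
        if df["count"].isna().any():
            r = int(df.index[df["count"].isna()][0])
            raise SchemaError(f"{path}: NaN count at row {r + 2}, column 'count'")
        if (df["count"] < 0).any():
            r = int(df.index[df["count"] < 0][0])
            raise SchemaError(f"{path}: negative count at row {r + 2}, column 'count'")
        bad = ~df["fraction"].isin(FRACTIONS)
        if bad.any():
            r = int(df.index[bad][0])
            raise SchemaError(f"{path}: row {r + 2}: fraction must be one of {FRACTIONS}")
        if df.duplicated(["guide_id", "screen", "fraction"]).any():
            r = int(df.index[df.duplicated(["guide_id", "screen", "fraction"])][0])
            raise SchemaError(f"{path}: duplicate (guide_id, screen, fraction) at row {r + 2}")
        df["count"] = df["count"].astype(np.int64)
        return df
    if schema == "expression_matrix":
        if df.columns[0] != "gene":
            raise SchemaError(f"{path}: first column must be 'gene'")
        if df["gene"].duplicated().any():
            dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
            raise SchemaError(f"{path}: duplicate gene {dup!r}")
        mat = df.set_index("gene")
        vals = mat.to_numpy()
        if np.isnan(vals).any():
            g, s = np.argwhere(np.isnan(vals))[0]
            raise SchemaError(f"{path}: NaN at gene {mat.index[g]!r}, sample {mat.columns[s]!r}")
        if (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise SchemaError(
                f"{path}: negative value at gene {mat.index[g]!r}, sample {mat.columns[s]!r}"
            )
        return mat
    if schema == "rank_table":
        _require_cols(df, ["gene", "r_pos", "r_neg"], path)
        if df["gene"].duplicated().any():
            dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
            raise SchemaError(f"{path}: duplicate gene {dup!r}")
        if (df[["r_pos", "r_neg"]] <= 0).any().any():
            raise SchemaError(f"{path}: ranks must be positive")
        return df
    if schema == "motif_hits":
        _require_cols(df, ["motif", "peak_id"], path)
        return df
    if schema == "tss_table":
        _require_cols(df, ["gene", "chrom", "tss_position", "strand"], path)
        if df["gene"].duplicated().any():
            dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
            raise SchemaError(f"{path}: duplicate gene {dup!r}")
        try:
            df["tss_position"] = df["tss_position"].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: non-integer tss_position") from exc
        return df
    raise AssertionError("unreachable")


def _require_cols(df: pd.DataFrame, cols: list[str], path: Path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _read_gmt(path: Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}: line {ln}: GMT needs term, description, >=1 gene")
            term, _desc, *genes = parts
            if term in out:
                raise SchemaError(f"{path}: line {ln}: duplicate term {term!r}")
            out[term] = set(genes)
    return out


def read_guide_library(path: str | Path) -> GuideLibrary:
    df = pd.read_csv(path, sep="\t")
    _require_cols(df, ["guide_id", "gene", "sequence"], Path(path))
    if "is_control" not in df.columns:
        df["is_control"] = False
    df["is_control"] = df["is_control"].astype(bool)
    return GuideLibrary(df)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Sample sheet for expression matrices: (sample, condition, time, replicate)."""
    df = pd.read_csv(path, sep="\t")
    _require_cols(df, ["sample", "condition", "time", "replicate"], Path(path))
    if df["sample"].duplicated().any():
        dup = df.loc[df["sample"].duplicated(), "sample"].iloc[0]
        raise SchemaError(f"{path}: duplicate sample {dup!r}")
    df["time"] = df["time"].astype(float)
    return df


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------


def read_bed_peaks(path: str | Path, **labels) -> PeakSet:
    """Read BED3+ peaks: chrom, start, end [, name [, score]].

    Missing names are synthesized as ``peak_<line>``; missing scores default
    to 0.0.  Coordinates must be non-negative integers with start < end.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SchemaError(f"{path}: line {ln}: BED needs >=3 columns, got {len(parts)}")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise SchemaError(f"{path}: line {ln}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise SchemaError(f"{path}: line {ln}: require 0 <= start < end")
            name = parts[3] if len(parts) > 3 else f"peak_{ln}"
            height = float(parts[4]) if len(parts) > 4 else 0.0
            rows.append((chrom, start, end, name, height))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id", "height"])
    return PeakSet(df, **labels)


def write_bed(peaks: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in peaks.table.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.id}\t{_fmt_float(r.height)}\n")


def _fmt_float(x: float) -> str:
    # repr round-trips doubles exactly; integers render without exponent
    return repr(float(x))


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Deterministic TSV writer (fixed float repr, LF endings)."""
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
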