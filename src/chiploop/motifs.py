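"""CTCF motif catalogs and candidate loop pairs.

A motif catalog is a :class:`pandas.DataFrame` with one row per motif hit
(columns ``chrom, start, end, strand, score, id``; coordinates 0-based
half-open, ``score`` the -log10 motif p-value).  Candidate pairs are all
same-chromosome motif pairs within a genomic distance cap, annotated with
the sequence features used by the loop model:

``d``
    distance in bp between the two motif centers,
``o``
    orientation category of the strand combination (``convergent``,
    ``forward``, ``reverse`` or ``divergent``),
``s``
    minimum of the two motif scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "ORIENTATIONS",
    "DEFAULT_P_CUTOFF",
    "DEFAULT_MAX_DIST",
    "load_motifs",
    "build_pairs",
    "orientation",
    "motif_center",
    "write_pairs",
]

#: orientation categories for (left_strand, right_strand), left upstream
ORIENTATIONS = ("convergent", "forward", "reverse", "divergent")

_ORIENT_MAP = {
    ("+", "-"): "convergent",
    ("+", "+"): "forward",
    ("-", "-"): "reverse",
    ("-", "+"): "divergent",
}

DEFAULT_P_CUTOFF = 2.5e-6
DEFAULT_MAX_DIST = 1_000_000

CATALOG_COLUMNS = ["chrom", "start", "end", "strand", "score", "id"]


class MotifFileError(ValueError):
    """Raised for malformed motif track files; the message names the line."""


def orientation(left_strand: str, right_strand: str) -> str:
    """Orientation category of a motif pair.

    ``left_strand`` belongs to the genomically upstream motif.  The four
    strand combinations map to (+,-) convergent, (+,+) forward, (-,-)
    reverse and (-,+) divergent.
    """
    try:
        return _ORIENT_MAP[(left_strand, right_strand)]
    except KeyError:
        raise ValueError(
            f"invalid strand combination ({left_strand!r}, {right_strand!r}); "
            "strands must be '+' or '-'"
        ) from None


def motif_center(start, end):
    """Integer motif center, floor((start+end)/2) in 0-based coordinates."""
    return (np.asarray(start) + np.asarray(end)) // 2


def load_motifs(
    path,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    dialect: str = "jaspar",
) -> pd.DataFrame:
    """Load a motif hit track, filter by significance and assign ids.

    Parameters
    ----------
    path
        Tab-separated motif track.  Two dialects are understood:

        ``"jaspar"``
            the JASPAR UCSC-tracks TSV: ``chrom start end name score
            strand`` with 1-based inclusive ``start`` and the score column
            holding ``100 * (-log10 p)`` (converted at parse time);
        ``"bed6"``
            standard BED6 (0-based half-open) whose score column is the
            -log10 p-value directly, with an optional seventh column
            giving the raw p-value (used preferentially when present).
    p_cutoff
        Keep only hits with motif p-value <= ``p_cutoff`` (equivalently
        score >= -log10 p_cutoff).  Default 2.5e-6.
    dialect
        ``"jaspar"`` or ``"bed6"``.

    Returns
    -------
    pandas.DataFrame
        Catalog sorted by (chrom, start), deduplicated on
        (chrom, start, end, strand), with a stable integer ``id`` column.
    """
    if not 0 < p_cutoff <= 1:
        raise ValueError(f"p_cutoff must be in (0, 1], got {p_cutoff}")
    if dialect not in ("jaspar", "bed6"):
        raise ValueError(f"unknown motif-track dialect {dialect!r}")

    raw = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        skip_blank_lines=True,
    )
    if raw.shape[1] < 6:
        raise MotifFileError(
            f"{path}: expected >= 6 tab-separated columns "
            f"(chrom, start, end, name, score, strand), found {raw.shape[1]}"
        )

    chrom = raw.iloc[:, 0].astype(str)
    start = pd.to_numeric(raw.iloc[:, 1], errors="raise").astype(np.int64)
    end = pd.to_numeric(raw.iloc[:, 2], errors="raise").astype(np.int64)
    score_col = pd.to_numeric(raw.iloc[:, 4], errors="coerce")
    strand = raw.iloc[:, 5].astype(str)

    bad_strand = ~strand.isin(["+", "-"])
    if bad_strand.any():
        i = int(np.flatnonzero(bad_strand.to_numpy())[0])
        raise MotifFileError(
            f"{path}: line {i + 1}: unknown strand symbol {strand.iloc[i]!r} "
            "(expected '+' or '-')"
        )
    if score_col.isna().any():
        i = int(np.flatnonzero(score_col.isna().to_numpy())[0])
        raise MotifFileError(
            f"{path}: line {i + 1}: missing or non-numeric score column"
        )

    if dialect == "jaspar":
        start = start - 1  # 1-based inclusive -> 0-based half-open
        score = score_col.to_numpy(dtype=float) / 100.0
    else:
        score = score_col.to_numpy(dtype=float)
        if raw.shape[1] >= 7:
            pvals = pd.to_numeric(raw.iloc[:, 6], errors="coerce")
            has_p = pvals.notna().to_numpy()
            with np.errstate(divide="ignore"):
                score = np.where(has_p, -np.log10(pvals.to_numpy(dtype=float)), score)

    cat = pd.DataFrame(
        {"chrom": chrom, "start": start, "end": end, "strand": strand, "score": score}
    )
    if (cat["start"] >= cat["end"]).any():
        i = int(np.flatnonzero((cat["start"] >= cat["end"]).to_numpy())[0])
        raise MotifFileError(f"{path}: line {i + 1}: start >= end")

    min_score = -np.log10(p_cutoff)
    cat = cat[cat["score"] >= min_score]
    cat = cat.drop_duplicates(subset=["chrom", "start", "end", "strand"])
    cat = cat.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    cat = cat.reset_index(drop=True)
    cat["id"] = np.arange(len(cat), dtype=np.int64)
    return cat


def build_pairs(catalog: pd.DataFrame, max_dist: int = DEFAULT_MAX_DIST) -> pd.DataFrame:
    """Enumerate candidate motif pairs within ``max_dist``.

    Every unordered pair of distinct same-chromosome motifs whose center
    distance is <= ``max_dist`` appears exactly once, the left motif being
    the genomically upstream one.  Columns: the two motif ids, intervals
    and strands, plus the features ``d``, ``o`` and ``s``.
    """
    if max_dist <= 0:
        raise ValueError(f"max_dist must be positive, got {max_dist}")

    chunks = []
    for _, grp in catalog.groupby("chrom", sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        centers = motif_center(grp["start"].to_numpy(), grp["end"].to_numpy())
        order = np.argsort(centers, kind="stable")
        grp = grp.iloc[order]
        centers = centers[order]
        n = len(grp)
        if n < 2:
            continue
        # two-pointer window over center-sorted motifs
        hi = np.searchsorted(centers, centers + max_dist, side="right")
        left_idx = np.repeat(np.arange(n), hi - np.arange(n) - 1)
        right_idx = np.concatenate(
            [np.arange(i + 1, h) for i, h in enumerate(hi) if h > i + 1]
        ) if len(left_idx) else np.empty(0, dtype=np.int64)

        lstr = grp["strand"].to_numpy()[left_idx]
        rstr = grp["strand"].to_numpy()[right_idx]
        o = np.array([_ORIENT_MAP[(a, b)] for a, b in zip(lstr, rstr)], dtype=object)
        chunks.append(
            pd.DataFrame(
                {
                    "chrom": grp["chrom"].to_numpy()[left_idx],
                    "left_id": grp["id"].to_numpy()[left_idx],
                    "right_id": grp["id"].to_numpy()[right_idx],
                    "left_start": grp["start"].to_numpy()[left_idx],
                    "left_end": grp["end"].to_numpy()[left_idx],
                    "left_strand": lstr,
                    "right_start": grp["start"].to_numpy()[right_idx],
                    "right_end": grp["end"].to_numpy()[right_idx],
                    "right_strand": rstr,
                    "d": centers[right_idx] - centers[left_idx],
                    "o": o,
                    "s": np.minimum(
                        grp["score"].to_numpy()[left_idx],
                        grp["score"].to_numpy()[right_idx],
                    ),
                }
            )
        )
    if not chunks:
        return pd.DataFrame(
            columns=[
                "chrom", "left_id", "right_id", "left_start", "left_end",
                "left_strand", "right_start", "right_end", "right_strand",
                "d", "o", "s",
            ]
        )
    pairs = pd.concat(chunks, ignore_index=True)
    pairs = pairs.sort_values(
        ["chrom", "left_start", "right_start", "left_end", "right_end"],
        kind="mergesort",
    ).reset_index(drop=True)
    return pairs


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """Write candidate (or annotated) pairs as TSV."""
    pairs.to_csv(path, sep="\t", index=False)
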