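"""Label candidate motif pairs with experimentally measured loops.

A motif pair is a true loop when at least one measured interaction exists
whose one anchor overlaps (by >= 1 bp) the left motif interval and whose
other anchor overlaps the right motif interval — under either assignment
of anchors to motifs, but the two anchors must hit the two distinct
motifs.  Truth interactions come from paired-interval files (BEDPE from
Hi-C loop calls, ChIA-PET interaction lists); several sources may be
combined by union (default) or intersection.

Genome-scale labeling uses a per-chromosome interval tree over loop
anchors; its output is contractually identical to the brute-force
pair-by-loop overlap scan, which the test suite checks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = ["load_loops", "label_pairs", "label_pairs_bruteforce", "label_stats"]

LOOP_COLUMNS = [
    "chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b", "source",
]


def load_loops(path, source: str = "", one_based: bool = False) -> pd.DataFrame:
    """Parse a BEDPE-like file of measured interactions.

    Reads the first six columns (chromA, startA, endA, chromB, startB,
    endB); further columns are ignored.  Malformed rows are skipped with
    a logged count.  ``one_based`` converts 1-based inclusive starts to
    the internal 0-based half-open convention.
    """
    raw = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        skip_blank_lines=True,
    )
    if raw.shape[1] < 6:
        raise ValueError(f"{path}: BEDPE needs >= 6 columns, found {raw.shape[1]}")
    coords = raw.iloc[:, [1, 2, 4, 5]].apply(pd.to_numeric, errors="coerce")
    ok = coords.notna().all(axis=1)
    ok &= (coords.iloc[:, 0] < coords.iloc[:, 1]) & (coords.iloc[:, 2] < coords.iloc[:, 3])
    n_bad = int((~ok).sum())
    if n_bad:
        log.warning("%s: skipped %d malformed loop rows", path, n_bad)
    raw = raw[ok]
    coords = coords[ok].astype(np.int64)
    loops = pd.DataFrame(
        {
            "chrom_a": raw.iloc[:, 0].astype(str).to_numpy(),
            "start_a": coords.iloc[:, 0].to_numpy(),
            "end_a": coords.iloc[:, 1].to_numpy(),
            "chrom_b": raw.iloc[:, 3].astype(str).to_numpy(),
            "start_b": coords.iloc[:, 2].to_numpy(),
            "end_b": coords.iloc[:, 3].to_numpy(),
            "source": source or str(path),
        }
    )
    if one_based:
        loops["start_a"] -= 1
        loops["start_b"] -= 1
    return loops.reset_index(drop=True)


def label_pairs(
    pairs: pd.DataFrame,
    loops: pd.DataFrame | list[pd.DataFrame],
    mode: str = "union",
) -> pd.DataFrame:
    """Assign a boolean ``label`` column to candidate pairs.

    Parameters
    ----------
    pairs
        Candidate pairs with motif intervals (``left_start``/``left_end``,
        ``right_start``/``right_end``).  The motif hit span itself is the
        overlap target, not the profile window around it.
    loops
        One loop table or a list of them.  With ``mode="union"`` a pair
        is positive if any source supports it; ``mode="intersection"``
        requires support from every source (the truth-set sensitivity
        analysis).  Inter-chromosomal loop records never label any pair.

    Returns
    -------
    pandas.DataFrame
        Copy of ``pairs`` with ``label`` (bool) and ``label_sources``
        (comma-joined supporting source tags, union mode only).
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown labeling mode {mode!r}")
    loop_list = loops if isinstance(loops, list) else [loops]
    if mode == "union":
        merged = pd.concat(loop_list, ignore_index=True) if loop_list else pd.DataFrame(columns=LOOP_COLUMNS)
        label, sources = _label_one_set(pairs, merged, want_sources=True)
        out = pairs.copy()
        out["label"] = label
        out["label_sources"] = sources
        return out
    label = np.ones(len(pairs), dtype=bool)
    for lset in loop_list:
        l, _ = _label_one_set(pairs, lset, want_sources=False)
        label &= l
    out = pairs.copy()
    out["label"] = label
    out["label_sources"] = np.where(label, "intersection", "")
    return out


def _label_one_set(pairs: pd.DataFrame, loops: pd.DataFrame, want_sources: bool):
    if len(loops) == 0:
        return np.zeros(len(pairs), dtype=bool), np.full(len(pairs), "", dtype=object)
    intra = loops[loops["chrom_a"] == loops["chrom_b"]].reset_index(drop=True)
    trees: dict[str, IntervalTree] = {}
    for row, rec in enumerate(intra.itertuples(index=False)):
        tree = trees.setdefault(rec.chrom_a, IntervalTree())
        tree.addi(rec.start_a, rec.end_a, (row, 0))
        tree.addi(rec.start_b, rec.end_b, (row, 1))

    label = np.zeros(len(pairs), dtype=bool)
    sources = np.full(len(pairs), "", dtype=object)
    src_col = intra["source"].to_numpy() if len(intra) else np.array([], dtype=object)
    for k, rec in enumerate(pairs.itertuples(index=False)):
        tree = trees.get(rec.chrom)
        if tree is None:
            continue
        left_hits: dict[int, set[int]] = {}
        for iv in tree.overlap(rec.left_start, rec.left_end):
            row, side = iv.data
            left_hits.setdefault(row, set()).add(side)
        if not left_hits:
            continue
        supporting: set[int] = set()
        for iv in tree.overlap(rec.right_start, rec.right_end):
            row, side = iv.data
            sides = left_hits.get(row)
            if sides is None:
                continue
            # the two anchors must hit the two distinct motifs: the left
            # motif must overlap the *other* anchor of this loop (a loop
            # whose both anchors cover both motifs satisfies this too)
            if (1 - side) in sides:
                supporting.add(row)
        if supporting:
            label[k] = True
            if want_sources:
                sources[k] = ",".join(sorted({str(src_col[r]) for r in supporting}))
    return label, sources


def label_pairs_bruteforce(pairs: pd.DataFrame, loops: pd.DataFrame) -> np.ndarray:
    """O(pairs x loops) reference labeling; the tree index must match it."""

    def ovl(a0, a1, b0, b1):
        return max(a0, b0) < min(a1, b1)

    intra = loops[loops["chrom_a"] == loops["chrom_b"]]
    label = np.zeros(len(pairs), dtype=bool)
    for k, p in enumerate(pairs.itertuples(index=False)):
        for l in intra.itertuples(index=False):
            if l.chrom_a != p.chrom:
                continue
            la = ovl(l.start_a, l.end_a, p.left_start, p.left_end)
            ra = ovl(l.start_a, l.end_a, p.right_start, p.right_end)
            lb = ovl(l.start_b, l.end_b, p.left_start, p.left_end)
            rb = ovl(l.start_b, l.end_b, p.right_start, p.right_end)
            if (la and rb) or (lb and ra):
                label[k] = True
                break
    return label


def label_stats(labeled: pd.DataFrame) -> dict:
    """Summary of a labeled pair set.

    Returns totals, positive count and fraction, and the orientation
    composition (percent per category) within the looping and
    non-looping strata.
    """
    n = len(labeled)
    pos = int(labeled["label"].sum()) if n else 0
    stats = {
        "n_pairs": n,
        "n_positive": pos,
        "positive_rate": (pos / n) if n else 0.0,
        "orientation_pct": {},
    }
    from .motifs import ORIENTATIONS

    for stratum, sel in (("looping", labeled["label"]), ("non_looping", ~labeled["label"])):
        sub = labeled[sel] if n else labeled
        m = len(sub)
        stats["orientation_pct"][stratum] = {
            o: (100.0 * (sub["o"] == o).sum() / m) if m else float("nan")
            for o in ORIENTATIONS
        }
    return stats
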