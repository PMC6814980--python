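"""Strand-oriented coverage profiles around motif centers.

The loop predictor quantifies anchor similarity as the Pearson correlation
of per-base coverage vectors extracted around the two motifs of a pair.
The window is half-open, ``[center - half_window, center + half_window)``,
so a half-window of 500 bp yields a 1000-long vector with no privileged
center base.  Profiles of minus-strand motifs are reversed: CTCF motifs
are assumed to be symmetrically aligned when cooperating at loop anchors,
so reversal puts both anchors of a pair into a common motif-relative
frame.  Missing track values read as 0 (read-coverage semantics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pyBigWig

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_HALF_WINDOW",
    "CoverageProfile",
    "bedgraph_to_bigwig",
    "extract_profile",
    "extract_profile_matrix",
    "pair_correlation",
    "pair_correlations",
    "across_track_correlation",
    "anchor_signal",
]

DEFAULT_HALF_WINDOW = 500


def bedgraph_to_bigwig(bedgraph_path, bigwig_path, chrom_sizes: dict) -> str:
    """Convert a bedGraph text track to bigWig.

    ``chrom_sizes`` maps chromosome name -> length.  Intervals must be
    sorted within each chromosome (bedGraph convention); uncovered bases
    read as 0 downstream.
    """
    import csv

    entries: dict[str, list] = {c: [] for c in chrom_sizes}
    with open(bedgraph_path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith(("#", "track")):
                continue
            chrom, start, end, value = row[0], int(row[1]), int(row[2]), float(row[3])
            if chrom not in entries:
                raise ValueError(f"{bedgraph_path}: unknown chromosome {chrom!r}")
            entries[chrom].append((start, end, value))
    bw = pyBigWig.open(str(bigwig_path), "w")
    try:
        bw.addHeader(sorted(chrom_sizes.items()))
        for chrom in sorted(chrom_sizes):
            if entries[chrom]:
                starts, ends, values = map(list, zip(*entries[chrom]))
                bw.addEntries([chrom] * len(starts), starts, ends=ends,
                              values=values)
    finally:
        bw.close()
    return str(bigwig_path)


@dataclass
class CoverageProfile:
    """Per-base signal around one motif, oriented to the motif strand."""

    motif_id: int
    track_name: str
    values: np.ndarray = field(repr=False)
    oriented: bool = True
    complete: bool = True


def _read_window(bw, chrom: str, start: int, end: int):
    """Per-base values over [start, end); returns (values, complete)."""
    chrom_len = bw.chroms(chrom)
    if chrom_len is None:
        return np.zeros(0), False
    if start < 0 or end > chrom_len:
        lo, hi = max(start, 0), min(end, int(chrom_len))
        vals = np.zeros(end - start)
        if hi > lo:
            seg = np.asarray(bw.values(chrom, lo, hi, numpy=True), dtype=float)
            vals[lo - start : hi - start] = np.nan_to_num(seg, nan=0.0)
        return vals, False
    vals = np.asarray(bw.values(chrom, start, end, numpy=True), dtype=float)
    return np.nan_to_num(vals, nan=0.0), True


def extract_profile(
    track,
    site,
    half_window: int = DEFAULT_HALF_WINDOW,
    track_name: str = "",
    bin_size: int = 1,
) -> CoverageProfile:
    """Extract the oriented coverage vector around one motif site.

    Parameters
    ----------
    track
        An open :mod:`pyBigWig` handle (or a path to a bigWig file).
    site
        Mapping with ``chrom``, ``start``, ``end``, ``strand``, ``id``
        (a catalog row works directly).
    half_window
        Bases on each side of the motif center; the window is
        ``[center - half_window, center + half_window)``.
    bin_size
        Optional averaging of consecutive bases into bins (must divide
        ``2 * half_window``); default 1 keeps per-base resolution.

    Notes
    -----
    A window crossing a chromosome boundary, or a chromosome absent from
    the track, yields ``complete=False`` (absent chromosome additionally
    logs a warning and returns an empty vector).  Minus-strand vectors
    are reversed so both strands share a motif-relative frame.
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    own = isinstance(track, str)
    bw = pyBigWig.open(track) if own else track
    try:
        center = (int(site["start"]) + int(site["end"])) // 2
        vals, complete = _read_window(
            bw, str(site["chrom"]), center - half_window, center + half_window
        )
        if vals.size == 0 and not complete:
            log.warning(
                "chromosome %s absent from track %s; motif %s profile empty",
                site["chrom"], track_name or track, site.get("id", "?"),
            )
    finally:
        if own:
            bw.close()
    if site["strand"] == "-":
        vals = vals[::-1].copy()
    if bin_size > 1 and vals.size:
        if vals.size % bin_size:
            raise ValueError("bin_size must divide the window size")
        vals = vals.reshape(-1, bin_size).mean(axis=1)
    return CoverageProfile(
        motif_id=int(site.get("id", -1)),
        track_name=track_name,
        values=vals,
        oriented=True,
        complete=complete,
    )


def extract_profile_matrix(
    track_path: str,
    catalog,
    half_window: int = DEFAULT_HALF_WINDOW,
    bin_size: int = 1,
):
    """Oriented profiles for a whole catalog as an (n_motifs, W) matrix.

    Returns ``(matrix, complete)`` where ``complete`` is a boolean vector;
    incomplete rows are zero-filled where the window left the chromosome.
    Row order follows the catalog.
    """
    n = len(catalog)
    w = 2 * half_window // bin_size
    mat = np.zeros((n, w))
    complete = np.zeros(n, dtype=bool)
    with pyBigWig.open(track_path) as bw:
        for k, (_, site) in enumerate(catalog.iterrows()):
            prof = extract_profile(bw, site, half_window, bin_size=bin_size)
            if prof.values.size == w:
                mat[k] = prof.values
            complete[k] = prof.complete
    return mat, complete


def pair_correlation(profile_a, profile_b) -> float:
    """Pearson correlation of two oriented profiles, or NaN when undefined.

    Undefined when either profile is incomplete or has zero variance.
    """
    a, b = _as_profile_pair(profile_a, profile_b)
    if a is None:
        return float("nan")
    if a.size != b.size:
        raise ValueError(f"profile length mismatch: {a.size} vs {b.size}")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    za = (a - a.mean()) / a.std()
    zb = (b - b.mean()) / b.std()
    return float(za @ zb / a.size)


def _as_profile_pair(pa, pb):
    for p in (pa, pb):
        if isinstance(p, CoverageProfile) and not p.complete:
            return None, None
    a = pa.values if isinstance(pa, CoverageProfile) else np.asarray(pa, dtype=float)
    b = pb.values if isinstance(pb, CoverageProfile) else np.asarray(pb, dtype=float)
    return a, b


def pair_correlations(matrix, complete, left_idx, right_idx):
    """Vectorized per-pair Pearson correlations from a profile matrix.

    ``left_idx``/``right_idx`` are row indices into ``matrix``.  Pairs with
    an incomplete or zero-variance member get NaN.
    """
    matrix = np.asarray(matrix, dtype=float)
    sd = matrix.std(axis=1)
    ok = complete & (sd > 0)
    z = np.zeros_like(matrix)
    nz = sd > 0
    z[nz] = (matrix[nz] - matrix[nz].mean(axis=1, keepdims=True)) / sd[nz, None]
    r = np.einsum("ij,ij->i", z[left_idx], z[right_idx]) / matrix.shape[1]
    r[~(ok[left_idx] & ok[right_idx])] = np.nan
    return r


def across_track_correlation(profiles_a, profiles_b) -> float:
    """Single correlation across several tracks for one motif pair.

    ``profiles_a``/``profiles_b`` map track name -> profile for the left
    and right anchor.  Each track's oriented vector is standardized to
    mean 0 / variance 1, the segments are concatenated in a fixed
    (sorted) track order, and one Pearson correlation is returned.
    Tracks with zero variance on either side make the result NaN.
    """
    if set(profiles_a) != set(profiles_b):
        raise ValueError(
            f"track sets differ: {sorted(profiles_a)} vs {sorted(profiles_b)}"
        )
    segs_a, segs_b = [], []
    for name in sorted(profiles_a):
        a, b = _as_profile_pair(profiles_a[name], profiles_b[name])
        if a is None:
            return float("nan")
        if a.size != b.size:
            raise ValueError(f"profile length mismatch on track {name!r}")
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        segs_a.append((a - a.mean()) / a.std())
        segs_b.append((b - b.mean()) / b.std())
    return pair_correlation(np.concatenate(segs_a), np.concatenate(segs_b))


def anchor_signal(profile) -> float:
    """Total signal in the window; NaN for an incomplete profile.

    Used as the per-anchor feature of the signal-strength baseline model
    that replaces profile correlation with raw anchor coverage.
    """
    if isinstance(profile, CoverageProfile):
        if not profile.complete:
            return float("nan")
        return float(profile.values.sum())
    return float(np.asarray(profile, dtype=float).sum())
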