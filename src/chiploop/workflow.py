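"""End-to-end steps tying catalogs, tracks, labels and the model together.

These are the functions the command-line interface wraps: annotate
candidate pairs with per-track anchor correlations, assemble the feature
table, and run train / predict / evaluate round trips on files.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import labeling as _labeling
from . import model as _model
from . import motifs as _motifs
from . import profiles as _profiles

__all__ = ["annotate_correlations", "annotate_anchor_signals", "candidate_pairs"]


def candidate_pairs(motif_path, p_cutoff=_motifs.DEFAULT_P_CUTOFF,
                    max_dist=_motifs.DEFAULT_MAX_DIST, dialect="jaspar"):
    """Load a motif track and enumerate candidate pairs."""
    catalog = _motifs.load_motifs(motif_path, p_cutoff, dialect)
    return catalog, _motifs.build_pairs(catalog, max_dist)


def annotate_correlations(
    pairs: pd.DataFrame,
    catalog: pd.DataFrame,
    tracks: dict[str, str],
    half_window: int = _profiles.DEFAULT_HALF_WINDOW,
    bin_size: int = 1,
    across: bool = False,
) -> pd.DataFrame:
    """Add one ``r_<track>`` column per coverage track to a pair table.

    Profiles are extracted once per motif and correlated per pair;
    undefined correlations (incomplete window, zero variance, absent
    chromosome) are left as NaN for the model layer to impute.  With
    ``across=True`` an additional ``r_across`` column holds the single
    correlation of the per-track-standardized concatenated profiles.
    """
    id_to_row = pd.Series(np.arange(len(catalog)), index=catalog["id"].to_numpy())
    li = id_to_row[pairs["left_id"].to_numpy()].to_numpy()
    ri = id_to_row[pairs["right_id"].to_numpy()].to_numpy()

    out = pairs.copy()
    mats, completes = [], []
    for name, path in tracks.items():
        mat, complete = _profiles.extract_profile_matrix(
            path, catalog, half_window, bin_size
        )
        out[f"r_{name}"] = _profiles.pair_correlations(mat, complete, li, ri)
        mats.append(mat)
        completes.append(complete)

    if across:
        zs = []
        ok_all = np.logical_and.reduce(completes)
        for mat in mats:
            sd = mat.std(axis=1)
            ok_all = ok_all & (sd > 0)
            z = np.zeros_like(mat)
            nz = sd > 0
            z[nz] = (mat[nz] - mat[nz].mean(axis=1, keepdims=True)) / sd[nz, None]
            zs.append(z)
        concat = np.hstack(zs)
        out["r_across"] = _profiles.pair_correlations(concat, ok_all, li, ri)
    return out


def annotate_anchor_signals(
    pairs: pd.DataFrame,
    catalog: pd.DataFrame,
    tracks: dict[str, str],
    half_window: int = _profiles.DEFAULT_HALF_WINDOW,
) -> pd.DataFrame:
    """Add per-anchor total-signal columns (the signal-strength baseline).

    For each track, ``sig_<track>_left`` and ``sig_<track>_right`` hold
    the summed coverage in the anchor windows; incomplete windows give
    NaN.  These replace the correlation feature in the baseline model
    that asks whether anchor similarity (not mere signal strength)
    carries the loop information.
    """
    id_to_row = pd.Series(np.arange(len(catalog)), index=catalog["id"].to_numpy())
    li = id_to_row[pairs["left_id"].to_numpy()].to_numpy()
    ri = id_to_row[pairs["right_id"].to_numpy()].to_numpy()
    out = pairs.copy()
    for name, path in tracks.items():
        mat, complete = _profiles.extract_profile_matrix(path, catalog, half_window)
        sums = mat.sum(axis=1)
        sums = np.where(complete, sums, np.nan)
        out[f"sig_{name}_left"] = sums[li]
        out[f"sig_{name}_right"] = sums[ri]
    return out


def feature_columns(pairs: pd.DataFrame, kind: str = "r") -> list[str]:
    """Extra model columns of a pair table (``r_*`` or ``sig_*``)."""
    prefix = {"r": "r_", "sig": "sig_"}[kind]
    return [c for c in pairs.columns if c.startswith(prefix)]


def signal_design_matrix(rows: pd.DataFrame, sig_columns: list[str] | None = None):
    """Design matrix of the signal-strength baseline model.

    Sequence features as usual, but the per-anchor total signals replace
    the correlation terms; NaN signals are imputed as 0.
    """
    if sig_columns is None:
        sig_columns = feature_columns(rows, "sig")
    X, names, imputed = _model.design_matrix(rows, r_columns=[])
    extra = []
    for c in sig_columns:
        v = rows[c].to_numpy(dtype=float)
        extra.append(np.nan_to_num(v, nan=0.0))
    if extra:
        X = np.column_stack([X] + extra)
        names = tuple(list(names) + sig_columns)
    return X, names, imputed
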