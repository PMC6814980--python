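"""The loop-prediction logistic regression.

The interaction probability p of a CTCF motif pair is modeled as

    ln(p / (1 - p)) = b0 + b1*d + b2*o + b3*s + b4*r

with d the center distance in bp, o the orientation category (dummy-coded
against the *convergent* reference level, the category most associated
with loops), s the minimum -log10 motif p-value, and one correlation term
r per coverage track (missing correlations imputed as 0, i.e. absence of
evidence of anchor similarity, with an imputation flag kept per pair).

Coefficients are maximum-likelihood estimates from plain (unregularized)
binomial regression, fitted by iteratively reweighted least squares with
a fixed convergence tolerance so fits are deterministic and reproducible
across implementations.  A fitted model carries an f1-optimal probability
cutoff for binary calls; models fitted to different tracks but sharing a
feature manifest can be averaged coefficient-wise into a default model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LoopModel",
    "FitDiagnostics",
    "SeparationError",
    "design_matrix",
    "fit",
    "fit_pairs",
    "predict",
    "predict_pairs",
    "average_models",
    "select_cutoff",
    "save_model",
    "load_model",
]

#: dummy contrasts for orientation; convergent is the reference level
ORIENTATION_CONTRASTS = ("forward", "reverse", "divergent")

DEFAULT_CUTOFF = 0.15  # f1-optimal region reported for well-performing tracks

IRLS_TOL = 1e-8
IRLS_MAX_ITER = 100


class SeparationError(RuntimeError):
    """Logistic MLE does not exist or IRLS failed to converge.

    Carries the last iterate and a diagnostic message.
    """

    def __init__(self, message: str, last_beta: np.ndarray | None = None):
        super().__init__(message)
        self.last_beta = last_beta


@dataclass
class FitDiagnostics:
    n_iter: int
    converged: bool
    deviance: float
    std_errors: np.ndarray


@dataclass
class LoopModel:
    """Fitted (or averaged) loop model: coefficients + decision cutoff."""

    features: tuple[str, ...]
    beta: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    provenance: str = "trained"
    diagnostics: FitDiagnostics | None = field(default=None, compare=False)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.features),):
            raise ValueError(
                f"{len(self.features)} features but {self.beta.size} coefficients"
            )
        if not 0 < self.cutoff < 1:
            raise ValueError(f"cutoff must be in (0,1), got {self.cutoff}")


def design_matrix(
    rows: pd.DataFrame,
    r_columns: list[str] | None = None,
    log_dist: bool = False,
):
    """Build the model matrix (with intercept) from annotated pairs.

    Parameters
    ----------
    rows
        Pairs annotated with ``d``, ``o``, ``s`` and zero or more
        correlation columns.
    r_columns
        Correlation columns to include (default: every column starting
        with ``"r_"``, in frame order).  NaN correlations are imputed as
        0; the returned frame of imputation flags records which.
    log_dist
        Replace d by log10(d) (off by default; the model uses raw bp).

    Returns
    -------
    X : ndarray of shape (n, k)
    names : tuple of feature names (the model manifest)
    imputed : DataFrame of boolean imputation flags, one column per r term
    """
    if r_columns is None:
        r_columns = [c for c in rows.columns if c.startswith("r_")]
    n = len(rows)
    cols = [np.ones(n)]
    names = ["intercept"]

    d = rows["d"].to_numpy(dtype=float)
    if log_dist:
        d = np.log10(np.maximum(d, 1.0))
    cols.append(d)
    names.append("log10_d" if log_dist else "d")

    o = rows["o"].to_numpy()
    for level in ORIENTATION_CONTRASTS:
        cols.append((o == level).astype(float))
        names.append(f"o_{level}")

    cols.append(rows["s"].to_numpy(dtype=float))
    names.append("s")

    imputed = {}
    for rc in r_columns:
        r = rows[rc].to_numpy(dtype=float)
        imputed[rc] = np.isnan(r)
        cols.append(np.nan_to_num(r, nan=0.0))
        names.append(rc)

    return np.column_stack(cols), tuple(names), pd.DataFrame(imputed, index=rows.index)


def fit(
    X: np.ndarray,
    y: np.ndarray,
    features: tuple[str, ...],
    cutoff: float = DEFAULT_CUTOFF,
    tol: float = IRLS_TOL,
    max_iter: int = IRLS_MAX_ITER,
) -> LoopModel:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Newton/IRLS from beta = 0; converged when max |delta beta| < ``tol``.
    Deterministic given the data.  Raises :class:`SeparationError` when the
    labels are single-class, the iteration diverges (complete separation)
    or fails to converge; the exception carries the last iterate.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValueError("X must be (n, k) and y length n")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    npos = int(y.sum())
    if npos == 0 or npos == len(y):
        raise SeparationError("labels are single-class; no MLE exists")

    beta = np.zeros(X.shape[1])
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = -2.0 * float(np.sum(np.where(y == 1, np.log(p), np.log1p(-p))))
        if dev < 1e-8:
            # perfect fit: the likelihood is unbounded, no finite MLE
            raise SeparationError(
                f"complete separation detected at iteration {it} (deviance ~ 0)",
                beta,
            )
        w = p * (1.0 - p)
        xtw = X.T * w
        try:
            delta = np.linalg.solve(xtw @ X, X.T @ (y - p))
        except np.linalg.LinAlgError as e:
            raise SeparationError(
                f"singular information matrix at iteration {it} "
                "(complete separation or collinear features)", beta
            ) from e
        beta = beta + delta
        if not np.isfinite(beta).all():
            raise SeparationError(
                f"divergent coefficients at iteration {it}", beta
            )
        if np.max(np.abs(delta)) < tol:
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            with np.errstate(divide="ignore", invalid="ignore"):
                ll = np.where(y == 1, np.log(p), np.log1p(-p))
            w = p * (1.0 - p)
            cov = np.linalg.inv((X.T * w) @ X)
            return LoopModel(
                features=tuple(features),
                beta=beta,
                cutoff=cutoff,
                provenance="trained",
                diagnostics=FitDiagnostics(
                    n_iter=it,
                    converged=True,
                    deviance=float(-2.0 * np.sum(ll)),
                    std_errors=np.sqrt(np.diag(cov)),
                ),
            )
    raise SeparationError(
        f"IRLS did not converge in {max_iter} iterations "
        "(possible quasi-separation)", beta
    )


def fit_pairs(
    rows: pd.DataFrame,
    r_columns: list[str] | None = None,
    log_dist: bool = False,
    cutoff: float = DEFAULT_CUTOFF,
) -> LoopModel:
    """Convenience wrapper: design matrix + fit from a labeled pair frame."""
    X, names, _ = design_matrix(rows, r_columns, log_dist)
    return fit(X, rows["label"].to_numpy(dtype=float), names, cutoff)


def predict(model: LoopModel, X: np.ndarray, features: tuple[str, ...] | None = None):
    """Interaction probabilities p = logistic(X beta) for rows of X.

    ``features``, when given, is checked against the model manifest; a
    mismatch is a hard error rather than a silently wrong prediction.
    """
    if features is not None and tuple(features) != tuple(model.features):
        raise ValueError(
            f"feature manifest mismatch: model {model.features}, data {tuple(features)}"
        )
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.beta.size:
        raise ValueError(
            f"feature manifest mismatch: model has {model.beta.size} terms, "
            f"data has {X.shape[1]} columns"
        )
    return 1.0 / (1.0 + np.exp(-(X @ model.beta)))


def predict_pairs(
    model: LoopModel,
    rows: pd.DataFrame,
    r_columns: list[str] | None = None,
    log_dist: bool = False,
) -> pd.DataFrame:
    """Score a pair frame: adds ``p`` (probability) and ``call`` columns."""
    X, names, _ = design_matrix(rows, r_columns, log_dist)
    p = predict(model, X, names)
    out = rows.copy()
    out["p"] = p
    out["call"] = p >= model.cutoff
    return out


def average_models(models: list[LoopModel]) -> LoopModel:
    """Coefficient-wise mean of models sharing a feature manifest.

    The averaged model's cutoff is the mean member cutoff.  This is how a
    track-agnostic default model is built from many per-track fits.
    """
    if not models:
        raise ValueError("no models to average")
    manifest = models[0].features
    for m in models[1:]:
        if m.features != manifest:
            raise ValueError(
                f"feature manifest mismatch: {manifest} vs {m.features}"
            )
    beta = np.mean([m.beta for m in models], axis=0)
    cutoff = float(np.mean([m.cutoff for m in models]))
    return LoopModel(manifest, beta, cutoff, provenance="averaged")


def select_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """f1-maximizing probability threshold over all distinct scores.

    f1 is the harmonic mean of precision and recall of the binary call
    (score >= threshold), evaluated at every distinct score; ties on f1
    resolve to the smallest threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("cutoff selection needs both classes")
    thresholds = np.unique(scores)  # ascending
    # descending sort once; cumulative TP/FP above each threshold
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    tp_cum = np.cumsum(labels[order])
    npos = int(labels.sum())
    # index of last element >= t in descending order
    idx = len(s_sorted) - np.searchsorted(s_sorted[::-1], thresholds, side="left")
    tp = tp_cum[idx - 1]
    called = idx
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = tp / called
        rec = tp / npos
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    best = np.flatnonzero(f1 == f1.max())[0]  # smallest threshold on ties
    return float(thresholds[best])


# -- serialization: flat key=value text, bit-exact round trip --------------

def save_model(model: LoopModel, path) -> None:
    """Write a model as flat ``key=value`` text (floats via repr, so the
    round trip through :func:`load_model` is bit-exact)."""
    lines = [
        "format=chiploop-model-v1",
        f"provenance={model.provenance}",
        f"cutoff={float(model.cutoff)!r}",
        f"features={','.join(model.features)}",
    ]
    for name, b in zip(model.features, model.beta):
        lines.append(f"coef.{name}={float(b)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> LoopModel:
    """Read a model written by :func:`save_model`."""
    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    if kv.get("format") != "chiploop-model-v1":
        raise ValueError(f"{path}: not a chiploop model file")
    features = tuple(kv["features"].split(","))
    beta = np.array([float(kv[f"coef.{n}"]) for n in features])
    return LoopModel(
        features=features,
        beta=beta,
        cutoff=float(kv["cutoff"]),
        provenance=kv.get("provenance", "trained"),
    )
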