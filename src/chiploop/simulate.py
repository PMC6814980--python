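"""Synthetic motif catalogs, truth loops and loop-coupled coverage tracks.

The generator produces a genome in miniature with the statistical
structure the loop predictor assumes, so the whole pipeline is testable
without any external data:

* CTCF-like motifs placed uniformly without overlap on a few synthetic
  chromosomes (named ``chrS1, chrS2, ...`` so they can never be confused
  with a real genome), with random strands and -log10 p-value scores;
* true loops drawn per candidate pair with probability proportional to
  ``exp(-d / decay_scale)`` times a convergent-orientation odds
  multiplier, normalized so the expected positive rate hits a configured
  target — reproducing the distance decay and convergence bias of real
  loop data;
* a coverage track in which directly bound motifs carry a sharp
  Gaussian-shaped peak at a per-motif offset from the motif center, and
  the partner anchor of every true loop receives the same peak shape at
  the mirrored distance-to-motif, attenuated by a factor ``alpha`` — the
  cross-linking mechanism that makes anchor profiles of looping pairs
  correlate.  Per-base counts are Poisson so tracks resemble read
  coverage.

Everything is a pure function of the config seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pyBigWig

from . import motifs as _motifs

__all__ = ["SimConfig", "simulate_catalog", "simulate_track", "make_fixture"]

MOTIF_LENGTH = 19  # span of the canonical CTCF recognition motif


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic genome and coverage mechanism."""

    # genome
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_motifs: int = 400
    strand_prob: float = 0.5          # probability of '+' strand
    score_min: float = 5.602          # -log10(2.5e-6), the catalog cutoff
    score_scale: float = 1.5          # exponential tail above score_min
    edge_margin: int = 1_000          # keep profile windows inside chroms
    # loop placement
    max_dist: int = 100_000
    target_positive_rate: float = 0.05
    decay_scale: float = 35_000.0     # bp; exp(-d/decay_scale)
    convergent_multiplier: float = 4.0
    anchor_pad: int = 250             # truth anchors = motif span +/- pad
    # coverage signal
    peak_amplitude: float = 12.0      # median peak height (counts/base)
    amplitude_sigma: float = 0.5      # lognormal spread of peak heights
    peak_width: float = 40.0          # Gaussian sd of the peak, bp
    direct_binding_prob: float = 0.8  # motifs carrying their own peak
    attenuation: float = 0.8          # alpha: looped-partner peak scale
    noise_rate: float = 3.0           # Poisson background, counts/base
    binding_offset_range: int = 400   # |delta| cap, bp, oriented frame
    seed: int = 0

    def __post_init__(self):
        for name in ("strand_prob", "target_positive_rate",
                     "direct_binding_prob", "attenuation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.decay_scale <= 0:
            raise ValueError("decay_scale must be positive")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _chrom_names(config: SimConfig) -> list[str]:
    return [f"chrS{i + 1}" for i in range(config.n_chroms)]


def simulate_catalog(config: SimConfig):
    """Draw a motif catalog, candidate pairs and truth loops.

    Returns
    -------
    catalog : DataFrame
        Motif catalog in the standard layout (sorted, ids assigned).
    pairs : DataFrame
        All candidate pairs within ``max_dist`` with ``d``, ``o``, ``s``
        and the generative truth in a boolean ``label`` column.
    loops : DataFrame
        The true loops as a paired-interval table (anchors = motif spans
        padded by ``anchor_pad``) in the loop-table layout.
    """
    rng = _rng(config, 0)
    per_chrom = np.full(config.n_chroms, config.n_motifs // config.n_chroms)
    per_chrom[: config.n_motifs % config.n_chroms] += 1

    frames = []
    for chrom, n in zip(_chrom_names(config), per_chrom):
        usable = config.chrom_length - 2 * config.edge_margin - n * MOTIF_LENGTH
        if n > 0 and usable <= 0:
            raise ValueError(
                f"infeasible motif density: {n} motifs of {MOTIF_LENGTH} bp "
                f"do not fit in {chrom}"
            )
        if n == 0:
            continue
        # stars-and-bars placement: uniform non-overlapping motif starts
        gaps = np.sort(rng.integers(0, usable + 1, size=n))
        starts = config.edge_margin + gaps + np.arange(n) * MOTIF_LENGTH
        strands = np.where(rng.random(n) < config.strand_prob, "+", "-")
        scores = config.score_min + rng.exponential(config.score_scale, size=n)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": starts + MOTIF_LENGTH,
                    "strand": strands,
                    "score": scores,
                }
            )
        )
    catalog = pd.concat(frames, ignore_index=True)
    catalog = catalog.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    catalog["id"] = np.arange(len(catalog), dtype=np.int64)

    pairs = _motifs.build_pairs(catalog, config.max_dist)
    w = np.exp(-pairs["d"].to_numpy(dtype=float) / config.decay_scale)
    w *= np.where(pairs["o"].to_numpy() == "convergent", config.convergent_multiplier, 1.0)
    total = w.sum()
    if config.target_positive_rate > 0 and total > 0:
        c = config.target_positive_rate * len(pairs) / total
        p = np.clip(c * w, 0.0, 0.98)
    else:
        p = np.zeros(len(pairs))
    pairs = pairs.copy()
    pairs["label"] = _rng(config, 1).random(len(pairs)) < p

    true = pairs[pairs["label"]]
    loops = pd.DataFrame(
        {
            "chrom_a": true["chrom"].to_numpy(),
            "start_a": np.maximum(true["left_start"].to_numpy() - config.anchor_pad, 0),
            "end_a": true["left_end"].to_numpy() + config.anchor_pad,
            "chrom_b": true["chrom"].to_numpy(),
            "start_b": np.maximum(true["right_start"].to_numpy() - config.anchor_pad, 0),
            "end_b": true["right_end"].to_numpy() + config.anchor_pad,
            "source": "sim",
        }
    ).reset_index(drop=True)
    return catalog, pairs, loops


def _oriented_to_genomic(delta: int, strand: str) -> int:
    """Genomic center offset of a peak at oriented offset ``delta``.

    The oriented profile of a half-open window [c-h, c+h) maps genomic
    offset g to index h+g on '+' and to index h-1-g on '-'; inverting the
    latter puts an oriented offset delta at genomic offset -(delta+1).
    """
    return delta if strand == "+" else -(delta + 1)


def _add_peak(intensity: np.ndarray, pos: float, amp: float, sigma: float) -> None:
    lo = max(int(pos - 4 * sigma), 0)
    hi = min(int(pos + 4 * sigma) + 1, intensity.size)
    if hi <= lo:
        return
    x = np.arange(lo, hi)
    intensity[lo:hi] += amp * np.exp(-((x - pos) ** 2) / (2.0 * sigma**2))


def simulate_track(config: SimConfig, catalog: pd.DataFrame,
                   truth: pd.DataFrame, path) -> str:
    """Write a loop-coupled synthetic coverage track as bigWig.

    ``truth`` is the candidate-pair table from :func:`simulate_catalog`
    (only rows with ``label`` True couple the anchors).  Each directly
    bound motif gets a Gaussian peak of lognormal amplitude at its
    per-motif oriented offset delta; for every true loop with a directly
    bound anchor the partner motif receives the same peak shape at the
    same oriented distance-to-motif, scaled by ``attenuation``, plus the
    independent Poisson noise every base gets.
    """
    rng = _rng(config, 2)
    n = len(catalog)
    direct = rng.random(n) < config.direct_binding_prob
    amps = config.peak_amplitude * rng.lognormal(0.0, config.amplitude_sigma, size=n)
    deltas = rng.integers(-config.binding_offset_range,
                          config.binding_offset_range + 1, size=n)

    chrom_of = catalog["chrom"].to_numpy()
    centers = _motifs.motif_center(
        catalog["start"].to_numpy(), catalog["end"].to_numpy()
    )
    strands = catalog["strand"].to_numpy()
    id_to_row = {int(i): k for k, i in enumerate(catalog["id"].to_numpy())}

    names = _chrom_names(config)
    intensity = {c: np.full(config.chrom_length, float(config.noise_rate)) for c in names}

    for k in range(n):
        if direct[k]:
            pos = centers[k] + _oriented_to_genomic(int(deltas[k]), strands[k])
            _add_peak(intensity[chrom_of[k]], pos, amps[k], config.peak_width)

    true_pairs = truth[truth["label"]] if "label" in truth.columns else truth
    for rec in true_pairs.itertuples(index=False):
        i = id_to_row[int(rec.left_id)]
        j = id_to_row[int(rec.right_id)]
        for src, dst in ((i, j), (j, i)):
            if not direct[src]:
                continue
            # mirrored peak: same oriented distance-to-motif as the bound
            # anchor, expressed in the partner's strand frame
            pos = centers[dst] + _oriented_to_genomic(int(deltas[src]), strands[dst])
            _add_peak(
                intensity[chrom_of[dst]], pos,
                config.attenuation * amps[src], config.peak_width,
            )

    path = str(path)
    bw = pyBigWig.open(path, "w")
    try:
        bw.addHeader([(c, config.chrom_length) for c in names])
        for c in names:
            counts = rng.poisson(intensity[c]).astype(np.float64)
            bw.addEntries(c, 0, values=counts, span=1, step=1)
    finally:
        bw.close()
    return path


def make_fixture(config: SimConfig, outdir, force: bool = False) -> dict:
    """Write a self-describing fixture bundle consumable by every command.

    Produces ``motifs.tsv`` (JASPAR-dialect motif track), ``track.bw``
    (coverage), ``loops.bedpe`` (truth interactions) and ``manifest.txt``
    (flat key=value record of the full config).  Refuses to write into a
    non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise FileExistsError(f"{outdir} is not empty (use force to overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)

    catalog, pairs, loops = simulate_catalog(config)
    paths = {
        "motifs": outdir / "motifs.tsv",
        "track": outdir / "track.bw",
        "loops": outdir / "loops.bedpe",
        "manifest": outdir / "manifest.txt",
    }
    # JASPAR TSV dialect: 1-based start, score column = 100 * (-log10 p)
    jaspar = pd.DataFrame(
        {
            "chrom": catalog["chrom"],
            "start": catalog["start"] + 1,
            "end": catalog["end"],
            "name": "CTCF",
            "score": [repr(v) for v in catalog["score"] * 100.0],
            "strand": catalog["strand"],
        }
    )
    jaspar.to_csv(paths["motifs"], sep="\t", header=False, index=False)
    loops.drop(columns=["source"]).to_csv(
        paths["loops"], sep="\t", header=False, index=False
    )
    simulate_track(config, catalog, pairs, paths["track"])

    lines = ["format=chiploop-fixture-v1", "rng=numpy-pcg64"]
    lines += [f"config.{k}={v!r}" for k, v in asdict(config).items()]
    paths["manifest"].write_text("\n".join(lines) + "\n")
    return {k: str(v) for k, v in paths.items()}


def config_from_manifest(path) -> SimConfig:
    """Rebuild a :class:`SimConfig` from a fixture manifest."""
    import ast

    kv = {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("config."):
            key, _, val = line[len("config."):].partition("=")
            kv[key] = ast.literal_eval(val)
    return SimConfig(**kv)
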