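import numpy as np
import pandas as pd
import pyBigWig
import pytest

from chiploop import simulate as S
from chiploop import workflow as W


def write_bigwig(path, chroms: dict):
    """Write per-base value arrays as a bigWig file."""
    bw = pyBigWig.open(str(path), "w")
    try:
        bw.addHeader([(c, len(v)) for c, v in chroms.items()])
        for c, v in chroms.items():
            bw.addEntries(c, 0, values=np.asarray(v, dtype=np.float64),
                          span=1, step=1)
    finally:
        bw.close()
    return str(path)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but non-degenerate synthetic genome: one 300 kb chromosome."""
    return S.SimConfig(
        n_chroms=1,
        chrom_length=300_000,
        n_motifs=80,
        max_dist=60_000,
        decay_scale=25_000.0,
        target_positive_rate=0.08,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_fixture(tiny_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    paths = S.make_fixture(tiny_config, outdir, force=True)
    return paths


@pytest.fixture(scope="session")
def tiny_features(tiny_config, tiny_fixture):
    """Labeled, correlation-annotated candidate pairs of the tiny genome."""
    catalog, pairs, _ = S.simulate_catalog(tiny_config)
    return W.annotate_correlations(
        pairs, catalog, {"sim": tiny_fixture["track"]}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_catalog(rng, n, chroms=("chrA", "chrB"), span=1_000_000):
    """Random motif catalog for oracle tests."""
    starts = rng.integers(0, span - 19, size=n)
    frame = pd.DataFrame(
        {
            "chrom": rng.choice(list(chroms), size=n),
            "start": starts,
            "end": starts + 19,
            "strand": rng.choice(["+", "-"], size=n),
            "score": 5.61 + rng.exponential(1.5, size=n),
        }
    )
    frame = frame.drop_duplicates(["chrom", "start", "end", "strand"])
    frame = frame.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    frame["id"] = np.arange(len(frame), dtype=np.int64)
    return frame


def brute_force_pairs(catalog, max_dist):
    """O(n^2) reference pair enumeration."""
    out = []
    rows = catalog.to_dict("records")
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            a, b = rows[i], rows[j]
            if a["chrom"] != b["chrom"]:
                continue
            ca = (a["start"] + a["end"]) // 2
            cb = (b["start"] + b["end"]) // 2
            if abs(cb - ca) > max_dist:
                continue
            left, right = (a, b) if ca <= cb else (b, a)
            out.append(
                (left["chrom"], left["id"], right["id"], abs(cb - ca),
                 min(left["score"], right["score"]))
            )
    return sorted(out)
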