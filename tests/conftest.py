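import numpy as np
import pandas as pd
import pytest

from methclock import QCConfig, SimConfig, SiteUniverse, simulate_cohort
from methclock.io import CohortMatrix


@pytest.fixture
def tiny_universe():
    """8 sites across chr1/chr2 plus one each on chrX and chrM."""
    return SiteUniverse.from_pairs(
        [
            ("chr1", 100),
            ("chr1", 250),
            ("chr1", 400),
            ("chr2", 100),
            ("chr2", 220),
            ("chr2", 340),
            ("chrX", 50),
            ("chrM", 10),
        ]
    )


@pytest.fixture
def bedgraph_file(tmp_path):
    """Five covered sites of the tiny universe, hand-set counts."""
    text = (
        'track type="bedGraph" description="t"\n'
        "chr1\t100\t101\t75\t3\t1\n"
        "chr1\t250\t251\t0\t0\t10\n"
        "chr1\t400\t401\t100\t5\t0\n"
        "chr2\t100\t101\t50\t6\t6\n"
        "chrX\t50\t51\t25\t1\t3\n"
    )
    path = tmp_path / "sampleA.bedGraph"
    path.write_text(text)
    return path


def make_cohort(beta, depth, ages, universe=None, meth=None):
    beta = np.asarray(beta, dtype=float)
    depth = np.asarray(depth, dtype=np.int64)
    s, n = beta.shape
    if universe is None:
        universe = SiteUniverse.from_pairs([("chr1", 100 + 10 * i) for i in range(n)])
    samples = pd.DataFrame(
        {"sample_id": [f"S{i:03d}" for i in range(s)], "age": np.asarray(ages, float)}
    )
    return CohortMatrix(
        universe=universe, beta=beta, depth=depth, samples=samples, meth=meth
    )


@pytest.fixture(scope="session")
def small_cohort():
    """60 samples x 400 sites at ~30x: fast shared cohort for unit tests."""
    cfg = SimConfig(n_samples=60, n_sites=400, seed=1)
    return simulate_cohort(cfg)


@pytest.fixture
def qc_cfg():
    return QCConfig()
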