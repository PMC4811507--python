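import numpy as np
import pandas as pd
import pytest

import epishift as ep
from epishift.pipeline import StudyData


@pytest.fixture(scope="session")
def cellline_study():
    """One simulated isogenic cell-line study (default conditions)."""
    return ep.simulate_study(ep.SyntheticConfig.cellline(seed=7))


@pytest.fixture(scope="session")
def cellline_data(cellline_study):
    return StudyData.from_study(cellline_study)


@pytest.fixture(scope="session")
def cellline_track(cellline_data):
    return ep.compute_delta_beta(cellline_data.beta, cellline_data.sheet,
                                 grouping="condition")


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_manifest(rng, n=500, n_chroms=2, spacing=100):
    """Probe manifest with unique, sorted positions on a toy genome."""
    rows = []
    pid = 0
    for c in range(n_chroms):
        k = n // n_chroms + (1 if c < n % n_chroms else 0)
        pos = np.cumsum(rng.integers(1, spacing, size=k))
        for p in pos:
            rows.append((f"cg{pid:06d}", f"chr{c + 1}", int(p)))
            pid += 1
    man = pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])
    man["feature"] = "intergenic"
    man["enhancer_class"] = "none"
    man["nearest_gene"] = ""
    return man


def occupancy(intervals, length=10_000):
    """Per-base boolean occupancy oracle for a list of (start, end)."""
    occ = np.zeros(length, dtype=bool)
    for s, e in intervals:
        occ[s:e] = True
    return occ
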