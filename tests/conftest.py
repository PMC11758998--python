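import numpy as np
import pandas as pd
import pytest

from paleonts import synthdata, trends
from paleonts.formulas import MolecularFormula, parse_formula


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic record shared across tests (seed 0)."""
    return synthdata.generate(synthdata.GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def kept_profiles(default_dataset):
    rejects = set(default_dataset.truth.reject_ids)
    return [p for p in default_dataset.profiles if p.id not in rejects]


@pytest.fixture(scope="session")
def default_binned(default_dataset, kept_profiles):
    return trends.bin_series(kept_profiles, default_dataset.samples, 5, 1800)


def random_formula(rng: np.random.Generator) -> MolecularFormula:
    """A random valid elemental formula over the CHNOS(+Cl) space."""
    c = int(rng.integers(1, 31))
    n = int(rng.integers(0, 4))
    o = int(rng.integers(0, 16))
    s = int(rng.integers(0, 3))
    cl = int(rng.integers(0, 2)) if rng.random() < 0.1 else 0
    h = int(rng.integers(1, 2 * c + 3))
    counts = {"C": c, "H": h}
    for sym, k in (("N", n), ("O", o), ("S", s), ("Cl", cl)):
        if k:
            counts[sym] = k
    return MolecularFormula(counts)


def make_binned(matrix: np.ndarray, bin_years=None, ids=None, width=5) -> trends.BinnedSeries:
    """Wrap a raw molecules x bins array into a BinnedSeries."""
    matrix = np.asarray(matrix, dtype=float)
    if bin_years is None:
        bin_years = 1800 + width * np.arange(matrix.shape[1])
    if ids is None:
        ids = [f"M{i:03d}" for i in range(matrix.shape[0])]
    df = pd.DataFrame(matrix, index=ids, columns=bin_years)
    return trends.BinnedSeries(bin_years=np.asarray(bin_years, float), matrix=df, bin_width=width)
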