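import numpy as np
import pandas as pd
import pytest

from divscan.formats import MISSING, GenotypeMatrix, PopulationMap


def make_matrix(
    calls,
    pos=None,
    chrom="chr1",
    is_variant=None,
    qual=60.0,
    depth=90.0,
    samples=None,
):
    """Build a GenotypeMatrix from a (n_sites, n_samples) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    pos = np.asarray(pos)
    if is_variant is None:
        is_variant = np.ones(n_sites, dtype=bool)
    is_variant = np.asarray(is_variant, dtype=bool)
    chroms = [chrom] * n_sites if isinstance(chrom, str) else list(chrom)
    qual = np.full(n_sites, qual, dtype=float) if np.isscalar(qual) else np.asarray(qual)
    depth = np.full(n_sites, depth, dtype=float) if np.isscalar(depth) else np.asarray(depth)
    sites = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": "A",
            "alt": np.where(is_variant, "G", "."),
            "qual": qual,
            "depth": depth,
            "is_variant": is_variant,
        }
    )
    if samples is None:
        samples = [f"S{i}" for i in range(n_samples)]
    return GenotypeMatrix(sites=sites, samples=samples, calls=calls)


@pytest.fixture
def two_pop_map():
    """7 + 2 samples, the resequencing sampling design."""
    assignments = {f"G{i}": "GLG" for i in range(1, 8)}
    assignments.update({f"wls{i}": "WL" for i in range(1, 3)})
    return PopulationMap(assignments)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


MISSING = MISSING  # re-exported for test readability
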