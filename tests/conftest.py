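import numpy as np
import pandas as pd
import pytest

import gametecnv as g


@pytest.fixture(scope="session")
def genome():
    """The default 10-chromosome ~400 Mb scaled test genome."""
    return g.default_genome(seed=0)


@pytest.fixture(scope="session")
def small_genome():
    """Two small chromosomes for cheap binning/segmentation tests."""
    return g.make_genome([("chr1", 10_000_000), ("chr2", 8_000_000)],
                         centromere_fraction=0.05, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def uniform_scheme(genome, bin_bp):
    """Equal-width variable-stage scheme for hand-built profiles."""
    import gametecnv.bins as cb

    rows = []
    for chrom, length in genome.chromosomes:
        edges = list(range(0, length, bin_bp)) + [length]
        edges = sorted(set(edges))
        for i in range(len(edges) - 1):
            rows.append((chrom, edges[i], edges[i + 1]))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return cb.BinScheme(bins, "variable", genome)


def profile_from_counts(scheme, counts, sample_id="s", pseudocount=0.5,
                        median=None):
    """Build a CNRProfile directly from per-bin counts (noiseless oracle).

    ``median`` overrides the empirical median, e.g. to express a profile
    whose aberrant bins are not a minority of the genome.
    """
    import gametecnv.bins as cb

    counts = np.asarray(counts, dtype=np.int64)
    if median is None:
        median = float(np.median(counts[~scheme.masked]))
    cnr = counts / median
    adjusted = np.where(counts == 0, pseudocount, counts)
    log2 = np.log2(adjusted / median)
    return cb.CNRProfile(sample_id, scheme, counts, cnr, log2,
                         scheme.masked.copy(), median, pseudocount)
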