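import numpy as np
import pytest

from streampop import GenotypeMatrix, MISSING


def make_matrix(populations, genotypes, locus_ids=None, ids=None):
    """Convenience builder: populations is a list of labels per individual."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, l = genotypes.shape
    if locus_ids is None:
        locus_ids = [f"L{j}" for j in range(l)]
    if ids is None:
        counts = {}
        ids = []
        for p in populations:
            counts[p] = counts.get(p, 0) + 1
            ids.append(f"{p}_{counts[p]}")
    return GenotypeMatrix(ids, list(populations), genotypes, locus_ids)


@pytest.fixture
def two_pop_matrix():
    """Two populations, three loci, including a missing call."""
    return make_matrix(
        ["pop1", "pop1", "pop2", "pop2"],
        [[2, 1, 0], [1, 2, MISSING], [0, 0, 2], [0, 1, 2]],
    )


def random_matrix(rng, n_pops=2, ind_per_pop=4, n_loci=5, missing_rate=0.1):
    pops = [f"pop{k + 1}" for k in range(n_pops) for _ in range(ind_per_pop)]
    g = rng.integers(0, 3, size=(len(pops), n_loci)).astype(np.int8)
    if missing_rate > 0:
        g[rng.random(g.shape) < missing_rate] = MISSING
    return make_matrix(pops, g)
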