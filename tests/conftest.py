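import numpy as np
import pandas as pd
import pytest

from motukit import DistanceMatrix, TaxonomyTable, build_matrix
from motukit.synthetic_data import SimulationParams, simulate


@pytest.fixture(scope="session")
def default_community():
    """20 species (4 genera x 5), 5 individuals each, defaults, seed 1."""
    return simulate(SimulationParams(seed=1))


@pytest.fixture(scope="session")
def default_dm(default_community):
    return build_matrix(default_community.seqs)


@pytest.fixture
def tiny_taxonomy():
    """Six specimens, three species, two genera."""
    rows = []
    for sid, sp, genus in [
        ("s1", "Alpha one", "Alpha"),
        ("s2", "Alpha one", "Alpha"),
        ("s3", "Alpha two", "Alpha"),
        ("s4", "Alpha two", "Alpha"),
        ("s5", "Beta one", "Beta"),
        ("s6", "Beta one", "Beta"),
    ]:
        rows.append(
            dict(
                specimen_id=sid,
                species_apriori=sp,
                species_final=sp,
                genus=genus,
                subfamily="Subf",
                family="Fam",
            )
        )
    return TaxonomyTable(pd.DataFrame(rows))


def matrix_from_array(ids, arr):
    """DistanceMatrix from a plain square array (L filled with ones)."""
    arr = np.asarray(arr, dtype=float)
    return DistanceMatrix(list(ids), arr, np.ones_like(arr, dtype=np.int64))


@pytest.fixture
def tiny_dm(tiny_taxonomy):
    """Distances consistent with tiny_taxonomy: intra 0.01, congeneric 0.1,
    between-genus 0.2."""
    ids = tiny_taxonomy.ids
    sp = {i: tiny_taxonomy.species(i) for i in ids}
    genus = {i: tiny_taxonomy.rank(i, "genus") for i in ids}
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = ids[i], ids[j]
            if sp[a] == sp[b]:
                d[i, j] = d[j, i] = 0.01
            elif genus[a] == genus[b]:
                d[i, j] = d[j, i] = 0.10
            else:
                d[i, j] = d[j, i] = 0.20
    return matrix_from_array(ids, d)
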