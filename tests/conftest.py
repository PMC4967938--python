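import numpy as np
import pandas as pd
import pytest

from pathconcord import ExpressionDataset, GeneSetCollection, PathwayStateProfile


def make_dataset(values, genes, case_n, control_n, dataset_id="ds"):
    """Two-class dataset with controls first, cases after."""
    n = case_n + control_n
    cols = [f"k{i}" for i in range(control_n)] + [f"c{i}" for i in range(case_n)]
    vals = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=cols)
    ph = pd.Series(["control"] * control_n + ["case"] * case_n, index=cols)
    return ExpressionDataset(values=vals, phenotype=ph, case="case",
                             control="control", dataset_id=dataset_id)


def make_profile(pathways, up=(), down=(), dataset_id="p", q_sig=0.01):
    idx = pd.Index(list(pathways), name="pathway")
    states = pd.Series("null", index=idx)
    nes = pd.Series(np.nan, index=idx)
    q = pd.Series(np.nan, index=idx)
    for s in up:
        states[s], nes[s], q[s] = "up", 1.5, q_sig
    for s in down:
        states[s], nes[s], q[s] = "down", -1.5, q_sig
    return PathwayStateProfile(dataset_id=dataset_id, states=states, nes=nes, q=q)


@pytest.fixture
def two_gene_dataset():
    # gA: clear case>control difference; gB: constant classes (floor rule)
    return make_dataset([[1, 2, 3, 3, 4, 5], [1, 1, 1, 2, 2, 2]],
                        ["gA", "gB"], case_n=3, control_n=3)


@pytest.fixture
def ten_pathways():
    return [f"P{i}" for i in range(1, 11)]


@pytest.fixture
def small_collection():
    sets = {f"S{i}": tuple(f"g{i}_{j}" for j in range(3)) for i in range(1, 4)}
    return GeneSetCollection(sets=sets, descriptions={k: "d" for k in sets})
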