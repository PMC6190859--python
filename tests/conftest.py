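import numpy as np
import pandas as pd
import pytest

from sinktrace import OTUTable, STParams, SourceLibrary


def make_table(counts, ids=None, envs=None, **meta_cols):
    counts = np.asarray(counts)
    ids = ids or [f"s{i}" for i in range(counts.shape[0])]
    meta = {"environment": envs or ["env"] * counts.shape[0]}
    meta.update(meta_cols)
    return OTUTable(
        pd.DataFrame(counts, index=ids, columns=[f"O{j}" for j in range(counts.shape[1])]),
        pd.DataFrame(meta, index=ids),
    )


@pytest.fixture
def two_source_library():
    """Two well-separated sources with disjoint OTU support, 3 samples each."""
    rng = np.random.default_rng(42)
    rows, ids, envs = [], [], []
    pa = np.concatenate([rng.dirichlet(np.ones(10)), np.zeros(10)])
    pb = np.concatenate([np.zeros(10), rng.dirichlet(np.ones(10))])
    for name, prof in (("A", pa), ("B", pb)):
        for j in range(3):
            rows.append(rng.multinomial(2000, prof))
            ids.append(f"{name}{j}")
            envs.append(name)
    table = make_table(rows, ids, envs)
    return SourceLibrary(table, {"A": ids[:3], "B": ids[3:]})


@pytest.fixture
def fast_params():
    return STParams(seed=7, restarts=4, draws_per_restart=5, burnin=40, delay=2,
                    train_rarefaction_depth=None)


def planted_dmm_table(k, n_per, seed, n_otus=100, depth=2000, concentration=20):
    """Samples from a k-component Dirichlet-multinomial mixture with known labels."""
    rng = np.random.default_rng(seed)
    comps = [rng.dirichlet(np.ones(n_otus)) * concentration for _ in range(k)]
    rows, labels = [], []
    for c, alpha in enumerate(comps):
        for _ in range(n_per):
            rows.append(rng.multinomial(depth, rng.dirichlet(alpha)))
            labels.append(c)
    return make_table(rows), np.array(labels)


def best_permutation_accuracy(pred_codes, true_codes, k):
    from itertools import permutations

    return max(
        float(np.mean([p[c] == t for c, t in zip(pred_codes, true_codes)]))
        for p in permutations(range(k))
    )
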