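import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from sinktrace import (
    OTUTable,
    STParams,
    SourceLibrary,
    gibbs_fit,
    loo_crossvalidation,
    otu_source_posteriors,
)

from conftest import make_table


def enumerate_posterior(train_counts, reads, p, unknown=True):
    """Exact posterior mean proportions and per-OTU source marginals by
    exhaustive enumeration of all label configurations of the collapsed model."""
    m = np.asarray(train_counts, dtype=float)
    V, T = m.shape
    N = len(reads)
    phi = (m + p.alpha1) / (m.sum(axis=1, keepdims=True) + p.alpha1 * T)
    a2N, a2NT = p.alpha2 * N, p.alpha2 * N * T
    VU = V + 1 if unknown else V
    total = 0.0
    mean = np.zeros(VU)
    reads_per_otu = Counter(reads)
    otu_marg = np.zeros((T, VU))
    for z in itertools.product(range(VU), repeat=N):
        n = Counter(z)
        logw = sum(gammaln(n[v] + p.beta) for v in range(VU))
        for t, v in zip(reads, z):
            if v < V:
                logw += np.log(phi[v, t])
        if unknown:
            u = Counter(t for t, v in zip(reads, z) if v == V)
            logw += sum(gammaln(u[t] + a2N) - gammaln(a2N) for t in range(T))
            logw -= gammaln(sum(u.values()) + a2NT) - gammaln(a2NT)
        w = np.exp(logw)
        total += w
        for v in range(VU):
            mean[v] += w * n[v] / N
        for t, v in zip(reads, z):
            otu_marg[t, v] += w / reads_per_otu[t]
    mean /= total
    otu_marg /= total
    sums = otu_marg.sum(axis=1, keepdims=True)
    otu_marg = np.divide(otu_marg, sums, out=np.zeros_like(otu_marg), where=sums > 0)
    return mean, otu_marg


def library_from(counts, names):
    ids = [f"{n}1" for n in names]
    table = make_table(counts, ids=ids, envs=list(names))
    return SourceLibrary(table, {n: [i] for n, i in zip(names, ids)})


def sink_from(reads, n_otus, columns=None):
    row = np.bincount(reads, minlength=n_otus)
    counts = pd.DataFrame([row], index=["snk"], columns=columns or [f"O{j}" for j in range(n_otus)])
    return OTUTable(counts, pd.DataFrame({"environment": ["sink"]}, index=["snk"]))


ENUM_PARAMS = STParams(
    restarts=20, draws_per_restart=150, burnin=100, delay=3, seed=5,
    train_rarefaction_depth=None,
)


class TestGibbsOracle:
    @pytest.mark.parametrize(
        "train,reads,unknown",
        [
            ([[8, 2], [1, 9]], [0, 0, 0, 1, 1], True),
            ([[5, 5], [9, 1]], [0, 1, 1, 1], True),
            ([[6, 2, 2], [1, 8, 1], [2, 2, 6]], [0, 1, 2, 2, 0, 1], False),
        ],
    )
    def test_matches_exhaustive_enumeration(self, train, reads, unknown):
        names = ["A", "B", "C"][: len(train)]
        lib = library_from(train, names)
        sink = sink_from(reads, len(train[0]))
        fit = gibbs_fit(lib, sink, ENUM_PARAMS, unknown=unknown)
        mean, otu_marg = enumerate_posterior(train, reads, ENUM_PARAMS, unknown=unknown)
        assert np.allclose(fit.proportions_mean.loc["snk"].to_numpy(), mean, atol=0.02)
        post = otu_source_posteriors(fit, "snk")
        for t in sorted(set(reads)):
            assert np.allclose(post.loc[f"O{t}"].to_numpy(), otu_marg[t], atol=0.02)

    def test_degenerate_support_goes_to_owning_source(self):
        # all sink reads in an OTU private to source A (alpha1 -> 0 limit):
        # with no Unknown partition the owning source takes everything; with
        # the Unknown enabled it remains the dominant known source (a novel
        # one-OTU cluster is legitimately explainable by the Unknown too)
        lib = library_from([[50, 0], [0, 50]], ["A", "B"])
        sink = sink_from([0] * 30, 2)
        p = STParams(seed=1, alpha1=1e-9, restarts=5, draws_per_restart=10,
                     burnin=50, train_rarefaction_depth=None)
        fit = gibbs_fit(lib, sink, p, unknown=False)
        assert fit.proportions_mean.loc["snk", "A"] > 0.999
        fit_u = gibbs_fit(lib, sink, p)
        props = fit_u.proportions_mean.loc["snk"]
        assert props["A"] > 10 * props["B"]

    def test_single_source_no_unknown_is_exactly_one(self):
        lib = library_from([[10, 10]], ["A"])
        sink = sink_from([0, 1, 1], 2)
        fit = gibbs_fit(lib, sink, STParams(seed=0, train_rarefaction_depth=None), unknown=False)
        assert fit.proportions_mean.loc["snk", "A"] == 1.0


class TestResultContracts:
    def test_posterior_rows_sum_to_one_and_bounds(self, two_source_library, fast_params):
        sink = sink_from([0, 0, 3, 11, 11, 15], 20)
        fit = gibbs_fit(two_source_library, sink, fast_params)
        post = otu_source_posteriors(fit, "snk")
        assert np.allclose(post.sum(axis=1), 1.0, atol=1e-9)
        assert ((post.to_numpy() >= 0) & (post.to_numpy() <= 1)).all()
        # OTUs without sink reads are excluded rather than NaN-filled
        assert set(post.index) == {"O0", "O3", "O11", "O15"}

    def test_same_seed_is_bit_reproducible(self, two_source_library, fast_params):
        sink = sink_from([0, 1, 11, 12] * 5, 20)
        a = gibbs_fit(two_source_library, sink, fast_params)
        b = gibbs_fit(two_source_library, sink, fast_params)
        pd.testing.assert_frame_equal(a.proportions_mean, b.proportions_mean)
        pd.testing.assert_frame_equal(a.otu_posteriors["snk"], b.otu_posteriors["snk"])

    def test_otu_permutation_changes_nothing_beyond_mc_noise(self, two_source_library):
        p = STParams(seed=3, restarts=8, draws_per_restart=20, burnin=60,
                     train_rarefaction_depth=None)
        sink = sink_from([0, 0, 1, 11, 12, 12] * 4, 20)
        fit = gibbs_fit(two_source_library, sink, p)
        perm = list(np.random.default_rng(0).permutation(20))
        cols = [f"O{j}" for j in perm]
        lib2 = SourceLibrary(
            two_source_library.table.subset_otus(cols), two_source_library.sources
        )
        fit2 = gibbs_fit(lib2, sink_from([0, 0, 1, 11, 12, 12] * 4, 20).subset_otus(cols), p)
        diff = (fit.proportions_mean - fit2.proportions_mean).abs().to_numpy().max()
        assert diff < 0.05

    def test_duplicate_training_sample_invariance(self, two_source_library, fast_params):
        sink = sink_from([0, 1, 2, 11, 12] * 6, 20)
        base = gibbs_fit(two_source_library, sink, fast_params)
        t = two_source_library.table
        dup_counts = pd.concat([t.counts, t.counts.loc[["A0"]].rename(index={"A0": "A0dup"})])
        dup_meta = pd.concat([t.sample_meta, t.sample_meta.loc[["A0"]].rename(index={"A0": "A0dup"})])
        lib2 = SourceLibrary(
            OTUTable(dup_counts, dup_meta),
            {"A": ["A0", "A1", "A2", "A0dup"], "B": ["B0", "B1", "B2"]},
        )
        dup = gibbs_fit(lib2, sink, fast_params)
        diff = (base.proportions_mean - dup.proportions_mean).abs().to_numpy().max()
        assert diff < 0.05

    def test_zero_read_sink_errors(self, two_source_library, fast_params):
        sink = make_table([[0] * 20], ids=["snk"], envs=["sink"])
        with pytest.raises(ValueError, match="zero reads"):
            gibbs_fit(two_source_library, sink, fast_params)

    def test_unfitted_sink_raises(self, two_source_library, fast_params):
        fit = gibbs_fit(two_source_library, sink_from([0, 11], 20), fast_params)
        with pytest.raises(KeyError):
            otu_source_posteriors(fit, "nope")


class TestLOOCV:
    def test_disjoint_sources_fully_traced(self, two_source_library, fast_params):
        loo = loo_crossvalidation(two_source_library, fast_params)
        assert loo.accuracy == 1.0
        assert int(np.diag(loo.confusion.to_numpy()).sum()) == 6

    def test_shuffled_labels_fall_to_chance(self, fast_params):
        # sources built from one common pool carry no label signal
        rng = np.random.default_rng(11)
        prof = rng.dirichlet(np.ones(30))
        rows = [rng.multinomial(2000, prof) for _ in range(12)]
        ids = [f"s{i}" for i in range(12)]
        table = make_table(rows, ids=ids, envs=["A"] * 6 + ["B"] * 6)
        lib = SourceLibrary(table, {"A": ids[:6], "B": ids[6:]})
        loo = loo_crossvalidation(lib, fast_params)
        assert 0.1 <= loo.accuracy <= 0.9  # near 1/2, far from perfect tracing

    def test_single_sample_source_errors(self, fast_params):
        t = make_table([[5, 5], [4, 6]], ids=["a", "b"], envs=["A", "B"])
        lib = SourceLibrary(t, {"A": ["a"], "B": ["b"]})
        with pytest.raises(ValueError, match="single sample"):
            loo_crossvalidation(lib, fast_params)
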