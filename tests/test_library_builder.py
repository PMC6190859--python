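import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from sinktrace import (
    LibraryError,
    STParams,
    ScenarioSpec,
    SinkSpec,
    SourceLibrary,
    SourceSpec,
    WaterSpec,
    build_library,
    dmm_fit,
    fib_candidates,
    generate_scenario,
    laplace_score,
    preliminary_screen,
    select_background_dm,
)
from sinktrace.library_builder import DMMFit, _trim_source

from conftest import make_table, planted_dmm_table, best_permutation_accuracy


class TestFIBCandidates:
    def test_clean_sample_included(self):
        meta = pd.DataFrame(
            {"ecoli_mpn": [0.0], "coliform_mpn": [0.0]}, index=["w1"]
        )
        assert fib_candidates(meta) == ["w1"]

    def test_thresholds_are_strict(self):
        meta = pd.DataFrame(
            {"ecoli_mpn": [25.0, 24.9], "coliform_mpn": [50.0, 100.0]},
            index=["at_ecoli", "at_coliform"],
        )
        assert fib_candidates(meta) == []

    def test_missing_values_excluded_with_warning(self):
        meta = pd.DataFrame(
            {"ecoli_mpn": [1.0, np.nan], "coliform_mpn": [1.0, 2.0]},
            index=["ok", "na"],
        )
        with pytest.warns(UserWarning, match="missing FIB"):
            assert fib_candidates(meta) == ["ok"]

    def test_matches_brute_force_predicate(self):
        rng = np.random.default_rng(0)
        meta = pd.DataFrame(
            {
                "ecoli_mpn": rng.uniform(0, 60, 50),
                "coliform_mpn": rng.uniform(0, 250, 50),
            },
            index=[f"w{i}" for i in range(50)],
        )
        expected = [
            i for i in meta.index
            if meta.loc[i, "ecoli_mpn"] < 25 and meta.loc[i, "coliform_mpn"] < 100
        ]
        assert fib_candidates(meta) == expected


def tiny_scenario():
    return ScenarioSpec(
        n_otus=200,
        sources=[
            SourceSpec("sewage", n_samples=10, reads_per_sample=20_000,
                       support_size=40, water_overlap=0.7),
            SourceSpec("cow", n_samples=10, reads_per_sample=20_000,
                       support_size=40, water_overlap=0.2),
        ],
        water=WaterSpec(n_locations=2, samples_per_location=14,
                        reads_per_sample=20_000, block_size=60),
        sinks=[SinkSpec("L1", {"background": 1.0}, depth=20_000)],
        seed=3,
    )


@pytest.fixture(scope="module")
def scenario_tables():
    return generate_scenario(tiny_scenario(), seed=0)


FAST = STParams(seed=5, restarts=3, draws_per_restart=3, burnin=30,
                train_rarefaction_depth=None)


class TestPreliminaryScreen:
    def test_clean_water_retained_contaminated_dropped(self, scenario_tables):
        fecal, water, sinks, truth = scenario_tables
        env = fecal.environments()
        lib = SourceLibrary(
            fecal, {str(e): list(env.index[env == e]) for e in env.unique()}
        )
        cand = water.subset_samples(water.sample_ids[:8])
        # spike one candidate with 20% sewage reads
        spiked = cand.counts.copy()
        sewage_profile = truth.source_profiles.loc["sewage"].to_numpy()
        rng = np.random.default_rng(0)
        sid = cand.sample_ids[0]
        extra = rng.multinomial(4000, sewage_profile)
        spiked.loc[sid] = (0.8 * spiked.loc[sid]).astype(int) + extra
        cand_spiked = type(cand)(spiked, cand.sample_meta)
        kept = preliminary_screen(cand_spiked, lib, FAST, 0.99)
        assert sid not in kept
        assert len(kept) >= 5  # most genuine waters survive

    def test_zero_threshold_retains_all(self, scenario_tables):
        fecal, water, _, _ = scenario_tables
        env = fecal.environments()
        lib = SourceLibrary(
            fecal, {str(e): list(env.index[env == e]) for e in env.unique()}
        )
        cand = water.subset_samples(water.sample_ids[:4])
        assert preliminary_screen(cand, lib, FAST, 0.0) == cand.sample_ids

    def test_empty_candidates_error(self, scenario_tables):
        fecal, water, _, _ = scenario_tables
        env = fecal.environments()
        lib = SourceLibrary(
            fecal, {str(e): list(env.index[env == e]) for e in env.unique()}
        )
        with pytest.raises(ValueError, match="empty candidate"):
            preliminary_screen(water.subset_samples([]), lib, FAST)


def single_dm_negloglik(theta, X):
    alpha = np.exp(theta)
    A = alpha.sum()
    N = X.sum(axis=1)
    ll = (
        gammaln(A) - gammaln(N + A)
        + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1)
    ).sum()
    return -ll


class TestDMM:
    def test_k1_is_single_component_mle(self):
        t, _ = planted_dmm_table(1, 25, seed=4, n_otus=30)
        fit = dmm_fit(t, 1, seed=0)
        assert np.allclose(fit.responsibilities.to_numpy(), 1.0)
        # independent direct optimization from a different start
        X = t.counts.to_numpy(dtype=float)
        res = minimize(
            single_dm_negloglik, np.zeros(30), args=(X,), method="L-BFGS-B"
        )
        assert fit.log_likelihood >= -res.fun - 1.0

    def test_em_loglik_monotone(self):
        t, _ = planted_dmm_table(2, 15, seed=5)
        fit = dmm_fit(t, 2, seed=1)
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_planted_two_components_recovered(self):
        t, labels = planted_dmm_table(2, 20, seed=6)
        fit = dmm_fit(t, 2, seed=2)
        codes = pd.factorize(fit.hard_assignments)[0]
        assert best_permutation_accuracy(codes, labels, 2) >= 0.95

    def test_invalid_inputs(self):
        t, _ = planted_dmm_table(1, 5, seed=0, n_otus=10)
        with pytest.raises(ValueError):
            dmm_fit(t, 0, seed=0)


class TestLaplace:
    def test_single_component_data_prefers_k1_over_k4(self):
        t, _ = planted_dmm_table(1, 30, seed=7)
        s1 = dmm_fit(t, 1, seed=0).laplace
        s4 = dmm_fit(t, 4, seed=0).laplace
        assert s1 < s4

    def test_minimum_at_planted_k2(self):
        t, _ = planted_dmm_table(2, 25, seed=8)
        scores = {k: dmm_fit(t, k, seed=3).laplace for k in range(1, 5)}
        assert min(scores, key=scores.get) == 2

    def test_count_doubling_preserves_k_ordering(self):
        t, _ = planted_dmm_table(2, 20, seed=9)
        doubled = make_table(t.counts.to_numpy() * 2)
        order = lambda tab: sorted(range(1, 4), key=lambda k: dmm_fit(tab, k, seed=4).laplace)
        assert order(t)[0] == order(doubled)[0] == 2


class TestSelectBackground:
    def test_homogeneous_pool_returned_whole(self):
        t, _ = planted_dmm_table(1, 16, seed=10)
        # include the sink as the last sample; all 15 others are its cluster
        sink_id = t.sample_ids[-1]
        ids, info = select_background_dm(sink_id, t, k_min=2, k_max=3, n_min=10,
                                         n_max=25, seed=0)
        assert set(ids) == set(t.sample_ids) - {sink_id}

    def test_planted_three_cluster_precision(self):
        hits = []
        for seed in (0, 1):
            t, labels = planted_dmm_table(3, 20, seed=20 + seed)
            sink_id = t.sample_ids[25]  # a member of cluster 1
            ids, _ = select_background_dm(sink_id, t, k_min=2, k_max=4, n_min=10,
                                          n_max=25, seed=seed)
            cluster = {t.sample_ids[i] for i in np.flatnonzero(labels == labels[25])}
            precision = len(set(ids) & cluster) / len(ids)
            hits.append(precision)
        assert np.mean(hits) >= 0.9

    def test_walks_ranking_to_second_best(self):
        # fabricated fits: best-scoring fit has an oversized sink component,
        # second-best fits the 10-25 window and must win
        samples = [f"s{i}" for i in range(40)] + ["sink"]
        r1 = pd.DataFrame(0.0, index=samples, columns=["C1", "C2"])
        r1.loc[:, "C1"] = 1.0  # k=2 fit: everyone with the sink (40 members)
        f1 = DMMFit(2, np.ones((2, 5)), np.array([0.5, 0.5]), r1,
                    r1.idxmax(axis=1), laplace=100.0, log_likelihood=0.0,
                    converged=True, counts=np.ones((41, 5)))
        r2 = pd.DataFrame(0.0, index=samples, columns=["C1", "C2", "C3"])
        r2.iloc[:15, 0] = 1.0
        r2.iloc[15:, 1] = 1.0
        r2.loc["sink"] = [1.0, 0.0, 0.0]  # sink with 15 members
        f2 = DMMFit(3, np.ones((3, 5)), np.full(3, 1 / 3), r2,
                    r2.idxmax(axis=1), laplace=200.0, log_likelihood=0.0,
                    converged=True, counts=np.ones((41, 5)))
        t = make_table(np.ones((41, 5), dtype=int), ids=samples)
        ids, info = select_background_dm("sink", t, k_min=2, k_max=3, n_min=10,
                                         n_max=25, seed=0, fits={2: f1, 3: f2})
        assert info["k"] == 3 and len(ids) == 15
        assert set(ids) == set(samples[:15])

    def test_too_few_candidates_error(self):
        t, _ = planted_dmm_table(1, 5, seed=11, n_otus=20)
        with pytest.raises(LibraryError, match="candidates available"):
            select_background_dm(t.sample_ids[0], t, n_min=10, seed=0)


class TestBuildLibrary:
    def test_wb_has_no_background(self, scenario_tables):
        fecal, water, sinks, _ = scenario_tables
        lib = build_library("WB", fecal, water, sinks.sample_ids[0], FAST,
                            sink_table=sinks)
        assert lib.background_samples == []
        assert set(lib.sources) == {"sewage", "cow"}
        lib.validate()

    def test_lb_uses_prescreened_local_waters(self, scenario_tables):
        fecal, water, sinks, _ = scenario_tables
        sink_id = sinks.sample_ids[0]
        loc = sinks.sample_meta.loc[sink_id, "location"]
        local = [s for s in water.sample_ids
                 if water.sample_meta.loc[s, "location"] == loc][:12]
        lib = build_library("LB", fecal, water, sink_id, FAST, sink_table=sinks,
                            prescreened=local)
        assert set(lib.background_samples) == set(local)
        assert set(lib.sources["Background"]) == set(local)
        lib.validate()

    def test_dm_background_from_sink_cluster(self, scenario_tables):
        fecal, water, sinks, truth = scenario_tables
        sink_id = sinks.sample_ids[0]
        loc = sinks.sample_meta.loc[sink_id, "location"]
        lib = build_library("DM", fecal, water, sink_id, FAST, sink_table=sinks,
                            prescreened=list(water.sample_ids), dmm_seed=0)
        assert 10 <= len(lib.background_samples) <= 25
        # the sink is pure local background, so its cluster is its location
        same_loc = {s for s in lib.background_samples
                    if water.sample_meta.loc[s, "location"] == loc}
        assert len(same_loc) / len(lib.background_samples) >= 0.9
        lib.validate()

    def test_undersized_source_fails_loudly(self, scenario_tables):
        fecal, water, sinks, _ = scenario_tables
        small = fecal.subset_samples(fecal.sample_ids[:12])  # sewage 10, cow 2
        with pytest.raises(LibraryError, match="usable samples"):
            build_library("WB", small, water, sinks.sample_ids[0], FAST,
                          sink_table=sinks)

    def test_unknown_mode_rejected(self, scenario_tables):
        fecal, water, sinks, _ = scenario_tables
        with pytest.raises(ValueError, match="unknown library mode"):
            build_library("XX", fecal, water, sinks.sample_ids[0], FAST)


class TestTrim:
    def test_drops_newest_from_most_represented_location(self):
        meta = pd.DataFrame(
            {
                "location": ["L1"] * 4 + ["L2"] * 2,
                "date": pd.to_datetime(
                    ["2014-01-05", "2014-01-01", "2014-01-03", "2014-01-02",
                     "2014-01-04", "2014-01-06"]
                ),
            },
            index=[f"s{i}" for i in range(6)],
        )
        kept = _trim_source(list(meta.index), meta, 4)
        # two newest L1 samples (s0 then s2) go first
        assert kept == ["s1", "s3", "s4", "s5"]
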