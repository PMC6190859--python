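"""Collapsed Gibbs sampler for Dirichlet-multinomial source tracking.

Each sink read carries a latent source label. Known sources have fixed OTU
distributions estimated from (rarefied) training counts with ``alpha1``
smoothing; an extra Unknown source re-estimates its OTU distribution from the
reads currently assigned to it with ``alpha2`` smoothing scaled by the sink
depth; the mixing proportions carry a symmetric Dirichlet(``beta``) prior.
The full conditional for read ``i`` of OTU ``t`` is

    P(z_i = v | z_-i) ∝ (n_v^(-i) + beta) * P(x_i = t | v)

with ``P(t | v known) = (m_vt + alpha1) / (m_v. + alpha1 T)`` and
``P(t | Unknown) = (u_t^(-i) + alpha2 N) / (u_.^(-i) + alpha2 N T)`` where
``u`` counts current Unknown assignments, ``N`` the sink depth and ``T`` the
number of OTUs. Retained draws (after burn-in, thinned, across random
restarts) yield mean/sd mixing proportions and the per-OTU source posterior,
the latter normalized to one per observed OTU for each sink.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from numba import njit

from .otu_io import OTUTable, rarefy

if TYPE_CHECKING:  # pragma: no cover
    from .library_builder import SourceLibrary

UNKNOWN = "Unknown"


@dataclass
class STParams:
    """Sampler hyper-parameters (defaults follow the reference implementation)."""

    alpha1: float = 0.001
    alpha2: float = 0.1
    beta: float = 10.0
    restarts: int = 10
    draws_per_restart: int = 1
    burnin: int = 100
    delay: int = 1
    seed: int = 0
    train_rarefaction_depth: int | None = 10_000
    rarefy_sinks: bool = False

    def __post_init__(self) -> None:
        if min(self.alpha1, self.alpha2, self.beta) <= 0:
            raise ValueError("alpha1, alpha2 and beta must be positive")
        if self.burnin < 0 or self.restarts < 1 or self.draws_per_restart < 1:
            raise ValueError("invalid chain schedule")

    @property
    def n_draws(self) -> int:
        return self.restarts * self.draws_per_restart


@dataclass
class MSTResult:
    """Per-sink mixing estimates plus per-OTU source posteriors."""

    source_names: list[str]                      # known sources + "Unknown" (if enabled)
    proportions_mean: pd.DataFrame               # sink x source
    proportions_sd: pd.DataFrame
    otu_posteriors: dict[str, pd.DataFrame]      # sink -> observed OTU x source
    draws: dict[str, np.ndarray]                 # sink -> (n_draws x source) proportions
    sink_counts: pd.DataFrame = field(repr=False, default=None)

    def __post_init__(self) -> None:
        sums = self.proportions_mean.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("mixing proportions must sum to one per sink")


# ---------------------------------------------------------------------------
# numba kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _gibbs_one_sink(
    read_otu, phi, beta, alpha2, restarts, burnin, draws_per_restart, delay, seed, use_unknown
):  # pragma: no cover - exercised via gibbs_fit
    N = read_otu.size
    V = phi.shape[0]
    T = phi.shape[1]
    VU = V + 1 if use_unknown else V
    a2N = alpha2 * N
    a2NT = alpha2 * N * T
    n_draws = restarts * draws_per_restart
    props = np.zeros((n_draws, VU))
    otu_frac = np.zeros((T, VU))
    reads_per_otu = np.zeros(T, dtype=np.int64)
    for i in range(N):
        reads_per_otu[read_otu[i]] += 1

    np.random.seed(seed)
    z = np.empty(N, dtype=np.int64)
    n = np.zeros(VU, dtype=np.int64)
    u = np.zeros(T, dtype=np.int64)
    w = np.empty(VU)
    d_out = 0
    for _ in range(restarts):
        # uniform random initialization of the assignment vector
        n[:] = 0
        u[:] = 0
        u_tot = 0
        for i in range(N):
            v0 = np.random.randint(0, VU)
            z[i] = v0
            n[v0] += 1
            if use_unknown and v0 == V:
                u[read_otu[i]] += 1
                u_tot += 1
        for d in range(draws_per_restart):
            sweeps = burnin + delay if d == 0 else delay
            for _s in range(sweeps):
                for i in range(N):
                    t = read_otu[i]
                    v_old = z[i]
                    n[v_old] -= 1
                    if use_unknown and v_old == V:
                        u[t] -= 1
                        u_tot -= 1
                    tot = 0.0
                    for v in range(V):
                        w[v] = (n[v] + beta) * phi[v, t]
                        tot += w[v]
                    if use_unknown:
                        w[V] = (n[V] + beta) * (u[t] + a2N) / (u_tot + a2NT)
                        tot += w[V]
                    r = np.random.random() * tot
                    acc = 0.0
                    v_new = VU - 1
                    for v in range(VU):
                        acc += w[v]
                        if r <= acc:
                            v_new = v
                            break
                    z[i] = v_new
                    n[v_new] += 1
                    if use_unknown and v_new == V:
                        u[t] += 1
                        u_tot += 1
            # record the retained draw
            for v in range(VU):
                props[d_out, v] = n[v] / N
            counts_tv = np.zeros((T, VU), dtype=np.int64)
            for i in range(N):
                counts_tv[read_otu[i], z[i]] += 1
            for t in range(T):
                if reads_per_otu[t] > 0:
                    for v in range(VU):
                        otu_frac[t, v] += counts_tv[t, v] / reads_per_otu[t]
            d_out += 1
    otu_frac /= n_draws
    return props, otu_frac, reads_per_otu


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _training_matrix(library: "SourceLibrary", otu_union: pd.Index, p: STParams) -> tuple[list[str], np.ndarray]:
    """Per-source pooled training counts on the aligned OTU space."""
    table = library.table
    counts = table.counts
    depth = p.train_rarefaction_depth
    if depth:
        totals = counts.sum(axis=1)
        if (totals >= depth).all():
            counts = rarefy(table, depth, np.random.default_rng(p.seed)).counts
        else:
            warnings.warn(
                "training samples below the rarefaction depth; using raw counts",
                stacklevel=2,
            )
    names = list(library.sources)
    m = np.zeros((len(names), len(otu_union)))
    aligned = counts.reindex(columns=otu_union, fill_value=0)
    for k, name in enumerate(names):
        ids = [s for s in library.sources[name] if s in aligned.index]
        if not ids:
            raise ValueError(f"source {name!r} has no training samples after rarefaction")
        m[k] = aligned.loc[ids].sum(axis=0).to_numpy()
    return names, m


def gibbs_fit(
    library: "SourceLibrary",
    sinks: OTUTable,
    p: STParams,
    unknown: bool = True,
) -> MSTResult:
    """Run the collapsed Gibbs sampler for every sink against ``library``.

    Sinks are left unrarefied unless ``p.rarefy_sinks`` is set; training
    samples are rarefied to ``p.train_rarefaction_depth`` when they are deep
    enough. OTU spaces are aligned on the union, zero-filled.
    """
    if sinks.n_samples == 0:
        raise ValueError("no sink samples")
    otu_union = library.table.counts.columns.union(sinks.counts.columns, sort=False)
    names, m = _training_matrix(library, otu_union, p)
    T = len(otu_union)
    phi = (m + p.alpha1) / (m.sum(axis=1, keepdims=True) + p.alpha1 * T)

    sink_counts = sinks.counts.reindex(columns=otu_union, fill_value=0)
    if p.rarefy_sinks and p.train_rarefaction_depth:
        sink_tab = rarefy(
            OTUTable(sink_counts, sinks.sample_meta, None),
            p.train_rarefaction_depth,
            np.random.default_rng(p.seed + 1),
        )
        sink_counts = sink_tab.counts

    out_names = names + [UNKNOWN] if unknown else list(names)
    means, sds = [], []
    posteriors: dict[str, pd.DataFrame] = {}
    draws: dict[str, np.ndarray] = {}
    root = np.random.SeedSequence(p.seed)
    for idx, sid in enumerate(sink_counts.index):
        row = sink_counts.loc[sid].to_numpy()
        N = int(row.sum())
        if N == 0:
            raise ValueError(f"sink {sid!r} has zero reads")
        read_otu = np.repeat(np.arange(T), row).astype(np.int64)
        kernel_seed = int(np.random.SeedSequence((p.seed, idx)).generate_state(1)[0] % (2**31))
        props, otu_frac, reads_per_otu = _gibbs_one_sink(
            read_otu,
            phi,
            float(p.beta),
            float(p.alpha2),
            p.restarts,
            p.burnin,
            p.draws_per_restart,
            p.delay,
            kernel_seed,
            unknown,
        )
        means.append(props.mean(axis=0))
        sds.append(props.std(axis=0, ddof=1) if props.shape[0] > 1 else np.zeros(props.shape[1]))
        observed = reads_per_otu > 0
        post = otu_frac[observed]
        post = post / post.sum(axis=1, keepdims=True)
        posteriors[sid] = pd.DataFrame(post, index=otu_union[observed], columns=out_names)
        draws[sid] = props
    mean_df = pd.DataFrame(means, index=sink_counts.index, columns=out_names)
    sd_df = pd.DataFrame(sds, index=sink_counts.index, columns=out_names)
    return MSTResult(out_names, mean_df, sd_df, posteriors, draws, sink_counts)


def otu_source_posteriors(r: MSTResult, sink_id: str) -> pd.DataFrame:
    """Per-OTU source posterior for one fitted sink (rows sum to one).

    Rows are restricted to OTUs with at least one sink read; an OTU's entry for
    source ``v`` is the average fraction of its reads assigned to ``v`` across
    retained draws, renormalized per row.
    """
    if sink_id not in r.otu_posteriors:
        raise KeyError(f"sink {sink_id!r} was not fitted")
    return r.otu_posteriors[sink_id]


# ---------------------------------------------------------------------------
# leave-one-out cross-validation
# ---------------------------------------------------------------------------

@dataclass
class LOOCVResult:
    proportions: pd.DataFrame       # sample x known sources (+ Unknown)
    true_source: pd.Series
    predicted: pd.Series            # argmax over known sources
    confusion: pd.DataFrame
    accuracy: float


def loo_crossvalidation(library: "SourceLibrary", p: STParams, unknown: bool = True) -> LOOCVResult:
    """Each library sample in turn becomes the sink against the rest of the library."""
    from .library_builder import SourceLibrary  # local import to avoid a cycle

    for name, ids in library.sources.items():
        if len(ids) < 2:
            raise ValueError(f"source {name!r} has a single sample; LOO-CV undefined")
    rows, truth = [], []
    sample_order: list[str] = []
    for name, ids in library.sources.items():
        for sid in ids:
            reduced_sources = {
                n: [s for s in ss if s != sid] for n, ss in library.sources.items()
            }
            reduced = SourceLibrary(
                table=library.table.subset_samples(
                    [s for s in library.table.sample_ids if s != sid]
                ),
                sources=reduced_sources,
                background_mode=library.background_mode,
                background_samples=[s for s in library.background_samples if s != sid],
            )
            sink = library.table.subset_samples([sid])
            fit = gibbs_fit(reduced, sink, p, unknown=unknown)
            rows.append(fit.proportions_mean.loc[sid])
            truth.append(name)
            sample_order.append(sid)
    props = pd.DataFrame(rows, index=sample_order)
    known = [c for c in props.columns if c != UNKNOWN]
    predicted = props[known].idxmax(axis=1)
    true_s = pd.Series(truth, index=sample_order)
    names = list(library.sources)
    confusion = pd.crosstab(true_s, predicted).reindex(index=names, columns=names, fill_value=0)
    accuracy = float((predicted == true_s).mean())
    return LOOCVResult(props, true_s, predicted, confusion, accuracy)
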