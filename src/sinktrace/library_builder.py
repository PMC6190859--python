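"""Construction of source-tracking libraries under the three background
strategies, plus the Dirichlet-multinomial mixture (DMM) machinery used by the
cluster-selected background.

Library modes
-------------
WB   fecal/sewage sources only, no background water source.
DM   WB sources plus a background source chosen by DMM clustering: candidates
     passing the FIB screen and a preliminary source-tracking screen are
     clustered together with the sink for k = 2..8 components; the fits are
     ranked by the Laplace model-selection score and the ranking is walked
     until the sink's component contains an acceptable number (10-25) of water
     communities, which become the background source.
LB   WB sources plus water communities from the sink's own location that pass
     the FIB screen (E. coli < 25 MPN/100 ml, coliforms < 100 MPN/100 ml) and
     assign to the non-fecal fraction with probability >= 0.99 in a
     preliminary source-tracking run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, polygamma, psi

from .otu_io import OTUTable
from .source_tracker import STParams, UNKNOWN, gibbs_fit

BACKGROUND = "Background"


class LibraryError(ValueError):
    """A constructed library violates the library invariants."""


@dataclass
class SourceLibrary:
    """A named set of training sources plus an optional background source."""

    table: OTUTable
    sources: dict[str, list[str]]
    background_mode: str = "WB"                 # WB | DM | LB
    background_samples: list[str] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    @property
    def fecal_sources(self) -> list[str]:
        return [s for s in self.sources if s != BACKGROUND]

    def validate(self, n_min: int = 10, n_max: int = 25, min_reads: int = 15_000) -> None:
        totals = self.table.sample_totals()
        for name, ids in self.sources.items():
            if not (n_min <= len(ids) <= n_max):
                raise LibraryError(
                    f"source {name!r} has {len(ids)} samples, outside [{n_min}, {n_max}]"
                )
            low = [s for s in ids if totals[s] <= min_reads]
            if low:
                raise LibraryError(f"source {name!r} has samples at <= {min_reads} reads: {low}")


# ---------------------------------------------------------------------------
# FIB screening and the preliminary MST screen
# ---------------------------------------------------------------------------

def fib_candidates(
    meta: pd.DataFrame, ecoli_max: float = 25.0, coliform_max: float = 100.0
) -> list[str]:
    """Samples uncontaminated by fecal-indicator levels (strict inequalities).

    Samples with missing FIB values are excluded with a warning.
    """
    if "ecoli_mpn" not in meta.columns or "coliform_mpn" not in meta.columns:
        raise ValueError("metadata lacks FIB columns")
    ecoli = pd.to_numeric(meta["ecoli_mpn"], errors="coerce")
    coli = pd.to_numeric(meta["coliform_mpn"], errors="coerce")
    missing = meta.index[ecoli.isna() | coli.isna()]
    if len(missing):
        warnings.warn(f"excluding {len(missing)} sample(s) with missing FIB values", stacklevel=2)
    keep = (ecoli < ecoli_max) & (coli < coliform_max)
    return list(meta.index[keep.fillna(False)])


def preliminary_screen(
    candidates: OTUTable,
    fecal_library: SourceLibrary,
    p: STParams,
    min_background_prob: float = 0.99,
) -> list[str]:
    """Retain candidates whose estimated non-fecal assignment probability
    (background water source plus Unknown) reaches ``min_background_prob``.

    Each candidate is screened against the fecal sources plus a provisional
    background source formed by the remaining candidates (leave-one-out), so
    that shared water OTUs compete against a genuine water source rather than
    being absorbed by overlapping fecal sources. Candidates below the
    threshold are treated as contaminated (e.g. during sample processing) and
    dropped from the background pool.
    """
    if candidates.n_samples == 0:
        raise ValueError("empty candidate set")
    kept: list[str] = []
    cols = fecal_library.table.counts.columns.union(candidates.counts.columns, sort=False)
    for sid in candidates.sample_ids:
        others = [s for s in candidates.sample_ids if s != sid]
        if others:
            merged = pd.concat(
                [
                    fecal_library.table.counts.reindex(columns=cols, fill_value=0),
                    candidates.counts.loc[others].reindex(columns=cols, fill_value=0),
                ]
            )
            meta = pd.concat(
                [fecal_library.table.sample_meta, candidates.sample_meta.loc[others]]
            )
            sources = dict(fecal_library.sources)
            sources[BACKGROUND] = others
            lib = SourceLibrary(OTUTable(merged, meta), sources, "WB")
        else:
            lib = fecal_library
        fit = gibbs_fit(lib, candidates.subset_samples([sid]), p, unknown=True)
        non_fecal_cols = [c for c in fit.proportions_mean.columns if c in (UNKNOWN, BACKGROUND)]
        non_fecal = float(fit.proportions_mean.loc[sid, non_fecal_cols].sum())
        if non_fecal >= min_background_prob:
            kept.append(sid)
    return kept


# ---------------------------------------------------------------------------
# Dirichlet-multinomial mixture
# ---------------------------------------------------------------------------

@dataclass
class DMMFit:
    """A fitted k-component Dirichlet-multinomial mixture."""

    k: int
    alphas: np.ndarray                 # (k, T) strictly positive
    weights: np.ndarray                # (k,) summing to one
    responsibilities: pd.DataFrame     # sample x component, rows sum to one
    hard_assignments: pd.Series        # sample -> argmax component
    laplace: float
    log_likelihood: float
    converged: bool
    flagged: bool = False
    otu_ids: list[str] = field(default_factory=list)
    counts: np.ndarray | None = field(default=None, repr=False)
    loglik_trace: list[float] = field(default_factory=list, repr=False)


def _dm_loglik_rows(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-sample Dirichlet-multinomial log-likelihood (multinomial coefficient
    omitted; it is constant across components and k)."""
    A = alpha.sum()
    N = X.sum(axis=1)
    return (
        gammaln(A)
        - gammaln(N + A)
        + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1)
    )


def _weighted_dm_negloglik(theta: np.ndarray, X: np.ndarray, w: np.ndarray) -> tuple[float, np.ndarray]:
    alpha = np.exp(theta)
    A = alpha.sum()
    N = X.sum(axis=1)
    ll = w @ (
        gammaln(A) - gammaln(N + A) + (gammaln(X + alpha) - gammaln(alpha)).sum(axis=1)
    )
    g_A = w @ (psi(A) - psi(N + A))
    g_t = w @ (psi(X + alpha) - psi(alpha)) + g_A
    return -ll, -(alpha * g_t)


def _moment_init(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Moment-matching initial Dirichlet parameters for a weighted sample."""
    N = X.sum(axis=1, keepdims=True)
    P = X / np.maximum(N, 1)
    wn = w / w.sum()
    pbar = wn @ P
    var = wn @ (P - pbar) ** 2
    mask = (pbar > 1e-8) & (var > 1e-12)
    if mask.sum() >= 2:
        ratios = pbar[mask] * (1 - pbar[mask]) / var[mask] - 1.0
        A = float(np.clip(np.median(ratios), 1e-2, 1e6))
    else:
        A = 1.0
    return np.maximum(A * pbar, 1e-6)


def _fit_component(X: np.ndarray, w: np.ndarray, alpha0: np.ndarray | None) -> tuple[np.ndarray, float]:
    """Weighted DM maximum likelihood for one component (quasi-Newton on log-alpha)."""
    if alpha0 is None:
        alpha0 = _moment_init(X, w)
    theta0 = np.log(np.maximum(alpha0, 1e-8))
    res = minimize(
        _weighted_dm_negloglik,
        theta0,
        args=(X, w),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-20.0, 12.0)] * len(theta0),
        options={"maxiter": 60, "ftol": 1e-10},
    )
    f0 = _weighted_dm_negloglik(theta0, X, w)[0]
    if res.fun <= f0:
        return np.exp(res.x), -res.fun
    return np.exp(theta0), -f0


def dmm_fit(t: OTUTable, k: int, seed: int, max_iter: int = 100, tol: float = 1e-6) -> DMMFit:
    """Fit a k-component Dirichlet-multinomial mixture by EM.

    The E-step computes responsibilities from component DM likelihoods and
    mixture weights; the M-step re-estimates each component's Dirichlet
    parameters by quasi-Newton maximization of the weighted DM log-likelihood
    (moment-matching initialization, warm-started across iterations). The
    observed-data log-likelihood is monitored and non-decreasing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if t.n_samples == 0 or t.n_otus == 0:
        raise ValueError("empty table")
    nonzero = t.counts.sum(axis=0) > 0
    otu_ids = list(t.counts.columns[nonzero])
    X = t.counts.loc[:, nonzero].to_numpy(dtype=np.float64)
    n = X.shape[0]

    # initial responsibilities: k-means on sqrt relative abundances
    R = np.full((n, k), 1.0 / k)
    if k > 1:
        from sklearn.cluster import KMeans

        P = np.sqrt(X / X.sum(axis=1, keepdims=True))
        labels = KMeans(n_clusters=k, n_init=4, random_state=seed % (2**31)).fit_predict(P)
        R = np.full((n, k), 0.05 / max(k - 1, 1))
        R[np.arange(n), labels] = 0.95

    alphas: list[np.ndarray | None] = [None] * k
    weights = np.full(k, 1.0 / k)
    prev_ll = -np.inf
    converged = False
    trace: list[float] = []
    logp = np.empty((n, k))
    for _ in range(max_iter):
        # M-step
        new_alphas = []
        for c in range(k):
            w = np.maximum(R[:, c], 1e-10)
            a, _ = _fit_component(X, w, alphas[c])
            new_alphas.append(a)
        alphas = new_alphas
        weights = np.maximum(R.mean(axis=0), 1e-12)
        weights = weights / weights.sum()
        # E-step
        for c in range(k):
            logp[:, c] = _dm_loglik_rows(X, alphas[c]) + np.log(weights[c])
        ll = float(logsumexp(logp, axis=1).sum())
        trace.append(ll)
        R = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol * (1 + abs(prev_ll)):
            prev_ll = ll
            converged = True
            break
        prev_ll = ll
    if not converged:
        warnings.warn(f"DMM EM (k={k}) did not converge in {max_iter} iterations", stacklevel=2)

    A = np.vstack([np.asarray(a) for a in alphas])
    resp = pd.DataFrame(R, index=t.sample_ids, columns=[f"C{c + 1}" for c in range(k)])
    hard = resp.idxmax(axis=1)
    fit = DMMFit(
        k=k,
        alphas=A,
        weights=weights,
        responsibilities=resp,
        hard_assignments=hard,
        laplace=np.nan,
        log_likelihood=prev_ll,
        converged=converged,
        otu_ids=otu_ids,
        counts=X,
        loglik_trace=trace,
    )
    fit.laplace = laplace_score(fit)
    return fit


def laplace_score(f: DMMFit) -> float:
    """Laplace approximation to the negative log model evidence (lower = better).

    Computed as ``-logL - (d/2) log 2π + 0.5 log|H|`` at the fitted mode with a
    flat prior on the Dirichlet parameters, where ``H`` is the negative
    Hessian of the log-likelihood in (per-component Dirichlet parameters, free
    mixture weights). The per-component Hessian is diagonal-plus-rank-one, so
    its determinant is exact; near-singular directions are floored and the
    fit flagged.
    """
    X, R = f.counts, f.responsibilities.to_numpy()
    if X is None:
        raise ValueError("fit carries no data; cannot score")
    n, T = X.shape
    N = X.sum(axis=1)
    logdet = 0.0
    d_total = f.k * T + (f.k - 1)
    flagged = False
    for c in range(f.k):
        w = np.maximum(R[:, c], 1e-10)
        alpha = f.alphas[c]
        A = alpha.sum()
        # Hessian of the weighted log-likelihood wrt alpha: diag(d_t) + c1 * J
        c1 = float(w @ (polygamma(1, A) - polygamma(1, N + A)))
        d_t = w @ (polygamma(1, X + alpha) - polygamma(1, alpha))
        # negative Hessian, diag(m) + (-c1) J; determinant by the matrix lemma
        m = -d_t
        if (m <= 1e-12).any():
            m = np.maximum(m, 1e-12)
            flagged = True
        lemma = 1.0 + (-c1) * float((1.0 / m).sum())
        if lemma <= 1e-10:
            lemma = 1e-10
            flagged = True
        logdet += float(np.log(m).sum()) + np.log(lemma)
    if f.k > 1:
        nhat = np.maximum(R.sum(axis=0), 1e-10)
        wv = f.weights
        diag = nhat[:-1] / wv[:-1] ** 2
        lemma_w = 1.0 + (nhat[-1] / wv[-1] ** 2) * float((1.0 / diag).sum())
        logdet += float(np.log(diag).sum()) + np.log(max(lemma_w, 1e-10))
    f.flagged = f.flagged or flagged
    return float(-f.log_likelihood - 0.5 * d_total * np.log(2 * np.pi) + 0.5 * logdet)


def select_background_dm(
    sink_id: str,
    candidates: OTUTable,
    k_min: int = 2,
    k_max: int = 8,
    n_min: int = 10,
    n_max: int = 25,
    seed: int = 0,
    exclude: Sequence[str] = (),
    fits: dict[int, DMMFit] | None = None,
) -> tuple[list[str], dict]:
    """Choose background communities by walking the Laplace ranking of DMM fits.

    ``candidates`` must include the sink's own counts. For each k in
    [k_min, k_max] (best Laplace score first) the sink's component is
    inspected; the first fit whose component holds between ``n_min`` and
    ``n_max`` other communities (ids in ``exclude`` — e.g. other sinks — never
    count) wins. If no fit qualifies, the ``n_max`` candidates nearest to the
    sink by responsibility similarity in the best-scoring fit are taken and
    the selection is flagged.
    """
    if sink_id not in candidates.sample_ids:
        raise ValueError("candidates must include the sink sample")
    pool = [s for s in candidates.sample_ids if s != sink_id and s not in set(exclude)]
    if len(pool) < n_min:
        raise LibraryError(f"only {len(pool)} candidates available; need at least {n_min}")
    if fits is None:
        fits = {}
    for k in range(k_min, k_max + 1):
        if k not in fits:
            fits[k] = dmm_fit(candidates, k, seed=seed + k)
    ranked = sorted(fits.values(), key=lambda f: f.laplace)
    info: dict = {"ranking": [(f.k, f.laplace) for f in ranked], "fallback": False}
    for f in ranked:
        comp = f.hard_assignments[sink_id]
        members = [s for s in f.hard_assignments.index[f.hard_assignments == comp] if s in pool]
        if n_min <= len(members) <= n_max:
            info.update(k=f.k, component=comp)
            return members, info
    best = ranked[0]
    sink_r = best.responsibilities.loc[sink_id].to_numpy()
    dist = ((best.responsibilities.loc[pool].to_numpy() - sink_r) ** 2).sum(axis=1)
    order = [pool[i] for i in np.argsort(dist, kind="stable")]
    info.update(k=best.k, component=best.hard_assignments[sink_id], fallback=True)
    return order[:n_max], info


# ---------------------------------------------------------------------------
# library assembly
# ---------------------------------------------------------------------------

def _trim_source(ids: list[str], meta: pd.DataFrame, n_max: int) -> list[str]:
    """Drop the newest samples from the most-represented location until <= n_max."""
    kept = list(ids)
    while len(kept) > n_max:
        sub = meta.loc[kept]
        if "location" in sub.columns and sub["location"].notna().any():
            top_loc = sub["location"].value_counts().idxmax()
            group = sub[sub["location"] == top_loc]
        else:
            group = sub
        if "date" in group.columns and group["date"].notna().any():
            victim = group["date"].idxmax()
        else:
            victim = sorted(group.index)[-1]
        kept.remove(victim)
    return kept


def _fecal_sources(
    fecal_table: OTUTable, n_min: int, n_max: int, min_reads: int, provenance: list[str]
) -> dict[str, list[str]]:
    totals = fecal_table.sample_totals()
    env = fecal_table.environments()
    sources: dict[str, list[str]] = {}
    for name in env.unique():
        ids = [s for s in env.index[env == name]]
        deep = [s for s in ids if totals[s] > min_reads]
        for s in set(ids) - set(deep):
            provenance.append(f"excluded {s}: <= {min_reads} reads")
        if len(deep) > n_max:
            trimmed = _trim_source(deep, fecal_table.sample_meta, n_max)
            for s in set(deep) - set(trimmed):
                provenance.append(f"excluded {s}: source {name} trimmed to {n_max}")
            deep = trimmed
        if len(deep) < n_min:
            raise LibraryError(f"source {name!r} has only {len(deep)} usable samples")
        sources[str(name)] = deep
    return sources


def build_library(
    mode: str,
    fecal_table: OTUTable,
    water_table: OTUTable,
    sink_id: str,
    p: STParams,
    *,
    sink_table: OTUTable | None = None,
    n_min: int = 10,
    n_max: int = 25,
    min_reads: int = 15_000,
    min_background_prob: float = 0.99,
    dm_candidate_scope: str = "all",      # "all" or "location"
    dm_extra_samples: OTUTable | None = None,
    dmm_seed: int | None = None,
    dmm_fits: dict[int, DMMFit] | None = None,
    prescreened: list[str] | None = None,
) -> SourceLibrary:
    """Assemble a WB, DM or LB source library for one sink.

    ``prescreened`` short-circuits the FIB + preliminary screens with an
    already-screened candidate id list (the pipeline screens once for all
    sinks). ``dm_extra_samples`` lets the DM clustering include additional sink
    communities (they are never selected as background); ``dmm_fits`` caches
    fitted mixtures across sinks sharing a candidate pool.
    """
    mode = mode.upper()
    if mode not in {"WB", "DM", "LB"}:
        raise ValueError(f"unknown library mode {mode!r}")
    provenance: list[str] = []
    sources = _fecal_sources(fecal_table, n_min, n_max, min_reads, provenance)
    fecal_ids = [s for ids in sources.values() for s in ids]
    lib = SourceLibrary(
        table=fecal_table.subset_samples(fecal_ids),
        sources=sources,
        background_mode=mode,
        provenance=provenance,
    )
    if mode == "WB":
        lib.validate(n_min, n_max, min_reads)
        return lib

    sink_tab = sink_table if sink_table is not None else water_table
    if sink_id not in sink_tab.sample_ids:
        raise ValueError(f"sink {sink_id!r} not found")
    sink_meta = sink_tab.sample_meta.loc[sink_id]

    water_meta = water_table.sample_meta
    is_water = water_meta.get("environment", pd.Series("water", index=water_meta.index)) != "sink"
    pool_ids = [s for s in water_meta.index[is_water] if s != sink_id]
    if mode == "LB":
        loc = sink_meta.get("location")
        pool_ids = [s for s in pool_ids if water_meta.loc[s, "location"] == loc]
        if not pool_ids:
            raise LibraryError(f"no water samples at sink location {loc!r}")
    elif dm_candidate_scope == "location":
        loc = sink_meta.get("location")
        pool_ids = [s for s in pool_ids if water_meta.loc[s, "location"] == loc]

    if prescreened is not None:
        screened = [s for s in prescreened if s in pool_ids]
        provenance.append(f"{len(screened)} candidates taken from pre-screened pool")
    else:
        fib_ok = [s for s in fib_candidates(water_meta.loc[pool_ids]) if s in pool_ids]
        for s in set(pool_ids) - set(fib_ok):
            provenance.append(f"excluded {s}: FIB screen")
        wb = SourceLibrary(lib.table, dict(sources), "WB")
        screened = preliminary_screen(
            water_table.subset_samples(fib_ok), wb, p, min_background_prob
        )
        for s in set(fib_ok) - set(screened):
            provenance.append(f"excluded {s}: preliminary MST screen (< {min_background_prob})")

    if mode == "LB":
        background = screened
        if len(background) > n_max:
            background = _trim_source(background, water_meta, n_max)
        if len(background) < n_min:
            raise LibraryError(f"only {len(background)} local background samples; need {n_min}")
        provenance.append(f"LB background: {len(background)} samples at {sink_meta.get('location')}")
    else:
        cand_ids = list(screened)
        cand = water_table.subset_samples(cand_ids)
        extra_ids: list[str] = []
        parts = [cand.counts]
        metas = [cand.sample_meta]
        if dm_extra_samples is not None:
            extra_ids = [s for s in dm_extra_samples.sample_ids if s != sink_id]
            extra = dm_extra_samples.subset_samples(extra_ids)
            parts.append(extra.counts.reindex(columns=cand.counts.columns, fill_value=0))
            metas.append(extra.sample_meta)
        sink_row = sink_tab.subset_samples([sink_id])
        parts.append(sink_row.counts.reindex(columns=cand.counts.columns, fill_value=0))
        metas.append(sink_row.sample_meta)
        pool_tab = OTUTable(pd.concat(parts), pd.concat(metas))
        background, info = select_background_dm(
            sink_id,
            pool_tab,
            n_min=n_min,
            n_max=n_max,
            seed=p.seed if dmm_seed is None else dmm_seed,
            exclude=extra_ids,
            fits=dmm_fits,
        )
        provenance.append(f"DM background: k={info.get('k')} fallback={info['fallback']}")

    bg_tab = water_table.subset_samples(background)
    all_cols = lib.table.counts.columns.union(bg_tab.counts.columns, sort=False)
    merged_counts = pd.concat(
        [
            lib.table.counts.reindex(columns=all_cols, fill_value=0),
            bg_tab.counts.reindex(columns=all_cols, fill_value=0),
        ]
    )
    merged_meta = pd.concat([lib.table.sample_meta, bg_tab.sample_meta])
    table = OTUTable(merged_counts, merged_meta, fecal_table.taxonomy)
    sources = dict(sources)
    sources[BACKGROUND] = list(background)
    out = SourceLibrary(table, sources, mode, list(background), provenance)
    out.validate(n_min, n_max, min_reads)
    return out
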