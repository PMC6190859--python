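"""End-to-end orchestration: build libraries in one or more background modes,
run source tracking per sink, score the signals, and (when all three modes
ran) fit the two hierarchical Bayesian models.

A single master seed fans out to per-stage seeds through a fixed counter
scheme (`SeedSequence((master, stage))`, stages numbered 0 = data,
1 = source tracking, 2 = DMM clustering, 3 = model 1, 4 = model 2), so any
stage can be rerun in isolation. Every sample excluded by a screening rule is
logged to an exclusions table with the rule that fired.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes_models as bm
from .library_builder import (
    SourceLibrary,
    build_library,
    fib_candidates,
    preliminary_screen,
    _fecal_sources,
)
from .otu_io import OTUTable, filter_low_abundance, read_otu_table
from .signal_metrics import call_contamination, signal_summaries, total_contamination
from .source_tracker import STParams, gibbs_fit, MSTResult
from .synthetic import ScenarioSpec, generate_scenario, true_contamination

MODES = ("WB", "DM", "LB")


@dataclass
class RunConfig:
    scenario: ScenarioSpec | None = None      # synthetic mode when set
    fecal_table: str | None = None            # otherwise TSV paths
    fecal_meta: str | None = None
    water_table: str | None = None
    water_meta: str | None = None
    sinks_table: str | None = None
    sinks_meta: str | None = None
    modes: tuple[str, ...] = MODES
    st: STParams = field(default_factory=STParams)
    p_hi: float = 0.7
    p_floor: float = 0.1
    min_prop: float = 0.003
    ecoli_max: float = 25.0
    coliform_max: float = 100.0
    min_background_prob: float = 0.99
    exclusion_window_h: float = 48.0
    n_min: int = 10
    n_max: int = 25
    min_reads: int = 15_000
    apply_abundance_filter: bool = True
    mcmc_chains: int = 8
    mcmc_iterations: int = 1000
    mcmc_burnin: int = 500
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        self.modes = tuple(m.upper() for m in self.modes)
        bad = set(self.modes) - set(MODES)
        if bad:
            raise ValueError(f"unknown modes: {sorted(bad)}")
        for v in (self.p_hi, self.p_floor, self.min_prop, self.min_background_prob):
            if not (0 <= v <= 1):
                raise ValueError("thresholds must lie in [0, 1]")

    def stage_seed(self, stage: int) -> int:
        return int(np.random.SeedSequence((self.seed, stage)).generate_state(1)[0] % (2**31))


@dataclass
class ReportBundle:
    results: dict[str, MSTResult]
    signals: pd.DataFrame                  # Table-4-shaped per-signal summaries
    totals: pd.DataFrame                   # sink x mode total contamination (+ FIB, stratum)
    calls: pd.DataFrame
    strata_means: pd.DataFrame             # Table-3-shaped means by quality stratum
    correlations: pd.DataFrame | None = None
    accuracy_coefficients: pd.DataFrame | None = None
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)
    truth: object | None = None
    mvglmm: bm.GLMMPosterior | None = None
    accuracy_glmm: bm.GLMMPosterior | None = None


def _load_tables(cfg: RunConfig):
    if cfg.scenario is not None:
        spec = replace(cfg.scenario)
        fecal, water, sinks, truth = generate_scenario(spec, cfg.stage_seed(0))
        return fecal, water, sinks, truth
    paths = (cfg.fecal_table, cfg.fecal_meta, cfg.water_table, cfg.water_meta,
             cfg.sinks_table, cfg.sinks_meta)
    if any(p is None for p in paths):
        raise ValueError("either a scenario or all six table/metadata paths are required")
    fecal = read_otu_table(cfg.fecal_table, cfg.fecal_meta)
    water = read_otu_table(cfg.water_table, cfg.water_meta)
    sinks = read_otu_table(cfg.sinks_table, cfg.sinks_meta)
    return fecal, water, sinks, None


def _apply_filter(fecal: OTUTable, water: OTUTable, sinks: OTUTable):
    cols = fecal.counts.columns.union(water.counts.columns).union(sinks.counts.columns)
    merged = pd.concat(
        [t.counts.reindex(columns=cols, fill_value=0) for t in (fecal, water, sinks)]
    )
    meta = pd.concat([t.sample_meta for t in (fecal, water, sinks)])
    filtered = filter_low_abundance(OTUTable(merged, meta))
    keep = filtered.counts.columns

    def cut(t: OTUTable) -> OTUTable:
        kept = [c for c in keep if c in t.counts.columns]
        return t.subset_otus(kept)

    return cut(fecal), cut(water), cut(sinks)


def run_experiment(cfg: RunConfig) -> ReportBundle:
    """Run the configured analysis and return (and optionally write) the report
    bundle: per-mode proportions, signal summaries, contamination calls and,
    with all three modes, the correlation and accuracy-model tables."""
    fecal, water, sinks, truth = _load_tables(cfg)
    if cfg.apply_abundance_filter:
        fecal, water, sinks = _apply_filter(fecal, water, sinks)

    st = replace(cfg.st, seed=cfg.stage_seed(1))
    exclusions: list[dict] = []

    # ---- screen background candidates once (FIB rule + preliminary MST) ----
    water_meta = water.sample_meta
    prov: list[str] = []
    wb_sources = _fecal_sources(fecal, cfg.n_min, cfg.n_max, cfg.min_reads, prov)
    wb_lib = SourceLibrary(
        fecal.subset_samples([s for ids in wb_sources.values() for s in ids]),
        wb_sources,
        "WB",
        provenance=prov,
    )
    screened: list[str] = []
    if set(cfg.modes) - {"WB"}:
        fib_ok = fib_candidates(water_meta, cfg.ecoli_max, cfg.coliform_max)
        for s in set(water.sample_ids) - set(fib_ok):
            exclusions.append({"sample_id": s, "rule": "FIB screen"})
        totals_w = water.sample_totals()
        deep = [s for s in fib_ok if totals_w[s] > cfg.min_reads]
        for s in set(fib_ok) - set(deep):
            exclusions.append({"sample_id": s, "rule": f"<= {cfg.min_reads} reads"})
        screened = preliminary_screen(
            water.subset_samples(deep), wb_lib, st, cfg.min_background_prob
        )
        for s in set(deep) - set(screened):
            exclusions.append(
                {"sample_id": s, "rule": f"preliminary MST screen (< {cfg.min_background_prob})"}
            )

    # ---- fit each mode ----------------------------------------------------
    results: dict[str, MSTResult] = {}
    dmm_cache: dict[int, object] = {}
    for mode in cfg.modes:
        if mode == "WB":
            results[mode] = gibbs_fit(wb_lib, sinks, st)
        elif mode == "LB":
            parts = []
            for loc, group in sinks.sample_meta.groupby("location"):
                sink_ids = list(group.index)
                lib = build_library(
                    "LB", fecal, water, sink_ids[0], st,
                    sink_table=sinks, n_min=cfg.n_min, n_max=cfg.n_max,
                    min_reads=cfg.min_reads, prescreened=screened,
                )
                parts.append(gibbs_fit(lib, sinks.subset_samples(sink_ids), st))
            results[mode] = _merge_results(parts)
        else:  # DM
            parts = []
            for sid in sinks.sample_ids:
                lib = build_library(
                    "DM", fecal, water, sid, st,
                    sink_table=sinks, n_min=cfg.n_min, n_max=cfg.n_max,
                    min_reads=cfg.min_reads, prescreened=screened,
                    dm_extra_samples=sinks, dmm_seed=cfg.stage_seed(2),
                    dmm_fits=dmm_cache,
                )
                parts.append(gibbs_fit(lib, sinks.subset_samples([sid]), st))
            results[mode] = _merge_results(parts)

    # ---- score ------------------------------------------------------------
    sig_frames = []
    for mode, r in results.items():
        df = signal_summaries(r, cfg.p_hi, cfg.p_floor)
        df.insert(0, "setup", mode)
        sig_frames.append(df)
    signals = pd.concat(sig_frames, ignore_index=True)

    totals = pd.DataFrame(
        {
            mode: total_contamination(results[mode], include_unknown=(mode != "WB"))
            for mode in cfg.modes
        }
    )
    fib_cols = [c for c in ("ecoli_mpn", "coliform_mpn", "enterococci_mpn")
                if c in sinks.sample_meta.columns]
    for c in fib_cols:
        totals[c] = sinks.sample_meta.loc[totals.index, c]
    if fib_cols:
        good = (
            (totals.get("ecoli_mpn", 0) < cfg.ecoli_max)
            & (totals.get("coliform_mpn", 0) < cfg.coliform_max)
        )
        totals["quality"] = np.where(good, "good", "poor")

    call_rows = []
    for mode, r in results.items():
        for sid, called in call_contamination(r, cfg.min_prop, include_unknown=(mode != "WB")).items():
            call_rows.append({"setup": mode, "sink_id": sid, "called_sources": ";".join(called)})
    calls = pd.DataFrame(call_rows)

    strata = []
    if "quality" in totals.columns:
        for mode in cfg.modes:
            for q, grp in totals.groupby("quality"):
                strata.append(
                    {
                        "setup": mode,
                        "quality": q,
                        "unknown_added": mode != "WB",
                        "n": len(grp),
                        "mean_contamination": grp[mode].mean(),
                        "sd_contamination": grp[mode].std(ddof=1),
                    }
                )
    strata_means = pd.DataFrame(strata)

    # ---- Bayesian models (need all three modes) ---------------------------
    correlations = coef_table = None
    mv_post = acc_post = None
    if set(MODES) <= set(cfg.modes) and fib_cols:
        contam = totals[list(MODES)].copy()
        meta = sinks.sample_meta.copy()
        if "enterococci_mpn" not in meta.columns:
            meta["enterococci_mpn"] = 0.0
        mv_data = bm.prepare_mvglmm_data(contam, meta, cfg.exclusion_window_h)
        mv_post = bm.fit_mvglmm(
            mv_data, cfg.stage_seed(3), cfg.mcmc_chains, cfg.mcmc_iterations, cfg.mcmc_burnin
        )
        correlations = bm.posterior_correlations(mv_post)

        sig = signals[
            (signals["proportion_mean"] > cfg.min_prop) & (signals["n_otus"] > 0)
        ].copy()
        sig["location"] = sinks.sample_meta.loc[sig["sink_id"], "location"].to_numpy()
        acc_frame = sig.rename(columns={"sink_id": "sample_id"})
        acc_post = bm.fit_accuracy_glmm(
            acc_frame[["n_accurate", "n_otus", "sample_id", "location", "source", "setup"]],
            cfg.stage_seed(4),
            cfg.mcmc_chains,
            cfg.mcmc_iterations,
            cfg.mcmc_burnin,
        )
        coef_table = bm.coefficient_summary(acc_post)

    bundle = ReportBundle(
        results=results,
        signals=signals,
        totals=totals,
        calls=calls,
        strata_means=strata_means,
        correlations=correlations,
        accuracy_coefficients=coef_table,
        exclusions=pd.DataFrame(exclusions, columns=["sample_id", "rule"]),
        truth=truth,
        mvglmm=mv_post,
        accuracy_glmm=acc_post,
    )
    if cfg.out_dir:
        _write_bundle(cfg, bundle)
    return bundle


def _merge_results(parts: list[MSTResult]) -> MSTResult:
    names = parts[0].source_names
    mean = pd.concat([p.proportions_mean for p in parts])
    sd = pd.concat([p.proportions_sd for p in parts])
    posts: dict[str, pd.DataFrame] = {}
    draws: dict[str, np.ndarray] = {}
    for p in parts:
        posts.update(p.otu_posteriors)
        draws.update(p.draws)
    counts = pd.concat([p.sink_counts for p in parts]).fillna(0).astype(np.int64)
    return MSTResult(names, mean, sd, posts, draws, counts)


def _write_bundle(cfg: RunConfig, b: ReportBundle) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for mode, r in b.results.items():
        r.proportions_mean.to_csv(out / f"proportions_mean_{mode}.tsv", sep="\t")
        r.proportions_sd.to_csv(out / f"proportions_sd_{mode}.tsv", sep="\t")
        for sid, post in r.otu_posteriors.items():
            post.to_csv(out / f"otu_posteriors_{mode}_{sid}.tsv", sep="\t")
    b.signals.to_csv(out / "signal_summaries.tsv", sep="\t", index=False)
    b.totals.to_csv(out / "contamination_totals.tsv", sep="\t")
    b.calls.to_csv(out / "contamination_calls.tsv", sep="\t", index=False)
    b.strata_means.to_csv(out / "strata_means.tsv", sep="\t", index=False)
    b.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    if b.correlations is not None:
        b.correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
    if b.accuracy_coefficients is not None:
        b.accuracy_coefficients.to_csv(out / "accuracy_coefficients.tsv", sep="\t", index=False)
    manifest = {
        "seed": cfg.seed,
        "modes": list(cfg.modes),
        "config_hash": hashlib.sha256(
            json.dumps(_cfg_dict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _cfg_dict(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    return d


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file; a ``scenario`` mapping selects
    synthetic mode and is passed through to :class:`ScenarioSpec`."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "scenario" in raw and raw["scenario"] is not None:
        raw["scenario"] = ScenarioSpec(**raw["scenario"])
    if "st" in raw and raw["st"] is not None:
        raw["st"] = STParams(**raw["st"])
    if "modes" in raw:
        raw["modes"] = tuple(raw["modes"])
    return RunConfig(**raw)
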