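"""Synthetic communities for source tracking: fecal/sewage sources with
Dirichlet-multinomial sampling, multi-location water backgrounds with
logistic-normal seasonal drift, sink samples mixed from known proportions, and
fecal-indicator counts coupled to the true contamination level.

The default scenario emulates the structure a source-tracking study sees:
eight contaminating source environments with planted OTU-support overlap
against water (sewage and dog sharing the most, calf the least), water sampled
repeatedly at several treatment-plant locations, and sinks that are convex
mixtures of a local water community and contaminating sources. Every draw is
deterministic under the scenario seed, and the generator returns the ground
truth (mixing vectors, read-level origins, latent FIB means) that downstream
tests score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otu_io import OTUTable

DEFAULT_OVERLAP = {
    # fraction of each source's OTU support drawn from the shared water block
    "sewage": 0.80,
    "dog": 0.70,
    "wild_bird": 0.30,
    "pig": 0.30,
    "horse": 0.25,
    "cow": 0.20,
    "sheep": 0.20,
    "calf": 0.10,
}


@dataclass
class SourceSpec:
    name: str
    n_samples: int = 12
    reads_per_sample: int = 20_000
    support_size: int = 100
    water_overlap: float = 0.3
    # within-source tightness: per-sample profile ~ Dirichlet(concentration * base)
    concentration: float = 60.0
    # relative Dirichlet weight of water-shared OTUs in the source's mean
    # profile: fecal communities share presence with water but their read
    # mass is dominated by source-specific taxa
    shared_weight: float = 0.3


@dataclass
class WaterSpec:
    n_locations: int = 3
    samples_per_location: int = 20
    reads_per_sample: int = 20_000
    block_size: int = 250          # OTUs in the shared water block
    baseline_alpha: float = 1.0    # per-OTU Dirichlet parameter of location baselines
    drift_sd: float = 0.5          # logistic-normal seasonal drift magnitude
    hours_between_samples: float = 96.0


@dataclass
class SinkSpec:
    location: str
    mixing: Mapping[str, float]    # source name (or "background") -> proportion
    depth: int = 20_000


@dataclass
class FIBSpec:
    """log-mean of each indicator is affine in the true contamination fraction."""

    baselines: Mapping[str, float] = field(
        default_factory=lambda: {"ecoli_mpn": 2.0, "coliform_mpn": 30.0, "enterococci_mpn": 1.0}
    )
    slopes: Mapping[str, float] = field(
        default_factory=lambda: {"ecoli_mpn": 30.0, "coliform_mpn": 25.0, "enterococci_mpn": 20.0}
    )
    dispersion: float = 8.0        # negative-binomial size; 0 => deterministic means


def default_sources() -> list[SourceSpec]:
    return [
        SourceSpec(name, water_overlap=DEFAULT_OVERLAP[name]) for name in DEFAULT_OVERLAP
    ]


def default_sinks(locations: Sequence[str]) -> list[SinkSpec]:
    """Five clean sinks and five sewage-contaminated sinks across locations."""
    levels = [0.0, 0.0, 0.0, 0.0, 0.0, 0.005, 0.01, 0.02, 0.05, 0.10]
    sinks = []
    for i, c in enumerate(levels):
        loc = locations[i % len(locations)]
        sinks.append(SinkSpec(loc, {"background": 1.0 - c, "sewage": c}))
    return sinks


@dataclass
class ScenarioSpec:
    n_otus: int = 800
    sources: list[SourceSpec] = field(default_factory=default_sources)
    water: WaterSpec = field(default_factory=WaterSpec)
    sinks: list[SinkSpec] | None = None   # None -> default_sinks over water locations
    fib: FIBSpec = field(default_factory=FIBSpec)
    seed: int = 0

    def location_names(self) -> list[str]:
        return [f"L{i + 1}" for i in range(self.water.n_locations)]

    def resolved_sinks(self) -> list[SinkSpec]:
        return self.sinks if self.sinks is not None else default_sinks(self.location_names())


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside the generated tables."""

    source_profiles: pd.DataFrame | None = None       # source x OTU mean profile
    water_baselines: pd.DataFrame | None = None       # location x OTU baseline
    water_labels: pd.Series | None = None             # water sample -> location
    sink_mixing: pd.DataFrame | None = None           # sink x component proportions
    read_origins: dict[str, pd.DataFrame] | None = None  # sink -> (OTU x component) counts
    fib_means: pd.DataFrame | None = None             # sample x indicator latent mean


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _otu_ids(n: int) -> list[str]:
    return [f"OTU{i:04d}" for i in range(n)]


def _synthetic_taxonomy(n_otus: int, rng: np.random.Generator) -> pd.Series:
    phyla = [
        "Proteobacteria", "Bacteroidetes", "Firmicutes", "Actinobacteria",
        "Planctomycetes", "Verrucomicrobia", "Cyanobacteria", "Fusobacteria",
    ]
    labels = rng.choice(phyla, size=n_otus)
    lineages = [f"k__Bacteria;p__{p};c__;o__;f__;g__;s__" for p in labels]
    return pd.Series(lineages, index=_otu_ids(n_otus), name="taxonomy")


def _support_blocks(spec: ScenarioSpec, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Assign each source an OTU support: a private block plus a planted overlap
    with the shared water block."""
    water_block = np.arange(spec.water.block_size)
    cursor = spec.water.block_size
    supports: dict[str, np.ndarray] = {"water": water_block}
    weights: dict[str, np.ndarray] = {}
    for s in spec.sources:
        n_shared = int(round(s.water_overlap * s.support_size))
        n_private = s.support_size - n_shared
        if cursor + n_private > spec.n_otus:
            raise ValueError("n_otus too small for the requested source supports")
        private = np.arange(cursor, cursor + n_private)
        cursor += n_private
        shared = rng.choice(water_block, size=n_shared, replace=False)
        support = np.concatenate([shared, private])
        wts = np.concatenate(
            [np.full(n_shared, s.shared_weight), np.ones(n_private)]
        )
        order = np.argsort(support)
        supports[s.name] = support[order]
        weights[s.name] = wts[order]
    supports["__weights__"] = weights  # type: ignore[assignment]
    return supports


def _dirichlet_on_support(
    rng: np.random.Generator, n_otus: int, support: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    p = np.zeros(n_otus)
    p[support] = rng.dirichlet(alpha)
    return p


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_sources(spec: ScenarioSpec, seed: int) -> tuple[OTUTable, SyntheticTruth]:
    """Sample the fecal/sewage training communities.

    Each source has a mean profile drawn on its planted support; individual
    samples draw a per-sample profile from Dirichlet(concentration * mean) and
    then multinomial reads.
    """
    rng = np.random.default_rng(seed)
    supports = _support_blocks(spec, np.random.default_rng(spec.seed))
    otus = _otu_ids(spec.n_otus)
    rows, ids, envs = [], [], []
    profiles = {}
    weights = supports["__weights__"]
    for s in spec.sources:
        support = supports[s.name]
        base = _dirichlet_on_support(rng, spec.n_otus, support, weights[s.name])
        profiles[s.name] = base
        for j in range(s.n_samples):
            alpha = s.concentration * base[support]
            prof = _dirichlet_on_support(rng, spec.n_otus, support, alpha)
            rows.append(rng.multinomial(s.reads_per_sample, prof))
            ids.append(f"{s.name}_{j:02d}")
            envs.append(s.name)
    counts = pd.DataFrame(np.array(rows, dtype=np.int64), index=ids, columns=otus)
    meta = pd.DataFrame({"environment": envs}, index=ids)
    truth = SyntheticTruth(source_profiles=pd.DataFrame(profiles, index=otus).T)
    tax = _synthetic_taxonomy(spec.n_otus, np.random.default_rng(spec.seed + 1))
    return OTUTable(counts, meta, tax), truth


def generate_water(spec: ScenarioSpec, seed: int) -> tuple[OTUTable, SyntheticTruth]:
    """Sample background water communities with location structure and drift.

    Per location a baseline profile lives on the shared water block; each
    sample perturbs the baseline by a logistic-normal drift of magnitude
    ``drift_sd`` before multinomial read sampling. Collection dates are spaced
    ``hours_between_samples`` apart per location (>= 48 h by default so the
    auto-correlation exclusion rule only fires when a scenario asks for it).
    """
    rng = np.random.default_rng(seed)
    w = spec.water
    supports = _support_blocks(spec, np.random.default_rng(spec.seed))
    block = supports["water"]
    otus = _otu_ids(spec.n_otus)
    baselines = {}
    rows, ids, envs, locs, dates = [], [], [], [], []
    t0 = pd.Timestamp("2014-01-01")
    for li, loc in enumerate(spec.location_names()):
        base = rng.dirichlet(np.full(len(block), w.baseline_alpha))
        baselines[loc] = base
        for j in range(w.samples_per_location):
            prof = drift_profile(base, w.drift_sd, rng)
            full = np.zeros(spec.n_otus)
            full[block] = prof
            rows.append(rng.multinomial(w.reads_per_sample, full))
            ids.append(f"water_{loc}_{j:02d}")
            envs.append("water")
            locs.append(loc)
            dates.append(t0 + pd.Timedelta(hours=w.hours_between_samples * j + 11 * li))
    counts = pd.DataFrame(np.array(rows, dtype=np.int64), index=ids, columns=otus)
    meta = pd.DataFrame({"environment": envs, "location": locs, "date": dates}, index=ids)
    base_df = pd.DataFrame(
        {loc: _embed(block, b, spec.n_otus) for loc, b in baselines.items()}, index=otus
    ).T
    truth = SyntheticTruth(water_baselines=base_df, water_labels=pd.Series(locs, index=ids))
    tax = _synthetic_taxonomy(spec.n_otus, np.random.default_rng(spec.seed + 1))
    return OTUTable(counts, meta, tax), truth


def drift_profile(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Logistic-normal perturbation of a composition (sd = 0 returns it unchanged)."""
    if sd == 0:
        return base
    z = np.log(np.maximum(base, 1e-300)) + rng.normal(0.0, sd, size=base.size)
    z -= z.max()
    p = np.exp(z)
    return p / p.sum()


def _embed(idx: np.ndarray, values: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros(n)
    out[idx] = values
    return out


def generate_sinks(
    sources: tuple[OTUTable, SyntheticTruth],
    water: tuple[OTUTable, SyntheticTruth],
    spec: ScenarioSpec,
    seed: int,
) -> tuple[OTUTable, SyntheticTruth]:
    """Mix sink communities from a fresh local water draw plus source profiles.

    Reads are drawn component-first (multinomial over the mixing vector), then
    OTU within component, so exact read-level origin labels are retained.
    """
    rng = np.random.default_rng(seed)
    _, src_truth = sources
    _, wat_truth = water
    otus = list(src_truth.source_profiles.columns)
    rows, ids, locs, envs, dates = [], [], [], [], []
    mixing_rows = {}
    origins: dict[str, pd.DataFrame] = {}
    t0 = pd.Timestamp("2015-03-01")
    for i, sk in enumerate(spec.resolved_sinks()):
        mix = dict(sk.mixing)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"mixing for sink {i} does not sum to 1")
        comp_names = list(mix)
        comp_profiles = []
        for name in comp_names:
            if name == "background":
                base = wat_truth.water_baselines.loc[sk.location].to_numpy()
                comp_profiles.append(drift_profile(base, spec.water.drift_sd, rng))
            else:
                if name not in src_truth.source_profiles.index:
                    raise ValueError(f"sink mixes over undefined source {name!r}")
                comp_profiles.append(src_truth.source_profiles.loc[name].to_numpy())
        n_per_comp = rng.multinomial(sk.depth, [mix[c] for c in comp_names])
        counts = np.zeros(len(otus), dtype=np.int64)
        origin = np.zeros((len(otus), len(comp_names)), dtype=np.int64)
        for c, (n_c, prof) in enumerate(zip(n_per_comp, comp_profiles)):
            if n_c:
                draw = rng.multinomial(n_c, prof)
                counts += draw
                origin[:, c] = draw
        sid = f"sink_{i:02d}"
        rows.append(counts)
        ids.append(sid)
        locs.append(sk.location)
        envs.append("sink")
        dates.append(t0 + pd.Timedelta(hours=96 * i))
        mixing_rows[sid] = mix
        origins[sid] = pd.DataFrame(origin, index=otus, columns=comp_names)
    counts = pd.DataFrame(np.array(rows, dtype=np.int64), index=ids, columns=otus)
    meta = pd.DataFrame({"environment": envs, "location": locs, "date": dates}, index=ids)
    mixing = pd.DataFrame(mixing_rows).T.fillna(0.0)
    truth = SyntheticTruth(sink_mixing=mixing, read_origins=origins)
    tax = _synthetic_taxonomy(spec.n_otus, np.random.default_rng(spec.seed + 1))
    return OTUTable(counts, meta, tax), truth


def true_contamination(truth: SyntheticTruth) -> pd.Series:
    """Total non-background mixing proportion per sink."""
    mix = truth.sink_mixing
    cols = [c for c in mix.columns if c != "background"]
    return mix[cols].sum(axis=1)


def generate_fib(
    contamination: pd.Series, fib: FIBSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw MPN counts whose log-mean is affine in true contamination.

    Returns (counts, latent means). ``dispersion`` is the negative-binomial
    size parameter; 0 gives the deterministic rounded means.
    """
    rng = np.random.default_rng(seed)
    means = {}
    draws = {}
    for col, base in fib.baselines.items():
        mu = base * np.exp(fib.slopes[col] * contamination.to_numpy())
        means[col] = mu
        if fib.dispersion == 0:
            draws[col] = np.round(mu)
        else:
            r = fib.dispersion
            draws[col] = rng.negative_binomial(r, r / (r + mu)).astype(float)
    idx = contamination.index
    return pd.DataFrame(draws, index=idx), pd.DataFrame(means, index=idx)


def generate_scenario(
    spec: ScenarioSpec, seed: int | None = None
) -> tuple[OTUTable, OTUTable, OTUTable, SyntheticTruth]:
    """Full scenario: (fecal table, water table, sink table, merged truth).

    FIB metadata is attached to water samples (clean by construction) and to
    sinks (coupled to their true contamination).
    """
    root = np.random.SeedSequence(spec.seed if seed is None else seed)
    s_src, s_wat, s_snk, s_fib = [int(c.generate_state(1)[0] % 2**31) for c in root.spawn(4)]
    fecal, src_truth = generate_sources(spec, s_src)
    water, wat_truth = generate_water(spec, s_wat)
    sinks, snk_truth = generate_sinks((fecal, src_truth), (water, wat_truth), spec, s_snk)

    contam = true_contamination(snk_truth)
    water_contam = pd.Series(0.0, index=water.sample_ids)
    all_contam = pd.concat([water_contam, contam])
    fib_counts, fib_means = generate_fib(all_contam, spec.fib, s_fib)
    for t in (water, sinks):
        for col in fib_counts.columns:
            t.sample_meta[col] = fib_counts.loc[t.sample_ids, col].to_numpy()

    truth = SyntheticTruth(
        source_profiles=src_truth.source_profiles,
        water_baselines=wat_truth.water_baselines,
        water_labels=wat_truth.water_labels,
        sink_mixing=snk_truth.sink_mixing,
        read_origins=snk_truth.read_origins,
        fib_means=fib_means,
    )
    return fecal, water, sinks, truth
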