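"""Scoring of source-tracking signals.

A *signal* is one (sink, source) pair from a fitted run: its estimated mixing
proportion plus the set of OTUs attributed to the source. OTUs whose posterior
probability of originating from the source exceeds the attribution floor
(default 0.1, the visualization floor) count toward the signal; those at or
above the accuracy threshold (default 0.7) are *source-accurate* OTUs, and the
ratio of the two counts is the signal's accuracy — the fraction of the signal
resting on OTUs the model confidently places in that source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library_builder import BACKGROUND
from .source_tracker import MSTResult, UNKNOWN, otu_source_posteriors


@dataclass
class SignalSummary:
    sink_id: str
    source_name: str
    proportion_mean: float | None
    proportion_sd: float | None
    n_otus: int
    n_accurate: int

    @property
    def accuracy(self) -> float | None:
        if self.n_otus == 0:
            return None
        return self.n_accurate / self.n_otus


def source_accuracy(
    posteriors: pd.DataFrame,
    source: str,
    p_hi: float = 0.7,
    p_floor: float = 0.1,
    sink_id: str = "",
    proportion_mean: float | None = None,
    proportion_sd: float | None = None,
) -> SignalSummary:
    """Count attributed and source-accurate OTUs for one source.

    ``n_otus`` counts OTUs with posterior > ``p_floor`` toward the source;
    ``n_accurate`` counts those at >= ``p_hi`` (accurate OTUs are a subset of
    attributed ones whenever ``p_hi > p_floor``).
    """
    if source not in posteriors.columns:
        raise KeyError(f"unknown source {source!r}")
    col = posteriors[source]
    attributed = col > p_floor
    accurate = attributed & (col >= p_hi)
    return SignalSummary(
        sink_id=sink_id,
        source_name=source,
        proportion_mean=proportion_mean,
        proportion_sd=proportion_sd,
        n_otus=int(attributed.sum()),
        n_accurate=int(accurate.sum()),
    )


def signal_summaries(
    r: MSTResult, p_hi: float = 0.7, p_floor: float = 0.1
) -> pd.DataFrame:
    """Per-(sink, source) signal table mirroring the proportions/OTU-count layout."""
    rows = []
    for sid in r.proportions_mean.index:
        post = r.otu_posteriors[sid]
        for src in r.source_names:
            s = source_accuracy(
                post,
                src,
                p_hi,
                p_floor,
                sink_id=sid,
                proportion_mean=float(r.proportions_mean.loc[sid, src]),
                proportion_sd=float(r.proportions_sd.loc[sid, src]),
            )
            rows.append(
                {
                    "sink_id": sid,
                    "source": src,
                    "proportion_mean": s.proportion_mean,
                    "proportion_sd": s.proportion_sd,
                    "n_otus": s.n_otus,
                    "n_accurate": s.n_accurate,
                    "accuracy": s.accuracy,
                }
            )
    return pd.DataFrame(rows)


def call_contamination(
    r: MSTResult, min_prop: float = 0.003, include_unknown: bool = False
) -> dict[str, list[str]]:
    """Sources called contaminating per sink: proportion above ``min_prop``,
    background excluded, Unknown included only on request."""
    calls: dict[str, list[str]] = {}
    for sid in r.proportions_mean.index:
        row = r.proportions_mean.loc[sid]
        named = [
            src
            for src in r.source_names
            if src != BACKGROUND
            and (include_unknown or src != UNKNOWN)
            and row[src] > min_prop
        ]
        calls[sid] = named
    return calls


def total_contamination(r: MSTResult, include_unknown: bool = False) -> pd.Series:
    """Summed non-background source proportions per sink (the total fecal load
    proxy); with Unknown included this equals one minus the background share."""
    cols = [
        src
        for src in r.source_names
        if src != BACKGROUND and (include_unknown or src != UNKNOWN)
    ]
    return r.proportions_mean[cols].sum(axis=1)


# ---------------------------------------------------------------------------
# read-reassignment accounting between two runs
# ---------------------------------------------------------------------------

def _phylum(lineage: str | float) -> str:
    if not isinstance(lineage, str):
        return "unclassified"
    for part in lineage.split(";"):
        part = part.strip()
        if part.startswith("p__") and len(part) > 3:
            return part[3:]
    return "unclassified"


def reassignment_table(
    run_a: MSTResult,
    run_b: MSTResult,
    sink_id: str,
    taxonomy: pd.Series | None = None,
) -> pd.DataFrame:
    """Cross-tabulate where each sink read's source attribution moves between
    two runs of the same sink.

    Every read inherits its OTU's most probable source in each run (per-OTU
    argmax of the posterior); OTUs with tied top sources in either run are
    dropped, as no single origin can be assigned. Rows are
    (source_a, source_b, phylum, read_count) and the read total is conserved
    up to the dropped ties.
    """
    post_a = otu_source_posteriors(run_a, sink_id)
    post_b = otu_source_posteriors(run_b, sink_id)
    counts_a = run_a.sink_counts.loc[sink_id]
    counts_b = run_b.sink_counts.loc[sink_id]
    if int(counts_a.sum()) != int(counts_b.sum()):
        raise ValueError("runs were fitted on differing sink depths")
    common = post_a.index.intersection(post_b.index)
    rows = []
    for otu in common:
        ra, rb = post_a.loc[otu], post_b.loc[otu]
        if (ra == ra.max()).sum() > 1 or (rb == rb.max()).sum() > 1:
            continue  # ambiguous source origin
        nreads = int(counts_a[otu])
        phylum = _phylum(taxonomy.get(otu) if taxonomy is not None else None)
        rows.append((ra.idxmax(), rb.idxmax(), phylum, nreads))
    df = pd.DataFrame(rows, columns=["source_a", "source_b", "phylum", "read_count"])
    return df.groupby(["source_a", "source_b", "phylum"], as_index=False)["read_count"].sum()
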