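"""OTU-table containers, TSV round-trips, abundance filtering, rarefaction and
shared-OTU accounting.

The on-disk dialect is the classic tab-separated OTU table (first column
``#OTU ID``, one column per sample, optional trailing ``taxonomy`` column of
Greengenes-style lineage strings) together with a sample-metadata TSV carrying
at least ``sample_id`` and ``environment`` columns and, when available,
``location``, ``date`` (ISO-8601) and the three fecal-indicator columns
``ecoli_mpn``, ``coliform_mpn``, ``enterococci_mpn``.

In memory a table holds samples on rows and OTUs on columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

TAXONOMY_COLUMN = "taxonomy"
OTU_ID_COLUMN = "#OTU ID"
META_REQUIRED = ("sample_id", "environment")
FIB_COLUMNS = ("ecoli_mpn", "coliform_mpn", "enterococci_mpn")


class OTUTableError(ValueError):
    """Malformed table, metadata mismatch or invalid counts."""


@dataclass
class OTUTable:
    """Integer count matrix (samples x OTUs) with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by sample id, columns are OTU ids, entries are
        non-negative integers.
    sample_meta
        DataFrame indexed by sample id; must cover exactly the samples of
        ``counts``. An ``environment`` column is expected.
    taxonomy
        Optional Series mapping OTU id -> lineage string.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.index.has_duplicates:
            raise OTUTableError("duplicate sample ids")
        if self.counts.columns.has_duplicates:
            raise OTUTableError("duplicate OTU ids")
        values = self.counts.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise OTUTableError("counts must be integral")
            self.counts = self.counts.round().astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise OTUTableError("counts must be non-negative")
        meta = self.sample_meta.copy()
        if "sample_id" in meta.columns:
            meta = meta.set_index("sample_id")
        if meta.index.has_duplicates:
            raise OTUTableError("duplicate sample ids in metadata")
        missing = self.counts.index.difference(meta.index)
        if len(missing):
            raise OTUTableError(f"samples missing from metadata: {sorted(missing)}")
        self.sample_meta = meta.loc[self.counts.index]
        if self.taxonomy is not None:
            self.taxonomy = self.taxonomy.reindex(self.counts.columns)

    # -- convenience -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def subset_samples(self, sample_ids: Sequence[str]) -> "OTUTable":
        ids = list(sample_ids)
        return OTUTable(self.counts.loc[ids], self.sample_meta.loc[ids], self.taxonomy)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OTUTable":
        ids = list(otu_ids)
        tax = self.taxonomy.loc[ids] if self.taxonomy is not None else None
        return OTUTable(self.counts[ids], self.sample_meta, tax)

    def environments(self) -> pd.Series:
        if "environment" not in self.sample_meta.columns:
            raise OTUTableError("metadata lacks an 'environment' column")
        return self.sample_meta["environment"]


@dataclass
class SharedOTUMatrix:
    """Symmetric matrix of OTUs jointly present in pairs of pooled sources."""

    source_names: list[str]
    shared: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        m = self.shared.to_numpy()
        if not np.array_equal(m, m.T):
            raise OTUTableError("shared-OTU matrix must be symmetric")

    def richness(self) -> pd.Series:
        return pd.Series(np.diag(self.shared.to_numpy()), index=self.source_names)


# ---------------------------------------------------------------------------
# TSV round-trip
# ---------------------------------------------------------------------------

def read_otu_table(table_path: str | Path, meta_path: str | Path) -> OTUTable:
    """Read a classic OTU-table TSV plus its sample-metadata TSV."""
    table_path, meta_path = Path(table_path), Path(meta_path)
    raw = pd.read_csv(table_path, sep="\t", comment=None, skiprows=_comment_rows(table_path))
    if raw.columns[0] != OTU_ID_COLUMN:
        raise OTUTableError(f"first column must be {OTU_ID_COLUMN!r}, got {raw.columns[0]!r}")
    raw = raw.set_index(OTU_ID_COLUMN)
    taxonomy = None
    if TAXONOMY_COLUMN in raw.columns:
        taxonomy = raw[TAXONOMY_COLUMN].astype(str)
        raw = raw.drop(columns=[TAXONOMY_COLUMN])
    counts = raw.T  # samples x OTUs
    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
    for col in META_REQUIRED:
        if col not in meta.columns:
            raise OTUTableError(f"metadata lacks required column {col!r}")
    if "date" in meta.columns:
        meta["date"] = pd.to_datetime(meta["date"], format="ISO8601")
    counts.index = counts.index.astype(str)
    return OTUTable(counts, meta, taxonomy)


def _comment_rows(path: Path) -> list[int]:
    """Row numbers of leading comment lines that are not the header itself."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith("#") and not line.startswith(OTU_ID_COLUMN):
                rows.append(i)
            else:
                break
    return rows


def write_otu_table(t: OTUTable, table_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write ``t`` in the same classic TSV dialect that :func:`read_otu_table` accepts."""
    out = t.counts.T
    out.index.name = OTU_ID_COLUMN
    if t.taxonomy is not None:
        out = out.assign(**{TAXONOMY_COLUMN: t.taxonomy.values})
    out.to_csv(table_path, sep="\t")
    if meta_path is not None:
        meta = t.sample_meta.copy()
        meta.index.name = "sample_id"
        meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_low_abundance(
    t: OTUTable,
    min_total_frac: float = 1e-5,
    min_samples: int = 3,
) -> OTUTable:
    """Drop singleton OTUs, OTUs below ``min_total_frac`` of all reads, and OTUs
    seen in fewer than ``min_samples`` samples.

    All three predicates are evaluated in one pass on the original totals, so
    the operation is idempotent. Samples are never removed.
    """
    if t.n_otus == 0 or t.n_samples == 0:
        raise OTUTableError("cannot filter an empty table")
    totals = t.counts.sum(axis=0)
    grand = int(totals.sum())
    prevalence = (t.counts > 0).sum(axis=0)
    keep = (totals > 1) & (totals >= min_total_frac * grand) & (prevalence >= min_samples)
    return t.subset_otus(list(t.counts.columns[keep]))


# ---------------------------------------------------------------------------
# Rarefaction and pooling
# ---------------------------------------------------------------------------

def rarefy(t: OTUTable, depth: int, seed: int | np.random.Generator) -> OTUTable:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total is below ``depth`` are dropped with a warning, matching
    the single_rarefaction convention. Sampling is multivariate hypergeometric
    and deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = t.sample_totals()
    kept = totals[totals >= depth].index
    dropped = sorted(set(t.sample_ids) - set(kept))
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth {depth}: {dropped}",
            stacklevel=2,
        )
    rows = np.empty((len(kept), t.n_otus), dtype=np.int64)
    for i, sid in enumerate(kept):
        row = t.counts.loc[sid].to_numpy()
        if row.sum() == depth:
            rows[i] = row
        else:
            rows[i] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(rows, index=list(kept), columns=t.counts.columns)
    return OTUTable(counts, t.sample_meta.loc[list(kept)], t.taxonomy)


def pool_by_source(t: OTUTable) -> OTUTable:
    """Collapse samples to one row per environment label by summing counts."""
    env = t.environments()
    pooled = t.counts.groupby(env.values).sum()
    pooled.index = pooled.index.astype(str)
    meta = pd.DataFrame({"environment": pooled.index}, index=pooled.index)
    return OTUTable(pooled, meta, t.taxonomy)


def shared_otus(pooled: OTUTable, depth: int = 1_000_000, seed: int | np.random.Generator = 0) -> SharedOTUMatrix:
    """Shared-OTU matrix between pooled sources after even-depth rarefaction.

    Sources below ``depth`` total reads are skipped (reported via the
    rarefaction warning). Entry (a, b) counts OTUs with nonzero reads in both
    sources; the diagonal is per-source richness.
    """
    rare = rarefy(pooled, depth, seed)
    present = (rare.counts.to_numpy() > 0).astype(np.int64)
    shared = present @ present.T
    names = rare.sample_ids
    df = pd.DataFrame(shared.astype(np.int64), index=names, columns=names)
    return SharedOTUMatrix(names, df)


def write_shared_otus(m: SharedOTUMatrix, path: str | Path) -> None:
    m.shared.to_csv(path, sep="\t")
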