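"""Species-level OTU table container, filtering, relative abundance,
abundance/incidence core-microbiota summary, and the ln(F/B) phylum ratio.

Filtering boundaries are strict: a taxon is retained when its total count is
strictly greater than ``min_total`` (default 10), and a species counts toward
incidence in a sample only when its relative abundance is strictly greater
than the threshold (default 1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OtuTable",
    "filter_by_total",
    "relative_abundance",
    "incidence_summary",
    "fb_ratio",
]


@dataclass
class OtuTable:
    """Samples-by-taxa count table with per-taxon annotations.

    counts : DataFrame, taxa (rows) x samples (columns), nonnegative integers.
    taxonomy : taxon id -> species name.
    phylum : taxon id -> phylum name.
    sample_group : sample id -> 'control' | 'dementia' (optional).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    phylum: pd.Series
    sample_group: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate taxon ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integral")
        self.counts = self.counts.astype(np.int64)
        self.taxonomy = self.taxonomy.reindex(self.counts.index)
        self.phylum = self.phylum.reindex(self.counts.index)
        if self.sample_group is not None:
            self.sample_group = self.sample_group.reindex(self.counts.columns)

    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset_samples(self, samples) -> "OtuTable":
        sg = self.sample_group.loc[samples] if self.sample_group is not None else None
        return OtuTable(self.counts[list(samples)], self.taxonomy, self.phylum, sg)

    def to_tsv(self, path) -> None:
        """Write as TSV: taxa rows, sample columns, plus taxonomy/phylum columns."""
        out = self.counts.copy()
        out["taxonomy"] = self.taxonomy
        out["phylum"] = self.phylum
        out.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path, sample_group: Mapping[str, str] | None = None) -> "OtuTable":
        df = pd.read_csv(path, sep="\t", index_col="taxon")
        taxonomy = df.pop("taxonomy")
        phylum = df.pop("phylum")
        sg = pd.Series(sample_group) if sample_group is not None else None
        return cls(df, taxonomy, phylum, sg)


def filter_by_total(table: OtuTable, min_total: int = 10) -> OtuTable:
    """Retain taxa whose total count across samples is strictly > min_total."""
    totals = table.counts.sum(axis=1)
    keep = totals > min_total
    if not keep.any():
        logger.warning("filter_by_total removed every taxon (min_total=%s)", min_total)
    kept = table.counts.loc[keep]
    return replace(table, counts=kept, taxonomy=table.taxonomy.loc[keep],
                   phylum=table.phylum.loc[keep])


def relative_abundance(table: OtuTable) -> pd.DataFrame:
    """Per-sample closure to proportions (taxa x samples)."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    return table.counts / totals


def incidence_summary(
    props: pd.DataFrame,
    groups: pd.Series,
    threshold: float = 0.01,
    top_n: int = 15,
) -> pd.DataFrame:
    """Mean relative abundance (%) and incidence (%) per (taxon, group).

    Incidence counts samples within the group whose proportion is strictly
    greater than ``threshold``.  Taxa are ranked by overall mean abundance
    and the top ``top_n`` reported; rank ties break lexicographically.
    """
    groups = groups.reindex(props.columns)
    if groups.isna().any():
        raise ValueError("groups must cover every sample")
    overall = props.mean(axis=1)
    order = overall.to_frame("m").assign(name=overall.index).sort_values(
        ["m", "name"], ascending=[False, True]
    ).index
    top = order[:top_n]
    rows = []
    for g, cols in props.T.groupby(groups).groups.items():
        if len(cols) == 0:
            raise ValueError(f"empty group {g!r}")
        sub = props[list(cols)]
        for taxon in top:
            rows.append(
                {
                    "taxon": taxon,
                    "group": g,
                    "abundance_pct": 100.0 * sub.loc[taxon].mean(),
                    "incidence_pct": 100.0 * (sub.loc[taxon] > threshold).mean(),
                }
            )
    return pd.DataFrame(rows)


def fb_ratio(table: OtuTable) -> pd.Series:
    """Per-sample natural log of the Firmicutes/Bacteroidetes count ratio.

    Samples with a zero count in either phylum get NaN (flagged undefined);
    callers exclude them pairwise from group tests.
    """
    if table.phylum.isna().all():
        raise ValueError("phylum annotations missing")
    f = table.counts[table.phylum == "Firmicutes"].sum(axis=0).astype(float)
    b = table.counts[table.phylum == "Bacteroidetes"].sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(f / b)
    out[(f == 0) | (b == 0)] = np.nan
    n_bad = int(out.isna().sum())
    if n_bad:
        logger.warning("fb_ratio undefined for %d sample(s); excluded pairwise", n_bad)
    return out
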