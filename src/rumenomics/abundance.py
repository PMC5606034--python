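"""OTU-table handling: count filtering, relative-abundance normalisation,
taxonomic aggregation, and group-level composition summaries.

The central objects are :class:`OtuTable` (integer counts, samples x OTUs,
with a taxonomy lineage per OTU and a group label per sample) and
:class:`AbundanceTable` (per-sample fractions summing to one).  All
downstream community statistics operate on these.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Taxonomic ranks recognised in lineage tables, coarsest first.
RANKS = ("phylum", "class", "order", "family", "genus")

#: Label under which lineages missing at a rank are pooled.
UNCLASSIFIED = "unclassified"

_ROW_SUM_TOL = 1e-9


def _check_groups(groups: pd.Series, sample_ids: pd.Index) -> None:
    if not groups.index.equals(sample_ids):
        missing = sample_ids.difference(groups.index).tolist()
        extra = groups.index.difference(sample_ids).tolist()
        raise ValidationError(
            f"group labels do not match sample ids (missing {missing}, extra {extra})"
        )


@dataclass(frozen=True)
class OtuTable:
    """Integer OTU counts (samples x OTUs) with taxonomy and sample groups.

    Parameters
    ----------
    counts
        Non-negative integer counts, one row per sample, one column per OTU.
    taxonomy
        Lineage table indexed by OTU id with a column per rank (subset of
        :data:`RANKS`); missing values are treated as ``unclassified``.
    groups
        Group label per sample (e.g. ``MC`` / ``LC``), indexed by sample id.
    animals
        Optional animal id per sample.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    groups: pd.Series
    animals: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if c.index.has_duplicates:
            raise ValidationError("duplicate sample ids in count table")
        if c.columns.has_duplicates:
            raise ValidationError("duplicate OTU ids in count table")
        values = c.to_numpy()
        if values.size:
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise ValidationError(
                    f"negative count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
                )
            if not np.allclose(values, np.round(values)):
                i, j = np.argwhere(values != np.round(values))[0]
                raise ValidationError(
                    f"non-integer count at sample {c.index[i]!r}, OTU {c.columns[j]!r}"
                )
        missing_tax = c.columns.difference(self.taxonomy.index)
        if len(missing_tax):
            raise ValidationError(f"OTUs without taxonomy lineage: {list(missing_tax)[:5]}")
        unknown_ranks = [r for r in self.taxonomy.columns if r not in RANKS]
        if unknown_ranks:
            raise ValidationError(f"unknown taxonomy ranks: {unknown_ranks}")
        _check_groups(self.groups, c.index)

    @property
    def sample_ids(self) -> list:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list:
        return list(self.counts.columns)

    def restrict_otus(self, otus: Iterable) -> "OtuTable":
        keep = [o for o in self.counts.columns if o in set(otus)]
        return replace(self, counts=self.counts[keep])


@dataclass(frozen=True)
class AbundanceTable:
    """Relative abundances (samples x taxa); every row sums to one.

    ``rank`` is ``None`` for OTU-level tables and a rank name after
    aggregation; OTU-level tables keep the taxonomy for later aggregation.
    """

    fractions: pd.DataFrame
    groups: pd.Series
    rank: str | None = None
    taxonomy: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        f = self.fractions.to_numpy()
        if f.size:
            if (f < -_ROW_SUM_TOL).any():
                raise ValidationError("negative relative abundance")
            sums = f.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.fractions.index[np.argmax(np.abs(sums - 1.0))]
                raise ValidationError(f"abundances of sample {bad!r} do not sum to 1")
        _check_groups(self.groups, self.fractions.index)

    @property
    def sample_ids(self) -> list:
        return list(self.fractions.index)

    @property
    def taxon_ids(self) -> list:
        return list(self.fractions.columns)


def filter_min_count(t: OtuTable, min_count: int = 3) -> OtuTable:
    """Retain OTUs whose count is *strictly greater* than ``min_count`` in at
    least one sample (the "more than 3" rule).  An empty table passes through.
    """
    if t.counts.shape[1] == 0:
        return t
    keep = (t.counts > min_count).any(axis=0)
    counts = t.counts.loc[:, keep]
    return replace(t, counts=counts, taxonomy=t.taxonomy.loc[counts.columns])


def relative_abundance(t: OtuTable) -> AbundanceTable:
    """Divide each sample's counts by its total.  A sample with zero total
    count has no defined composition and raises a :class:`ValidationError`.
    """
    totals = t.counts.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"samples with zero total count: {zero}")
    fractions = t.counts.div(totals, axis=0).astype(float)
    return AbundanceTable(fractions=fractions, groups=t.groups, rank=None, taxonomy=t.taxonomy)


def detectable_otus(a: AbundanceTable, threshold: float = 0.01) -> set:
    """Taxa reaching ``threshold`` relative abundance (inclusive) in at least
    one sample — the "at least 1% in at least one sample" rule.
    """
    keep = (a.fractions >= threshold).any(axis=0)
    return set(a.fractions.columns[keep])


def _rank_labels(taxonomy: pd.DataFrame, rank: str) -> pd.Series:
    if rank not in taxonomy.columns:
        raise ValidationError(f"rank {rank!r} not present (have {list(taxonomy.columns)})")
    labels = taxonomy[rank].astype("object")
    labels = labels.where(labels.notna() & (labels != ""), UNCLASSIFIED)
    return labels


def aggregate_taxa(a: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum abundances over OTUs sharing a lineage label at ``rank``.

    Unclassified lineages are pooled into a single ``unclassified`` column so
    per-sample mass is conserved exactly.
    """
    if a.taxonomy is None:
        raise ValidationError("abundance table has no taxonomy; aggregate from OTU level")
    labels = _rank_labels(a.taxonomy.loc[a.fractions.columns], rank)
    agg = a.fractions.T.groupby(labels.to_numpy()).sum().T
    agg = agg.sort_index(axis=1)
    return AbundanceTable(fractions=agg, groups=a.groups, rank=rank, taxonomy=None)


def group_overlap(a: AbundanceTable, rank: str | None = None) -> dict:
    """Partition taxa into shared / group-exclusive sets (Venn-style).

    A taxon is "present in a group" iff its abundance is nonzero in at least
    one sample of that group.  Requires exactly two groups.  Returns a dict
    with keys ``shared``, ``only_<group1>``, ``only_<group2>`` (groups in
    sorted label order).
    """
    if rank is not None and rank != a.rank:
        a = aggregate_taxa(a, rank)
    names = sorted(a.groups.unique())
    if len(names) != 2:
        raise ValidationError(f"group overlap requires exactly 2 groups, found {names}")
    present = {}
    for g in names:
        sub = a.fractions.loc[a.groups[a.groups == g].index]
        present[g] = set(sub.columns[(sub > 0).any(axis=0)])
    g1, g2 = names
    return {
        "shared": present[g1] & present[g2],
        f"only_{g1}": present[g1] - present[g2],
        f"only_{g2}": present[g2] - present[g1],
    }


def percent_change(
    a: AbundanceTable,
    taxon,
    rank: str | None = None,
    numerator: str = "MC",
    reference: str = "LC",
) -> float:
    """Signed percent change of a taxon's group-mean abundance,
    ``100 * (mean_numerator - mean_reference) / mean_reference``.
    """
    if rank is not None and rank != a.rank:
        a = aggregate_taxa(a, rank)
    if taxon not in a.fractions.columns:
        raise ValidationError(f"taxon {taxon!r} not found at rank {a.rank!r}")
    for g in (numerator, reference):
        if g not in set(a.groups):
            raise ValidationError(f"group {g!r} not present")
    col = a.fractions[taxon]
    m_num = col[a.groups == numerator].mean()
    m_ref = col[a.groups == reference].mean()
    if m_ref == 0:
        raise ValidationError(f"reference group {reference!r} has zero mean for {taxon!r}")
    return 100.0 * (m_num - m_ref) / m_ref
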