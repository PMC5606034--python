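"""Host transcriptome handling: RPKM normalisation, expressed-gene filtering,
two-group differential expression, and gene-family summaries.

Differential expression is a Welch t-test on log2(RPKM + 1); a read-level
engine is deliberately out of scope, so results are method-comparable (not
identical) to count-based testers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control

from .diversity import welch_t_test
from .errors import ValidationError

FAMILIES = ("GPR", "HDAC", "other")


@dataclass(frozen=True)
class ExpressionMatrix:
    """RPKM values (genes x samples) with a gene-family tag per gene.

    Raw counts / gene lengths / mapped totals are optionally retained so the
    normalisation is recomputable.
    """

    rpkm: pd.DataFrame
    families: pd.Series  # gene -> GPR | HDAC | other
    groups: pd.Series  # sample -> group label
    counts: pd.DataFrame | None = None
    lengths_bp: pd.Series | None = None
    mapped_totals: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.rpkm.to_numpy() < 0).any():
            raise ValidationError("RPKM values must be nonnegative")
        if self.rpkm.index.has_duplicates:
            raise ValidationError("duplicate gene ids")
        missing = self.rpkm.index.difference(self.families.index)
        if len(missing):
            raise ValidationError(f"genes without family tag: {list(missing)[:5]}")
        if not set(self.groups.index) >= set(self.rpkm.columns):
            raise ValidationError("every sample needs a group label")

    @property
    def gene_ids(self) -> list:
        return list(self.rpkm.index)

    @property
    def sample_ids(self) -> list:
        return list(self.rpkm.columns)

    def restrict_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.rpkm.index if g in set(genes)]
        return replace(self, rpkm=self.rpkm.loc[keep])


def rpkm(
    counts: pd.DataFrame,
    lengths_bp: pd.Series,
    mapped_totals: pd.Series,
    families: pd.Series | None = None,
    groups: pd.Series | None = None,
) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million normalisation,
    ``10^9 * count / (mapped_total * length_bp)``.
    """
    bad_len = lengths_bp.reindex(counts.index)
    if bad_len.isna().any() or (bad_len <= 0).any():
        g = bad_len.index[bad_len.isna() | (bad_len <= 0)][0]
        raise ValidationError(f"nonpositive or missing length for gene {g!r}")
    bad_tot = mapped_totals.reindex(counts.columns)
    if bad_tot.isna().any() or (bad_tot <= 0).any():
        s = bad_tot.index[bad_tot.isna() | (bad_tot <= 0)][0]
        raise ValidationError(f"nonpositive or missing mapped total for sample {s!r}")
    values = 1e9 * counts.div(bad_tot, axis=1).div(bad_len, axis=0)
    if families is None:
        families = pd.Series("other", index=counts.index)
    if groups is None:
        groups = pd.Series("all", index=counts.columns)
    return ExpressionMatrix(
        rpkm=values,
        families=families,
        groups=groups,
        counts=counts,
        lengths_bp=lengths_bp,
        mapped_totals=mapped_totals,
    )


def expressed_genes(e: ExpressionMatrix, min_rpkm: float = 1.0) -> set:
    """Genes reaching ``min_rpkm`` (inclusive) in at least one sample."""
    keep = (e.rpkm >= min_rpkm).any(axis=1)
    return set(e.rpkm.index[keep])


def differential_expression(
    e: ExpressionMatrix,
    numerator: str = "MC",
    reference: str = "LC",
    alpha: float = 0.05,
    adjust: str = "none",
    expressed: set | None = None,
) -> pd.DataFrame:
    """Two-group Welch t-test per gene on log2(RPKM + 1).

    Returns a frame indexed by gene with group means (RPKM scale), log2 fold
    change (numerator vs reference, computed on the log2(RPKM+1) scale),
    p-value, BH q-value, and a ``significant`` flag using the (adjusted)
    p < alpha criterion.
    """
    if adjust not in ("none", "BH"):
        raise ValidationError(f"unknown adjustment {adjust!r}")
    if expressed is None:
        expressed = expressed_genes(e)
    genes = [g for g in e.rpkm.index if g in expressed]
    groups = e.groups.reindex(e.rpkm.columns)
    idx_n = groups[groups == numerator].index
    idx_r = groups[groups == reference].index
    if len(idx_n) < 2 or len(idx_r) < 2:
        raise ValidationError("differential expression needs >= 2 samples per group")
    log2 = np.log2(e.rpkm.loc[genes] + 1.0)
    rows = []
    for g in genes:
        xn = log2.loc[g, idx_n].to_numpy()
        xr = log2.loc[g, idx_r].to_numpy()
        _, p = welch_t_test(xn, xr)
        rows.append(
            {
                "gene": g,
                f"mean_{numerator}": e.rpkm.loc[g, idx_n].mean(),
                f"mean_{reference}": e.rpkm.loc[g, idx_r].mean(),
                "log2fc": xn.mean() - xr.mean(),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    if len(out):
        out["q"] = false_discovery_control(out["p"].to_numpy(), method="bh")
        crit = out["q"] if adjust == "BH" else out["p"]
        out["significant"] = crit < alpha
    else:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def family_expression_summary(
    e: ExpressionMatrix,
    expressed: set | None = None,
    milestones: tuple = (10.0, 100.0),
) -> pd.DataFrame:
    """Per gene family: number of expressed members, the member with the
    highest maximum RPKM, and the members exceeding each RPKM milestone.
    """
    if expressed is None:
        expressed = expressed_genes(e)
    fam = e.families.reindex(e.rpkm.index)
    rows = {}
    for family in sorted(fam.unique()):
        members = [g for g in e.rpkm.index[fam == family] if g in expressed]
        row = {"n_expressed": len(members)}
        if members:
            maxima = e.rpkm.loc[members].max(axis=1)
            row["top_gene"] = maxima.idxmax()
            for m in milestones:
                row[f"members_ge_{m:g}"] = sorted(maxima.index[maxima >= m])
        else:
            row["top_gene"] = None
            for m in milestones:
                row[f"members_ge_{m:g}"] = []
        rows[family] = row
    return pd.DataFrame(rows).T
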