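"""Multi-omics integration: SCFA statistics and molar proportions, the
OTU-vs-SCFA rank-correlation screen, and constrained correspondence analysis
(CCA) relating taxa to SCFA proportions and receptor/deacetylase expression.

CCA is implemented directly from the chi-square standardised residual matrix:
the community table is double-centred under the independence model, projected
onto the weighted span of the environmental constraints, and the projection is
decomposed by SVD; the residual gives the unconstrained axes, so constrained
plus unconstrained inertia always equals the table's total inertia (chi-square
statistic over the grand total).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .abundance import AbundanceTable, _rank_labels
from .coexpression import DEFAULT_EXACT_LIMIT, spearman_test
from .diversity import welch_t_test
from .errors import UndefinedCorrelationError, ValidationError
from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

#: The six short-chain fatty acids, concentration columns of a SCFA table.
SCFAS = ("acetate", "propionate", "butyrate", "valerate", "isobutyrate", "isovalerate")
TIME_POINTS = (0, 2, 5, 8)


@dataclass(frozen=True)
class ScfaProfile:
    """Per sample x time point SCFA concentrations (mmol/L) and pH.

    ``data`` is tidy: columns ``sample``, ``time_h``, the six SCFAs, ``pH``,
    and ``total`` (computed as the sum of the six when absent).
    """

    data: pd.DataFrame
    groups: pd.Series  # sample -> group label

    def __post_init__(self) -> None:
        required = {"sample", "time_h", *SCFAS}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"SCFA table missing columns: {sorted(missing)}")
        conc = self.data[list(SCFAS)].to_numpy(float)
        if (conc < 0).any():
            raise ValidationError("SCFA concentrations must be nonnegative")
        if "total" in self.data.columns:
            if not np.allclose(self.data["total"], conc.sum(axis=1), atol=1e-6):
                raise ValidationError("total column inconsistent with the six SCFAs")
        else:
            object.__setattr__(
                self, "data", self.data.assign(total=conc.sum(axis=1))
            )
        unknown = set(self.data["sample"]) - set(self.groups.index)
        if unknown:
            raise ValidationError(f"samples without group label: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list:
        return sorted(set(self.data["sample"]))

    @property
    def time_points(self) -> list:
        return sorted(set(self.data["time_h"]))

    def at_time(self, time_h) -> pd.DataFrame:
        sub = self.data[self.data["time_h"] == time_h]
        if sub.empty:
            raise ValidationError(f"time point {time_h} not present (have {self.time_points})")
        return sub.set_index("sample")


def molar_proportions(s: ScfaProfile, time_point=8) -> pd.DataFrame:
    """Per-sample fraction of each SCFA in the total at ``time_point``.

    Rows sum to one; a zero total leaves the proportion undefined and raises.
    """
    sub = s.at_time(time_point)
    conc = sub[list(SCFAS)]
    totals = conc.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"zero total SCFA for samples {zero} at {time_point} h")
    return conc.div(totals, axis=0)


def one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classic fixed-effects one-way ANOVA from between/within sums of squares.

    Zero between- and within-group variability returns F = 0, p = 1.
    """
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("ANOVA needs >= 2 cells with >= 2 observations each")
    all_values = np.concatenate(groups)
    grand = all_values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_values) - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(f_dist.sf(f, df_between, df_within))
    return float(f), p


def scfa_group_stats(
    s: ScfaProfile, proportion_time: int = 8
) -> pd.DataFrame:
    """Fermentation-profile statistics mirroring a two-diet time-course design.

    Per analyte (six SCFAs, total, pH): a one-way ANOVA across time points
    within each group, a between-group Welch t-test at each time point, and
    between-group t-tests on the molar proportions at ``proportion_time``.
    Degenerate cells (fewer than 2 observations) are flagged missing (NaN).
    """
    names = sorted(s.groups.unique())
    if len(names) != 2:
        raise ValidationError(f"SCFA group stats require exactly 2 groups, found {names}")
    analytes = list(SCFAS) + ["total"] + (["pH"] if "pH" in s.data.columns else [])
    rows = []
    for analyte in analytes:
        for g in names:
            cells = []
            ok = True
            for t in s.time_points:
                sub = s.at_time(t)
                vals = sub.loc[sub.index.isin(s.groups.index[s.groups == g]), analyte]
                vals = vals.dropna().to_numpy()
                if len(vals) < 2:
                    ok = False
                cells.append(vals)
            if ok and len(cells) >= 2:
                f, p = one_way_anova(cells)
            else:
                f, p = np.nan, np.nan
            rows.append(
                {"analyte": analyte, "test": "anova_time", "group": g,
                 "time_h": np.nan, "statistic": f, "p": p}
            )
        for t in s.time_points:
            sub = s.at_time(t)
            vals = [
                sub.loc[sub.index.isin(s.groups.index[s.groups == g]), analyte]
                .dropna().to_numpy()
                for g in names
            ]
            if all(len(v) >= 2 for v in vals):
                stat, p = welch_t_test(vals[0], vals[1])
            else:
                stat, p = np.nan, np.nan
            rows.append(
                {"analyte": analyte, "test": "ttest_group", "group": None,
                 "time_h": t, "statistic": stat, "p": p}
            )
    props = molar_proportions(s, proportion_time)
    for scfa in SCFAS:
        vals = [
            props.loc[props.index.isin(s.groups.index[s.groups == g]), scfa].to_numpy()
            for g in names
        ]
        if all(len(v) >= 2 for v in vals):
            stat, p = welch_t_test(vals[0], vals[1])
        else:
            stat, p = np.nan, np.nan
        rows.append(
            {"analyte": scfa, "test": "ttest_proportion", "group": None,
             "time_h": proportion_time, "statistic": stat, "p": p}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the OTU-vs-SCFA molar-proportion correlation screen."""

    retained: set
    n_input: int
    best: pd.DataFrame  # per retained OTU: best (rho, p, scfa)
    dropped_constant: tuple

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def removed_fraction(self) -> float:
        if self.n_input == 0:
            return float("nan")  # 0/0 sentinel: nothing to remove
        return 1.0 - self.n_retained / self.n_input


def otu_scfa_screen(
    a: AbundanceTable,
    m: pd.DataFrame,
    rho_min: float = 0.6,
    p_max: float = 0.05,
    absolute: bool = False,
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> ScreenResult:
    """Dimensionality reduction of the community table: keep an OTU iff its
    abundance has Spearman rho > ``rho_min`` (signed unless ``absolute``) and
    p < ``p_max`` against at least one SCFA molar proportion.

    ``m`` is the molar-proportion frame (samples x SCFAs) aligned on sample
    ids with ``a``.  Constant abundance vectors have no defined correlation
    and are removed with a log message.
    """
    samples = [sid for sid in a.sample_ids if sid in set(m.index)]
    if a.fractions.shape[1] and len(samples) != len(a.sample_ids):
        missing = sorted(set(a.sample_ids) - set(samples))
        raise ValidationError(f"samples without molar proportions: {missing}")
    retained = set()
    rows = []
    dropped = []
    mm = m.loc[samples]
    for otu in a.fractions.columns:
        x = a.fractions.loc[samples, otu].to_numpy(float)
        best = None
        try:
            for scfa in mm.columns:
                res = spearman_test(x, mm[scfa].to_numpy(float), exact_limit=exact_limit)
                size = abs(res.rho) if absolute else res.rho
                if size > rho_min and res.p_value < p_max:
                    if best is None or abs(res.rho) > abs(best[1]):
                        best = (scfa, res.rho, res.p_value)
        except UndefinedCorrelationError:
            dropped.append(otu)
            logger.info("screen: OTU %s dropped (constant abundance vector)", otu)
            continue
        if best is not None:
            retained.add(otu)
            rows.append({"otu": otu, "scfa": best[0], "rho": best[1], "p": best[2]})
    best_frame = pd.DataFrame(rows, columns=["otu", "scfa", "rho", "p"])
    n_input = a.fractions.shape[1]
    logger.info(
        "screen: removed %d/%d OTUs (%.0f%%)",
        n_input - len(retained), n_input,
        100.0 * (1 - len(retained) / n_input) if n_input else float("nan"),
    )
    return ScreenResult(
        retained=retained, n_input=n_input, best=best_frame, dropped_constant=tuple(dropped)
    )


@dataclass(frozen=True)
class CcaResult:
    """Eigen-decomposition of a constrained correspondence analysis."""

    eigenvalues: np.ndarray  # constrained, descending
    unconstrained_eigenvalues: np.ndarray
    total_inertia: float
    constrained_inertia: float
    unconstrained_inertia: float
    site_scores_lc: pd.DataFrame  # linear-combination (standard) coordinates
    site_scores_wa: pd.DataFrame  # weighted-average coordinates
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    rank: int
    row_weights: pd.Series
    col_weights: pd.Series


def cca(
    y: pd.DataFrame,
    x: pd.DataFrame,
    standardize: bool = True,
    axis_tol: float = 1e-10,
) -> CcaResult:
    """Constrained correspondence analysis of a nonnegative community table
    ``y`` (samples x species) on environmental constraints ``x``.

    Constraints are weighted-centred (and by default standardised to unit
    weighted variance); projection uses a pseudo-inverse so rank-deficient
    constraint sets are handled, with the effective rank reported.  When the
    constraints span the full site space (rank = n_samples - 1) the analysis
    degenerates to plain correspondence analysis and a warning is issued.
    """
    yv = np.asarray(y, float)
    if (yv < 0).any():
        raise ValidationError("community table must be nonnegative")
    if yv.sum() <= 0:
        raise ValidationError("community table has zero grand total")
    row_ok = yv.sum(axis=1) > 0
    col_ok = yv.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn(
            f"dropping {int((~row_ok).sum())} zero-sum rows and "
            f"{int((~col_ok).sum())} zero-sum columns", stacklevel=2
        )
    rows = list(np.asarray(y.index)[row_ok])
    cols = list(np.asarray(y.columns)[col_ok])
    yv = yv[np.ix_(row_ok, col_ok)]
    xv = np.asarray(x, float)
    if xv.shape[0] != len(row_ok):
        raise ValidationError("constraint rows must align with community samples")
    xv = xv[row_ok]

    total = yv.sum()
    p = yv / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    expected = np.outer(r, c)
    q = (p - expected) / np.sqrt(expected)
    total_inertia = float((q**2).sum())

    xc = xv - r @ xv
    if standardize:
        sd = np.sqrt(r @ (xc**2))
        keep = sd > 1e-12
        if not keep.all():
            warnings.warn("dropping constant constraint columns", stacklevel=2)
        xc = xc[:, keep] / sd[keep]
        constraint_names = list(np.asarray(x.columns)[keep])
    else:
        constraint_names = list(x.columns)
    xw = np.sqrt(r)[:, None] * xc
    rank = int(np.linalg.matrix_rank(xw))
    if rank >= len(rows) - 1:
        warnings.warn(
            "constraints span the full site space (rank = n - 1); "
            "CCA degenerates to unconstrained correspondence analysis",
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(xw, q, rcond=None)
    q_fit = xw @ beta
    u, s, vt = np.linalg.svd(q_fit, full_matrices=False)
    keep_ax = s**2 > axis_tol * max(total_inertia, 1.0)
    eig = s[keep_ax] ** 2
    u = u[:, keep_ax]
    v = vt[keep_ax].T
    q_res = q - q_fit
    _, s_res, _ = np.linalg.svd(q_res, full_matrices=False)
    eig_res = s_res[s_res**2 > axis_tol * max(total_inertia, 1.0)] ** 2

    axes = [f"CCA{i + 1}" for i in range(len(eig))]
    sqrt_r = np.sqrt(r)[:, None]
    sqrt_c = np.sqrt(c)[:, None]
    species = pd.DataFrame(v / sqrt_c, index=cols, columns=axes)
    site_lc = pd.DataFrame(u / sqrt_r, index=rows, columns=axes)
    # weighted averages of species scores = D_r^{-1/2} Q V
    site_wa = pd.DataFrame((q @ v) / sqrt_r, index=rows, columns=axes)
    # biplot arrows: weighted correlation of constraints with LC site axes
    col_norm = np.sqrt((xw**2).sum(axis=0))
    biplot = pd.DataFrame(
        (xw.T @ u) / col_norm[:, None], index=constraint_names, columns=axes
    )
    return CcaResult(
        eigenvalues=eig,
        unconstrained_eigenvalues=eig_res,
        total_inertia=total_inertia,
        constrained_inertia=float((q_fit**2).sum()),
        unconstrained_inertia=float((q_res**2).sum()),
        site_scores_lc=site_lc,
        site_scores_wa=site_wa,
        species_scores=species,
        biplot_scores=biplot,
        rank=rank,
        row_weights=pd.Series(r, index=rows),
        col_weights=pd.Series(c, index=cols),
    )


def genus_centroids(
    res: CcaResult, taxonomy: pd.DataFrame, weighting: str = "abundance"
) -> pd.DataFrame:
    """Centroid of each genus's member-OTU species scores on the CCA axes.

    ``abundance`` weighting uses the OTUs' column masses from the analysed
    table; ``uniform`` takes a plain mean.  Genera with no retained OTUs are
    absent from the result.
    """
    if weighting not in ("abundance", "uniform"):
        raise ValidationError(f"unknown weighting {weighting!r}")
    otus = res.species_scores.index
    labels = _rank_labels(taxonomy.loc[otus], "genus")
    weights = (
        res.col_weights.reindex(otus)
        if weighting == "abundance"
        else pd.Series(1.0, index=otus)
    )
    rows = {}
    for genus, members in res.species_scores.groupby(labels.to_numpy()):
        w = weights.loc[members.index].to_numpy()
        rows[genus] = (members.to_numpy() * w[:, None]).sum(axis=0) / w.sum()
    return pd.DataFrame(rows, index=res.species_scores.columns).T


def association_signs(
    m: pd.DataFrame,
    e: ExpressionMatrix,
    a: AbundanceTable,
    pairs: list[tuple],
    exact_limit: int = DEFAULT_EXACT_LIMIT,
) -> pd.DataFrame:
    """Signed Spearman associations between named variables.

    A variable name resolves to a SCFA molar proportion (column of ``m``),
    a gene's RPKM row, or a taxon column of ``a`` (typically genus level).
    Unknown names raise with the candidate lists.  Samples are aligned on
    the intersection used by all three tables.
    """
    samples = [s for s in m.index if s in set(e.sample_ids) and s in set(a.sample_ids)]
    if len(samples) < 3:
        raise ValidationError("fewer than 3 shared samples across the three tables")

    def resolve(name):
        if name in m.columns:
            return m.loc[samples, name].to_numpy(float)
        if name in e.rpkm.index:
            return e.rpkm.loc[name, samples].to_numpy(float)
        if name in a.fractions.columns:
            return a.fractions.loc[samples, name].to_numpy(float)
        raise ValidationError(
            f"unknown variable {name!r}; candidates are SCFAs {list(m.columns)}, "
            f"genes like {list(e.rpkm.index[:5])}, taxa like {list(a.fractions.columns[:5])}"
        )

    rows = []
    for name1, name2 in pairs:
        res = spearman_test(resolve(name1), resolve(name2), exact_limit=exact_limit)
        rows.append(
            {
                "var1": name1,
                "var2": name2,
                "rho": res.rho,
                "p": res.p_value,
                "method": res.method,
                "sign": int(np.sign(res.rho)),
            }
        )
    return pd.DataFrame(rows)
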