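"""Community diversity and ordination: Shannon/Simpson indices, Bray-Curtis
dissimilarity, non-metric multidimensional scaling (NMDS), and analysis of
similarities (ANOSIM).

The dissimilarity, the NMDS loop (Kruskal stress-1 minimised by SMACOF
majorisation with isotonic disparities), and the ANOSIM permutation test are
implemented here directly; scipy supplies only rank/isotonic primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression
from scipy.stats import rankdata, t as t_dist

from .abundance import AbundanceTable, _rank_labels
from .errors import ValidationError


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric dissimilarity matrix with named samples."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.ids):
            raise ValidationError("distance matrix must be square and match ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS configuration with its Kruskal stress-1 and search metadata."""

    coordinates: pd.DataFrame  # samples x k
    stress: float
    n_starts: int
    best_start: int
    converged: bool
    stress_history: tuple  # stress sequence of the best start


@dataclass(frozen=True)
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int


def shannon(p: np.ndarray) -> float:
    """Shannon entropy in nats over the nonzero entries of ``p``."""
    p = np.asarray(p, float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(p: np.ndarray) -> float:
    """Gini-Simpson index, ``1 - sum(p_i^2)``."""
    p = np.asarray(p, float)
    return float(1.0 - (p**2).sum())


def alpha_diversity(
    a: AbundanceTable, rank: str | None = None, taxon=None
) -> pd.DataFrame:
    """Per-sample Shannon (nats) and Gini-Simpson indices.

    With ``rank``/``taxon`` given, indices are computed within that clade:
    member-OTU abundances are renormalised to sum to one inside each sample
    first.  A sample where the clade is absent gets NaN (missing), not zero.
    """
    frac = a.fractions
    if taxon is not None:
        if a.taxonomy is None:
            raise ValidationError("within-taxon diversity needs an OTU-level table")
        labels = _rank_labels(a.taxonomy.loc[frac.columns], rank)
        frac = frac.loc[:, (labels == taxon).to_numpy()]
    out = {}
    for s, row in frac.iterrows():
        p = row.to_numpy(float)
        total = p.sum()
        if total <= 0:
            out[s] = (np.nan, np.nan)
        else:
            p = p / total
            out[s] = (shannon(p), simpson(p))
    return pd.DataFrame(out, index=["shannon", "simpson"]).T


def welch_t_test(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Welch two-sample t-test (unequal variances).

    Degenerate convention: if both groups have zero variance, p is 1 for
    equal means and 0 otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Welch t-test needs at least 2 samples per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        return (0.0, 1.0) if x.mean() == y.mean() else (math.inf, 0.0)
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / (vx**2 / (len(x) ** 2 * (len(x) - 1)) + vy**2 / (len(y) ** 2 * (len(y) - 1)))
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), float(p)


def diversity_group_test(alpha: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Welch t-test comparing each diversity index between two groups.

    NaN index values (clade absent in a sample) are dropped per index.
    """
    names = sorted(groups.unique())
    if len(names) != 2:
        raise ValidationError(f"diversity test requires exactly 2 groups, found {names}")
    rows = {}
    for index in alpha.columns:
        vals = alpha[index].dropna()
        g1 = vals[groups.reindex(vals.index) == names[0]].to_numpy()
        g2 = vals[groups.reindex(vals.index) == names[1]].to_numpy()
        t, p = welch_t_test(g1, g2)
        rows[index] = {"t": t, "p": p}
    return pd.DataFrame(rows).T


def bray_curtis(a: AbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, ``sum|x-y| / sum(x+y)``."""
    x = a.fractions.to_numpy(float)
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = (x[i] + x[j]).sum()
            if denom == 0:
                raise ValidationError(
                    f"Bray-Curtis undefined for all-zero pair "
                    f"({a.sample_ids[i]!r}, {a.sample_ids[j]!r})"
                )
            d[i, j] = d[j, i] = np.abs(x[i] - x[j]).sum() / denom
    return DistanceMatrix(ids=tuple(a.sample_ids), values=d)


def _pdist(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    diff = x[iu[0]] - x[iu[1]]
    return np.sqrt((diff**2).sum(axis=1))


def _nmds_single(
    d: np.ndarray, n: int, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, float, list, bool]:
    iu = np.triu_indices(n, k=1)
    x = rng.normal(size=(n, k))
    best = (math.inf, x)
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        delta = _pdist(x)
        if (delta == 0).any():
            x = x + rng.normal(scale=1e-8, size=x.shape)
            delta = _pdist(x)
        # Kruskal's primary treatment of ties: within equal input
        # dissimilarities the fit is free, realised by ordering tied pairs
        # by their current configuration distance before the PAV fit.
        order = np.lexsort((delta, d))
        dhat = np.empty_like(delta)
        dhat[order] = isotonic_regression(delta[order]).x
        dhat *= math.sqrt((delta**2).sum() / max((dhat**2).sum(), 1e-300))
        stress = math.sqrt(((dhat - delta) ** 2).sum() / (delta**2).sum())
        if stress < best[0]:
            best = (stress, x.copy())
        if history and stress >= history[-1] - tol:
            if stress <= history[-1]:
                history.append(stress)
            converged = True
            break
        history.append(stress)
        # Guttman transform (SMACOF majorisation step).
        ratio = np.zeros((n, n))
        ratio[iu] = dhat / delta
        ratio += ratio.T
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x = b @ x / n
        x -= x.mean(axis=0)
    return best[1], best[0], history, converged


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_starts: int = 8,
    max_iter: int = 500,
    tol: float = 1e-10,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1 over ``n_starts`` random
    Gaussian initialisations; deterministic given ``seed``.
    """
    if k >= d.n:
        raise ValidationError(f"k={k} must be smaller than the number of samples ({d.n})")
    dv = d.condensed()
    ss = np.random.SeedSequence(seed)
    best = None
    for start, child in enumerate(ss.spawn(n_starts)):
        rng = np.random.default_rng(child)
        x, stress, history, conv = _nmds_single(dv, d.n, k, rng, max_iter, tol)
        if best is None or stress < best[1]:
            best = (x, stress, history, conv, start)
    x, stress, history, conv, start = best
    coords = pd.DataFrame(
        x, index=list(d.ids), columns=[f"NMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(
        coordinates=coords,
        stress=float(stress),
        n_starts=n_starts,
        best_start=start,
        converged=conv,
        stress_history=tuple(history),
    )


def anosim_r(d: DistanceMatrix, groups: pd.Series) -> float:
    """The ANOSIM R statistic: mean rank dissimilarity between groups minus
    within groups, scaled by M/2 with M = n(n-1)/2 pairs, so R is in [-1, 1].
    """
    labels = groups.reindex(list(d.ids)).to_numpy()
    return _anosim_r_from_ranks(rankdata(d.condensed()), _between_mask(labels, d.n))


def _between_mask(labels: np.ndarray, n: int) -> np.ndarray:
    iu = np.triu_indices(n, k=1)
    return labels[iu[0]] != labels[iu[1]]


def _anosim_r_from_ranks(ranks: np.ndarray, between: np.ndarray) -> float:
    m = len(ranks)
    rb = ranks[between].mean()
    rw = ranks[~between].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    d: DistanceMatrix, groups: pd.Series, n_perm: int = 999, seed: int = 0
) -> AnosimResult:
    """ANOSIM permutation test for group separation in a dissimilarity matrix.

    p-value uses the (1 + exceedances) / (1 + n_perm) convention so it is
    never zero.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    labels = groups.reindex(list(d.ids)).to_numpy()
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValidationError("ANOSIM needs >= 2 groups with >= 2 samples each")
    ranks = rankdata(d.condensed())
    observed = _anosim_r_from_ranks(ranks, _between_mask(labels, d.n))
    rng = np.random.default_rng(seed)
    exceed = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        r = _anosim_r_from_ranks(ranks, _between_mask(perm_labels, d.n))
        if r >= observed - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return AnosimResult(r=observed, p_value=float(p), n_permutations=n_perm, seed=seed)
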